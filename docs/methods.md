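# Methods

This note documents the models and procedures implemented in `phytogrowth`,
the choices made where several defensible options existed, and the limits of
what the synthetic-data benchmarks demonstrate.

## Hydrographic reductions

**Density.** σ<sub>t</sub> is the EOS-80 one-atmosphere density anomaly
(UNESCO/Millero–Poisson polynomial) evaluated at pressure 0 — the
conventional σ<sub>t</sub>, not in-situ or TEOS-10 density. The
implementation reproduces the standard's published check values
(σ<sub>t</sub>(35, 5) = 27.67547, σ<sub>t</sub>(0, 5) = −0.03325,
σ<sub>t</sub>(35, 25) = 23.34306 kg m⁻³) to better than 10⁻⁵. Validity is
enforced over S ∈ [0, 42], T ∈ [−2, 40].

**Surface value.** "Surface" always means the shallowest sampled level
(required to be ≤ 5 m), never an extrapolation to 0 m; this matches CTD
practice and avoids inventing data above the first bottle.

**Mixed-layer depth.** UMLz is the first depth at which σ<sub>t</sub>
exceeds the surface value by a threshold, 0.125 kg m⁻³ by default. The
crossing is located by linear interpolation between the bracketing samples;
a discrete variant (first *sampled* depth past the threshold,
`interpolate=False`) is provided for comparison with coarser conventions.
Interpolation was chosen because it removes grid-resolution artifacts: the
answer is then a property of the water column, not of the bottle spacing.
If the threshold is never reached the deepest sampled depth is returned with
an explicit `uml_not_reached` flag rather than an error, because weakly
stratified polar stations (Δσ<sub>t</sub> ≈ 0.02 kg m⁻³) are legitimate
inputs that must flow through the pipeline.

**Euphotic depth.** 1%PARz interpolates linearly in log PAR versus depth,
which is exact for exponentially attenuated light whatever the sampling
grid (a property the test suite asserts to 10⁻⁶ m). Profiles that never
reach the 1% level return the deepest lit depth with `par_floor_not_reached`.

**Stratification index.** Δσ<sub>t</sub> = σ<sub>t</sub>(1%PARz) −
σ<sub>t</sub>(surface), interpolated linearly. Negative values (density
inversions) are returned as computed; the caller decides.

**Nitrate at the euphotic base.** Linear interpolation at 1%PARz over the
levels with nitrate data. Values below the analytical detection limit
(0.05 µmol L⁻¹) are replaced by the limit itself — a conservative,
traceable upper bound that keeps the supply index finite — and flagged
`no3_censored`. An interpolated value ≤ 0.2 µmol L⁻¹ triggers a QC
*warning* (not an error): such values are unusually low for the base of the
euphotic layer and usually indicate a profile problem.

## Resource supply index

RSI = (NO₃ at 1%PARz / Δσ<sub>t</sub>) × (1%PARz / UMLz), in mmol N kg⁻¹
(µmol L⁻¹ per kg m⁻³ ≡ mmol m⁻³ per kg m⁻³). The first factor grows with
the nutrient reservoir below the lit layer and shrinks as stratification
suppresses vertical exchange; the second is the light-climate factor, large
when cells sit in a shallow mixed layer relative to the lit depth. It is a
*comparative* index for contrasting hydrographic regimes, not an estimate of
nutrient flux.

Two exclusion rules apply. Iron-limited Southern Ocean stations are excluded
by region label: where iron, not nitrogen or light, limits growth, the index
does not measure the limiting resource. Independently, stations with
Δσ<sub>t</sub> below a configurable floor (default 0.05 kg m⁻³) are marked
excluded because the index diverges as stratification vanishes; the numeric
value is still reported for inspection. The floor value is a package choice
(the weakly stratified polar group spans Δσ<sub>t</sub> 0.02–0.23 kg m⁻³,
and the index is undefined in spirit as Δσ<sub>t</sub> → 0).

## Rate metrics

P<sup>C</sup> = P / C (d⁻¹) is the carbon-specific daily fixation rate,
equivalent to the community's intrinsic growth rate under balanced growth;
C:Chl *a* = C / chl. Both are always recomputed from the primary fields.
Biovolume→carbon conversion uses per-group power laws
(pgC cell⁻¹ = a·V^b): diatom (0.288, 0.811) and non-diatom (0.216, 0.939)
protist fits, and a linear 0.23 pgC µm⁻³ factor for picophytoplankton.
These are literature-standard defaults shipped as *configuration* (any
`group,a,b` CSV can replace them), because conversion coefficients are
protocol-dependent. The synthetic pipeline generates carbon biomass
directly and does not exercise this conversion; it exists for real-data use
and is unit-tested standalone.

## Statistics

**Reduced major axis.** The scaling fits are model-II regressions on log₁₀
variables: slope = sign(r)·sd(y)/sd(x) with sample (n−1) SDs, intercept
through the means. RMA is appropriate because both variables (production,
biomass, chlorophyll) carry comparable measurement error; the test suite
cross-checks the slope against the OLS geometric-mean identity and the
x↔y duality.

**Bootstrap.** Confidence intervals resample *cases* (stations) with
replacement, 2000 draws by default, percentile interval. Percentile was
chosen as the plainest reading of "bootstrapping over cases"; BCa is
available behind `method="bca"`. Resamples with zero variance in either
variable are redrawn and counted; more than 10% of them aborts with an
instability error rather than reporting a meaningless interval. All
resampling is driven by an explicit seed — there is no global random state
— so reports are byte-identical across runs. Simulated coverage of the 95%
interval at n = 60 is verified to lie in 92–98%.

**Mann-Whitney U.** The standard rank-sum test with midrank ties: exact
p by enumeration when the pooled sample is tie-free and n₁n₂ ≤ 400,
otherwise the normal approximation with tie and continuity corrections.
All comparisons are two-sided. Note the named test compares stochastic
ordering (rank sums), which is the conventional non-parametric reading of
"comparing means"; it is not a t-test. No multiple-testing correction is
applied to the pairwise bin comparisons — they are reported raw.

**Chlorophyll bins.** Right-open intervals [lo, hi) over 0, 0.2, 0.5, 2, 5
mg m⁻³ with a final (5, ∞) class, so a station at exactly 0.2 falls in
0.2–0.5. The boundary convention is arbitrary; it is documented here and
configurable.

## Synthetic data generator

The generator's defaults are the study conditions: eight regional groups
with the published station counts (8, 4, 5, 13, 8, 26, 6, 2; Σ = 72) and
the published mean ± SD of temperature, NO₃ at the euphotic base,
Δσ<sub>t</sub>, euphotic and mixed-layer depths, chlorophyll, phytoplankton
carbon and primary production.

**Marginals.** Positive, strongly skewed quantities are lognormal with
moments matched exactly (σ² = ln(1 + s²/m²), µ = ln m − σ²/2). Normals are
infeasible here: several groups have SD ≈ mean (coastal production
248 ± 271 mgC m⁻³ d⁻¹) and would go negative. Temperature is normal
truncated to the physical range (−2, 40 °C); the truncation bias is
negligible (every regional mean is ≥ 5σ from the bounds).

**Within-region correlation.** log C, log P and log chl share a Gaussian
copula with chain structure corr(logC, logP) = corr(logC, logchl) = 0.9 and
corr(logP, logchl) = 0.81 (production and chlorophyll couple only through
carbon). The 0.9 value is the single structural knob: the published tables
say nothing about station-level scatter, so it was fixed once, a priori, at
a value that makes region clouds elongated along the global relation — and
it is exposed as configuration (`log_cp_correlation`,
`log_cchl_correlation`). A direct coupling of chlorophyll to carbon through
multiplicative noise was rejected because it cannot *reduce* the coefficient
of variation: one region (equatorial upwelling) has chl CV smaller than
carbon CV, which that construction cannot reach, whereas matched marginals
plus a copula recover every printed moment exactly in expectation.
P<sup>C</sup> is always computed as P/C, never drawn, so claims about
turnover are honest consequences of the generator. Hydrographic targets are
drawn independently of the biology and of each other; Δσ<sub>t</sub> draws
are capped at 6 kg m⁻³ (a physical ceiling that keeps the implied deep
density within the equation of state's invertible envelope; exceedance
probability < 4·10⁻⁴ everywhere, so moments are unaffected in practice).

**Profiles by inversion.** Each station's profile is constructed so that
the *package's own* reductions recover the drawn targets: a piecewise-linear
σ<sub>t</sub> shape whose interpolated 0.125-crossing sits exactly at the
target UMLz and whose value at the target 1%PARz exceeds the surface by
exactly Δσ<sub>t</sub>; temperature (and, for very dense targets, salinity)
obtained by root-finding against the EOS-80 code to 10⁻⁴; exponential PAR
with the 1% level at the target depth; a logistic nitracline centred on the
euphotic depth hitting the nitrate target there. When Δσ<sub>t</sub> <
0.125 kg m⁻³ the crossing necessarily lies below the euphotic depth — the
deeply mixed polar regime. A monotone density profile cannot honour every
independent draw: Δσ<sub>t</sub> ≥ 0.125 forces UMLz ≤ 1%PARz and vice
versa. Draws are left unconstrained (so the printed moments are preserved);
an infeasible combination is resolved in profile construction by moving the
mixed-layer target to 0.95× (or 1.05×) the euphotic depth while honouring
the other three targets exactly. The round-trip guarantee
(derive ∘ build = identity within UMLz ± 1 m, 1%PARz ± 0.5 m,
Δσ<sub>t</sub> ± 0.01 kg m⁻³, NO₃ ± 0.05 µmol L⁻¹) therefore applies to
feasible target sets, which is what the test suite draws.

**What the benchmarks show — and don't.** With no cross-region structure
imposed, the pipeline recovers superlinear production–biomass scaling
(slope ≈ 1.47, CI above 1 in every tested seed), production–chl ≈ 1.30,
sublinear carbon–chl ≈ 0.89, a near-zero temperature correlation of
P<sup>C</sup> (r ≈ −0.13), and a positive RSI correlation (r ≈ 0.35–0.5)
— i.e. the headline pattern emerges from the between-region contrast of the
printed summaries plus within-region lognormal scatter alone. That is a
*consistency* demonstration, not a reanalysis: the generator knows nothing
about real within-region covariance (e.g. nitrate–stratification coupling),
seasonal or spatial autocorrelation, T–S covariation, or iron chemistry.
Quantities that sit near a boundary in the real data sit near it here too:
the mean P<sup>C</sup> of high-chlorophyll bins exceeds 1.2 d⁻¹ only
marginally (the coastal mean P/C is ≈ 1.23), and the coastal-to-oligotrophic
production ratio scatters widely around ~110 because coastal production has
CV ≈ 1.1 at n = 26. One emergent artifact deserves note: within RSI strata
the OLS of P<sup>C</sup> on temperature can come out weakly negative and
nominally significant in synthetic data, because a stratum mixes regions
whose temperature and turnover differ jointly; the generator has no
within-region temperature effect to detect, and the strata inherit
between-region contrast instead. Real-data strata need not behave this way.

## Numerical and degenerate-input choices

- All interpolation is linear (log-linear for PAR); no smoothing or QC
  (spike removal, sensor drift) is applied — inputs are assumed clean.
- Profile validation requires ≥ 2 strictly increasing depths, a surface
  sample ≤ 5 m, positive PAR, non-negative nitrate; readers sort rows before
  validation, so row order in CSVs is immaterial.
- Zero variance raises a degenerate-data error in every fit; fits inside
  the pipeline record the reason and the run continues.
- A station missing an optional input is dropped from the affected analysis
  only, and every reported statistic carries its own n.
- Root-finding (profile inversion) uses Brent's method with 10⁻⁹
  tolerances; the test suite checks the realised σ<sub>t</sub> against the
  intended structure to 10⁻⁴.

## Problem sizes

Default analyses run 72 stations with 2000 bootstrap resamples. The
multi-seed benchmarks in the test suite and the acceptance script use 20
seeds with 500 resamples per fit, which characterises the seed-to-seed
spread of every reported statistic while keeping a full run around half a
minute; bootstrap resampling is vectorised, so larger values change little.

## Known limitations

- EOS-80, not TEOS-10; pressure effects ignored (surface-referenced
  σ<sub>t</sub> only). Appropriate for mixed-layer work, not for deep
  stratification.
- The carbon conversion table is a stand-in for protocol-specific
  coefficients; real analyses should supply their own.
- The synthetic generator reproduces first and second moments and one
  correlation knob per pair — not tails, not joint hydrographic structure.
- Mann-Whitney p-values with heavy ties rely on the normal approximation;
  exact-with-ties enumeration is not implemented.
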