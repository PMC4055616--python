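"""Synthetic station generator calibrated to the eight regional groups.

The study's station-level data are not deposited; what is printed are
per-region station counts and mean +/- SD summaries of surface temperature,
nitrate at the euphotic base, stratification, euphotic and mixed-layer
depths, chlorophyll a, phytoplankton carbon, and primary production.  This
module turns those summaries into full synthetic datasets:

* positive, strongly skewed quantities (chl a, carbon, production, nitrate,
  stratification, layer depths) are drawn from lognormal distributions whose
  first two moments match the printed mean and SD exactly
  (sigma2 = ln(1 + (s/m)^2), mu = ln m - sigma2/2);
* within a region, log carbon, log production and log chlorophyll are
  correlated (Gaussian copula, chain structure C-P and C-chl) so that region
  clouds are elongated along the global scaling relation;
* the carbon-specific production rate P^C is always computed as P / C,
  never drawn, so any statement about P^C is an honest consequence of the
  generator;
* temperature is normal, truncated to the physically meaningful range;
* each station gets a depth profile built by *inversion*: the sigma_t,
  PAR and nitrate profiles are constructed so that the hydrography module's
  own reductions recover the drawn per-station targets (mixed-layer depth,
  euphotic depth, delta sigma_t, nitrate at the euphotic base).

Cross-region structure (for example the superlinear production-biomass
scaling) is never imposed: it must emerge from the between-region contrast
of the printed summaries alone.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import truncnorm

from .eos80 import SALINITY_RANGE, TEMPERATURE_RANGE, sigma_t
from .errors import ConfigurationError, ProfileConstructionError
from .hydrography import UML_THRESHOLD, DepthProfile
from .regions import REGIONS, validate_region

#: Fields of the regional summary table, with (mean, sd) values each.
_MOMENT_FIELDS = (
    "temp",
    "no3_zeu",
    "delta_sigma_t",
    "euphotic_depth",
    "uml_depth",
    "chl",
    "phyto_c",
    "pp",
)


@dataclass
class RegionParams:
    """One region's station count and summary moments.

    Each moment field is a ``(mean, sd)`` pair in the units of the
    corresponding measurement: temp degC, no3_zeu umol L-1, delta_sigma_t
    kg m-3, euphotic_depth / uml_depth m, chl mg m-3, phyto_c mgC m-3,
    pp mgC m-3 d-1.  ``log_cp_correlation`` is the log-space correlation
    between carbon biomass and production within the region;
    ``log_cchl_correlation`` the one between carbon and chlorophyll.
    """

    region: str
    n_stations: int
    temp: tuple[float, float]
    no3_zeu: tuple[float, float]
    delta_sigma_t: tuple[float, float]
    euphotic_depth: tuple[float, float]
    uml_depth: tuple[float, float]
    chl: tuple[float, float]
    phyto_c: tuple[float, float]
    pp: tuple[float, float]
    log_cp_correlation: float = 0.9
    log_cchl_correlation: float = 0.9

    def __post_init__(self):
        validate_region(self.region)
        if self.n_stations < 1:
            raise ConfigurationError(
                f"region {self.region}: n_stations must be >= 1"
            )
        for name in _MOMENT_FIELDS:
            m, s = getattr(self, name)
            if not m > 0:
                raise ConfigurationError(
                    f"region {self.region}: {name} mean must be > 0, got {m}"
                )
            if s < 0:
                raise ConfigurationError(
                    f"region {self.region}: {name} sd must be >= 0, got {s}"
                )
        for name in ("log_cp_correlation", "log_cchl_correlation"):
            v = getattr(self, name)
            if not -1 < v < 1:
                raise ConfigurationError(
                    f"region {self.region}: {name} must be in (-1, 1), got {v}"
                )


# Regional summaries: n, then (mean, sd) of temp, NO3_zeu, delta sigma_t,
# euphotic depth, mixed-layer depth, chl a, phytoplankton C, production.
_DEFAULT_TABLE: tuple[tuple, ...] = (
    ("temperate_n", 8, (15.9, 3.5), (6.7, 1.6), (0.6, 0.5), (68, 23), (64, 35),
     (0.44, 0.56), (30, 22), (13, 15)),
    ("temperate_s", 4, (13.4, 4.5), (9.8, 4.2), (0.4, 0.2), (57, 22), (50, 15),
     (0.71, 0.29), (34, 10), (15, 6)),
    ("oligotrophic_n", 5, (22.3, 2.3), (1.9, 1.5), (0.8, 0.5), (115, 14), (47, 13),
     (0.10, 0.03), (11, 3), (2.5, 0.8)),
    ("oligotrophic_s", 13, (24.4, 2.9), (0.9, 1.2), (0.9, 0.6), (126, 24), (59, 22),
     (0.13, 0.07), (9, 2), (2.1, 0.8)),
    ("upwelling", 8, (27.3, 1.4), (14.0, 2.1), (3.2, 0.6), (83, 13), (29, 12),
     (0.20, 0.07), (16, 11), (10, 11)),
    ("coastal", 26, (15.3, 2.0), (6.8, 3.2), (0.8, 0.6), (20, 4), (7, 4),
     (3.5, 3.2), (202, 187), (248, 271)),
    ("soiree_in", 6, (2.8, 0.1), (23.2, 1.1), (0.02, 0.01), (47, 1), (72, 3),
     (1.19, 0.16), (89, 33), (25, 3)),
    ("soiree_out", 2, (2.7, 0.0), (25.4, 0.4), (0.23, 0.02), (74, 8), (69, 2),
     (0.20, 0.03), (12, 3), (2.0, 0.6)),
)


def default_region_table() -> list[RegionParams]:
    """The eight shipped regional groups (72 stations in total)."""
    return [
        RegionParams(
            region=r[0], n_stations=r[1], temp=r[2], no3_zeu=r[3],
            delta_sigma_t=r[4], euphotic_depth=r[5], uml_depth=r[6],
            chl=r[7], phyto_c=r[8], pp=r[9],
        )
        for r in _DEFAULT_TABLE
    ]


@dataclass
class SyntheticConfig:
    """Knobs of the generator; the defaults define the study conditions."""

    seed: int = 0
    surface_par: float = 1500.0  # umol photons m-2 s-1, typical midday surface
    profile_grid: float = 2.0  # depth sampling interval, m
    salinity_baseline: float = 35.0  # PSU, open-ocean baseline
    #: Ceiling on drawn delta sigma_t (kg m-3): keeps the implied deep-water
    #: density within the seawater equation of state's reach.  Far beyond any
    #: regional 3-sigma value, so its effect on moments is negligible.
    dst_cap: float = 6.0
    region_table: Optional[list[RegionParams]] = None

    def regions(self) -> list[RegionParams]:
        return list(self.region_table) if self.region_table else default_region_table()


def lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """(mu, sigma) of the lognormal with the given mean and SD."""
    if not mean > 0:
        raise ConfigurationError(f"lognormal mean must be > 0, got {mean}")
    if sd < 0:
        raise ConfigurationError(f"lognormal sd must be >= 0, got {sd}")
    if sd == 0:
        return math.log(mean), 0.0
    sigma2 = math.log(1.0 + (sd / mean) ** 2)
    return math.log(mean) - sigma2 / 2.0, math.sqrt(sigma2)


def _truncated_normal(mean, sd, lo, hi, size, rng):
    if sd == 0:
        return np.full(size, float(mean))
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def sample_station_summaries(
    params: RegionParams,
    n_stations: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> pd.DataFrame:
    """Draw per-station surface biology and temperature for one region.

    Carbon, production and chlorophyll are a trivariate lognormal with
    moment-matched marginals; the Gaussian copula has the chain correlation
    structure corr(C,P) = rho_cp, corr(C,chl) = rho_cchl,
    corr(P,chl) = rho_cp * rho_cchl (production and chlorophyll are coupled
    only through carbon).  P^C and C:Chl are computed, never drawn.
    """
    rng = rng if rng is not None else np.random.default_rng()
    n = n_stations if n_stations is not None else params.n_stations

    mu_c, sg_c = lognormal_params(*params.phyto_c)
    mu_p, sg_p = lognormal_params(*params.pp)
    mu_l, sg_l = lognormal_params(*params.chl)
    rho_cp = params.log_cp_correlation
    rho_cl = params.log_cchl_correlation

    e = rng.standard_normal((n, 3))
    z_c = e[:, 0]
    z_p = rho_cp * e[:, 0] + math.sqrt(1 - rho_cp**2) * e[:, 1]
    z_l = rho_cl * e[:, 0] + math.sqrt(1 - rho_cl**2) * e[:, 2]

    phyto_c = np.exp(mu_c + sg_c * z_c)
    pp = np.exp(mu_p + sg_p * z_p)
    chl = np.exp(mu_l + sg_l * z_l)
    temp = _truncated_normal(*params.temp, *TEMPERATURE_RANGE, n, rng)

    return pd.DataFrame(
        {
            "region": params.region,
            "temp_c": temp,
            "chl_mg_m3": chl,
            "phyto_c_mgc_m3": phyto_c,
            "pp_mgc_m3_d": pp,
            "p_c": pp / phyto_c,
            "c_to_chl": phyto_c / chl,
        }
    )


def sample_hydro_targets(
    params: RegionParams,
    n_stations: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
    dst_cap: float = 6.0,
) -> pd.DataFrame:
    """Draw per-station hydrographic targets (independent lognormals)."""
    rng = rng if rng is not None else np.random.default_rng()
    n = n_stations if n_stations is not None else params.n_stations
    out = {}
    for name, col in (
        ("no3_zeu", "no3_zeu"),
        ("delta_sigma_t", "delta_sigma_t"),
        ("euphotic_depth", "euphotic_depth"),
        ("uml_depth", "uml_depth"),
    ):
        mu, sg = lognormal_params(*getattr(params, name))
        out[col] = np.exp(mu + sg * rng.standard_normal(n))
    out["delta_sigma_t"] = np.minimum(out["delta_sigma_t"], dst_cap)
    return pd.DataFrame(out)


def _invert_sigma_level(target: float, s0: float) -> tuple[float, float]:
    """(temperature, salinity) whose EOS-80 sigma_t equals ``target``.

    Prefers solving for temperature at the baseline salinity; when the
    target is denser than cold water at that salinity can be, salinity is
    increased at a near-freezing temperature instead.
    """
    t_lo, t_hi = TEMPERATURE_RANGE
    sig_cold = sigma_t(s0, t_lo)
    sig_warm = sigma_t(s0, t_hi)
    eps = 1e-9
    if sig_warm + eps <= target <= sig_cold - eps:
        t = brentq(lambda tt: sigma_t(s0, tt) - target, t_lo, t_hi, xtol=1e-9)
        return float(t), s0
    if target > sig_cold - eps:
        t_fix = -1.0
        s_hi = SALINITY_RANGE[1]
        if target > sigma_t(s_hi, t_fix):
            raise ProfileConstructionError(
                f"target sigma_t {target:.3f} exceeds the densest water "
                f"reachable (S={s_hi}, T={t_fix})"
            )
        s = brentq(lambda ss: sigma_t(ss, t_fix) - target, s0, s_hi, xtol=1e-9)
        return t_fix, float(s)
    # lighter than warm water at baseline salinity: freshen at a warm T
    t_fix = t_hi - 1.0
    if target < sigma_t(SALINITY_RANGE[0], t_fix):
        raise ProfileConstructionError(
            f"target sigma_t {target:.3f} below the lightest water reachable"
        )
    s = brentq(lambda ss: sigma_t(ss, t_fix) - target, SALINITY_RANGE[0], s0, xtol=1e-9)
    return t_fix, float(s)


def build_station_profile(
    station_id: str,
    temperature: float,
    targets: dict,
    config: Optional[SyntheticConfig] = None,
) -> DepthProfile:
    """Construct a depth profile that realises the requested targets.

    ``targets`` must contain ``uml_depth``, ``euphotic_depth``,
    ``delta_sigma_t`` and ``no3_zeu``.  The sigma_t profile is piecewise
    linear: a homogeneous surface layer, then a linear rise placed so that
    the interpolated crossing of surface + 0.125 kg m-3 sits exactly at the
    target mixed-layer depth and sigma_t at the euphotic depth exceeds the
    surface value by exactly delta_sigma_t.  When delta_sigma_t < 0.125 the
    crossing necessarily lies *below* the euphotic depth (the weakly
    stratified, deeply mixed regime).  Temperature (and, for very dense
    targets, salinity) is obtained by numerically inverting the package's
    own EOS-80 sigma_t, so the hydrography reductions recover the targets.

    A jointly infeasible combination — e.g. delta_sigma_t >= 0.125 with a
    drawn mixed layer deeper than the euphotic depth, impossible for a
    monotone density profile — is resolved by moving the mixed-layer target
    to just beside the euphotic depth; the other three targets are honoured
    exactly.

    PAR decays exponentially with the attenuation that puts the 1% light
    level at the euphotic target; nitrate follows a logistic nitracline
    centred on the euphotic depth, hitting the nitrate target there exactly.
    """
    config = config or SyntheticConfig()
    uml = float(targets["uml_depth"])
    zeu = float(targets["euphotic_depth"])
    dst = float(targets["delta_sigma_t"])
    no3_zeu = float(targets["no3_zeu"])
    for name, v in (("uml_depth", uml), ("euphotic_depth", zeu),
                    ("delta_sigma_t", dst), ("no3_zeu", no3_zeu)):
        if not v > 0:
            raise ProfileConstructionError(
                f"station {station_id}: target {name} must be > 0, got {v}"
            )
    if config.profile_grid > 5.0:
        raise ConfigurationError("profile_grid must be <= 5 m")

    s0 = config.salinity_baseline
    sigma0 = sigma_t(s0, temperature)

    # Piecewise-linear sigma_t offsets above sigma0, as (depth, offset) knots.
    if dst >= UML_THRESHOLD:
        uml_eff = uml if uml < zeu else 0.95 * zeu
        knots = [(0.0, 0.0), (uml_eff / 2.0, 0.0), (uml_eff, UML_THRESHOLD),
                 (zeu, dst)]
    else:
        uml_eff = uml if uml > zeu else 1.05 * zeu
        knots = [(0.0, 0.0), (zeu / 2.0, 0.0), (zeu, dst),
                 (uml_eff, UML_THRESHOLD)]
    deepest = max(zeu, uml_eff)
    zmax = deepest + max(10.0, 0.25 * deepest)
    # A gentle residual gradient below the deepest knot keeps the density
    # structure strictly increasing (so threshold crossings at the deepest
    # knot are robustly bracketed) without leaving the equation of state's
    # invertible range.
    knots.append((zmax, knots[-1][1] + 0.001 * (zmax - knots[-1][0])))
    knot_z = np.array([k[0] for k in knots])
    knot_off = np.array([k[1] for k in knots])

    grid = np.arange(0.0, zmax + config.profile_grid, config.profile_grid)
    depth = np.unique(np.round(np.concatenate([grid, knot_z]), 6))

    sig = sigma0 + np.interp(depth, knot_z, knot_off)

    ts = [_invert_sigma_level(v, s0) for v in sig]
    temp_profile = np.array([t for t, _ in ts])
    sal_profile = np.array([s for _, s in ts])

    k_par = math.log(100.0) / zeu
    par = config.surface_par * np.exp(-k_par * depth)

    width = zeu / 8.0
    nitrate = 2.0 * no3_zeu / (1.0 + np.exp(-(depth - zeu) / width))

    return DepthProfile(
        station_id=station_id,
        depth=depth,
        temperature=temp_profile,
        salinity=sal_profile,
        par=par,
        nitrate=nitrate,
    )


def generate_dataset(
    config: Optional[SyntheticConfig] = None,
) -> tuple[pd.DataFrame, list[DepthProfile]]:
    """Generate the full synthetic dataset (all regions at their n).

    Returns the station table (surface measurements) and one depth profile
    per station.  Fully deterministic for a fixed config seed.
    """
    config = config or SyntheticConfig()
    rng = np.random.default_rng(config.seed)
    frames = []
    profiles: list[DepthProfile] = []
    for params in config.regions():
        summaries = sample_station_summaries(params, rng=rng)
        hydro = sample_hydro_targets(
            params, rng=rng, dst_cap=config.dst_cap
        )
        ids = [f"{params.region}_{i + 1:02d}" for i in range(params.n_stations)]
        summaries.insert(0, "station_id", ids)
        for i, sid in enumerate(ids):
            profiles.append(
                build_station_profile(
                    sid,
                    float(summaries["temp_c"].iloc[i]),
                    hydro.iloc[i].to_dict(),
                    config,
                )
            )
        frames.append(summaries)
    stations = pd.concat(frames, ignore_index=True)
    return stations, profiles


def write_dataset(stations: pd.DataFrame, profiles, out_dir) -> dict[str, Path]:
    """Write the station and profile CSVs; returns the paths written."""
    from .hydrography import write_profiles_csv

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stations_path = out_dir / "stations.csv"
    profiles_path = out_dir / "profiles.csv"
    cols = ["station_id", "region", "temp_c", "chl_mg_m3", "phyto_c_mgc_m3",
            "pp_mgc_m3_d"]
    stations[cols].to_csv(stations_path, index=False)
    write_profiles_csv(profiles, profiles_path)
    return {"stations": stations_path, "profiles": profiles_path}


# ---------------------------------------------------------------------------
# Region parameter table CSV round-trip (long format: region,n,field,mean,sd)
# ---------------------------------------------------------------------------

def region_table_to_frame(table: Sequence[RegionParams]) -> pd.DataFrame:
    rows = []
    for p in table:
        for fname in _MOMENT_FIELDS:
            m, s = getattr(p, fname)
            rows.append(
                {"region": p.region, "n": p.n_stations, "field": fname,
                 "mean": m, "sd": s}
            )
    return pd.DataFrame(rows)


def read_region_table_csv(path) -> list[RegionParams]:
    df = pd.read_csv(path)
    needed = {"region", "n", "field", "mean", "sd"}
    if not needed.issubset(df.columns):
        raise ConfigurationError(
            f"region table needs columns {sorted(needed)}, got {list(df.columns)}"
        )
    out = []
    for region, g in df.groupby("region", sort=False):
        validate_region(str(region))
        kwargs = {"region": str(region), "n_stations": int(g["n"].iloc[0])}
        for fname in _MOMENT_FIELDS:
            row = g[g["field"] == fname]
            if row.empty:
                raise ConfigurationError(f"region {region}: missing field {fname}")
            kwargs[fname] = (float(row["mean"].iloc[0]), float(row["sd"].iloc[0]))
        out.append(RegionParams(**kwargs))
    return out


def write_region_table_csv(table: Sequence[RegionParams], path) -> None:
    region_table_to_frame(table).to_csv(path, index=False)
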