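"""End-to-end analysis: profiles + surface biology -> numeric report.

The report reproduces the study's analysis surface over any dataset in the
package's CSV formats:

* log10 reduced-major-axis fits with bootstrap CIs for production vs carbon
  biomass, production vs chl a, and carbon biomass vs chl a;
* the Pearson correlation of the carbon-specific production rate P^C with
  sea surface temperature (all stations) and with the resource supply index
  (RSI; stations with valid, non-excluded RSI only);
* P^C summaries within chlorophyll concentration bins, with pairwise
  Mann-Whitney comparisons;
* ordinary least-squares fits of P^C on temperature within RSI strata
  (low < 10, intermediate 10-20 mmol N kg-1) — the resource-controlled test
  of temperature dependence;
* a per-region summary table.

Analyses *ignore* stations missing an optional input (no nitrate profile
means no RSI, nothing more) and report per-analysis n; a fit whose
precondition fails is recorded as skipped with a reason, and the run
continues.  For a fixed dataset, configuration and seed the report is
bit-identical across runs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .biomass import StationRecord
from .errors import CoverageError, DegenerateDataError, ValidationError
from .hydrography import DepthProfile, HydroDerived, derive_hydrography
from .regions import SOIREE_REGIONS, validate_region
from .rsi import (
    MIN_DELTA_SIGMA_T,
    SOIREE_EXCLUSION_REASON,
    RSIResult,
    resource_supply_index,
)
from .stats import (
    CHL_BIN_EDGES,
    bin_by_chl,
    bootstrap_rma_ci,
    mann_whitney,
    ols_fit,
    pearson_test,
)

log = logging.getLogger(__name__)


@dataclass
class AnalysisConfig:
    seed: int = 0
    n_boot: int = 2000
    ci_level: float = 0.95
    min_delta_sigma_t: float = MIN_DELTA_SIGMA_T
    bin_edges: tuple[float, ...] = CHL_BIN_EDGES
    rsi_low: float = 10.0  # upper bound of the low-RSI stratum, mmol N kg-1
    rsi_mid: float = 20.0  # upper bound of the intermediate stratum

    def hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=list)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def process_station(
    profile: DepthProfile,
    surface: Mapping,
    min_delta_sigma_t: float = MIN_DELTA_SIGMA_T,
) -> tuple[StationRecord, HydroDerived, Optional[RSIResult]]:
    """Attach derived hydrography and RSI to one station's surface data.

    ``surface`` must carry region, temp_c, chl_mg_m3, phyto_c_mgc_m3 and
    pp_mgc_m3_d for the same station as ``profile``.  Southern Ocean
    iron-release stations are marked RSI-excluded by region; stations whose
    profile cannot yield RSI inputs (missing nitrate) get a NaN RSI and a
    logged warning.
    """
    sid = str(surface.get("station_id", profile.station_id))
    if sid != profile.station_id:
        raise ValidationError(
            f"surface data are for station {sid!r} but the profile is for "
            f"{profile.station_id!r}"
        )
    derived = derive_hydrography(profile)
    region = validate_region(str(surface["region"]))

    rsi_res: Optional[RSIResult] = None
    rsi_value = float("nan")
    excluded = False
    reason = None
    if not np.isfinite(derived.no3_euphotic_base):
        log.warning("station %s: no usable nitrate profile; RSI undefined", sid)
    elif derived.delta_sigma_t <= 0:
        log.warning("station %s: non-positive delta sigma_t; RSI undefined", sid)
    else:
        rsi_res = resource_supply_index(
            derived.no3_euphotic_base,
            derived.delta_sigma_t,
            derived.euphotic_depth,
            derived.uml_depth,
            min_delta_sigma_t=min_delta_sigma_t,
            station_id=sid,
        )
        rsi_value = rsi_res.rsi
        excluded = rsi_res.excluded
        reason = rsi_res.exclude_reason
    if region in SOIREE_REGIONS:
        excluded = True
        reason = SOIREE_EXCLUSION_REASON
        if rsi_res is not None:
            rsi_res.excluded = True
            rsi_res.exclude_reason = reason

    record = StationRecord(
        station_id=sid,
        region=region,
        temperature=float(surface["temp_c"]),
        chl_a=float(surface["chl_mg_m3"]),
        phyto_c=float(surface["phyto_c_mgc_m3"]),
        primary_production=float(surface["pp_mgc_m3_d"]),
        rsi=rsi_value,
        rsi_excluded=excluded,
        rsi_exclude_reason=reason,
    )
    return record, derived, rsi_res


def assemble_records(
    stations: pd.DataFrame,
    profiles: Sequence[DepthProfile],
    min_delta_sigma_t: float = MIN_DELTA_SIGMA_T,
) -> pd.DataFrame:
    """Pair every station row with its profile and derive physics + RSI.

    Raises a reconciliation error listing orphan ids when the two inputs do
    not describe the same station set.
    """
    by_id = {p.station_id: p for p in profiles}
    station_ids = list(stations["station_id"].astype(str))
    missing = sorted(set(station_ids) - set(by_id))
    orphans = sorted(set(by_id) - set(station_ids))
    if missing or orphans:
        raise ValidationError(
            "stations and profiles do not match; "
            f"stations without profile: {missing or 'none'}; "
            f"profiles without station: {orphans or 'none'}"
        )
    rows = []
    for _, surface in stations.iterrows():
        record, derived, _ = process_station(
            by_id[str(surface["station_id"])], surface, min_delta_sigma_t
        )
        rows.append(
            {
                "station_id": record.station_id,
                "region": record.region,
                "temp_c": record.temperature,
                "chl_mg_m3": record.chl_a,
                "phyto_c_mgc_m3": record.phyto_c,
                "pp_mgc_m3_d": record.primary_production,
                "p_c": record.p_c,
                "c_to_chl": record.c_to_chl,
                "uml_depth_m": derived.uml_depth,
                "euphotic_depth_m": derived.euphotic_depth,
                "delta_sigma_t": derived.delta_sigma_t,
                "no3_zeu_umol_l": derived.no3_euphotic_base,
                "rsi": record.rsi,
                "rsi_excluded": record.rsi_excluded,
                "rsi_exclude_reason": record.rsi_exclude_reason or "",
                "flags": ";".join(sorted(derived.flags)),
            }
        )
    return pd.DataFrame(rows)


def merge_derived(
    stations: pd.DataFrame,
    derived: pd.DataFrame,
    min_delta_sigma_t: float = MIN_DELTA_SIGMA_T,
) -> pd.DataFrame:
    """Like :func:`assemble_records` but from an already-derived CSV table."""
    sids = set(stations["station_id"].astype(str))
    dids = set(derived["station_id"].astype(str))
    if sids != dids:
        raise ValidationError(
            "stations and derived tables do not match; "
            f"stations missing derived: {sorted(sids - dids) or 'none'}; "
            f"derived without station: {sorted(dids - sids) or 'none'}"
        )
    df = stations.merge(derived, on="station_id", how="inner")
    rsi_vals, excl, reasons = [], [], []
    for _, row in df.iterrows():
        region = validate_region(str(row["region"]))
        value, excluded, reason = float("nan"), False, None
        if np.isfinite(row["no3_zeu_umol_l"]) and row["delta_sigma_t"] > 0:
            res = resource_supply_index(
                row["no3_zeu_umol_l"],
                row["delta_sigma_t"],
                row["euphotic_depth_m"],
                row["uml_depth_m"],
                min_delta_sigma_t=min_delta_sigma_t,
                station_id=str(row["station_id"]),
            )
            value, excluded, reason = res.rsi, res.excluded, res.exclude_reason
        if region in SOIREE_REGIONS:
            excluded, reason = True, SOIREE_EXCLUSION_REASON
        rsi_vals.append(value)
        excl.append(excluded)
        reasons.append(reason or "")
    df["p_c"] = df["pp_mgc_m3_d"] / df["phyto_c_mgc_m3"]
    df["c_to_chl"] = df["phyto_c_mgc_m3"] / df["chl_mg_m3"]
    df["rsi"] = rsi_vals
    df["rsi_excluded"] = excl
    df["rsi_exclude_reason"] = reasons
    return df


def _fit_or_skip(name, x, y, config, rng_seed):
    try:
        fit = bootstrap_rma_ci(
            x, y, n_boot=config.n_boot, ci_level=config.ci_level, seed=rng_seed
        )
        return fit.to_dict()
    except (ValidationError, DegenerateDataError) as exc:
        log.warning("fit %s skipped: %s", name, exc)
        return {"skipped": str(exc)}


def run_analysis(records: pd.DataFrame, config: Optional[AnalysisConfig] = None) -> dict:
    """Compute the full analysis report over assembled station records.

    ``records`` is the output of :func:`assemble_records` /
    :func:`merge_derived` (or any frame with the same columns).  Returns a
    JSON-serialisable dict.
    """
    config = config or AnalysisConfig()
    rec = records

    report: dict = {"fits": {}}
    pairs = {
        "pp_vs_c": ("phyto_c_mgc_m3", "pp_mgc_m3_d"),
        "pp_vs_chl": ("chl_mg_m3", "pp_mgc_m3_d"),
        "c_vs_chl": ("chl_mg_m3", "phyto_c_mgc_m3"),
    }
    for i, (name, (xcol, ycol)) in enumerate(pairs.items()):
        sub = rec[(rec[xcol] > 0) & (rec[ycol] > 0)]
        x = np.log10(sub[xcol].to_numpy(dtype=float))
        y = np.log10(sub[ycol].to_numpy(dtype=float))
        report["fits"][name] = _fit_or_skip(name, x, y, config, config.seed + i)

    # P^C vs temperature over every station (the generator draws production
    # and biomass independently of temperature within a region, so any
    # correlation here is between-region structure only).
    try:
        r, p, n = pearson_test(rec["temp_c"], rec["p_c"])
        report["temp_correlation"] = {"r": r, "p": p, "n": n}
    except (ValidationError, DegenerateDataError) as exc:
        report["temp_correlation"] = {"skipped": str(exc)}

    rsi_ok = rec[np.isfinite(rec["rsi"]) & ~rec["rsi_excluded"]]
    excluded_ids = sorted(
        rec.loc[rec["rsi_excluded"] | ~np.isfinite(rec["rsi"]), "station_id"]
    )
    try:
        r, p, n = pearson_test(rsi_ok["rsi"], rsi_ok["p_c"])
        report["rsi_correlation"] = {"r": r, "p": p, "n": n}
    except (ValidationError, DegenerateDataError) as exc:
        report["rsi_correlation"] = {"skipped": str(exc)}
    report["rsi_excluded_stations"] = [str(s) for s in excluded_ids]

    bins = bin_by_chl(rec, edges=config.bin_edges)
    pairwise = []
    usable = bins[bins["n"] >= 2]
    for i in range(len(usable)):
        for j in range(i + 1, len(usable)):
            bi, bj = usable.iloc[i], usable.iloc[j]
            a = rec[rec["station_id"].isin(bi["station_ids"])]["p_c"]
            b = rec[rec["station_id"].isin(bj["station_ids"])]["p_c"]
            t = mann_whitney(a, b, group_a=bi["bin"], group_b=bj["bin"])
            pairwise.append(
                {
                    "bin_a": t.group_a,
                    "bin_b": t.group_b,
                    "u": t.u_statistic,
                    "p": t.p_value,
                    "n_a": t.n_a,
                    "n_b": t.n_b,
                    "method": t.method,
                }
            )
    report["chl_bins"] = {
        "summary": bins.drop(columns=["station_ids"]).to_dict(orient="records"),
        "pairwise_mann_whitney": pairwise,
    }

    strata = {
        "low_rsi": rsi_ok[rsi_ok["rsi"] < config.rsi_low],
        "mid_rsi": rsi_ok[(rsi_ok["rsi"] >= config.rsi_low)
                          & (rsi_ok["rsi"] <= config.rsi_mid)],
    }
    report["rsi_strata_fits"] = {}
    for name, sub in strata.items():
        if len(sub) < 3:
            report["rsi_strata_fits"][name] = {
                "skipped": f"only {len(sub)} stations in stratum"
            }
            continue
        try:
            fit = ols_fit(sub["temp_c"], sub["p_c"])
        except DegenerateDataError as exc:
            report["rsi_strata_fits"][name] = {"skipped": str(exc)}
            continue
        report["rsi_strata_fits"][name] = {
            "slope": fit.slope,
            "intercept": fit.intercept,
            "p_slope": fit.p_slope,
            "n": fit.n,
            "temp_range": [float(sub["temp_c"].min()), float(sub["temp_c"].max())],
        }

    summaries = []
    for region, g in rec.groupby("region", sort=False):
        rsi_g = g[np.isfinite(g["rsi"]) & ~g["rsi_excluded"]]["rsi"]
        row = {"region": region, "n": int(len(g))}
        for col in ("temp_c", "chl_mg_m3", "phyto_c_mgc_m3", "pp_mgc_m3_d",
                    "p_c", "c_to_chl"):
            row[f"mean_{col}"] = float(g[col].mean())
            row[f"sd_{col}"] = float(g[col].std(ddof=1)) if len(g) > 1 else float("nan")
        row["mean_rsi"] = float(rsi_g.mean()) if len(rsi_g) else float("nan")
        row["sd_rsi"] = float(rsi_g.std(ddof=1)) if len(rsi_g) > 1 else float("nan")
        row["n_rsi"] = int(len(rsi_g))
        summaries.append(row)
    report["region_summaries"] = summaries

    report["provenance"] = {
        "package_version": __version__,
        "seed": config.seed,
        "n_boot": config.n_boot,
        "ci_level": config.ci_level,
        "min_delta_sigma_t": config.min_delta_sigma_t,
        "bin_edges": list(config.bin_edges),
        "config_hash": config.hash(),
        "n_stations": int(len(rec)),
    }
    return report


def _json_default(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serialisable: {type(o)}")


def write_report(report: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")
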