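"""Resource supply index (RSI).

The index combines nutrient and light availability into a single relative
number per station:

    RSI = (NO3_zeu / delta_sigma_t) * (zeu / uml)        [mmol N kg-1]

where NO3_zeu is nitrate at the base of the euphotic zone (umol L-1),
delta_sigma_t the sigma_t difference between surface and euphotic base
(kg m-3), zeu the euphotic depth and uml the upper-mixed-layer depth (m).
The first factor grows with the nutrient pool below the euphotic layer and
shrinks as stratification throttles vertical transport; the second factor is
large when phytoplankton are held in a shallow mixed layer relative to the
lit layer (high mean irradiance) and small under deep mixing.

Unit identity: (umol L-1) / (kg m-3) = (mmol m-3) / (kg m-3) = mmol N kg-1.

The index is a comparative, between-regime quantity — it is not an estimate
of local nutrient flux.  Stations with a near-unstratified water column
(delta_sigma_t below a configurable floor) are marked excluded, because the
index diverges as stratification vanishes; iron-limited Southern Ocean
stations are excluded on limitation grounds regardless of stratification.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .regions import SOIREE_REGIONS, validate_region

#: Stations with delta_sigma_t below this floor (kg m-3) are flagged as
#: excluded from RSI analyses: the index is undefined in spirit as
#: stratification vanishes.
MIN_DELTA_SIGMA_T = 0.05

SOIREE_EXCLUSION_REASON = "iron-limited (Soiree)"
WEAK_STRATIFICATION_REASON = "weak stratification (delta_sigma_t below floor)"


@dataclass
class RSIResult:
    station_id: str
    rsi: float
    term_nutrient: float  # NO3_zeu / delta_sigma_t, mmol N kg-1
    term_light: float  # zeu / uml, dimensionless
    excluded: bool = False
    exclude_reason: Optional[str] = None


def resource_supply_index(
    no3_zeu: float,
    delta_sigma_t: float,
    euphotic_depth: float,
    uml_depth: float,
    min_delta_sigma_t: float = MIN_DELTA_SIGMA_T,
    station_id: str = "",
) -> RSIResult:
    """Compute RSI for one station.

    All inputs must be strictly positive.  When ``delta_sigma_t`` falls below
    ``min_delta_sigma_t`` the station is marked ``excluded`` (weakly
    stratified regime) but the numeric value is still reported for
    inspection.
    """
    for name, v in (
        ("no3_zeu", no3_zeu),
        ("delta_sigma_t", delta_sigma_t),
        ("euphotic_depth", euphotic_depth),
        ("uml_depth", uml_depth),
    ):
        if not np.isfinite(v) or v <= 0:
            raise ValidationError(
                f"station {station_id or '?'}: {name} must be finite and > 0, got {v!r}"
            )
    term_nutrient = no3_zeu / delta_sigma_t
    term_light = euphotic_depth / uml_depth
    excluded = delta_sigma_t < min_delta_sigma_t
    return RSIResult(
        station_id=station_id,
        rsi=term_nutrient * term_light,
        term_nutrient=term_nutrient,
        term_light=term_light,
        excluded=excluded,
        exclude_reason=WEAK_STRATIFICATION_REASON if excluded else None,
    )


def summarize_rsi_by_region(
    results: Sequence[RSIResult], regions: Sequence[str]
) -> pd.DataFrame:
    """Per-region mean, sample SD, n and exclusion count of RSI.

    ``regions`` gives the region label of each result, aligned by position.
    Southern Ocean iron-release stations are always counted as excluded.
    Regions with no usable station get ``n=0`` and NaN mean/SD.
    """
    if len(results) != len(regions):
        raise ValidationError("results and regions must have the same length")
    for r in regions:
        validate_region(r)
    rows = {}
    for res, region in zip(results, regions):
        excluded = res.excluded or region in SOIREE_REGIONS
        rec = rows.setdefault(region, {"values": [], "n_excluded": 0})
        if excluded:
            rec["n_excluded"] += 1
        else:
            rec["values"].append(res.rsi)
    out = []
    for region, rec in rows.items():
        vals = np.asarray(rec["values"], dtype=float)
        out.append(
            {
                "region": region,
                "mean_rsi": float(vals.mean()) if vals.size else float("nan"),
                "sd_rsi": float(vals.std(ddof=1)) if vals.size > 1 else float("nan"),
                "n": int(vals.size),
                "n_excluded": rec["n_excluded"],
            }
        )
    return pd.DataFrame(out).set_index("region")


def rsi_results_to_frame(results: Sequence[RSIResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "station_id": r.station_id,
                "rsi_mmolN_kg": r.rsi,
                "term_nutrient": r.term_nutrient,
                "term_light": r.term_light,
                "excluded": r.excluded,
                "exclude_reason": r.exclude_reason or "",
            }
            for r in results
        ]
    )
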