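"""Phytoplankton biomass bookkeeping and rate metrics.

Two classes of computation live here:

* conversion of microscopy / cytometry biovolume measurements into carbon
  biomass through taxon-specific power laws, carbon_per_cell = a * V**b
  (pgC, V in um3) — configuration, not hard-coded truth, since conversion
  coefficients are protocol-dependent;
* the derived biological metrics: the carbon-specific (biomass-specific)
  production rate P^C = P / C (d-1), equivalent to the community's intrinsic
  growth rate, and the carbon-to-chlorophyll ratio C:Chl a.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ValidationError
from .regions import validate_region

STATION_COLUMNS = [
    "station_id",
    "region",
    "temp_c",
    "chl_mg_m3",
    "phyto_c_mgc_m3",
    "pp_mgc_m3_d",
]

#: Default biovolume->carbon power laws, carbon = a * volume**b (pgC, um3).
#: Diatom and non-diatom protist coefficients follow the widely used
#: Menden-Deuer & Lessard (2000) fits; picophytoplankton use a linear
#: volumetric factor of 230 fgC um-3.  These are documented substitutes for
#: protocol-specific coefficients and are fully overridable from a CSV.
_DEFAULT_COEFFS: dict[str, tuple[float, float]] = {
    "diatom": (0.288, 0.811),
    "non_diatom": (0.216, 0.939),
    "picocyanobacteria": (0.230, 1.0),
    "picoeukaryote": (0.216, 0.939),
}


@dataclass
class CarbonConversionTable:
    """Mapping taxon group -> (a, b) with carbon_per_cell = a * volume**b."""

    coefficients: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(_DEFAULT_COEFFS)
    )

    def __post_init__(self):
        for group, (a, b) in self.coefficients.items():
            if not a > 0:
                raise ConfigurationError(f"group {group!r}: scale a must be > 0, got {a}")
            if not 0 < b <= 1.2:
                raise ConfigurationError(
                    f"group {group!r}: exponent b must be in (0, 1.2], got {b}"
                )

    @classmethod
    def default(cls) -> "CarbonConversionTable":
        return cls()

    @classmethod
    def from_csv(cls, path) -> "CarbonConversionTable":
        """Load a ``group,a,b`` CSV."""
        df = pd.read_csv(path)
        missing = [c for c in ("group", "a", "b") if c not in df.columns]
        if missing:
            raise ConfigurationError(
                f"conversion table missing columns: {', '.join(missing)}"
            )
        return cls({row.group: (float(row.a), float(row.b)) for row in df.itertuples()})

    def lookup(self, group: str) -> tuple[float, float]:
        try:
            return self.coefficients[group]
        except KeyError:
            known = ", ".join(sorted(self.coefficients))
            raise ConfigurationError(
                f"unknown taxon group {group!r}; known groups: {known}"
            ) from None


def cell_carbon(
    volume_um3: float, group: str, table: Optional[CarbonConversionTable] = None
) -> float:
    """Per-cell carbon content in pgC from biovolume (um3 per cell)."""
    if not volume_um3 > 0:
        raise ValidationError(f"cell volume must be > 0, got {volume_um3}")
    table = table or CarbonConversionTable.default()
    a, b = table.lookup(group)
    return a * volume_um3**b


def biovolume_to_carbon(
    volume_um3: float,
    abundance_cells_ml: float,
    group: str,
    table: Optional[CarbonConversionTable] = None,
) -> float:
    """Community carbon biomass in mgC m-3.

    per-cell pgC x cells mL-1 gives pgC mL-1; pg->mg is 1e-9 and mL->m3 is
    1e6, a net factor of 1e-3.
    """
    if not abundance_cells_ml > 0:
        raise ValidationError(f"abundance must be > 0, got {abundance_cells_ml}")
    return cell_carbon(volume_um3, group, table) * abundance_cells_ml * 1e-3


def carbon_turnover(primary_production: float, phyto_c: float) -> float:
    """P^C = daily carbon fixation / phytoplankton carbon biomass, d-1."""
    if not phyto_c > 0:
        raise ValidationError(f"phytoplankton carbon must be > 0, got {phyto_c}")
    return primary_production / phyto_c


def carbon_to_chl(phyto_c: float, chl_a: float) -> float:
    """Carbon-to-chlorophyll-a ratio (dimensionless)."""
    if not chl_a > 0:
        raise ValidationError(f"chlorophyll a must be > 0, got {chl_a}")
    return phyto_c / chl_a


@dataclass
class StationRecord:
    """Surface biology + physics of one station.

    ``p_c`` and ``c_to_chl`` are always derived from the primary fields,
    never stored independently.  ``rsi`` is optional (NaN when the station
    lacks the hydrographic inputs or is excluded by design).
    """

    station_id: str
    region: str
    temperature: float  # degC, surface
    chl_a: float  # mg m-3
    phyto_c: float  # mgC m-3
    primary_production: float  # mgC m-3 d-1
    p_c: float = field(init=False)  # d-1
    c_to_chl: float = field(init=False)
    rsi: float = float("nan")  # mmol N kg-1
    rsi_excluded: bool = False
    rsi_exclude_reason: Optional[str] = None

    def __post_init__(self):
        validate_region(self.region)
        if not self.chl_a > 0:
            raise ValidationError(
                f"station {self.station_id}: chl_mg_m3 must be > 0, got {self.chl_a}"
            )
        if not self.phyto_c > 0:
            raise ValidationError(
                f"station {self.station_id}: phyto_c_mgc_m3 must be > 0, "
                f"got {self.phyto_c}"
            )
        if self.primary_production < 0:
            raise ValidationError(
                f"station {self.station_id}: pp_mgc_m3_d must be >= 0, "
                f"got {self.primary_production}"
            )
        self.p_c = carbon_turnover(self.primary_production, self.phyto_c)
        self.c_to_chl = carbon_to_chl(self.phyto_c, self.chl_a)


def read_stations_csv(path) -> pd.DataFrame:
    """Read and validate a station table CSV.

    Returns a DataFrame with the raw columns plus derived ``p_c`` and
    ``c_to_chl``.  Raises :class:`ValidationError` naming the first offending
    station and field.
    """
    df = pd.read_csv(path)
    missing = [c for c in STATION_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"station table missing columns: {', '.join(missing)}")
    return validate_stations_frame(df)


def validate_stations_frame(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    for _, row in df.iterrows():
        sid = row["station_id"]
        validate_region(str(row["region"]))
        for col, rule in (
            ("chl_mg_m3", "positive"),
            ("phyto_c_mgc_m3", "positive"),
            ("pp_mgc_m3_d", "nonnegative"),
        ):
            v = row[col]
            if not np.isfinite(v) or (rule == "positive" and v <= 0) or v < 0:
                raise ValidationError(
                    f"station {sid}: {col} must be "
                    f"{'> 0' if rule == 'positive' else '>= 0'}, got {v}"
                )
    df["p_c"] = df["pp_mgc_m3_d"] / df["phyto_c_mgc_m3"]
    df["c_to_chl"] = df["phyto_c_mgc_m3"] / df["chl_mg_m3"]
    return df


def write_stations_csv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, columns=[c for c in df.columns])
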