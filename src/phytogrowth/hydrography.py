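"""Reduction of CTD / optical / nutrient depth profiles to the quantities
that enter the resource supply index.

A station is represented by a :class:`DepthProfile` holding co-registered
vertical arrays of temperature, salinity, photosynthetically active radiation
(PAR) and nitrate.  From it we derive

* the surface density anomaly sigma_t (EOS-80, at the shallowest sample),
* the upper-mixed-layer depth: first depth at which sigma_t exceeds the
  surface value by a fixed threshold (default 0.125 kg m-3),
* the euphotic depth: the 1% surface-PAR level,
* the surface-to-euphotic-base density difference (stratification index), and
* nitrate concentration at the euphotic base.

"Surface" always means the shallowest sampled level — no extrapolation to
0 m.  All lookups interpolate linearly between bracketing samples (linearly
in log PAR for light, which is exact for exponentially attenuated
irradiance).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .eos80 import sigma_t
from .errors import CoverageError, NitrateQCWarning, ValidationError

FLAG_UML_NOT_REACHED = "uml_not_reached"
FLAG_PAR_FLOOR_NOT_REACHED = "par_floor_not_reached"
FLAG_NO3_CENSORED = "no3_censored"

#: Detection limit of the segmented-flow nitrate analysis, umol L-1.
NITRATE_DETECTION_LIMIT = 0.05

#: Default mixed-layer sigma_t offset, kg m-3.
UML_THRESHOLD = 0.125

#: Default euphotic-zone light level as a fraction of surface PAR.
EUPHOTIC_FRACTION = 0.01

PROFILE_COLUMNS = ["station_id", "depth_m", "temp_c", "sal_psu", "par", "no3_umol_l"]
DERIVED_COLUMNS = [
    "station_id",
    "sigma_t_surface",
    "uml_depth_m",
    "euphotic_depth_m",
    "delta_sigma_t",
    "no3_zeu_umol_l",
    "flags",
]


@dataclass
class DepthProfile:
    """One station's vertical profile, depth positive downward in metres.

    ``par`` and ``nitrate`` are optional per level: missing values are NaN.
    Depths must be strictly increasing with a shallowest sample at <= 5 m.
    """

    station_id: str
    depth: np.ndarray
    temperature: np.ndarray
    salinity: np.ndarray
    par: Optional[np.ndarray] = None
    nitrate: Optional[np.ndarray] = None

    def __post_init__(self):
        self.depth = np.asarray(self.depth, dtype=float)
        self.temperature = np.asarray(self.temperature, dtype=float)
        self.salinity = np.asarray(self.salinity, dtype=float)
        n = self.depth.size
        if n < 2:
            raise ValidationError(
                f"profile {self.station_id}: need at least 2 levels, got {n}"
            )
        for name in ("temperature", "salinity"):
            if getattr(self, name).size != n:
                raise ValidationError(
                    f"profile {self.station_id}: {name} length "
                    f"{getattr(self, name).size} != depth length {n}"
                )
        for name in ("par", "nitrate"):
            arr = getattr(self, name)
            if arr is not None:
                arr = np.asarray(arr, dtype=float)
                setattr(self, name, arr)
                if arr.size != n:
                    raise ValidationError(
                        f"profile {self.station_id}: {name} length {arr.size} "
                        f"!= depth length {n}"
                    )
        d = np.diff(self.depth)
        if np.any(d <= 0):
            raise ValidationError(
                f"profile {self.station_id}: depths must be strictly increasing "
                "(sort rows and remove duplicate depths first)"
            )
        if self.depth[0] > 5.0:
            raise ValidationError(
                f"profile {self.station_id}: shallowest sample at "
                f"{self.depth[0]:g} m; a surface sample (<= 5 m) is required"
            )
        if self.par is not None and np.any(self.par[np.isfinite(self.par)] <= 0):
            raise ValidationError(
                f"profile {self.station_id}: PAR values must be > 0 where present"
            )
        if self.nitrate is not None and np.any(
            self.nitrate[np.isfinite(self.nitrate)] < 0
        ):
            raise ValidationError(
                f"profile {self.station_id}: nitrate values must be >= 0"
            )

    def sigma_t_profile(self) -> np.ndarray:
        """sigma_t at each sampled level (EOS-80)."""
        return np.asarray(sigma_t(self.salinity, self.temperature))


@dataclass
class HydroDerived:
    """Per-station physics derived from a :class:`DepthProfile`."""

    station_id: str
    sigma_t_surface: float
    uml_depth: float
    euphotic_depth: float
    delta_sigma_t: float
    no3_euphotic_base: float  # NaN when nitrate is missing or uncovered
    flags: frozenset = field(default_factory=frozenset)


def mixed_layer_depth(
    profile: DepthProfile,
    threshold: float = UML_THRESHOLD,
    interpolate: bool = True,
) -> tuple[float, Optional[str]]:
    """Upper-mixed-layer depth by the sigma_t offset criterion.

    Returns the shallowest depth at which sigma_t reaches the surface value
    plus ``threshold``, located by linear interpolation between the
    bracketing samples.  With ``interpolate=False`` the first *sampled* depth
    at or past the crossing is returned instead (discrete-level variant, for
    comparison with coarser conventions).

    If the offset is never reached the deepest sampled depth is returned
    together with the flag ``"uml_not_reached"``.
    """
    sig = profile.sigma_t_profile()
    target = sig[0] + threshold
    idx = np.nonzero(sig >= target)[0]
    if idx.size == 0:
        return float(profile.depth[-1]), FLAG_UML_NOT_REACHED
    i = int(idx[0])
    if i == 0:
        return float(profile.depth[0]), None
    if not interpolate:
        return float(profile.depth[i]), None
    z0, z1 = profile.depth[i - 1], profile.depth[i]
    s0, s1 = sig[i - 1], sig[i]
    z = z0 + (z1 - z0) * (target - s0) / (s1 - s0)
    return float(z), None


def euphotic_depth(
    profile: DepthProfile, fraction: float = EUPHOTIC_FRACTION
) -> tuple[float, Optional[str]]:
    """Depth of the ``fraction`` x surface-PAR light level (default 1%).

    Interpolation is linear in log(PAR) versus depth, which reproduces an
    exponentially attenuated light field exactly whatever the sampling grid.
    If the profile never reaches the target level, the deepest depth with a
    PAR measurement is returned with the flag ``"par_floor_not_reached"``.
    """
    if profile.par is None:
        raise ValidationError(f"profile {profile.station_id}: no PAR data")
    ok = np.isfinite(profile.par)
    if not ok.any():
        raise ValidationError(f"profile {profile.station_id}: no PAR data")
    z = profile.depth[ok]
    p = profile.par[ok]
    if not np.isclose(z[0], profile.depth[0]):
        raise ValidationError(
            f"profile {profile.station_id}: PAR missing at the surface level"
        )
    target = p[0] * fraction
    idx = np.nonzero(p <= target)[0]
    if idx.size == 0:
        return float(z[-1]), FLAG_PAR_FLOOR_NOT_REACHED
    i = int(idx[0])
    if i == 0:
        return float(z[0]), None
    lp0, lp1 = np.log(p[i - 1]), np.log(p[i])
    frac = (lp0 - np.log(target)) / (lp0 - lp1)
    return float(z[i - 1] + (z[i] - z[i - 1]) * frac), None


def stratification_index(profile: DepthProfile, euphotic_depth_m: float) -> float:
    """Delta sigma_t: density anomaly at the euphotic base minus at surface.

    May be <= 0 for inverted profiles; returned as computed.
    """
    if not (profile.depth[0] <= euphotic_depth_m <= profile.depth[-1]):
        raise CoverageError(
            f"profile {profile.station_id}: euphotic depth {euphotic_depth_m:g} m "
            f"outside sampled range [{profile.depth[0]:g}, {profile.depth[-1]:g}] m"
        )
    sig = profile.sigma_t_profile()
    at_zeu = float(np.interp(euphotic_depth_m, profile.depth, sig))
    return at_zeu - float(sig[0])


def nitrate_at_euphotic_base(
    profile: DepthProfile,
    euphotic_depth_m: float,
    detection_limit: float = NITRATE_DETECTION_LIMIT,
) -> tuple[float, Optional[str]]:
    """Nitrate (umol L-1) linearly interpolated at the euphotic base.

    Input levels below the analytical detection limit are replaced by the
    limit itself (a conservative, traceable upper bound) and the result then
    carries the flag ``"no3_censored"``.  Emits :class:`NitrateQCWarning`
    (never an error) when the interpolated value is <= 0.2 umol L-1, an
    unusually low value for the base of the euphotic layer.
    """
    if profile.nitrate is None:
        raise ValidationError(f"profile {profile.station_id}: no nitrate data")
    ok = np.isfinite(profile.nitrate)
    if ok.sum() < 2:
        raise ValidationError(
            f"profile {profile.station_id}: nitrate needed at >= 2 levels"
        )
    z = profile.depth[ok]
    n = profile.nitrate[ok]
    if not (z[0] <= euphotic_depth_m <= z[-1]):
        raise CoverageError(
            f"profile {profile.station_id}: euphotic depth {euphotic_depth_m:g} m "
            f"outside nitrate coverage [{z[0]:g}, {z[-1]:g}] m"
        )
    censored = bool(np.any(n < detection_limit))
    n = np.maximum(n, detection_limit)
    value = float(np.interp(euphotic_depth_m, z, n))
    if value <= 0.2:
        warnings.warn(
            f"profile {profile.station_id}: nitrate at the euphotic base is "
            f"{value:.3g} umol/L (<= 0.2); check profile quality",
            NitrateQCWarning,
            stacklevel=2,
        )
    return value, (FLAG_NO3_CENSORED if censored else None)


def derive_hydrography(profile: DepthProfile) -> HydroDerived:
    """Compose the four profile reductions into one per-station record.

    Nitrate is optional: when the profile has no usable nitrate data (absent,
    fewer than two levels, or no coverage of the euphotic base) the
    ``no3_euphotic_base`` field is NaN and downstream RSI computation is
    skipped for the station; every other derived field is still reported.
    """
    sig0 = float(profile.sigma_t_profile()[0])
    flags: set[str] = set()
    zeu, f = euphotic_depth(profile)
    if f:
        flags.add(f)
    uml, f = mixed_layer_depth(profile)
    if f:
        flags.add(f)
    dsig = stratification_index(profile, zeu)
    try:
        no3, f = nitrate_at_euphotic_base(profile, zeu)
        if f:
            flags.add(f)
    except ValidationError:
        no3 = float("nan")
    return HydroDerived(
        station_id=profile.station_id,
        sigma_t_surface=sig0,
        uml_depth=uml,
        euphotic_depth=zeu,
        delta_sigma_t=dsig,
        no3_euphotic_base=no3,
        flags=frozenset(flags),
    )


# ---------------------------------------------------------------------------
# CSV interfaces
# ---------------------------------------------------------------------------

def profiles_to_frame(profiles: Iterable[DepthProfile]) -> pd.DataFrame:
    rows = []
    for p in profiles:
        n = p.depth.size
        rows.append(
            pd.DataFrame(
                {
                    "station_id": [p.station_id] * n,
                    "depth_m": p.depth,
                    "temp_c": p.temperature,
                    "sal_psu": p.salinity,
                    "par": p.par if p.par is not None else np.full(n, np.nan),
                    "no3_umol_l": p.nitrate if p.nitrate is not None else np.full(n, np.nan),
                }
            )
        )
    if not rows:
        return pd.DataFrame(columns=PROFILE_COLUMNS)
    return pd.concat(rows, ignore_index=True)


def frame_to_profiles(df: pd.DataFrame) -> list[DepthProfile]:
    missing = [c for c in PROFILE_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"profile table missing columns: {', '.join(missing)}")
    profiles = []
    for sid, g in df.groupby("station_id", sort=False):
        g = g.sort_values("depth_m")
        par = g["par"].to_numpy(dtype=float)
        no3 = g["no3_umol_l"].to_numpy(dtype=float)
        profiles.append(
            DepthProfile(
                station_id=str(sid),
                depth=g["depth_m"].to_numpy(dtype=float),
                temperature=g["temp_c"].to_numpy(dtype=float),
                salinity=g["sal_psu"].to_numpy(dtype=float),
                par=par if np.isfinite(par).any() else None,
                nitrate=no3 if np.isfinite(no3).any() else None,
            )
        )
    return profiles


def read_profiles_csv(path) -> list[DepthProfile]:
    """Read a long-format profile CSV (one row per station x depth level)."""
    return frame_to_profiles(pd.read_csv(path))


def write_profiles_csv(profiles: Iterable[DepthProfile], path) -> None:
    profiles_to_frame(profiles).to_csv(path, index=False)


def derived_to_frame(derived: Iterable[HydroDerived]) -> pd.DataFrame:
    rows = [
        {
            "station_id": d.station_id,
            "sigma_t_surface": d.sigma_t_surface,
            "uml_depth_m": d.uml_depth,
            "euphotic_depth_m": d.euphotic_depth,
            "delta_sigma_t": d.delta_sigma_t,
            "no3_zeu_umol_l": d.no3_euphotic_base,
            "flags": ";".join(sorted(d.flags)),
        }
        for d in derived
    ]
    return pd.DataFrame(rows, columns=DERIVED_COLUMNS)


def write_derived_csv(derived: Iterable[HydroDerived], path) -> None:
    derived_to_frame(derived).to_csv(path, index=False)


def read_derived_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in DERIVED_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"derived table missing columns: {', '.join(missing)}")
    df["flags"] = df["flags"].fillna("")
    return df
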