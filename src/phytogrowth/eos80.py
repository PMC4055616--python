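"""One-atmosphere seawater density from the EOS-80 equation of state.

Implements the UNESCO (1983) / Millero & Poisson (1981) polynomial for the
density of seawater at atmospheric pressure, rho(S, T, p=0), as a function of
practical salinity S (PSS-78) and temperature T (degC, IPTS-68).  The quantity
exposed is the conventional sigma-t,

    sigma_t = rho(S, T, 0) - 1000  [kg m-3],

which is the density anomaly oceanographers use to describe water-column
stratification when pressure effects are neglected.

Published check values for the standard (used in the test suite):
rho(35, 5, 0) = 1027.67547, rho(0, 5, 0) = 999.96675,
rho(35, 25, 0) = 1023.34306 kg m-3.
"""

from __future__ import annotations

import numpy as np

from .errors import ValidationError

# Pure-water density polynomial in T (Bigg 1967, as adopted by EOS-80).
_RW = (999.842594, 6.793952e-2, -9.095290e-3, 1.001685e-4, -1.120083e-6, 6.536332e-9)
# Salinity terms (Millero & Poisson 1981).
_A = (8.24493e-1, -4.0899e-3, 7.6438e-5, -8.2467e-7, 5.3875e-9)
_B = (-5.72466e-3, 1.0227e-4, -1.6546e-6)
_C = 4.8314e-4

#: Validity range of the one-atmosphere polynomial.
SALINITY_RANGE: tuple[float, float] = (0.0, 42.0)
TEMPERATURE_RANGE: tuple[float, float] = (-2.0, 40.0)


def _polyval(t: np.ndarray, coeffs) -> np.ndarray:
    out = np.zeros_like(t)
    for c in reversed(coeffs):
        out = out * t + c
    return out


def sigma_t(salinity, temperature):
    """Density anomaly sigma_t = rho(S, T, 0) - 1000 in kg m-3.

    Parameters
    ----------
    salinity : array_like
        Practical salinity, dimensionless (PSU), in [0, 42].
    temperature : array_like
        Temperature in degC, in [-2, 40].

    Returns
    -------
    float or ndarray
        sigma_t, elementwise over broadcast inputs; a Python float for
        scalar inputs.

    Raises
    ------
    ValidationError
        If any input falls outside the polynomial's validity range; the
        message names the offending value.
    """
    s = np.asarray(salinity, dtype=float)
    t = np.asarray(temperature, dtype=float)

    s_lo, s_hi = SALINITY_RANGE
    t_lo, t_hi = TEMPERATURE_RANGE
    bad_s = (s < s_lo) | (s > s_hi)
    if np.any(bad_s):
        offending = float(np.atleast_1d(s)[np.atleast_1d(bad_s)][0])
        raise ValidationError(
            f"salinity {offending} PSU outside EOS-80 validity range [{s_lo}, {s_hi}]"
        )
    bad_t = (t < t_lo) | (t > t_hi)
    if np.any(bad_t):
        offending = float(np.atleast_1d(t)[np.atleast_1d(bad_t)][0])
        raise ValidationError(
            f"temperature {offending} degC outside EOS-80 validity range [{t_lo}, {t_hi}]"
        )

    s, t = np.broadcast_arrays(s, t)
    rho_w = _polyval(t, _RW)
    a = _polyval(t, _A)
    b = _polyval(t, _B)
    rho = rho_w + a * s + b * s**1.5 + _C * s**2
    out = rho - 1000.0
    if out.ndim == 0:
        return float(out)
    return out
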