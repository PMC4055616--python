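"""Exception and warning types shared across the package.

All data-validation failures derive from :class:`ValidationError` (itself a
``ValueError``) so callers — in particular the command line layer — can map
"the input is wrong" onto a distinct exit status from "the code is broken".
"""


class ValidationError(ValueError):
    """Input data violate a documented contract (bad profile, bad CSV cell)."""


class CoverageError(ValidationError):
    """An interpolation target lies outside the depth range covered by data."""


class DegenerateDataError(ValidationError):
    """A statistic is undefined for the data (e.g. zero variance)."""


class BootstrapInstabilityError(RuntimeError):
    """Too many degenerate bootstrap resamples for a trustworthy interval."""


class ConfigurationError(ValidationError):
    """A configuration value is missing, unknown, or infeasible."""


class ProfileConstructionError(RuntimeError):
    """A synthetic profile cannot realise the requested targets."""


class NitrateQCWarning(UserWarning):
    """Nitrate at the euphotic base is suspiciously low (<= 0.2 umol/L)."""
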