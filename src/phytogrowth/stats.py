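"""Statistical layer: model-II regression and group comparisons.

The central tool is reduced major-axis (RMA) regression, the model-II fit
appropriate when both variables carry error (as both production and biomass
estimates do).  Its slope is sign(r) * sd(y)/sd(x) with sample (n-1)
standard deviations; confidence intervals come from bootstrapping over
cases (stations), percentile method by default.

Supporting routines — Pearson correlation with the t-transform p-value,
ordinary least squares with a slope t-test, and the Mann-Whitney U rank-sum
test — delegate to scipy; the surrounding contracts (degenerate-data
detection, exact-vs-asymptotic switching) are enforced here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import BootstrapInstabilityError, DegenerateDataError, ValidationError

#: Chlorophyll concentration bin edges (mg m-3); intervals are right-open
#: [lo, hi), the last bin extending to infinity.
CHL_BIN_EDGES: tuple[float, ...] = (0.0, 0.2, 0.5, 2.0, 5.0)


@dataclass
class RMAFit:
    """A reduced-major-axis fit, optionally with bootstrap CIs."""

    slope: float
    intercept: float
    pearson_r: float
    n: int
    ci_level: Optional[float] = None
    slope_ci: Optional[tuple[float, float]] = None
    intercept_ci: Optional[tuple[float, float]] = None
    n_boot: Optional[int] = None
    seed: Optional[int] = None
    n_degenerate_redrawn: int = 0

    def to_dict(self) -> dict:
        d = {
            "slope": self.slope,
            "intercept": self.intercept,
            "pearson_r": self.pearson_r,
            "n": self.n,
        }
        if self.slope_ci is not None:
            d.update(
                ci_level=self.ci_level,
                slope_ci=list(self.slope_ci),
                intercept_ci=list(self.intercept_ci),
                n_boot=self.n_boot,
                seed=self.seed,
                n_degenerate_redrawn=self.n_degenerate_redrawn,
            )
        return d


class OLSFit(NamedTuple):
    slope: float
    intercept: float
    p_slope: float
    n: int


@dataclass
class GroupTestResult:
    """Two-sided Mann-Whitney U comparison of two groups."""

    group_a: str
    group_b: str
    u_statistic: float
    p_value: float
    n_a: int
    n_b: int
    method: str = "exact"


def _check_xy(x, y, min_n: int = 3) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("x and y must be 1-D arrays of equal length")
    if x.size < min_n:
        raise ValidationError(f"need at least {min_n} observations, got {x.size}")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValidationError("x and y must be finite")
    return x, y


def rma_fit(x: Sequence[float], y: Sequence[float]) -> RMAFit:
    """Reduced-major-axis regression of y on x.

    slope = sign(r) * sd(y)/sd(x); intercept = mean(y) - slope * mean(x).
    Equivalently, |slope| is the geometric mean of the OLS(y|x) slope and
    the reciprocal of the OLS(x|y) slope.
    """
    x, y = _check_xy(x, y)
    sx = x.std(ddof=1)
    sy = y.std(ddof=1)
    if sx == 0 or sy == 0:
        raise DegenerateDataError("zero variance in x or y; RMA slope undefined")
    r = float(np.corrcoef(x, y)[0, 1])
    slope = (1.0 if r >= 0 else -1.0) * sy / sx
    intercept = float(y.mean() - slope * x.mean())
    return RMAFit(slope=float(slope), intercept=intercept, pearson_r=r, n=x.size)


def _rma_rows(xs: np.ndarray, ys: np.ndarray):
    """Row-wise RMA slope/intercept for a (m, n) matrix of resamples."""
    n = xs.shape[1]
    mx = xs.mean(axis=1)
    my = ys.mean(axis=1)
    xc = xs - mx[:, None]
    yc = ys - my[:, None]
    vx = (xc**2).sum(axis=1) / (n - 1)
    vy = (yc**2).sum(axis=1) / (n - 1)
    valid = (vx > 0) & (vy > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        cov = (xc * yc).sum(axis=1) / (n - 1)
        sign = np.where(cov >= 0, 1.0, -1.0)
        slope = sign * np.sqrt(vy / vx)
        intercept = my - slope * mx
    return slope, intercept, valid


def bootstrap_rma_ci(
    x: Sequence[float],
    y: Sequence[float],
    n_boot: int = 2000,
    ci_level: float = 0.95,
    seed: Optional[int] = None,
    method: str = "percentile",
) -> RMAFit:
    """RMA fit with case-resampling bootstrap confidence intervals.

    Stations (x_i, y_i) are resampled with replacement ``n_boot`` times and
    the ``ci_level`` percentile interval of the slope and intercept is
    reported.  Resamples with zero variance in either variable are redrawn
    and counted; more than 10% of them aborts with
    :class:`BootstrapInstabilityError`.  ``method="bca"`` switches to the
    bias-corrected accelerated interval (via scipy).
    """
    fit = rma_fit(x, y)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    rng = np.random.default_rng(seed)

    if method == "bca":
        lo_s, hi_s = _bca_interval(x, y, "slope", n_boot, ci_level, rng)
        lo_i, hi_i = _bca_interval(x, y, "intercept", n_boot, ci_level, rng)
        n_degenerate = 0
    elif method == "percentile":
        idx = rng.integers(0, n, size=(n_boot, n))
        slope, intercept, valid = _rma_rows(x[idx], y[idx])
        n_degenerate = int((~valid).sum())
        while not valid.all():
            if n_degenerate > 0.1 * n_boot:
                raise BootstrapInstabilityError(
                    f"{n_degenerate} degenerate resamples out of {n_boot}; "
                    "data too discrete or too small for a stable bootstrap"
                )
            bad = np.nonzero(~valid)[0]
            idx_new = rng.integers(0, n, size=(bad.size, n))
            s_new, i_new, v_new = _rma_rows(x[idx_new], y[idx_new])
            slope[bad] = s_new
            intercept[bad] = i_new
            valid[bad] = v_new
            n_degenerate += int((~v_new).sum())
        alpha = (1.0 - ci_level) / 2.0
        lo_s, hi_s = np.percentile(slope, [100 * alpha, 100 * (1 - alpha)])
        lo_i, hi_i = np.percentile(intercept, [100 * alpha, 100 * (1 - alpha)])
    else:
        raise ValidationError(f"unknown bootstrap method {method!r}")

    return RMAFit(
        slope=fit.slope,
        intercept=fit.intercept,
        pearson_r=fit.pearson_r,
        n=n,
        ci_level=ci_level,
        slope_ci=(float(lo_s), float(hi_s)),
        intercept_ci=(float(lo_i), float(hi_i)),
        n_boot=n_boot,
        seed=seed,
        n_degenerate_redrawn=n_degenerate,
    )


def _bca_interval(x, y, which, n_boot, ci_level, rng):
    def statistic(xs, ys):
        f = rma_fit(xs, ys)
        return f.slope if which == "slope" else f.intercept

    res = sps.bootstrap(
        (x, y),
        statistic,
        paired=True,
        vectorized=False,
        n_resamples=n_boot,
        confidence_level=ci_level,
        method="BCa",
        rng=rng,
    )
    return res.confidence_interval.low, res.confidence_interval.high


def pearson_test(x: Sequence[float], y: Sequence[float]) -> tuple[float, float, int]:
    """Pearson product-moment correlation with two-sided t-transform p-value."""
    x, y = _check_xy(x, y)
    if x.std(ddof=1) == 0 or y.std(ddof=1) == 0:
        raise DegenerateDataError("zero variance in x or y; correlation undefined")
    res = sps.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue), x.size


def ols_fit(x: Sequence[float], y: Sequence[float]) -> OLSFit:
    """Ordinary least squares of y on x with a two-sided slope t-test."""
    x, y = _check_xy(x, y)
    if x.std(ddof=1) == 0:
        raise DegenerateDataError("zero variance in x; OLS slope undefined")
    res = sps.linregress(x, y)
    return OLSFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        p_slope=float(res.pvalue),
        n=x.size,
    )


def mann_whitney(
    a: Sequence[float],
    b: Sequence[float],
    group_a: str = "a",
    group_b: str = "b",
) -> GroupTestResult:
    """Two-sided Mann-Whitney U rank-sum test.

    The p-value is exact (full enumeration of rank arrangements) when
    n_a * n_b <= 400 and the pooled data are tie-free; otherwise the normal
    approximation with midrank tie correction and continuity correction is
    used.  Note this is the standard rank-sum test of stochastic ordering,
    the conventional reading of "comparing means between groups"
    non-parametrically.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValidationError("both groups must be non-empty")
    if a.size < 2 or b.size < 2:
        raise ValidationError(
            f"need >= 2 observations per group, got {a.size} and {b.size}"
        )
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (not has_ties and a.size * b.size <= 400) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return GroupTestResult(
        group_a=group_a,
        group_b=group_b,
        u_statistic=float(res.statistic),
        p_value=float(min(res.pvalue, 1.0)),
        n_a=a.size,
        n_b=b.size,
        method=method,
    )


def chl_bin_label(lo: float, hi: float) -> str:
    return f">{lo:g}" if np.isinf(hi) else f"{lo:g}-{hi:g}"


def bin_by_chl(
    df: pd.DataFrame,
    edges: Sequence[float] = CHL_BIN_EDGES,
    chl_col: str = "chl_mg_m3",
    value_col: str = "p_c",
) -> pd.DataFrame:
    """Group stations into chlorophyll concentration classes.

    Bins are right-open intervals [lo, hi) over ``edges``, with a final
    (last_edge, inf) class, so a station at exactly 0.2 mg m-3 falls in the
    0.2-0.5 bin.  Returns one row per bin: label, n, member station ids and
    the mean, SD and mean chlorophyll of ``value_col`` members.
    """
    if (df[chl_col] <= 0).any():
        bad = df.loc[df[chl_col] <= 0, "station_id"].iloc[0]
        raise ValidationError(f"station {bad}: {chl_col} must be > 0")
    full_edges = list(edges) + [np.inf]
    labels = [chl_bin_label(lo, hi) for lo, hi in zip(full_edges[:-1], full_edges[1:])]
    cut = pd.cut(df[chl_col], bins=full_edges, right=False, labels=labels)
    rows = []
    for label in labels:
        sub = df[cut == label]
        vals = sub[value_col].to_numpy(dtype=float)
        rows.append(
            {
                "bin": label,
                "n": int(len(sub)),
                "mean_chl": float(sub[chl_col].mean()) if len(sub) else float("nan"),
                f"mean_{value_col}": float(vals.mean()) if vals.size else float("nan"),
                f"sd_{value_col}": float(vals.std(ddof=1)) if vals.size > 1 else float("nan"),
                "station_ids": list(sub["station_id"]) if "station_id" in sub else [],
            }
        )
    return pd.DataFrame(rows)
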