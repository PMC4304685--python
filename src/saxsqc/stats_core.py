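"""Regression t-test engine, χ² profile comparison and frame filtering.

The central statistic everywhere is the ordinary-least-squares slope of a
SAXS parameter against an abscissa (exposure number, or relative
concentration scale), tested with t = a/s_a on n−2 degrees of freedom.  A
two-tailed p-value below 0.05 is treated as evidence of a real trend —
radiation damage across an exposure series, interparticle interference
across a dilution series.

Frame filtering combines three pieces: a modified z-score outlier screen
(cutoff 3.5), pairwise reduced-χ² similarity to the first (lowest-dose)
exposure, and a sequential last-frame rejection loop: while the trend is
significant, the highest-dose frame is dropped and the regression is refit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .io_formats import ScatteringProfile, SeriesError

DEFAULT_ALPHA = 0.05
DEFAULT_Z_CUTOFF = 3.5

# residuals below this fraction of the response scale count as an exact fit
_EXACT_FIT_RTOL = 1e-10


@dataclass
class TrendTest:
    """OLS slope with its t-statistic and two-tailed p-value."""

    slope: float
    stderr: float
    t: float
    df: int
    p: float
    intercept: float

    @property
    def significant(self) -> bool:
        return self.p < DEFAULT_ALPHA


@dataclass
class ChiSq:
    """Reduced χ² between two same-grid profiles."""

    value: float
    n_points: int
    dof: int


def t_to_pvalue(t: float, df: int) -> float:
    """Two-tailed p-value of a t-statistic, p = 2·(1 − CDF_t(|t|, df)).

    Computed from the continuous Student-t CDF (regularized incomplete
    beta), not a lookup table.
    """
    if df < 1:
        raise ValueError("df must be at least 1")
    if not np.isfinite(t):
        return 0.0
    return float(2.0 * stats.t.sf(abs(t), df))


def linreg_ttest(
    x: np.ndarray, y: np.ndarray, y_err: np.ndarray | None = None
) -> TrendTest:
    """Ordinary least squares of y on x with a slope t-test.

    The standard error of the slope comes from the residual variance with
    n−2 degrees of freedom.  ``y_err`` is accepted for interface symmetry
    but the fit is unweighted.  Degenerate cases: an exactly flat response
    gives t = 0, p = 1; an exact nonzero trend (zero residuals) gives p = 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 points for a slope t-test")
    sxx = np.sum((x - x.mean()) ** 2)
    if sxx == 0:
        raise ValueError("degenerate regressor: all x equal")
    slope = float(np.sum((x - x.mean()) * (y - y.mean())) / sxx)
    intercept = float(y.mean() - slope * x.mean())
    resid = y - (intercept + slope * x)
    ssr = float(np.sum(resid**2))
    df = n - 2
    y_scale = float(np.max(np.abs(y))) or 1.0
    if ssr <= (_EXACT_FIT_RTOL * y_scale) ** 2 * n:
        # exact fit: zero slope -> no trend, nonzero slope -> certain trend
        if abs(slope) <= _EXACT_FIT_RTOL * y_scale:
            return TrendTest(slope, 0.0, 0.0, df, 1.0, intercept)
        return TrendTest(slope, 0.0, float("inf"), df, 0.0, intercept)
    s_a = float(np.sqrt(ssr / df / sxx))
    t = slope / s_a
    return TrendTest(slope, s_a, t, df, t_to_pvalue(t, df), intercept)


def chi2_compare(a: ScatteringProfile, b: ScatteringProfile) -> ChiSq:
    """Reduced χ² between two profiles on one q grid.

    χ² = (1/ν)·Σ (I_a − I_b)² / (σ_a² + σ_b²) with ν = n.  The two error
    columns are combined in quadrature, which makes the expectation exactly 1
    for two independent noisy realizations of the same curve; identical
    profiles give exactly 0.  The statistic is symmetric in its arguments.
    """
    if not a.same_grid(b):
        raise SeriesError("chi2_compare requires identical q grids")
    n = len(a)
    var = a.sigma**2 + b.sigma**2
    value = float(np.sum((a.intensity - b.intensity) ** 2 / var) / n)
    return ChiSq(value, n, n)


def modified_z_outliers(
    values: np.ndarray, cutoff: float = DEFAULT_Z_CUTOFF
) -> np.ndarray:
    """Flag outliers by the modified z-score M = 0.6745·(x − median)/MAD.

    Values with |M| > ``cutoff`` (default 3.5) are flagged.  When the MAD is
    zero (a majority of identical values) any value differing from the
    median is flagged instead.
    """
    x = np.asarray(values, dtype=float)
    if len(x) < 3:
        raise ValueError("need at least 3 values for outlier screening")
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    if mad == 0:
        return x != med
    m = 0.6745 * (x - med) / mad
    return np.abs(m) > cutoff


def average_profiles(profiles: list[ScatteringProfile]) -> ScatteringProfile:
    """Inverse-variance weighted pointwise average of same-grid profiles.

    The output error is σ = (Σ 1/σ_i²)^(−1/2), so averaging k equally noisy
    frames reduces σ by √k.
    """
    if not profiles:
        raise ValueError("cannot average an empty list of profiles")
    first = profiles[0]
    for p in profiles[1:]:
        if not first.same_grid(p):
            raise SeriesError("profiles to average must share one q grid")
    w = np.array([1.0 / p.sigma**2 for p in profiles])
    i = np.array([p.intensity for p in profiles])
    wsum = w.sum(axis=0)
    avg_i = (w * i).sum(axis=0) / wsum
    avg_sigma = 1.0 / np.sqrt(wsum)
    return ScatteringProfile(first.q.copy(), avg_i, avg_sigma, label="averaged")


def sequential_rejection(
    x: np.ndarray, y: np.ndarray, alpha: float = DEFAULT_ALPHA
) -> tuple[np.ndarray, TrendTest | None]:
    """Drop trailing points while the trend stays significant.

    Starting from the full series, while the two-tailed p of the slope is
    below ``alpha`` the highest-abscissa point is removed and the fit is
    recomputed.  If fewer than 3 points would remain, the entire series is
    rejected (empty kept set, no final fit).  Returns the kept positional
    indices (a prefix of the input order) and the final TrendTest.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3:
        raise ValueError("need at least 3 points")
    order = np.argsort(x, kind="stable")
    xs, ys = x[order], y[order]
    n = len(xs)
    while n >= 3:
        fit = linreg_ttest(xs[:n], ys[:n])
        if fit.p >= alpha:
            return order[:n], fit
        n -= 1
    return order[:0], None


def filter_frames(
    x: np.ndarray,
    y: np.ndarray,
    alpha: float = DEFAULT_ALPHA,
    z_cutoff: float = DEFAULT_Z_CUTOFF,
) -> tuple[np.ndarray, TrendTest | None]:
    """Combined frame filter: modified z-score screen, then sequential
    rejection of trailing frames on the survivors.

    The outlier screen catches step-like jumps (a few grossly deviating
    frames) that the trend test alone cannot isolate; the sequential loop
    then removes a residual dose-correlated trend.  Returns kept positional
    indices into the input arrays and the final trend fit.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    flags = modified_z_outliers(y, cutoff=z_cutoff)
    survivors = np.flatnonzero(~flags)
    if len(survivors) < 3:
        return survivors[:0], None
    kept_local, fit = sequential_rejection(x[survivors], y[survivors], alpha=alpha)
    return survivors[kept_local], fit
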