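"""Guinier analysis: R_g/I(0) fits, region selection and a linearity test.

For a monodisperse globular particle, ln I(q) is linear in q² at low q
(q < 1.3/R_g) with slope −R_g²/3 and intercept ln I(0).  Three fitting
regions are used, all terminating at q_max,G = 1.3/R_g with R_g taken from
the P(r) distribution:

* region 1 — every measured point below 1.3/R_g;
* region 2 — starts at the first Shannon channel, q_min,G = π/D_max;
* region 3 — starts at 0.65/R_g, i.e. half of q_max,G.

A sliding-window test probes linearity: the OLS slope of each block of
three consecutive (q², ln I) points is computed, the blocks advance one
point at a time, and the slopes are regressed against the window-center q².
A significant positive slope-of-slopes indicates attractive interparticle
interactions (low-q upturn); a negative one, repulsion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_formats import ScatteringProfile
from .stats_core import linreg_ttest

QMAX_RG_LIMIT = 1.3
MIN_REGION_POINTS = 5  # three sliding windows -> one slope-of-slopes df


@dataclass
class GuinierResult:
    rg: float
    rg_err: float
    i0: float
    i0_err: float
    q_min_G: float
    q_max_G: float
    n_points: int
    region_id: int | None = None
    converged: bool = True

    @property
    def ok(self) -> bool:
        return np.isfinite(self.rg) and self.rg > 0


@dataclass
class GuinierRegion:
    q_min_G: float
    q_max_G: float
    region_id: int
    usable: bool
    n_points: int


@dataclass
class NonlinearityResult:
    p: float
    sign: str  # "attractive" | "repulsive" | "none"
    n_windows: int
    slope_of_slopes: float = float("nan")


def guinier_fit(
    profile: ScatteringProfile,
    q_min_G: float,
    q_max_G: float,
    region_id: int | None = None,
) -> GuinierResult:
    """Least-squares line through (q², ln I) over q_min_G ≤ q < q_max_G
    (the Guinier regime is q strictly below 1.3/R_g);
    R_g = (−3·slope)^½ and I(0) = exp(intercept).

    A non-negative slope means R_g is undefined; the result is returned
    flagged with rg = NaN rather than raising, so callers can record the
    parameter as absent.
    """
    mask = (profile.q >= q_min_G) & (profile.q < q_max_G)
    n = int(mask.sum())
    if n < 3:
        raise ValueError(
            f"Guinier region [{q_min_G:.4g}, {q_max_G:.4g}) contains only {n} points"
        )
    q2 = profile.q[mask] ** 2
    intensity = profile.intensity[mask]
    if np.any(intensity <= 0):
        return GuinierResult(
            float("nan"), float("nan"), float("nan"), float("nan"),
            q_min_G, q_max_G, n, region_id, converged=False,
        )
    ln_i = np.log(intensity)
    fit = linreg_ttest(q2, ln_i)
    if fit.slope >= 0:
        return GuinierResult(
            float("nan"), float("nan"), float(np.exp(fit.intercept)), float("nan"),
            q_min_G, q_max_G, n, region_id, converged=False,
        )
    rg = float(np.sqrt(-3.0 * fit.slope))
    # error propagation: rg = (−3a)^½ -> σ_rg = 3 σ_a / (2 rg)
    rg_err = 1.5 * fit.stderr / rg
    # intercept stderr from the same residual variance
    q2bar = q2.mean()
    sxx = float(np.sum((q2 - q2bar) ** 2))
    resid = ln_i - (fit.intercept + fit.slope * q2)
    s2 = float(np.sum(resid**2)) / max(n - 2, 1)
    b_err = float(np.sqrt(s2 * (1.0 / n + q2bar**2 / sxx))) if sxx > 0 else 0.0
    i0 = float(np.exp(fit.intercept))
    return GuinierResult(
        rg, rg_err, i0, i0 * b_err, q_min_G, q_max_G, n, region_id
    )


def guinier_regions(
    rg_pr: float, dmax: float, q_grid: np.ndarray
) -> list[GuinierRegion]:
    """The three Guinier intervals, clipped to the measured q grid.

    A region holding fewer than 5 grid points is marked unusable (its
    parameters propagate as absent, not as failures).
    """
    if rg_pr <= 0 or dmax <= 0:
        raise ValueError("rg_pr and dmax must be positive")
    q = np.asarray(q_grid, dtype=float)
    q_max_G = QMAX_RG_LIMIT / rg_pr
    bounds = [
        (float(q[0]), q_max_G),
        (max(float(q[0]), np.pi / dmax), q_max_G),
        (max(float(q[0]), 0.65 / rg_pr), q_max_G),
    ]
    regions = []
    for rid, (lo, hi) in enumerate(bounds, start=1):
        n = int(np.sum((q >= lo) & (q < hi)))
        regions.append(GuinierRegion(lo, hi, rid, usable=n >= MIN_REGION_POINTS, n_points=n))
    return regions


def iterate_guinier(
    profile: ScatteringProfile,
    rg_seed: float,
    rtol: float = 0.01,
    max_iter: int = 10,
) -> GuinierResult:
    """Self-consistent Guinier fit: fit over q < 1.3/R_g, update R_g, repeat.

    Stops when R_g changes by less than ``rtol`` (relative) or after
    ``max_iter`` cycles; a non-convergent cycle returns the iterate with the
    smallest relative R_g change, flagged ``converged=False``.
    """
    if rg_seed <= 0:
        raise ValueError("rg_seed must be positive")
    rg = rg_seed
    best: GuinierResult | None = None
    best_delta = np.inf
    for _ in range(max_iter):
        q_hi = QMAX_RG_LIMIT / rg
        try:
            res = guinier_fit(profile, profile.q[0], q_hi, region_id=1)
        except ValueError:
            break
        if not res.ok:
            return res
        delta = abs(res.rg - rg) / rg
        if delta < best_delta:
            best, best_delta = res, delta
        if delta < rtol:
            return res
        rg = res.rg
    if best is None:
        return GuinierResult(
            float("nan"), float("nan"), float("nan"), float("nan"),
            profile.q[0], QMAX_RG_LIMIT / rg, 0, 1, converged=False,
        )
    best.converged = False
    return best


def crude_rg_seed(profile: ScatteringProfile, n_points: int = 20) -> float:
    """Fallback R_g seed from a Guinier fit of the first ``n_points`` points."""
    res = guinier_fit(profile, profile.q[0], profile.q[min(n_points, len(profile)) - 1])
    if res.ok:
        return res.rg
    # last resort: a generic small-protein size so iteration can start
    return 1.0 / profile.q[len(profile) // 4]


def rg_seed(profile: ScatteringProfile) -> float:
    """Converged low-q Guinier R_g used to seed the D_max search."""
    res = iterate_guinier(profile, crude_rg_seed(profile))
    if res.ok:
        return res.rg
    return crude_rg_seed(profile)


def nonlinearity_test(
    profile: ScatteringProfile,
    q_min_G: float,
    q_max_G: float,
    alpha: float = 0.05,
) -> NonlinearityResult:
    """Slope-of-slopes linearity test on a Guinier region.

    Each block of three consecutive (q², ln I) points is fit by least
    squares, the block advances one point at a time, and the resulting
    slopes are regressed against the mean q² of their block.  For a linear
    region every window slope is equal and p = 1.  The sign is reported only
    for a significant trend: positive slope-of-slopes → attractive,
    negative → repulsive.
    """
    mask = (profile.q >= q_min_G) & (profile.q < q_max_G)
    n = int(mask.sum())
    if n < MIN_REGION_POINTS:
        return NonlinearityResult(float("nan"), "none", max(n - 2, 0))
    q2 = profile.q[mask] ** 2
    intensity = profile.intensity[mask]
    if np.any(intensity <= 0):
        return NonlinearityResult(float("nan"), "none", n - 2)
    ln_i = np.log(intensity)
    n_windows = n - 2
    slopes = np.empty(n_windows)
    centers = np.empty(n_windows)
    for j in range(n_windows):
        xw, yw = q2[j : j + 3], ln_i[j : j + 3]
        xb = xw.mean()
        slopes[j] = np.sum((xw - xb) * (yw - yw.mean())) / np.sum((xw - xb) ** 2)
        centers[j] = xb
    fit = linreg_ttest(centers, slopes)
    if fit.p <= alpha:
        sign = "attractive" if fit.slope > 0 else "repulsive"
    else:
        sign = "none"
    return NonlinearityResult(fit.p, sign, n_windows, fit.slope)
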