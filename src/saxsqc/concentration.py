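"""Dilution-series analysis: relative scaling, the ten-parameter
concentration-dependence test, impact quantification and concentration
estimation.

Nominal concentrations of a serial dilution are unreliable (pipetting
error, evaporation), so each member of the series is put on a relative
scale computed from the data: the median ratio of its intensities to the
first (lowest) concentration over a window of 50 points starting at
q = 0.07 Å⁻¹ — a region flat enough to be insensitive to weak
interparticle interference yet still above the noise floor.  The first
member gets abscissa 1 and these scale factors are the regressors for
every trend test.

Ten parameters are tested against the abscissae: R_g and I(0) from the
P(r) distribution and from each of the three Guinier regions (4 + 4),
D_max, and the Porod molecular weight.  The impact of a trend is the
absolute regression slope as a percentage of its y-intercept, converted to
per mg ml⁻¹ using concentrations estimated from a calibration constant.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import guinier as gmod
from . import ift as ift_mod
from . import porod as porod_mod
from .io_formats import ConcentrationSeries, ScatteringProfile
from .stats_core import TrendTest, linreg_ttest

logger = logging.getLogger(__name__)

SCALE_Q_START = 0.07  # Å⁻¹
SCALE_N_POINTS = 50

#: canonical order of the ten concentration parameters
CONC_PARAMETERS = (
    "rg_pr", "rg_g1", "rg_g2", "rg_g3",
    "i0_pr", "i0_g1", "i0_g2", "i0_g3",
    "dmax", "mw_porod",
)


class ScalingError(ValueError):
    pass


@dataclass
class ScaleResult:
    abscissae: np.ndarray
    scaling_region: tuple[float, int]  # (q_start, n_points)


@dataclass
class ProfileParameters:
    """All per-profile quantities the trend tests consume."""

    values: dict[str, float]
    pr: ift_mod.PrResult | None = None
    regions: list[gmod.GuinierRegion] = field(default_factory=list)
    guinier_fits: dict[int, gmod.GuinierResult] = field(default_factory=dict)


@dataclass
class ParameterTrend:
    name: str
    values: list[float]
    test: TrendTest | None
    impact_percent: float | None  # % per mg/ml (or per unit abscissa if uncalibrated)


@dataclass
class ConcentrationReport:
    trends: dict[str, ParameterTrend]
    abscissae: np.ndarray
    estimated_concentrations: np.ndarray | None
    median_impact: float | None
    impact_units: str  # "percent_per_mg_ml" | "percent_per_abscissa"


def scale_series(
    series: ConcentrationSeries,
    q_start: float = SCALE_Q_START,
    n_points: int = SCALE_N_POINTS,
) -> ScaleResult:
    """Relative abscissae from median intensity ratios to the first member.

    If fewer than ``n_points`` grid points remain past ``q_start`` all of
    them are used with a warning; no points at all is a scaling error.
    """
    q = series.profiles[0].q
    start_idx = int(np.searchsorted(q, q_start))
    if start_idx >= len(q):
        raise ScalingError(f"no data points at q >= {q_start}")
    end_idx = start_idx + n_points
    if end_idx > len(q):
        logger.warning(
            "scaling region truncated: only %d points past q=%.3g",
            len(q) - start_idx, q_start,
        )
        end_idx = len(q)
    ref = series.profiles[0].intensity[start_idx:end_idx]
    abscissae = []
    for p in series.profiles:
        ratios = p.intensity[start_idx:end_idx] / ref
        abscissae.append(float(np.median(ratios)))
    return ScaleResult(np.array(abscissae), (q_start, end_idx - start_idx))


def profile_parameters(
    profile: ScatteringProfile, ift_alpha: float = ift_mod.DEFAULT_ALPHA
) -> ProfileParameters:
    """Compute the full parameter set of one averaged profile.

    P(r) (with automatic D_max) gives R_g, I(0) and D_max; the three
    Guinier regions give three more (R_g, I(0)) pairs; the Porod chain gives
    the molecular weight.  Unusable regions or failed fits leave NaN slots
    rather than raising.
    """
    values: dict[str, float] = {name: float("nan") for name in CONC_PARAMETERS}
    out = ProfileParameters(values)
    try:
        _, pr = ift_mod.auto_dmax(profile, alpha=ift_alpha)
    except ift_mod.IFTError as exc:
        logger.warning("IFT failed for %s: %s", profile.label, exc)
        return out
    out.pr = pr
    values["rg_pr"] = pr.rg_pr
    values["i0_pr"] = pr.i0_pr
    values["dmax"] = pr.dmax
    out.regions = gmod.guinier_regions(pr.rg_pr, pr.dmax, profile.q)
    for region in out.regions:
        if not region.usable:
            continue
        try:
            fit = gmod.guinier_fit(
                profile, region.q_min_G, region.q_max_G, region_id=region.region_id
            )
        except ValueError:
            continue
        out.guinier_fits[region.region_id] = fit
        if fit.ok:
            values[f"rg_g{region.region_id}"] = fit.rg
            values[f"i0_g{region.region_id}"] = fit.i0
    try:
        por = porod_mod.porod_analysis(profile, pr.i0_pr, rg=pr.rg_pr)
        values["mw_porod"] = por.mw
    except (porod_mod.PorodError, ValueError) as exc:
        logger.warning("Porod analysis failed for %s: %s", profile.label, exc)
    return out


def estimate_concentration(i0_pr: float, mw: float, calib: float) -> float:
    """Concentration in mg ml⁻¹ from forward scattering on a calibrated
    intensity scale: c = I(0) / (calib · MW).  Only as accurate as the
    calibration itself (water/standard-protein calibrations are good to
    roughly 10%)."""
    if calib <= 0:
        raise ValueError("calibration constant must be positive")
    if mw <= 0:
        raise ValueError("molecular weight must be positive")
    return i0_pr / (calib * mw)


def concentration_dependence(
    series: ConcentrationSeries,
    calib: float | None = None,
    q_start: float = SCALE_Q_START,
    n_points: int = SCALE_N_POINTS,
    ift_alpha: float = ift_mod.DEFAULT_ALPHA,
) -> ConcentrationReport:
    """The ten-parameter trend test across a dilution series.

    Members are first normalized by their relative scale factor so all
    parameters are per unit concentration; each parameter is then regressed
    against the abscissae.  The impact of a parameter is |slope|/intercept
    ×100 per unit abscissa, converted to per mg ml⁻¹ when a calibration
    constant allows concentrations to be estimated from the data.
    """
    scale = scale_series(series, q_start=q_start, n_points=n_points)
    abscissae = scale.abscissae
    per_member = []
    for p, a in zip(series.profiles, abscissae):
        scaled = p.scaled(1.0 / a)
        per_member.append(profile_parameters(scaled, ift_alpha=ift_alpha))
    est_conc = None
    if calib is not None:
        concs = []
        for pp, a in zip(per_member, abscissae):
            i0, mw = pp.values["i0_pr"], pp.values["mw_porod"]
            if np.isfinite(i0) and np.isfinite(mw) and mw > 0:
                # undo the scaling so I(0) reflects the as-measured member
                concs.append(estimate_concentration(i0 * a, mw, calib))
            else:
                concs.append(float("nan"))
        est_conc = np.array(concs)
    # abscissa-to-concentration conversion from the series span
    conv = None
    if est_conc is not None and np.all(np.isfinite(est_conc)):
        conc_span = est_conc[-1] - est_conc[0]
        absc_span = abscissae[-1] - abscissae[0]
        if conc_span > 0 and absc_span > 0:
            conv = absc_span / conc_span  # abscissa units per mg/ml
    trends: dict[str, ParameterTrend] = {}
    for name in CONC_PARAMETERS:
        vals = [pp.values[name] for pp in per_member]
        finite = np.isfinite(vals)
        if finite.sum() < 3:
            trends[name] = ParameterTrend(name, vals, None, None)
            continue
        x = abscissae[finite]
        y = np.asarray(vals)[finite]
        test = linreg_ttest(x, y)
        impact = None
        if test.intercept != 0:
            impact = abs(test.slope) / abs(test.intercept) * 100.0
            if conv is not None:
                impact *= conv
        trends[name] = ParameterTrend(name, vals, test, impact)
    impacts = [t.impact_percent for t in trends.values() if t.impact_percent is not None]
    median_impact = float(np.median(impacts)) if impacts else None
    units = "percent_per_mg_ml" if conv is not None else "percent_per_abscissa"
    return ConcentrationReport(trends, abscissae, est_conc, median_impact, units)
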