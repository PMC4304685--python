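"""Per-sample orchestration and reporting.

For each concentration of a sample the exposure series is screened for
radiation damage: five parameters (Guinier R_g, P(r) R_g, I(0), D_max and
the reduced χ² of each frame against the first) are tracked across frames,
outlier frames are removed by the modified z-score of the P(r) R_g, each
parameter is trend-tested against frame number with sequential last-frame
rejection, and the surviving frames are averaged.  The averaged profiles
then form the dilution series for the ten-parameter concentration-
dependence test.

Every p-value is classified for the correlation-frequency report:
green (p > 0.20, trend unlikely), yellow (0.05 < p ≤ 0.20, possible),
red (p ≤ 0.05, probable).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import guinier as gmod
from . import ift as ift_mod
from .concentration import (
    CONC_PARAMETERS,
    ConcentrationReport,
    concentration_dependence,
    profile_parameters,
)
from .io_formats import (
    ConcentrationSeries,
    ExposureSeries,
    ScatteringProfile,
    load_sample,
    write_profile,
)
from .stats_core import (
    DEFAULT_ALPHA,
    DEFAULT_Z_CUTOFF,
    TrendTest,
    average_profiles,
    chi2_compare,
    linreg_ttest,
    modified_z_outliers,
    sequential_rejection,
)

logger = logging.getLogger(__name__)

#: canonical order of the five radiation-damage parameters
RAD_PARAMETERS = ("rg_guinier", "rg_pr", "i0", "dmax", "chi2_vs_first")

GREEN_P, RED_P = 0.20, 0.05


def classify_p(p: float | None) -> str:
    """Color class of a trend p-value: green / yellow / red / absent."""
    if p is None or not np.isfinite(p):
        return "absent"
    if p > GREEN_P:
        return "green"
    if p > RED_P:
        return "yellow"
    return "red"


@dataclass
class RadiationReport:
    trends: dict[str, TrendTest | None]
    colors: dict[str, str]
    kept_frames: list[int]          # 1-based exposure indices averaged
    outlier_frames: list[int]       # flagged by the modified z-score screen
    averaged: ScatteringProfile | None
    parameter_values: dict[str, list[float]] = field(default_factory=dict)

    @property
    def n_red(self) -> int:
        return sum(c == "red" for c in self.colors.values())

    @property
    def flagged(self) -> bool:
        return self.n_red >= 1


def _frame_parameters(series: ExposureSeries, ift_alpha: float) -> dict[str, list[float]]:
    """The five damage-tracking parameters for every frame.

    The Guinier R_g and I(0) come from the Shannon-bounded region
    (q_min = π/D_max .. 1.3/R_g) anchored on each frame's own P(r) fit;
    χ² compares each frame with the first (lowest-dose) frame.
    """
    first = series.profiles[0]
    values: dict[str, list[float]] = {name: [] for name in RAD_PARAMETERS}
    for frame in series.profiles:
        row = {name: float("nan") for name in RAD_PARAMETERS}
        try:
            _, pr = ift_mod.auto_dmax(frame, alpha=ift_alpha)
            row["rg_pr"] = pr.rg_pr
            row["dmax"] = pr.dmax
            regions = gmod.guinier_regions(pr.rg_pr, pr.dmax, frame.q)
            region = regions[1] if regions[1].usable else regions[0]
            if region.usable:
                fit = gmod.guinier_fit(
                    frame, region.q_min_G, region.q_max_G, region_id=region.region_id
                )
                if fit.ok:
                    row["rg_guinier"] = fit.rg
                    row["i0"] = fit.i0
        except (ift_mod.IFTError, ValueError) as exc:
            logger.warning("frame %s: %s", frame.label, exc)
        row["chi2_vs_first"] = chi2_compare(frame, first).value
        for name in RAD_PARAMETERS:
            values[name].append(row[name])
    return values


def radiation_analysis(
    series: ExposureSeries,
    alpha: float = DEFAULT_ALPHA,
    z_cutoff: float = DEFAULT_Z_CUTOFF,
    outlier_screen: bool = True,
    ift_alpha: float = ift_mod.DEFAULT_ALPHA,
) -> RadiationReport:
    """Screen one exposure series for radiation damage and average the
    damage-free frames.

    Outlier frames are detected from the P(r) R_g (the most robustly
    determined parameter) with the modified z-score at cutoff ``z_cutoff``
    and excluded from both trend testing and averaging.  Each of the five
    parameters is then regressed against exposure number; significant trends
    trigger sequential rejection of the highest-dose frames.  Only frames
    damage-free in every parameter are averaged.
    """
    values = _frame_parameters(series, ift_alpha)
    idx = np.asarray(series.exposure_index, dtype=float)
    rg_pr = np.asarray(values["rg_pr"])
    outlier_mask = np.zeros(len(series), dtype=bool)
    if outlier_screen and np.isfinite(rg_pr).sum() >= 3:
        finite = np.isfinite(rg_pr)
        flags = modified_z_outliers(rg_pr[finite], cutoff=z_cutoff)
        outlier_mask[np.flatnonzero(finite)[flags]] = True
    keep = ~outlier_mask
    trends: dict[str, TrendTest | None] = {}
    colors: dict[str, str] = {}
    kept_sets: list[set[int]] = []
    for name in RAD_PARAMETERS:
        y = np.asarray(values[name])
        usable = keep & np.isfinite(y)
        if usable.sum() < 3:
            trends[name] = None
            colors[name] = "absent"
            continue
        x_u, y_u = idx[usable], y[usable]
        trends[name] = linreg_ttest(x_u, y_u)
        colors[name] = classify_p(trends[name].p)
        kept_pos, _ = sequential_rejection(x_u, y_u, alpha=alpha)
        kept_sets.append({int(x_u[i]) for i in kept_pos})
    if kept_sets:
        kept_frames = sorted(set.intersection(*kept_sets))
    else:
        kept_frames = [int(i) for i in idx[keep]]
    averaged = None
    if kept_frames:
        keep_profiles = [
            p
            for p, i in zip(series.profiles, series.exposure_index)
            if i in kept_frames
        ]
        averaged = average_profiles(keep_profiles)
    else:
        logger.warning("all frames rejected; no averaged profile")
    return RadiationReport(
        trends=trends,
        colors=colors,
        kept_frames=kept_frames,
        outlier_frames=[int(i) for i in idx[outlier_mask]],
        averaged=averaged,
        parameter_values=values,
    )


@dataclass
class SampleReport:
    name: str
    radiation: list[RadiationReport]          # one per concentration
    concentration: ConcentrationReport | None
    nonlinearity: list[dict[int, gmod.NonlinearityResult]] = field(default_factory=list)

    def correlation_frequency(self) -> dict:
        """Green/yellow/red/absent counts behind the summary plots."""
        rad_counts = []
        for rep in self.radiation:
            counts = {"green": 0, "yellow": 0, "red": 0, "absent": 0}
            for c in rep.colors.values():
                counts[c] += 1
            rad_counts.append(counts)
        conc_counts = {"green": 0, "yellow": 0, "red": 0, "absent": 0}
        if self.concentration is not None:
            for name in CONC_PARAMETERS:
                t = self.concentration.trends[name]
                conc_counts[classify_p(t.test.p if t.test else None)] += 1
        else:
            conc_counts["absent"] = len(CONC_PARAMETERS)
        return {"radiation": rad_counts, "concentration": conc_counts}


def run_sample(
    name: str,
    exposure_series: list[ExposureSeries],
    nominal_concentrations: list[float] | None = None,
    alpha: float = DEFAULT_ALPHA,
    z_cutoff: float = DEFAULT_Z_CUTOFF,
    calib: float | None = None,
    scale_q0: float = 0.07,
    scale_n: int = 50,
    ift_alpha: float = ift_mod.DEFAULT_ALPHA,
) -> SampleReport:
    """Full per-sample analysis: damage screening per concentration, then
    the dilution-series dependence test on the averaged profiles, plus the
    Guinier-linearity screen on every region of every concentration."""
    radiation = []
    averaged = []
    for series in exposure_series:
        rep = radiation_analysis(
            series, alpha=alpha, z_cutoff=z_cutoff, ift_alpha=ift_alpha
        )
        radiation.append(rep)
        if rep.averaged is not None:
            averaged.append(rep.averaged)
    conc_report = None
    if len(averaged) >= 3:
        conc_series = ConcentrationSeries(
            averaged, nominal_concentration=nominal_concentrations
        )
        try:
            conc_report = concentration_dependence(
                conc_series,
                calib=calib,
                q_start=scale_q0,
                n_points=scale_n,
                ift_alpha=ift_alpha,
            )
        except Exception as exc:  # keep batch runs alive
            logger.error("sample %s: concentration analysis failed: %s", name, exc)
    else:
        logger.warning(
            "sample %s: only %d usable concentrations (<3); dependence test skipped",
            name, len(averaged),
        )
    nonlin = []
    for prof in averaged:
        per_region: dict[int, gmod.NonlinearityResult] = {}
        pp = profile_parameters(prof, ift_alpha=ift_alpha)
        for region in pp.regions:
            if region.usable:
                per_region[region.region_id] = gmod.nonlinearity_test(
                    prof, region.q_min_G, region.q_max_G, alpha=alpha
                )
        nonlin.append(per_region)
    return SampleReport(name, radiation, conc_report, nonlin)


def run_manifest(manifest: dict, **kwargs) -> list[SampleReport]:
    """Analyze every sample in a manifest; per-sample failures are logged
    and skipped so one bad sample does not kill a batch."""
    reports = []
    calib = manifest.get("calibration_constant")
    for entry in manifest["samples"]:
        name = entry.get("name", "sample")
        try:
            series = load_sample(manifest, entry)
            nominal = [
                c.get("nominal_mg_ml") for c in entry["concentrations"]
            ]
            if any(v is None for v in nominal):
                nominal = None
            reports.append(
                run_sample(name, series, nominal_concentrations=nominal,
                           calib=calib, **kwargs)
            )
        except Exception as exc:
            logger.error("sample %s failed: %s", name, exc)
    return reports


def radiation_table(reports: list[SampleReport]) -> pd.DataFrame:
    rows = []
    for rep in reports:
        for ci, rad in enumerate(rep.radiation, start=1):
            for name in RAD_PARAMETERS:
                t = rad.trends.get(name)
                rows.append({
                    "sample": rep.name,
                    "concentration": ci,
                    "parameter": name,
                    "slope": t.slope if t else np.nan,
                    "stderr": t.stderr if t else np.nan,
                    "t": t.t if t else np.nan,
                    "p": t.p if t else np.nan,
                    "color": rad.colors.get(name, "absent"),
                    "kept_frames": ",".join(map(str, rad.kept_frames)),
                    "outlier_frames": ",".join(map(str, rad.outlier_frames)),
                })
    df = pd.DataFrame(rows)
    if not df.empty:
        df = df.sort_values(["sample", "concentration", "parameter"]).reset_index(drop=True)
    return df


def concentration_table(reports: list[SampleReport]) -> pd.DataFrame:
    rows = []
    for rep in reports:
        if rep.concentration is None:
            continue
        cr = rep.concentration
        for name in CONC_PARAMETERS:
            tr = cr.trends[name]
            rows.append({
                "sample": rep.name,
                "parameter": name,
                "values": ";".join(f"{v:.6g}" for v in tr.values),
                "slope": tr.test.slope if tr.test else np.nan,
                "p": tr.test.p if tr.test else np.nan,
                "color": classify_p(tr.test.p if tr.test else None),
                "impact_percent": tr.impact_percent if tr.impact_percent is not None else np.nan,
                "impact_units": cr.impact_units,
            })
        rows.append({
            "sample": rep.name,
            "parameter": "median_impact",
            "values": "",
            "slope": np.nan,
            "p": np.nan,
            "color": "",
            "impact_percent": cr.median_impact if cr.median_impact is not None else np.nan,
            "impact_units": cr.impact_units,
        })
    df = pd.DataFrame(rows)
    if not df.empty:
        df = df.sort_values(["sample", "parameter"]).reset_index(drop=True)
    return df


def summary_dict(reports: list[SampleReport]) -> dict:
    out = {}
    for rep in reports:
        cf = rep.correlation_frequency()
        out[rep.name] = {
            "correlation_frequency": cf,
            "median_impact": rep.concentration.median_impact
            if rep.concentration is not None
            else None,
            "impact_units": rep.concentration.impact_units
            if rep.concentration is not None
            else None,
        }
    return out


def write_reports(
    reports: list[SampleReport], out_dir: str | Path, write_averaged: bool = True
) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    radiation_table(reports).to_csv(out / "radiation_report.csv", index=False)
    concentration_table(reports).to_csv(out / "concentration_report.csv", index=False)
    with open(out / "summary.json", "w") as fh:
        json.dump(summary_dict(reports), fh, indent=2, sort_keys=True)
    if write_averaged:
        for rep in reports:
            for ci, rad in enumerate(rep.radiation, start=1):
                if rad.averaged is not None:
                    prof = rad.averaged
                    prof.label = f"{rep.name}_c{ci}_averaged"
                    write_profile(prof, out / f"{prof.label}.dat")
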