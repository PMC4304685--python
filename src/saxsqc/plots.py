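"""Diagnostic plots: Guinier fits with region bounds, P(r), slope-of-slopes."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .concentration import profile_parameters
from .io_formats import ScatteringProfile


def plot_guinier(profile: ScatteringProfile, path: str | Path) -> None:
    """Guinier plot with the fitted regions and the slope-of-slopes inset."""
    pp = profile_parameters(profile)
    fig, ax = plt.subplots(figsize=(6, 4.5))
    q2 = profile.q**2
    pos = profile.intensity > 0
    ax.plot(q2[pos], np.log(profile.intensity[pos]), ".", ms=3, color="0.6", label="data")
    colors = {1: "C0", 2: "C1", 3: "C2"}
    for rid, fit in pp.guinier_fits.items():
        if not fit.ok:
            continue
        qq = np.linspace(fit.q_min_G, fit.q_max_G, 50) ** 2
        ax.plot(qq, np.log(fit.i0) - fit.rg**2 / 3.0 * qq,
                color=colors[rid], label=f"region {rid}: Rg={fit.rg:.1f} Å")
    if pp.guinier_fits:
        lim = max(f.q_max_G for f in pp.guinier_fits.values()) ** 2 * 2.5
        ax.set_xlim(0, lim)
        inside = q2 <= lim
        ax.set_ylim(*np.percentile(np.log(profile.intensity[pos & inside]), [0, 100]))
    ax.set_xlabel("q² (Å⁻²)")
    ax.set_ylabel("ln I(q)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_pr(profile: ScatteringProfile, path: str | Path) -> None:
    """P(r) from the automatic D_max fit."""
    pp = profile_parameters(profile)
    if pp.pr is None:
        return
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(pp.pr.r, pp.pr.pr, "-", color="C0")
    ax.axhline(0, color="0.8", lw=0.8)
    ax.set_xlabel("r (Å)")
    ax.set_ylabel("P(r)")
    ax.set_title(
        f"Dmax={pp.pr.dmax:.1f} Å, Rg={pp.pr.rg_pr:.1f} Å, χ²={pp.pr.fit_chi2:.2f}"
    )
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
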