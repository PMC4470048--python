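"""Plot helpers: per-subject KE curves and Bland-Altman/scatter panels."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .intracardiac import KECurve
from .stats import PairedMeasurements, bland_altman, correlate

__all__ = ["ke_curve_plot", "agreement_plot"]


def ke_curve_plot(path: str | Path, curves: dict[str, KECurve], title: str = "") -> None:
    """Plot LV kinetic energy vs fraction of the cardiac cycle, one line per
    condition, mirroring a subject-by-subject presentation."""
    fig, ax = plt.subplots(figsize=(5, 3.5))
    for label, c in curves.items():
        frac = np.arange(c.ke.size) / c.ke.size
        ax.plot(frac, c.ke, label=label)
    ax.set_xlabel("fraction of cardiac cycle")
    ax.set_ylabel("KE (mJ)")
    if title:
        ax.set_title(title)
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def agreement_plot(path: str | Path, pm: PairedMeasurements,
                   xlabel: str = "condition A", ylabel: str = "condition B") -> None:
    """Scatter with line of identity plus Bland-Altman (bias +/- 1.96 SD)."""
    ba = bland_altman(pm)
    corr = correlate(pm)
    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(8, 3.5))

    ax1.scatter(pm.x, pm.y, s=18, color="k")
    lim = [min(pm.x.min(), pm.y.min()), max(pm.x.max(), pm.y.max())]
    ax1.plot(lim, lim, "k--", lw=0.8)
    ax1.set_xlabel(xlabel)
    ax1.set_ylabel(ylabel)
    ax1.set_title(f"R$^2$ = {corr.r2:.2f}")

    mean = (pm.x + pm.y) / 2.0
    diff = pm.x - pm.y
    ax2.scatter(mean, diff, s=18, color="k")
    ax2.axhline(ba.bias, color="k")
    for lo in ba.loa:
        ax2.axhline(lo, color="k", ls="--", lw=0.8)
    ax2.set_xlabel("mean of methods")
    ax2.set_ylabel("difference")
    ax2.set_title(f"bias {ba.bias:.2f} ± 1.96·{ba.sd:.2f}")

    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
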