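"""Plot helpers: GPR-vs-AGV scatter with trend lines, and depth-dose curves."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")  # headless-safe; callers may switch backends first
import matplotlib.pyplot as plt
import numpy as np

from .cohort_stats import COMPARISONS, AGVRecord, fit_trend

__all__ = ["plot_gpr_vs_agv", "plot_pdd_curves"]


def plot_gpr_vs_agv(records: list[AGVRecord], ax=None):
    """Scatter of GPR against AGV per comparison with the fitted trend lines
    and a horizontal 90% action level."""
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 5))
    agv = np.array([r.agv_cc for r in records])
    order = np.argsort(agv)
    for comp in COMPARISONS:
        gpr = np.array([r.gpr[comp] for r in records])
        fit = fit_trend(records, comp)
        label = f"{comp} (R$^2$={fit.r_squared:.2f})"
        sc = ax.plot(agv[order], gpr[order], "o", label=label)[0]
        xs = np.linspace(agv.min(), agv.max(), 50)
        ax.plot(xs, fit.slope * xs + fit.intercept, "-", color=sc.get_color(),
                alpha=0.7)
    ax.axhline(90.0, color="k", ls=":", lw=1)
    ax.set_xlabel("AGV (cc)")
    ax.set_ylabel("mean GPR (%)")
    ax.legend(fontsize=8)
    return ax


def plot_pdd_curves(pdds: dict, ax=None):
    """Central-axis percentage depth-dose curves, one per gap RED."""
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 5))
    for red, (depth, pdd) in sorted(pdds.items()):
        ax.plot(depth, pdd, label=f"RED {red:g}")
    ax.set_xlabel("depth (mm)")
    ax.set_ylabel("PDD (%)")
    ax.legend(fontsize=8, ncol=2)
    return ax
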