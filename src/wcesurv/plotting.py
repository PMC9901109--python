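"""Two-panel modified Kaplan-Meier plots with confidence bands.

Left panel: traditional time-to-first-event curves; right panel: weighted
composite endpoint curves; both arms on each, with shaded pointwise 95%
bands.  Steps are drawn right-continuous to match the estimator's grid
convention.  Plots are presentation artifacts only — numeric checks belong
on the exported CSVs.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .estimator import SurvivalCurve

_ARM_COLORS = ("tab:blue", "tab:orange")


def _draw_curve(ax, curve: SurvivalCurve, followup: float, color: str) -> None:
    t = np.append(curve.grid, followup)
    s = np.append(curve.estimate, curve.estimate[-1])
    ax.step(t, s, where="post", color=color, label=curve.arm or "arm")
    if curve.ci_lower is not None:
        lo = np.clip(np.append(curve.ci_lower, curve.ci_lower[-1]), 0, 1)
        hi = np.clip(np.append(curve.ci_upper, curve.ci_upper[-1]), 0, 1)
        ax.fill_between(t, lo, hi, step="post", alpha=0.25, color=color, lw=0)


def plot_comparison(
    traditional: dict[str, SurvivalCurve],
    wce: dict[str, SurvivalCurve],
    followup: float,
    path,
    ylim: tuple[float, float] | None = None,
) -> None:
    """Write the side-by-side (traditional | weighted) step plot to ``path``."""
    fig, axes = plt.subplots(1, 2, figsize=(10, 4.2), sharey=True)
    for ax, curves, title in (
        (axes[0], traditional, "Traditional (time to first event)"),
        (axes[1], wce, "Weighted composite endpoint"),
    ):
        for color, (label, curve) in zip(_ARM_COLORS, curves.items()):
            _draw_curve(ax, curve, followup, color)
        ax.set_title(title)
        ax.set_xlabel("days since randomization")
        ax.set_xlim(0, followup)
        if ylim:
            ax.set_ylim(*ylim)
        ax.legend(loc="lower left", frameon=False)
    axes[0].set_ylabel("survival probability")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
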