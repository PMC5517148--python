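"""Figure rendering for simulation results."""

from __future__ import annotations

from typing import Optional

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .model import SimulationResult

__all__ = ["mapping_plot", "gap_plot"]


def mapping_plot(result: SimulationResult, path=None, ax=None,
                 title: Optional[str] = None):
    """Anterior-posterior position as a function of naso-temporal origin."""
    if ax is None:
        fig, ax = plt.subplots(figsize=(4, 4))
    else:
        fig = ax.figure
    W = result.analysis_hints.get("field_width", 50.0)
    mob = np.asarray(result.mobile, dtype=bool)
    for sel, color, lbl in ((mob, "0.4", "terminal"),
                            (~mob, "0.85", "resident")):
        if sel.any():
            ax.scatter(result.origin_u[sel], result.final_x[sel] / W,
                       s=18, facecolors=color, edgecolors="k",
                       linewidths=0.4, label=lbl)
    ax.plot([0, 1], [1, 0], "k--", lw=0.8, alpha=0.6)
    ax.set_xlabel("n-t origin (0 = nasal)")
    ax.set_ylabel("a-p position (0 = anterior)")
    ax.set_xlim(-0.02, 1.02)
    ax.set_ylim(-0.02, 1.02)
    ax.set_title(title or result.scenario_tag)
    if path is not None:
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return ax


def gap_plot(result: SimulationResult, path=None, ax=None):
    """Final terminal positions over the gap-assay field layout."""
    if ax is None:
        fig, ax = plt.subplots(figsize=(8, 1.8))
    else:
        fig = ax.figure
    hints = result.analysis_hints
    W = hints.get("field_width", 200.0)
    H = hints.get("field_height", 8.0)
    for key in ("first_field_start", "second_field_start"):
        if key in hints:
            ax.axvline(hints[key], color="r", lw=1)
    if "first_field_end" in hints:
        ax.axvspan(hints["first_field_start"], hints["first_field_end"],
                   color="r", alpha=0.15)
    if "second_field_start" in hints:
        ax.axvspan(hints["second_field_start"], W, color="r", alpha=0.15)
    pos = result.final_positions
    ax.scatter(pos[:, 0], pos[:, 1], s=20, facecolors="0.5", edgecolors="k")
    ax.set_xlim(0, W)
    ax.set_ylim(0, H)
    ax.set_xlabel("x (units)")
    ax.set_title(result.scenario_tag)
    if path is not None:
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return ax
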