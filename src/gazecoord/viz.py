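"""Figure generation: phase-space plots, mean networks, alignment curves,
and repair-contrast panels.

All functions draw on matplotlib axes and save via ``savefig``; callers (the
CLI and examples) decide paths and formats (SVG/PNG).
"""

from __future__ import annotations

from typing import Dict, Iterable, Optional

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .gaze_model import PHASES
from . import ena_core
from .lag_alignment import AlignmentCurve

__all__ = [
    "plot_space",
    "plot_network",
    "plot_alignment_curves",
    "plot_difference_network",
]

PHASE_COLORS = {
    "pre_reference": "#1f77b4",
    "reference": "#ff7f0e",
    "post_reference": "#2ca02c",
    "action": "#d62728",
    "post_action": "#9467bd",
}


def plot_space(
    space: ena_core.ENASpace,
    group_summaries: Dict[str, ena_core.GroupSummary],
    group_of_unit=None,
    ax=None,
    title: str = "",
):
    """Unit projections as points, group mean centroids as solid squares
    surrounded by confidence-interval boxes."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 6))
    proj = space.projections
    labels = list(group_summaries)
    colors = {g: PHASE_COLORS.get(g, f"C{k}") for k, g in enumerate(labels)}
    if group_of_unit is not None:
        for g in labels:
            sel = np.array([group_of_unit(u) == g for u in space.unit_index])
            ax.scatter(
                proj[sel, 0], proj[sel, 1], s=12, alpha=0.45, color=colors[g], label=g
            )
    for g, summ in group_summaries.items():
        cx, cy = summ.centroid[:2]
        hw = summ.ci_half_width[:2]
        if np.all(np.isfinite(hw)):
            ax.add_patch(
                plt.Rectangle(
                    (cx - hw[0], cy - hw[1]),
                    2 * hw[0],
                    2 * hw[1],
                    fill=False,
                    edgecolor=colors[g],
                    linewidth=1.2,
                )
            )
        ax.scatter([cx], [cy], marker="s", s=70, color=colors[g], zorder=5)
    if space.node_positions is not None:
        for lbl, (x, y) in zip(space.code_set.labels, space.node_positions):
            ax.annotate(lbl, (x, y), fontsize=7, ha="center", color="0.25")
    ax.axhline(0, color="0.85", lw=0.8)
    ax.axvline(0, color="0.85", lw=0.8)
    ax.set_xlabel(f"dim 1 ({100 * space.variance_explained[0]:.0f}% var)")
    ax.set_ylabel(f"dim 2 ({100 * space.variance_explained[1]:.0f}% var)")
    ax.set_title(title)
    ax.legend(fontsize=7, loc="best")
    return ax


def plot_network(
    weights: pd.Series,
    space: ena_core.ENASpace,
    ax=None,
    title: str = "",
    max_width: float = 6.0,
):
    """One network: nodes at the fitted positions, edge width proportional to
    the mean normalised co-occurrence weight."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    if space.node_positions is None:
        raise ValueError("space has no node positions; call position_nodes first")
    pos = space.node_positions
    code_set = space.code_set
    w = np.asarray(weights, dtype=float)
    wmax = w.max() if w.max() > 0 else 1.0
    for p_idx, (a, b) in enumerate(code_set.pairs()):
        if w[p_idx] <= 0:
            continue
        ia = code_set.labels.index(a)
        ib = code_set.labels.index(b)
        ax.plot(
            [pos[ia, 0], pos[ib, 0]],
            [pos[ia, 1], pos[ib, 1]],
            lw=max_width * w[p_idx] / wmax,
            color="#d62728",
            alpha=0.6,
            zorder=1,
        )
    ax.scatter(pos[:, 0], pos[:, 1], s=40, color="0.2", zorder=3)
    for lbl, (x, y) in zip(code_set.labels, pos):
        ax.annotate(lbl, (x, y), fontsize=7, ha="center", va="bottom", color="0.1")
    ax.set_title(title, fontsize=9)
    ax.set_xticks([])
    ax.set_yticks([])
    return ax


def plot_alignment_curves(curves: Dict[str, AlignmentCurve], ax=None):
    """Alignment percentage against lag for all phases (positive lag =
    instructor leads)."""
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4.5))
    for p in PHASES:
        c = curves.get(p)
        if c is None:
            continue
        ax.plot(c.lags_ms / 1000.0, 100 * c.alignment, label=p, color=PHASE_COLORS[p])
    ax.set_xlabel("lag (s; positive = instructor leads)")
    ax.set_ylabel("gaze alignment (%)")
    ax.legend(fontsize=8)
    ax.grid(alpha=0.25)
    return ax


def plot_difference_network(
    diff: pd.Series,
    space: ena_core.ENASpace,
    ax=None,
    title: str = "",
    max_width: float = 6.0,
):
    """Difference network: red edges where the first group is stronger, blue
    where the second is."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    if space.node_positions is None:
        raise ValueError("space has no node positions; call position_nodes first")
    pos = space.node_positions
    code_set = space.code_set
    w = np.asarray(diff, dtype=float)
    wmax = np.abs(w).max() or 1.0
    for p_idx, (a, b) in enumerate(code_set.pairs()):
        if w[p_idx] == 0:
            continue
        ia = code_set.labels.index(a)
        ib = code_set.labels.index(b)
        ax.plot(
            [pos[ia, 0], pos[ib, 0]],
            [pos[ia, 1], pos[ib, 1]],
            lw=max_width * abs(w[p_idx]) / wmax,
            color="#d62728" if w[p_idx] > 0 else "#1f77b4",
            alpha=0.65,
        )
    ax.scatter(pos[:, 0], pos[:, 1], s=40, color="0.2", zorder=3)
    for lbl, (x, y) in zip(code_set.labels, pos):
        ax.annotate(lbl, (x, y), fontsize=7, ha="center", va="bottom")
    ax.set_title(title, fontsize=9)
    ax.set_xticks([])
    ax.set_yticks([])
    return ax
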