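"""Leave-one-dyad-out phase prediction from short gaze windows.

Validation of the phase-space separation: fit the ENA space on all dyads
but one, take the per-phase centroids of the training units, then project
randomly sampled 200-ms / 1000-ms windows of the held-out dyad's raw gaze
into the space and label each window with the nearest phase centroid.  The
resulting confusion matrix (actual phase x predicted phase) quantifies how
phase-specific the gaze coordination patterns are.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd

from .gaze_model import CodeSet, PHASES
from . import ena_core

__all__ = [
    "ConfusionMatrix",
    "loo_space",
    "sample_windows",
    "classify",
    "confusion",
    "predict_phases",
]

UNCODABLE = "uncodable"


@dataclass
class ConfusionMatrix:
    window_ms: int
    counts: pd.DataFrame  # rows = actual phase, columns = predicted phase
    n_uncodable: int

    @property
    def accuracy(self) -> float:
        total = self.counts.to_numpy().sum()
        return float(np.trace(self.counts.to_numpy()) / total) if total else float("nan")

    @property
    def recall(self) -> pd.Series:
        c = self.counts.to_numpy()
        with np.errstate(invalid="ignore"):
            r = np.diag(c) / c.sum(axis=1)
        return pd.Series(r, index=self.counts.index, name="recall")


def loo_space(
    segments: pd.DataFrame, held_out_dyad: str, d: int = 2
) -> tuple[ena_core.ENASpace, pd.DataFrame, Dict[str, np.ndarray]]:
    """ENA space built with one dyad held out, plus per-phase training centroids.

    Units are dyad-interaction x phase over the remaining dyads.  Returns
    ``(space, training_units, centroids)`` where ``centroids[phase]`` is the
    mean projection of that phase's training units.
    """
    dyads = segments["dyad_id"].unique()
    if held_out_dyad not in dyads:
        raise ValueError(f"held-out dyad {held_out_dyad!r} not present in the corpus")
    if len(dyads) < 2:
        raise ValueError("need at least 2 dyads for leave-one-out")
    train = segments[segments["dyad_id"] != held_out_dyad]
    units = ena_core.accumulate_units(train)
    space = ena_core.build_space(units, d=d)
    phase_level = units.index.get_level_values("phase")
    centroids = {
        PHASES[p]: space.projections[phase_level == p].mean(axis=0)
        for p in sorted(set(phase_level))
    }
    return space, units, centroids


def sample_windows(
    sequences: pd.DataFrame,
    window_ms: int,
    n_per_phase: int,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Randomly sample gaze windows that each fit inside a single phase.

    For each phase, ``n_per_phase`` windows are drawn uniformly over
    (phase occurrence, admissible start); occurrences shorter than the
    window are inadmissible, and a phase with no admissible occurrence is
    undersampled (0 rows) with a warning.  Reproducible under ``seed``.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rows = []
    for p_idx, p_name in enumerate(PHASES):
        starts = sequences[f"{p_name}_start_ms"].to_numpy()
        ends = sequences[f"{p_name}_end_ms"].to_numpy()
        slack = ends - starts - window_ms
        admissible = np.nonzero(slack >= 0)[0]
        if admissible.size == 0:
            warnings.warn(
                f"phase {p_name}: no occurrence long enough for a {window_ms}-ms window"
            )
            continue
        occ = rng.choice(admissible, size=n_per_phase, replace=True)
        offs = rng.integers(0, slack[occ] + 1)
        for o, off in zip(occ, offs):
            seq = sequences.iloc[int(o)]
            rows.append(
                {
                    "dyad_id": seq["dyad_id"],
                    "interaction_id": seq["interaction_id"],
                    "seq_index": seq["seq_index"],
                    "phase": p_idx,
                    "t_start_ms": int(starts[o] + off),
                    "t_end_ms": int(starts[o] + off) + window_ms,
                }
            )
    return pd.DataFrame(rows)


def classify(
    U: np.ndarray,
    space: ena_core.ENASpace,
    centroids: Dict[str, np.ndarray],
) -> str:
    """Nearest-centroid phase label for one window's adjacency vector.

    The window's counts are normalised, centred with the training mean and
    projected on the kept dimensions; a window with no co-occurrences at all
    is :data:`UNCODABLE`.  Exact distance ties break deterministically by
    phase order (with a warning).
    """
    U = np.asarray(U, dtype=float)
    if not np.any(U):
        return UNCODABLE
    p = ena_core.project(space, U)[0]
    names = [n for n in PHASES if n in centroids]
    dists = np.array([np.linalg.norm(p - centroids[n]) for n in names])
    best = dists.min()
    ties = np.nonzero(dists == best)[0]
    if ties.size > 1:
        warnings.warn(
            f"window equidistant to centroids {[names[i] for i in ties]}; "
            "breaking tie by phase order"
        )
    return names[int(ties[0])]


def confusion(windows: pd.DataFrame, window_ms: int) -> ConfusionMatrix:
    """Confusion matrix from classified windows (``actual``/``predicted`` columns)."""
    codable = windows[windows["predicted"] != UNCODABLE]
    counts = pd.DataFrame(0, index=list(PHASES), columns=list(PHASES), dtype=int)
    for _, row in codable.iterrows():
        counts.loc[row["actual"], row["predicted"]] += 1
    return ConfusionMatrix(
        window_ms=window_ms,
        counts=counts,
        n_uncodable=int((windows["predicted"] == UNCODABLE).sum()),
    )


def predict_phases(
    segments: pd.DataFrame,
    sequences: pd.DataFrame,
    held_out_dyad: str,
    window_ms: int = 200,
    n_per_phase: int = 50,
    seed: int | np.random.Generator = 0,
    d: int = 2,
    segment_ms: int = 50,
) -> ConfusionMatrix:
    """End-to-end leave-one-dyad-out phase prediction.

    Builds the space without the held-out dyad, samples windows from the
    held-out dyad's sequences, accumulates each window's segments into an
    adjacency vector and classifies it by nearest phase centroid.
    """
    space, _, centroids = loo_space(segments, held_out_dyad, d=d)
    held_seq = sequences[sequences["dyad_id"] == held_out_dyad]
    held_seg = segments[segments["dyad_id"] == held_out_dyad]
    windows = sample_windows(held_seq, window_ms, n_per_phase, seed)
    seg_groups = {
        k: g for k, g in held_seg.groupby(["interaction_id", "seq_index"], sort=False)
    }
    results = []
    for _, w in windows.iterrows():
        g = seg_groups.get((w["interaction_id"], w["seq_index"]))
        if g is None:
            pred = UNCODABLE
        else:
            mids = g["t_mid_ms"].to_numpy()
            in_win = (mids >= w["t_start_ms"]) & (mids < w["t_end_ms"])
            U = ena_core.accumulate(g[in_win])
            pred = classify(U, space, centroids)
        results.append({"actual": PHASES[int(w["phase"])], "predicted": pred})
    return confusion(pd.DataFrame(results), window_ms)
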