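"""Repair vs. no-repair gaze-network comparison.

Sequences that contain a conversational repair (a verbal clarification
after a breakdown) are accumulated into separate units from those that do
not, inside one shared ENA space (units = dyad-interaction x phase x
repair).  Per phase, the two strata's unit centroids are compared with a
two-sample t-test along one space dimension, and the stratum mean networks
are differenced edge by edge.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Dict, Optional

import numpy as np
import pandas as pd

from .gaze_model import CodeSet, PHASES
from . import ena_core

__all__ = [
    "RepairContrast",
    "split_units",
    "build_shared_space",
    "repair_contrast",
    "repair_report",
    "oriented_dimension_sign",
]

log = logging.getLogger(__name__)

REPAIR_UNIT_KEYS = ["dyad_id", "interaction_id", "phase", "repair"]


@dataclass
class RepairContrast:
    phase: str
    dimension: int
    mean_no_repair: float
    mean_repair: float
    t: float
    p: float
    cohens_d: float
    n_no_repair: int
    n_repair: int
    difference_network: pd.Series  # mean(repair) - mean(no-repair) per edge


def split_units(segments: pd.DataFrame, code_set: Optional[CodeSet] = None) -> pd.DataFrame:
    """Adjacency vectors keyed dyad-interaction x phase x repair stratum.

    Each unit accumulates only the segments of its repair stratum's
    sequences; units with no co-occurrences at all are dropped (logged).
    """
    units = ena_core.accumulate_units(
        segments, unit_keys=REPAIR_UNIT_KEYS, code_set=code_set, drop_empty=False
    )
    empty = units.sum(axis=1) == 0
    if empty.any():
        log.info("dropping %d empty repair-stratum units", int(empty.sum()))
    return units[~empty]


def build_shared_space(units: pd.DataFrame, d: int = 2) -> ena_core.ENASpace:
    """One ENA space over both repair strata (contrasts are computed inside it)."""
    space = ena_core.build_space(units, d=d)
    ena_core.position_nodes(space, units)
    return space


def oriented_dimension_sign(space: ena_core.ENASpace, dimension: int = 1, code: str = "W.Gaze_Other") -> float:
    """Sign that orients a space dimension so edges involving ``code`` load
    positively.

    SVD axes have arbitrary orientation (fixed here only by a deterministic
    sign convention), so directional statements like "repair networks sit
    toward worker-elsewhere gaze" need an interpretable orientation.  The
    returned sign is +1 if the summed loadings of all code pairs involving
    ``code`` are positive on the dimension, else -1.
    """
    mask = np.array([code in lbl.split("--") for lbl in space.pair_labels])
    s = float(space.loadings[mask, dimension].sum())
    return 1.0 if s >= 0 else -1.0


def repair_contrast(
    space: ena_core.ENASpace,
    units: pd.DataFrame,
    phase: str | int,
    dimension: int = 1,
    welch: bool = False,
) -> RepairContrast:
    """Repair vs. no-repair contrast for one phase inside a shared space.

    Projects each stratum's units onto the chosen dimension, runs the
    centroid t-test and differences the stratum mean networks
    (``repair - no_repair``, antisymmetric under label swap).
    """
    p_idx = PHASES.index(phase) if isinstance(phase, str) else int(phase)
    phase_level = np.asarray(units.index.get_level_values("phase"))
    repair_level = np.asarray(units.index.get_level_values("repair"), dtype=bool)
    in_phase = phase_level == p_idx
    sel_r = in_phase & repair_level
    sel_n = in_phase & ~repair_level
    if sel_r.sum() < 2 or sel_n.sum() < 2:
        raise ValueError(
            f"phase {PHASES[p_idx]}: need at least 2 units per repair stratum "
            f"(got {int(sel_n.sum())} no-repair, {int(sel_r.sum())} repair)"
        )
    proj = space.projections
    cmp = ena_core.compare_groups(proj[sel_r], proj[sel_n], dimension=dimension, welch=welch)
    mean_r = ena_core.mean_network(units[sel_r], proj[sel_r], label="repair")
    mean_n = ena_core.mean_network(units[sel_n], proj[sel_n], label="no_repair")
    return RepairContrast(
        phase=PHASES[p_idx],
        dimension=dimension,
        mean_no_repair=cmp.mean_b,
        mean_repair=cmp.mean_a,
        t=cmp.t,
        p=cmp.p,
        cohens_d=cmp.cohens_d,
        n_no_repair=cmp.n_b,
        n_repair=cmp.n_a,
        difference_network=mean_r.mean_network - mean_n.mean_network,
    )


def repair_report(
    segments: pd.DataFrame,
    dimension: int = 1,
    d: int = 2,
    welch: bool = False,
    bonferroni: bool = False,
) -> pd.DataFrame:
    """Per-phase repair contrasts as a tidy frame.

    Builds the shared space on all repair-split units and contrasts the two
    strata phase by phase.  p-values are uncorrected by default (a
    Bonferroni flag multiplies them by the number of tested phases).
    Phases with a missing or too-small stratum are skipped with a warning;
    a corpus with no repair sequences yields an empty frame.
    """
    if not segments["repair"].any():
        warnings.warn("corpus contains no repair sequences; contrast skipped")
        return pd.DataFrame()
    units = split_units(segments)
    space = build_shared_space(units, d=d)
    rows = []
    for p in PHASES:
        try:
            c = repair_contrast(space, units, p, dimension=dimension, welch=welch)
        except ValueError as e:
            warnings.warn(str(e))
            continue
        rows.append(
            {
                "phase": p,
                "mean_no_repair": c.mean_no_repair,
                "mean_repair": c.mean_repair,
                "t": c.t,
                "p": c.p,
                "cohens_d": c.cohens_d,
                "n_no_repair": c.n_no_repair,
                "n_repair": c.n_repair,
            }
        )
    report = pd.DataFrame(rows)
    if bonferroni and len(report):
        report["p"] = np.minimum(1.0, report["p"] * len(report))
    return report
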