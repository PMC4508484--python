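"""Epistemic network analysis (ENA) core.

ENA models the co-occurrence of coded behaviours within short time segments
as a weighted network per *unit of analysis* and embeds the units in a
low-dimensional space:

1. For each unit, count in how many segments each cross-person code pair is
   jointly active -- the cumulative adjacency vector ``U``.
2. Normalise each ``U`` to the unit hypersphere (``nU = U / ||U||_2``) so
   units are compared by the *relative* composition of their networks, not by
   how much data they contain.
3. Centre the ``nU`` vectors on their grand mean and decompose by SVD,
   keeping the leading components; each unit gets coordinates ``P_i``.
4. Place the network *nodes* (the codes) in the same plane by solving the
   linear least-squares problem that makes each unit's network centroid
   ``C_i`` -- the edge-weight-weighted mean of edge-endpoint midpoints --
   match its projection ``P_i`` as closely as possible.  With that centroid
   definition the objective ``sum_i ||P_i - C_i||^2`` is linear in the node
   coordinates and has a closed-form solution.

Group summaries (mean networks, centroids with confidence intervals) and the
two-sample centroid t-test on one dimension complete the toolkit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import linalg, stats

from .gaze_model import CodeSet, UNCODED

__all__ = [
    "ENASpace",
    "GroupSummary",
    "GroupComparison",
    "accumulate",
    "accumulate_units",
    "normalize",
    "build_space",
    "project",
    "position_nodes",
    "mean_network",
    "compare_groups",
    "space_to_json",
    "network_to_graphml",
    "edge_list",
]

UNIT_KEYS = ["dyad_id", "interaction_id", "phase"]


def accumulate(
    segments: pd.DataFrame,
    code_set: Optional[CodeSet] = None,
    i_col: str = "i_cat",
    w_col: str = "w_cat",
) -> np.ndarray:
    """Cumulative adjacency vector ``U`` for one unit's segments.

    ``U[pair]`` counts the segments in which both codes of the pair are
    active.  Because a participant activates at most one code per segment,
    each segment increments at most one pair; segments with either stream
    uncoded contribute nothing.
    """
    code_set = code_set or CodeSet.eight_codes()
    i = segments[i_col].to_numpy()
    w = segments[w_col].to_numpy()
    ok = (i != UNCODED) & (w != UNCODED)
    pair = i[ok].astype(np.int64) * code_set.n_worker + w[ok]
    return np.bincount(pair, minlength=code_set.n_pairs).astype(np.int64)


def accumulate_units(
    segments: pd.DataFrame,
    unit_keys: Sequence[str] = UNIT_KEYS,
    code_set: Optional[CodeSet] = None,
    i_col: str = "i_cat",
    w_col: str = "w_cat",
    drop_empty: bool = True,
) -> pd.DataFrame:
    """Adjacency vectors for every unit of analysis in one pass.

    Returns a frame indexed by the unit keys with ``n_pairs`` count columns
    (labelled by the code-pair names).  Units whose vector is all zero carry
    no network; they are dropped by default (``drop_empty``).
    """
    code_set = code_set or CodeSet.eight_codes()
    i = segments[i_col].to_numpy()
    w = segments[w_col].to_numpy()
    ok = (i != UNCODED) & (w != UNCODED)
    pair = np.where(ok, i.astype(np.int64) * code_set.n_worker + w, -1)
    df = segments.loc[:, list(unit_keys)].copy()
    df["pair"] = pair
    counts = (
        df[df["pair"] >= 0]
        .groupby(list(unit_keys) + ["pair"], sort=True)
        .size()
        .unstack("pair", fill_value=0)
    )
    counts = counts.reindex(columns=range(code_set.n_pairs), fill_value=0)
    counts.columns = code_set.pair_labels()
    if not drop_empty:
        all_units = df.groupby(list(unit_keys), sort=True).size().index
        counts = counts.reindex(all_units, fill_value=0)
    return counts.astype(np.int64)


def normalize(U: np.ndarray) -> np.ndarray:
    """Project adjacency vectors onto the unit hypersphere.

    Accepts one vector or a matrix of row vectors.  A zero vector has no
    direction and raises (an empty unit carries no network).
    """
    U = np.asarray(U, dtype=float)
    norms = np.linalg.norm(U, axis=-1, keepdims=True)
    if np.any(norms == 0):
        raise ValueError("empty unit: cannot normalize a zero adjacency vector")
    return U / norms


@dataclass
class ENASpace:
    """A fitted ENA projection space.

    ``loadings`` holds the kept right-singular vectors as columns
    (orthonormal, variance-ordered); ``projections`` are the training units'
    coordinates; ``mean`` is the centring vector (grand mean of the
    normalised adjacency vectors), so training projections are zero-mean.
    """

    pair_labels: list
    mean: np.ndarray
    loadings: np.ndarray  # (n_pairs, d)
    singular_values: np.ndarray  # full spectrum
    projections: np.ndarray  # (n_units, d)
    unit_index: pd.Index
    variance_explained: np.ndarray  # per kept dimension
    code_set: CodeSet = field(default_factory=CodeSet.eight_codes)
    node_positions: Optional[np.ndarray] = None  # (n_codes, d)
    positioning_residual: Optional[float] = None
    unconstrained_nodes: Optional[list] = None

    @property
    def d(self) -> int:
        return self.loadings.shape[1]


def build_space(units: pd.DataFrame, d: int = 2, code_set: Optional[CodeSet] = None) -> ENASpace:
    """Fit the ENA space from per-unit adjacency counts.

    ``units`` is the output of :func:`accumulate_units` (or any frame of
    non-negative counts indexed by unit keys).  Vectors are normalised,
    centred on their grand mean and decomposed by SVD; the top ``d``
    components are kept.  Sign convention: each loading's largest-magnitude
    entry is positive, which makes the fit deterministic.
    """
    code_set = code_set or CodeSet.eight_codes()
    X = normalize(units.to_numpy(dtype=float))
    if X.shape[0] < 2:
        raise ValueError("need at least 2 units to build a space")
    mean = X.mean(axis=0)
    Xc = X - mean
    if not np.any(np.abs(Xc) > 1e-12):
        raise ValueError("degenerate space: all units have identical normalized networks")
    U_, s, Vt = linalg.svd(Xc, full_matrices=False)
    d = min(d, Vt.shape[0])
    loadings = Vt[:d].T.copy()
    # deterministic orientation
    for j in range(d):
        k = int(np.argmax(np.abs(loadings[:, j])))
        if loadings[k, j] < 0:
            loadings[:, j] = -loadings[:, j]
    proj = Xc @ loadings
    total_var = float(np.sum(s**2))
    var_exp = (s[:d] ** 2) / total_var if total_var > 0 else np.zeros(d)
    return ENASpace(
        pair_labels=list(units.columns),
        mean=mean,
        loadings=loadings,
        singular_values=s,
        projections=proj,
        unit_index=units.index,
        variance_explained=var_exp,
        code_set=code_set,
    )


def project(space: ENASpace, U: np.ndarray) -> np.ndarray:
    """Project held-out adjacency counts into a fitted space.

    The new vectors are normalised and centred with the *training* mean, so
    projecting a training unit reproduces its stored coordinates.
    """
    X = normalize(np.atleast_2d(np.asarray(U, dtype=float)))
    return (X - space.mean) @ space.loadings


def _centroid_design(nU: np.ndarray, code_set: CodeSet) -> np.ndarray:
    """Design matrix A with ``C_i = A_i @ node_positions``.

    The network centroid of unit ``i`` is the weighted mean of its edges'
    endpoint midpoints, with the unit's edge weights renormalised to sum to
    one.  Each edge ``(a, b)`` contributes ``w/2`` to both endpoint columns.
    """
    n_units, n_pairs = nU.shape
    n_nodes = code_set.n_instructor + code_set.n_worker
    totals = nU.sum(axis=1, keepdims=True)
    if np.any(totals == 0):
        raise ValueError("unit with zero total edge weight")
    W = nU / totals
    A = np.zeros((n_units, n_nodes))
    for p in range(n_pairs):
        a = p // code_set.n_worker  # instructor node
        b = code_set.n_instructor + p % code_set.n_worker  # worker node
        A[:, a] += W[:, p] / 2.0
        A[:, b] += W[:, p] / 2.0
    return A


def position_nodes(
    space: ENASpace, units: Optional[pd.DataFrame] = None
) -> tuple[np.ndarray, float, list]:
    """Place the code nodes so unit network centroids match unit projections.

    Solves ``min_X sum_i ||P_i - A_i X||^2`` in closed form (linear least
    squares).  Codes that never co-occur with anything have an all-zero
    design column: they are unconstrained, flagged, and land at the origin
    (the minimum-norm solution).  Returns ``(positions, residual, flagged)``
    and caches them on the space.
    """
    if units is not None:
        nU = normalize(units.to_numpy(dtype=float))
    else:
        nU = space.mean + space.projections @ space.loadings.T  # rank-d reconstruction
    A = _centroid_design(nU, space.code_set)
    X, res, rank, _ = linalg.lstsq(A, space.projections)
    unconstrained = [
        label
        for label, col in zip(
            space.code_set.labels, (np.abs(A).sum(axis=0) < 1e-12)
        )
        if col
    ]
    residual = float(np.sum((space.projections - A @ X) ** 2))
    space.node_positions = X
    space.positioning_residual = residual
    space.unconstrained_nodes = unconstrained
    return X, residual, unconstrained


def network_centroids(nU: np.ndarray, positions: np.ndarray, code_set: CodeSet) -> np.ndarray:
    """Graph centroids ``C_i`` of each unit network under a node layout."""
    return _centroid_design(np.atleast_2d(nU), code_set) @ positions


# ---------------------------------------------------------------------------
# Group summaries and comparisons
# ---------------------------------------------------------------------------

@dataclass
class GroupSummary:
    label: str
    n: int
    mean_network: pd.Series  # mean normalised edge weight per pair
    centroid: np.ndarray  # mean of member projections, per dimension
    ci_half_width: np.ndarray  # t-based 95% half-width per dimension (NaN if n < 2)
    se: np.ndarray  # standard error per dimension


def mean_network(
    units: pd.DataFrame, projections: np.ndarray, label: str = "", conf: float = 0.95
) -> GroupSummary:
    """Mean network and centroid for a group of units.

    The mean network averages the *normalised* edge weights arithmetically
    (exactly, so a size-weighted mean over a partition of the group equals
    the group mean).  The centroid is the mean projection; the confidence
    half-width per dimension is ``t_{1-a/2, n-1} * sd / sqrt(n)``, undefined
    (NaN) for a single-unit group.
    """
    if len(units) == 0:
        raise ValueError("empty group")
    nU = normalize(units.to_numpy(dtype=float))
    proj = np.atleast_2d(projections)
    n = nU.shape[0]
    centroid = proj.mean(axis=0)
    if n >= 2:
        sd = proj.std(axis=0, ddof=1)
        se = sd / np.sqrt(n)
        half = stats.t.ppf(0.5 + conf / 2.0, n - 1) * se
    else:
        se = np.full(proj.shape[1], np.nan)
        half = np.full(proj.shape[1], np.nan)
    return GroupSummary(
        label=label,
        n=n,
        mean_network=pd.Series(nU.mean(axis=0), index=units.columns),
        centroid=centroid,
        ci_half_width=half,
        se=se,
    )


@dataclass
class GroupComparison:
    dimension: int
    mean_a: float
    mean_b: float
    t: float
    p: float
    cohens_d: float
    n_a: int
    n_b: int


def compare_groups(
    proj_a: np.ndarray,
    proj_b: np.ndarray,
    dimension: int = 1,
    welch: bool = False,
) -> GroupComparison:
    """Two-sample t-test on unit centroids along one space dimension.

    ``dimension`` is 0-based (0 = x-axis, 1 = y-axis).  Student's t with
    pooled variance by default; Welch's correction behind ``welch``.
    Cohen's d uses the pooled standard deviation.  Two degenerate groups with
    equal means compare as ``t = 0, p = 1``.
    """
    a = np.atleast_2d(proj_a)[:, dimension].astype(float)
    b = np.atleast_2d(proj_b)[:, dimension].astype(float)
    if a.size < 2 or b.size < 2:
        raise ValueError("both groups need at least 2 units")
    na, nb = a.size, b.size
    pooled_var = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    if pooled_var == 0:
        if a.mean() == b.mean():
            t_stat, p_val = 0.0, 1.0
        else:
            t_stat, p_val = np.inf * np.sign(a.mean() - b.mean()), 0.0
        d_val = 0.0 if a.mean() == b.mean() else np.inf * np.sign(a.mean() - b.mean())
    else:
        res = stats.ttest_ind(a, b, equal_var=not welch)
        t_stat, p_val = float(res.statistic), float(res.pvalue)
        d_val = float((a.mean() - b.mean()) / np.sqrt(pooled_var))
    return GroupComparison(
        dimension=dimension,
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
        t=t_stat,
        p=p_val,
        cohens_d=d_val,
        n_a=na,
        n_b=nb,
    )


# ---------------------------------------------------------------------------
# Export
# ---------------------------------------------------------------------------

def space_to_json(space: ENASpace, path=None) -> str:
    payload = {
        "pair_labels": space.pair_labels,
        "codes": list(space.code_set.labels),
        "mean": space.mean.tolist(),
        "loadings": space.loadings.tolist(),
        "singular_values": space.singular_values.tolist(),
        "variance_explained": space.variance_explained.tolist(),
        "projections": space.projections.tolist(),
        "unit_index": [list(map(str, idx if isinstance(idx, tuple) else (idx,))) for idx in space.unit_index],
        "node_positions": None
        if space.node_positions is None
        else space.node_positions.tolist(),
        "positioning_residual": space.positioning_residual,
        "unconstrained_nodes": space.unconstrained_nodes,
    }
    text = json.dumps(payload, indent=2)
    if path is not None:
        from pathlib import Path

        Path(path).write_text(text)
    return text


def edge_list(weights: pd.Series, code_set: Optional[CodeSet] = None) -> pd.DataFrame:
    """Edge-list frame (source, target, weight) from a pair-weight vector."""
    code_set = code_set or CodeSet.eight_codes()
    pairs = code_set.pairs()
    return pd.DataFrame(
        {
            "source": [p[0] for p in pairs],
            "target": [p[1] for p in pairs],
            "weight": np.asarray(weights, dtype=float),
        }
    )


def network_to_graphml(
    weights: pd.Series,
    path,
    code_set: Optional[CodeSet] = None,
    positions: Optional[np.ndarray] = None,
) -> None:
    """Write one network (e.g. a group mean network) as GraphML."""
    import networkx as nx

    code_set = code_set or CodeSet.eight_codes()
    g = nx.Graph()
    for k, label in enumerate(code_set.labels):
        attrs = {}
        if positions is not None:
            attrs = {"x": float(positions[k, 0]), "y": float(positions[k, 1])}
        g.add_node(label, **attrs)
    for (a, b), w in zip(code_set.pairs(), np.asarray(weights, dtype=float)):
        if w > 0:
            g.add_edge(a, b, weight=float(w))
    nx.write_graphml(g, path)
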