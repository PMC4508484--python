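"""Gaze-alignment lag scans, same/different recoding, and the lag-shifted ENA space.

*Alignment* at lag ``tau`` is the fraction of a phase's 50-ms segments in
which the worker gazes at the same object (raw AOI) the instructor gazed at
``tau`` earlier (positive lags = instructor leads).  Segments are pooled
over all dyads and sequences; pairs in which either stream is uncoded, or
whose shifted partner falls outside the sequence, drop out of the
denominator, and comparisons never straddle sequence boundaries.  The lag
maximising the curve is the phase's *optimal lag*; ties break toward the
smallest absolute lag and then toward the positive (instructor-lead) side.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Iterable, Optional, Tuple

import numpy as np
import pandas as pd

from .gaze_model import CodeSet, PHASES, UNCODED
from . import ena_core

__all__ = [
    "AlignmentCurve",
    "alignment_curve",
    "alignment_curves",
    "optimal_lag",
    "recode_same_different",
    "shift_instructor_reference",
    "shifted_ena",
    "curve_table",
    "peak_table",
]

SAME, DIFFERENT = 0, 1

_SEQ_KEYS = ["dyad_id", "interaction_id", "seq_index"]


@dataclass
class AlignmentCurve:
    """Alignment fraction per lag for one phase.

    ``n`` counts the comparable coded segment pairs entering each lag's
    denominator; lags with an empty denominator have NaN alignment and are
    excluded from peak search.
    """

    phase: str
    lags_ms: np.ndarray
    alignment: np.ndarray
    n: np.ndarray


def _match_columns(match: str) -> tuple[str, str]:
    if match == "aoi":
        return "i_aoi", "w_aoi"
    if match == "category":
        return "i_cat", "w_cat"
    raise ValueError("match must be 'aoi' or 'category'")


def _padded_streams(segments: pd.DataFrame, pad: int, match: str = "aoi"):
    """Concatenate per-sequence segment grids into flat arrays with ``pad``
    uncoded sentinel cells between sequences (so lagged comparisons can be
    done with one vectorised shift without leaking across sequences).

    ``match`` selects what "same target" compares: raw AOI identity
    (``"aoi"``, the default: same object) or the sequence-relative
    four-category code (``"category"``).  Unmapped gaze is -1 either way.
    """
    i_col, w_col = _match_columns(match)
    seg = segments.sort_values(_SEQ_KEYS + ["seg_index"], kind="mergesort")
    seq_id = seg.groupby(_SEQ_KEYS, sort=False).ngroup().to_numpy()
    seg_index = seg["seg_index"].to_numpy()
    # length of each sequence grid
    n_seq = seq_id.max() + 1 if len(seg) else 0
    lengths = np.zeros(n_seq, dtype=np.int64)
    np.maximum.at(lengths, seq_id, seg_index + 1)
    offsets = np.concatenate([[0], np.cumsum(lengths + pad)])
    total = int(offsets[-1]) if n_seq else 0
    pos = offsets[seq_id] + seg_index
    i_arr = np.full(total, UNCODED, dtype=np.int64)
    w_arr = np.full(total, UNCODED, dtype=np.int64)
    ph_arr = np.full(total, -1, dtype=np.int8)
    dyad_arr = np.full(total, -1, dtype=np.int64)
    i_arr[pos] = seg[i_col].to_numpy()
    w_arr[pos] = seg[w_col].to_numpy()
    ph_arr[pos] = seg["phase"].to_numpy()
    dyad_arr[pos] = seg.groupby("dyad_id", sort=True).ngroup().to_numpy()
    return i_arr, w_arr, ph_arr, dyad_arr


def alignment_curve(
    segments: pd.DataFrame,
    phase: str | int,
    lag_min_ms: int = -2000,
    lag_max_ms: int = 2000,
    step_ms: int = 50,
    segment_ms: int = 50,
    per_dyad: bool = False,
    match: str = "aoi",
    min_support_frac: float = 0.10,
) -> AlignmentCurve:
    """Scan alignment over a lag grid for one phase.

    Lags must live on the segment grid (``step_ms`` a multiple of
    ``segment_ms``).  "Same target" compares raw AOI identity by default
    (both participants on the same object); ``match="category"`` compares
    the four-category codes instead.  By default segment pairs are pooled
    across dyads before the fraction is taken; ``per_dyad`` instead
    averages the per-dyad fractions (unweighted) at each lag.

    At extreme lags only the rare longest sequences still contribute
    comparable pairs, so the fraction estimate degenerates; lags whose
    denominator falls below ``min_support_frac`` of the best-supported
    lag's denominator are reported as undefined (NaN) and excluded from
    peak search.
    """
    if step_ms % segment_ms != 0:
        raise ValueError("step_ms must be a multiple of the segment length")
    phase_idx = PHASES.index(phase) if isinstance(phase, str) else int(phase)
    lags = np.arange(lag_min_ms, lag_max_ms + 1, step_ms)
    max_steps = int(max(abs(lag_min_ms), abs(lag_max_ms)) // segment_ms) + 1
    i_arr, w_arr, ph_arr, dyad_arr = _padded_streams(segments, pad=max_steps, match=match)
    sel = np.nonzero((ph_arr == phase_idx) & (w_arr != UNCODED))[0]
    w_sel = w_arr[sel]
    dy_sel = dyad_arr[sel]
    n_dyads = int(dyad_arr.max()) + 1 if dyad_arr.size else 0

    align = np.full(lags.shape, np.nan)
    n_pairs = np.zeros(lags.shape, dtype=np.int64)
    for k, lag in enumerate(lags):
        shift = int(lag // segment_ms)
        src = sel - shift
        ok = (src >= 0) & (src < i_arr.size)
        src_codes = np.where(ok, i_arr[np.clip(src, 0, i_arr.size - 1)], UNCODED)
        comparable = src_codes != UNCODED
        same = comparable & (src_codes == w_sel)
        n_pairs[k] = int(comparable.sum())
        if per_dyad:
            num = np.bincount(dy_sel[same], minlength=n_dyads)
            den = np.bincount(dy_sel[comparable], minlength=n_dyads)
            with np.errstate(invalid="ignore"):
                fractions = num / den
            defined = den > 0
            align[k] = float(np.mean(fractions[defined])) if defined.any() else np.nan
        else:
            align[k] = same.sum() / n_pairs[k] if n_pairs[k] else np.nan
    align[n_pairs < min_support_frac * n_pairs.max()] = np.nan
    return AlignmentCurve(
        phase=PHASES[phase_idx], lags_ms=lags, alignment=align, n=n_pairs
    )


def alignment_curves(segments: pd.DataFrame, **kwargs) -> Dict[str, AlignmentCurve]:
    """Alignment curves for all five phases."""
    return {p: alignment_curve(segments, p, **kwargs) for p in PHASES}


def optimal_lag(curve: AlignmentCurve) -> Tuple[int, float]:
    """Peak of an alignment curve: ``(lag_ms, alignment_at_peak)``.

    Exact ties break toward the smallest absolute lag, then toward the
    positive (instructor-lead) side; a fully flat curve returns lag 0 with a
    warning.
    """
    defined = ~np.isnan(curve.alignment)
    if not defined.any():
        raise ValueError("alignment curve has no defined lag")
    best = np.nanmax(curve.alignment)
    cand = np.nonzero(defined & (curve.alignment == best))[0]
    if cand.size > 1:
        lo = np.nanmin(curve.alignment[defined])
        if best == lo:
            warnings.warn(f"flat alignment curve for phase {curve.phase}; returning lag 0")
            zero = np.nonzero(curve.lags_ms == 0)[0]
            k = int(zero[0]) if zero.size else int(cand[0])
            return int(curve.lags_ms[k]), float(curve.alignment[k])
        warnings.warn(
            f"tied alignment peak for phase {curve.phase} at lags "
            f"{curve.lags_ms[cand].tolist()}; breaking toward smallest |lag|, then positive"
        )
    lag_vals = curve.lags_ms[cand]
    order = np.lexsort((-np.sign(lag_vals), np.abs(lag_vals)))
    k = cand[order[0]]
    return int(curve.lags_ms[k]), float(curve.alignment[k])


# ---------------------------------------------------------------------------
# Same/different recoding and the shifted space
# ---------------------------------------------------------------------------

def recode_same_different(segments: pd.DataFrame, match: str = "aoi") -> pd.DataFrame:
    """Recode the worker stream as Same/Different relative to the instructor.

    Adds a ``w_sd`` column: ``W.Same`` (0) when the worker gazes at the same
    object as the instructor, ``W.Different`` (1) when both are coded and
    the objects differ, uncoded when either stream is unmapped.  Instructor
    codes pass through; pair with :meth:`CodeSet.six_codes`.
    """
    i_col, w_col = _match_columns(match)
    out = segments.copy()
    i = segments[i_col].to_numpy()
    w = segments[w_col].to_numpy()
    both = (i != UNCODED) & (w != UNCODED)
    sd = np.full(len(segments), UNCODED, dtype=np.int8)
    sd[both & (i == w)] = SAME
    sd[both & (i != w)] = DIFFERENT
    out["w_sd"] = sd
    return out


def shift_instructor_reference(
    segments: pd.DataFrame,
    lags_ms: Dict[str, int],
    segment_ms: int = 50,
) -> pd.DataFrame:
    """Re-pair each worker segment with the instructor code at the phase's
    optimal lag.

    The worker stream anchors the segment grid (consistent with
    :func:`alignment_curve`); for a segment in phase ``p`` the instructor
    code is taken ``lags_ms[p]`` earlier on the same sequence timeline.
    Segments whose shifted partner falls outside the sequence become
    instructor-uncoded.
    """
    for p, lag in lags_ms.items():
        if int(lag) % segment_ms != 0:
            raise ValueError(f"lag for phase {p} not on the {segment_ms}-ms grid")
    max_steps = max(abs(int(v)) // segment_ms for v in lags_ms.values()) + 1
    seg = segments.sort_values(_SEQ_KEYS + ["seg_index"], kind="mergesort").reset_index(drop=True)
    cat_arr, _, _, _ = _padded_streams(seg, pad=max_steps, match="category")
    aoi_arr, _, _, _ = _padded_streams(seg, pad=max_steps, match="aoi")
    seq_id = seg.groupby(_SEQ_KEYS, sort=False).ngroup().to_numpy()
    seg_index = seg["seg_index"].to_numpy()
    lengths = np.zeros(seq_id.max() + 1, dtype=np.int64)
    np.maximum.at(lengths, seq_id, seg_index + 1)
    offsets = np.concatenate([[0], np.cumsum(lengths + max_steps)])
    pos = offsets[seq_id] + seg_index

    shifted_cat = np.full(len(seg), UNCODED, dtype=np.int8)
    shifted_aoi = np.full(len(seg), -1, dtype=np.int64)
    for p_idx, p_name in enumerate(PHASES):
        shift = int(lags_ms.get(p_name, 0)) // segment_ms
        rows = np.nonzero(seg["phase"].to_numpy() == p_idx)[0]
        src = pos[rows] - shift
        ok = (src >= 0) & (src < cat_arr.size)
        shifted_cat[rows[ok]] = cat_arr[src[ok]]
        shifted_aoi[rows[ok]] = aoi_arr[src[ok]]
    out = seg.copy()
    out["i_cat"] = shifted_cat
    out["i_aoi"] = shifted_aoi
    return out


def shifted_ena(
    segments: pd.DataFrame,
    lags_ms: Dict[str, int],
    d: int = 2,
    unit_keys: Iterable[str] = ("dyad_id", "interaction_id", "phase"),
    segment_ms: int = 50,
):
    """Lag-shifted ENA over the 6-code set.

    Shifts the instructor/worker pairing of each phase by that phase's
    optimal lag, recodes the worker stream as Same/Different, accumulates
    units (dyad-interaction x phase by default) and fits the ENA space.
    Returns ``(space, units)``.
    """
    shifted = shift_instructor_reference(segments, lags_ms, segment_ms)
    recoded = recode_same_different(shifted)
    code_set = CodeSet.six_codes()
    units = ena_core.accumulate_units(
        recoded, unit_keys=list(unit_keys), code_set=code_set, w_col="w_sd"
    )
    space = ena_core.build_space(units, d=d, code_set=code_set)
    ena_core.position_nodes(space, units)
    return space, units


# ---------------------------------------------------------------------------
# Tabular export
# ---------------------------------------------------------------------------

def curve_table(curves: Dict[str, AlignmentCurve]) -> pd.DataFrame:
    rows = []
    for p, c in curves.items():
        for lag, a, n in zip(c.lags_ms, c.alignment, c.n):
            rows.append({"phase": p, "lag_ms": int(lag), "alignment": a, "n": int(n)})
    return pd.DataFrame(rows)


def peak_table(curves: Dict[str, AlignmentCurve]) -> pd.DataFrame:
    rows = []
    for p, c in curves.items():
        lag, value = optimal_lag(c)
        rows.append(
            {"phase": p, "optimal_lag_ms": lag, "alignment_pct": 100.0 * value}
        )
    return pd.DataFrame(rows)
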