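"""Data model, IO, gaze coding and descriptive statistics for dual-stream AOI fixation data.

The atomic input is a *fixation*: a half-open interval ``[t_start_ms, t_end_ms)``
during which one participant (the *instructor* or the *worker*) rests their
gaze on one labelled area of interest (AOI).  Fixations are grouped into
*reference-action sequences*, each divided into five contiguous phases
(pre-reference, reference, post-reference, action, post-action).  Within a
sequence, raw AOI labels are re-coded relative to that sequence's referent
into four categories per participant:

* ``reference`` -- the ingredient the instructor verbally refers to,
* ``other``     -- any other ingredient,
* ``target``    -- the bread the ingredient is moved to,
* ``person``    -- the conversational partner,

while fixations that hit no AOI (``unmapped``) carry no code.  The coded
timeline is discretised into fixed-length segments (50 ms by default); each
segment carries at most one instructor code and one worker code, determined
by the fixation covering the segment midpoint.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PHASES",
    "CATEGORIES",
    "ROLES",
    "TARGET_BREAD",
    "PARTNER",
    "UNMAPPED",
    "UNCODED",
    "CodeSet",
    "DescriptiveStats",
    "ValidationError",
    "categorize_aoi",
    "map_code",
    "read_fixations",
    "write_fixations",
    "read_sequences",
    "write_sequences",
    "discretize",
    "segments_to_indicators",
    "write_segments",
    "descriptive_stats",
]

ROLES = ("instructor", "worker")
PHASES = ("pre_reference", "reference", "post_reference", "action", "post_action")
CATEGORIES = ("reference", "other", "target", "person")

TARGET_BREAD = "target_bread"
PARTNER = "partner"
UNMAPPED = "unmapped"

#: integer code for "no active code" in segment tables
UNCODED = -1

_FIXATION_COLUMNS = ["dyad_id", "interaction_id", "role", "t_start_ms", "t_end_ms", "aoi_raw"]
_PHASE_BOUND_COLUMNS = [f"{p}_{which}_ms" for p in PHASES for which in ("start", "end")]
_SEQUENCE_COLUMNS = (
    ["dyad_id", "interaction_id", "seq_index", "referent_id"]
    + _PHASE_BOUND_COLUMNS
    + ["repair", "reference_onset_ms"]
)


class ValidationError(ValueError):
    """Raised when an input table violates a structural invariant."""


@dataclass(frozen=True)
class CodeSet:
    """An ordered set of gaze codes with an enumeration of cross-person code pairs.

    Edges in the co-occurrence networks only connect an instructor code with a
    worker code (one person cannot gaze at two targets at once), so the pair
    basis enumerates instructor x worker combinations in row-major order.
    """

    instructor_codes: tuple
    worker_codes: tuple

    @property
    def labels(self) -> tuple:
        return self.instructor_codes + self.worker_codes

    @property
    def n_instructor(self) -> int:
        return len(self.instructor_codes)

    @property
    def n_worker(self) -> int:
        return len(self.worker_codes)

    @property
    def n_pairs(self) -> int:
        return self.n_instructor * self.n_worker

    def pairs(self) -> list:
        """(instructor_code, worker_code) tuples in pair-index order."""
        return [(i, w) for i in self.instructor_codes for w in self.worker_codes]

    def pair_index(self, instructor_code: str, worker_code: str) -> int:
        return self.instructor_codes.index(instructor_code) * self.n_worker + self.worker_codes.index(
            worker_code
        )

    def pair_labels(self) -> list:
        return [f"{i}--{w}" for i, w in self.pairs()]

    @classmethod
    def eight_codes(cls) -> "CodeSet":
        """The 8-code set: four gaze-target categories per participant."""
        return cls(
            tuple(f"I.Gaze_{c.capitalize()}" for c in CATEGORIES),
            tuple(f"W.Gaze_{c.capitalize()}" for c in CATEGORIES),
        )

    @classmethod
    def six_codes(cls) -> "CodeSet":
        """The 6-code set used for lag-shifted analyses: instructor categories
        plus worker Same/Different relative to the instructor."""
        return cls(
            tuple(f"I.Gaze_{c.capitalize()}" for c in CATEGORIES),
            ("W.Same", "W.Different"),
        )


# ---------------------------------------------------------------------------
# AOI -> category coding
# ---------------------------------------------------------------------------

def categorize_aoi(aoi_raw: str, referent_id: str) -> int:
    """Map a raw AOI label to a category index relative to a sequence referent.

    Returns 0 (reference), 1 (other ingredient), 2 (target bread),
    3 (partner) or :data:`UNCODED` for unmapped gaze.  Referent identity is
    sequence-relative: the same physical ingredient AOI is ``reference`` in
    the sequence that refers to it and ``other`` elsewhere.
    """
    if aoi_raw == UNMAPPED:
        return UNCODED
    if aoi_raw == referent_id:
        return 0
    if aoi_raw == TARGET_BREAD:
        return 2
    if aoi_raw == PARTNER:
        return 3
    return 1


def map_code(fixation, sequence) -> Optional[str]:
    """Code label (e.g. ``I.Gaze_Reference``) for one fixation within one
    sequence, or ``None`` for unmapped gaze.

    ``fixation`` needs ``role`` and ``aoi_raw`` attributes (a fixation-table
    row works); ``sequence`` needs ``referent_id``.
    """
    cat = categorize_aoi(fixation.aoi_raw, sequence.referent_id)
    if cat == UNCODED:
        return None
    prefix = "I" if fixation.role == "instructor" else "W"
    return f"{prefix}.Gaze_{CATEGORIES[cat].capitalize()}"


# ---------------------------------------------------------------------------
# Table IO
# ---------------------------------------------------------------------------

def _read_table(path) -> pd.DataFrame:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    return pd.read_csv(path, sep=sep)


def _write_table(df: pd.DataFrame, path) -> None:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    df.to_csv(path, sep=sep, index=False)


def validate_fixations(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in _FIXATION_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"fixation table is missing columns: {missing}")
    bad_roles = set(df["role"].unique()) - set(ROLES)
    if bad_roles:
        raise ValidationError(f"unknown role labels: {sorted(bad_roles)}")
    if len(df) and not (df["t_end_ms"] > df["t_start_ms"]).all():
        rows = df.index[df["t_end_ms"] <= df["t_start_ms"]].tolist()
        raise ValidationError(f"fixations with t_end_ms <= t_start_ms at rows {rows}")
    df = df.sort_values(["dyad_id", "interaction_id", "role", "t_start_ms"], kind="mergesort")
    df = df.reset_index(drop=True)
    # one participant's fixations must not overlap
    for (dyad, inter, role), g in df.groupby(["dyad_id", "interaction_id", "role"], sort=False):
        starts = g["t_start_ms"].to_numpy()
        ends = g["t_end_ms"].to_numpy()
        bad = np.nonzero(starts[1:] < ends[:-1])[0]
        if bad.size:
            i = int(bad[0])
            raise ValidationError(
                f"overlapping fixations for {role} in dyad={dyad} interaction={inter}: "
                f"rows {g.index[i]} and {g.index[i + 1]} "
                f"([{starts[i]},{ends[i]}) overlaps [{starts[i + 1]},{ends[i + 1]}))"
            )
    return df


def read_fixations(path) -> pd.DataFrame:
    """Read and validate a fixation table (TSV/CSV by extension).

    Returns the fixations sorted by participant and onset time.
    """
    return validate_fixations(_read_table(path))


def write_fixations(df: pd.DataFrame, path) -> None:
    _write_table(df[_FIXATION_COLUMNS], path)


def validate_sequences(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in _SEQUENCE_COLUMNS if c not in df.columns and c != "reference_onset_ms"]
    if missing:
        raise ValidationError(f"sequence table is missing columns: {missing}")
    if "reference_onset_ms" not in df.columns:
        df = df.copy()
        df["reference_onset_ms"] = df["reference_start_ms"]
    for _, row in df.iterrows():
        bounds = [(row[f"{p}_start_ms"], row[f"{p}_end_ms"]) for p in PHASES]
        for p, (s, e) in zip(PHASES, bounds):
            if e < s:
                raise ValidationError(f"phase {p} has negative duration in seq {row['seq_index']}")
        for (prev_name, (_, e_prev)), (name, (s, _)) in zip(
            zip(PHASES, bounds), list(zip(PHASES, bounds))[1:]
        ):
            if s != e_prev:
                raise ValidationError(
                    f"phases {prev_name}/{name} not contiguous in seq {row['seq_index']}"
                )
    df = df.sort_values(["dyad_id", "interaction_id", "seq_index"], kind="mergesort").reset_index(
        drop=True
    )
    for (dyad, inter), g in df.groupby(["dyad_id", "interaction_id"], sort=False):
        starts = g["pre_reference_start_ms"].to_numpy()
        ends = g["post_action_end_ms"].to_numpy()
        if np.any(starts[1:] < ends[:-1]):
            raise ValidationError(
                f"overlapping sequences in dyad={dyad} interaction={inter}"
            )
    return df


def read_sequences(path) -> pd.DataFrame:
    return validate_sequences(_read_table(path))


def write_sequences(df: pd.DataFrame, path) -> None:
    cols = [c for c in _SEQUENCE_COLUMNS if c in df.columns]
    _write_table(df[cols], path)


# ---------------------------------------------------------------------------
# Discretisation
# ---------------------------------------------------------------------------

def _phase_bounds(seq_row) -> np.ndarray:
    """Array of the six phase boundaries (start of phase 0 .. end of phase 4)."""
    edges = [seq_row[f"{p}_start_ms"] for p in PHASES] + [seq_row[f"{PHASES[-1]}_end_ms"]]
    return np.asarray(edges, dtype=np.int64)


def _covering_fixation(mids: np.ndarray, starts: np.ndarray, ends: np.ndarray) -> np.ndarray:
    """Index of the fixation covering each midpoint (-1 where none).

    ``starts``/``ends`` describe non-overlapping, onset-sorted fixations;
    coverage uses the half-open convention, so a fixation ending exactly at a
    midpoint does not cover it.
    """
    out = np.full(mids.shape, -1, dtype=np.int64)
    if starts.size == 0:
        return out
    idx = np.searchsorted(starts, mids, side="right") - 1
    ok = idx >= 0
    covered = np.zeros_like(ok)
    covered[ok] = mids[ok] < ends[idx[ok]]
    out[covered] = idx[covered]
    return out


def discretize(
    fixations: pd.DataFrame,
    sequences: pd.DataFrame,
    segment_ms: int = 50,
) -> pd.DataFrame:
    """Tile every sequence with ``segment_ms`` segments and code each segment.

    The segment grid is anchored at each sequence's start.  Each segment
    carries the code of the fixation covering its midpoint, separately per
    participant, and belongs to the phase window containing its midpoint;
    midpoints falling in no phase are dropped (with contiguous phases this
    only happens for the final partial segment).

    Returns a data frame with one row per segment: unit keys
    (``dyad_id, interaction_id, seq_index``), ``phase`` (0..4 indexing
    :data:`PHASES`), ``repair``, ``seg_index`` (position on the sequence
    grid), ``t_mid_ms``, the category columns ``i_cat``/``w_cat`` (0..3
    indexing :data:`CATEGORIES`, :data:`UNCODED` for no code) and the raw
    AOI identity columns ``i_aoi``/``w_aoi`` (integer labels shared across
    the corpus, -1 for unmapped/no fixation) used for same-object matching.
    """
    if segment_ms <= 0:
        raise ValueError("segment_ms must be positive")
    fixations = fixations.sort_values(
        ["dyad_id", "interaction_id", "role", "t_start_ms"], kind="mergesort"
    ).copy()
    aoi_codes, _ = pd.factorize(fixations["aoi_raw"])
    aoi_codes = np.where(fixations["aoi_raw"].to_numpy() == UNMAPPED, -1, aoi_codes)
    fixations["_aoi_code"] = aoi_codes
    fix_groups = {
        key: g for key, g in fixations.groupby(["dyad_id", "interaction_id", "role"], sort=False)
    }
    out = []
    for _, seq in sequences.iterrows():
        edges = _phase_bounds(seq)
        seq_start, seq_end = int(edges[0]), int(edges[-1])
        zero_len = [PHASES[k] for k in range(5) if edges[k + 1] == edges[k]]
        if zero_len:
            import warnings

            warnings.warn(
                f"zero-length phases {zero_len} in seq {seq['seq_index']} contribute no segments"
            )
        n = max(0, (seq_end - seq_start - segment_ms // 2 - 1) // segment_ms + 1)
        if n == 0:
            continue
        mids = seq_start + segment_ms // 2 + segment_ms * np.arange(n, dtype=np.int64)
        phase = np.searchsorted(edges, mids, side="right") - 1
        keep = (phase >= 0) & (phase <= 4)
        mids, phase = mids[keep], phase[keep]
        seg_index = np.nonzero(keep)[0]
        cols = {}
        for role, cat_col, aoi_col in (
            ("instructor", "i_cat", "i_aoi"),
            ("worker", "w_cat", "w_aoi"),
        ):
            g = fix_groups.get((seq["dyad_id"], seq["interaction_id"], role))
            if g is None:
                cols[cat_col] = np.full(mids.shape, UNCODED, dtype=np.int8)
                cols[aoi_col] = np.full(mids.shape, -1, dtype=np.int64)
                continue
            cats = np.array(
                [categorize_aoi(a, seq["referent_id"]) for a in g["aoi_raw"]], dtype=np.int8
            )
            idx = _covering_fixation(
                mids, g["t_start_ms"].to_numpy(), g["t_end_ms"].to_numpy()
            )
            covered = idx >= 0
            cat_out = np.full(mids.shape, UNCODED, dtype=np.int8)
            aoi_out = np.full(mids.shape, -1, dtype=np.int64)
            cat_out[covered] = cats[idx[covered]]
            aoi_out[covered] = g["_aoi_code"].to_numpy()[idx[covered]]
            cols[cat_col] = cat_out
            cols[aoi_col] = aoi_out
        out.append(
            pd.DataFrame(
                {
                    "dyad_id": seq["dyad_id"],
                    "interaction_id": seq["interaction_id"],
                    "seq_index": seq["seq_index"],
                    "phase": phase.astype(np.int8),
                    "repair": bool(seq["repair"]),
                    "seg_index": seg_index,
                    "t_mid_ms": mids,
                    "i_cat": cols["i_cat"],
                    "w_cat": cols["w_cat"],
                    "i_aoi": cols["i_aoi"],
                    "w_aoi": cols["w_aoi"],
                }
            )
        )
    if not out:
        return pd.DataFrame(
            columns=[
                "dyad_id",
                "interaction_id",
                "seq_index",
                "phase",
                "repair",
                "seg_index",
                "t_mid_ms",
                "i_cat",
                "w_cat",
                "i_aoi",
                "w_aoi",
            ]
        )
    return pd.concat(out, ignore_index=True)


def segments_to_indicators(segments: pd.DataFrame, code_set: Optional[CodeSet] = None) -> pd.DataFrame:
    """Expand the compact category columns into one 0/1 column per code."""
    code_set = code_set or CodeSet.eight_codes()
    out = segments[["dyad_id", "interaction_id", "seq_index", "phase", "seg_index", "t_mid_ms"]].copy()
    out["phase"] = [PHASES[p] for p in segments["phase"]]
    for k, label in enumerate(code_set.instructor_codes):
        out[label] = (segments["i_cat"].to_numpy() == k).astype(np.int8)
    for k, label in enumerate(code_set.worker_codes):
        out[label] = (segments["w_cat"].to_numpy() == k).astype(np.int8)
    return out


def write_segments(segments: pd.DataFrame, path, code_set: Optional[CodeSet] = None) -> None:
    _write_table(segments_to_indicators(segments, code_set), path)


# ---------------------------------------------------------------------------
# Descriptive statistics
# ---------------------------------------------------------------------------

@dataclass
class DescriptiveStats:
    """Corpus-level gaze descriptives.

    Percentages are over 50-ms segments in which *both* streams carry a code
    (unmapped gaze is excluded from numerator and denominator, keeping the
    mutual-gaze and shared-gaze figures on one scale).  Latencies are in
    seconds, averaged over the sequences in which the event occurs.
    """

    mutual_gaze_pct: float
    same_target_pct: float  # matching target categories (code-level)
    same_object_pct: float  # both on the very same AOI (object-level)
    instructor_ref_lead_s: float  # first referent fixation -> reference onset
    worker_ref_latency_s: float  # reference onset -> first referent fixation
    instructor_ref_fix_count: float  # referent fixations before reference onset
    n_segments: int
    n_segments_both_coded: int
    n_sequences: int


def descriptive_stats(
    fixations: pd.DataFrame,
    sequences: pd.DataFrame,
    segments: Optional[pd.DataFrame] = None,
    segment_ms: int = 50,
) -> DescriptiveStats:
    """Compute gaze descriptives for a coded corpus.

    Segment-level percentages come from the discretised streams; the latency
    and count statistics scan the fixation streams directly, relative to each
    sequence's reference onset.  If the sequence table lacks reference-onset
    annotations the latencies are reported as NaN.
    """
    if segments is None:
        segments = discretize(fixations, sequences, segment_ms)
    both = (segments["i_cat"].to_numpy() >= 0) & (segments["w_cat"].to_numpy() >= 0)
    n_both = int(both.sum())
    if n_both:
        i_cat = segments["i_cat"].to_numpy()[both]
        w_cat = segments["w_cat"].to_numpy()[both]
        mutual = float(np.mean((i_cat == 3) & (w_cat == 3))) * 100.0
        # shared gaze at the level the segments are coded: matching target
        # categories (two participants scanning different non-referent
        # ingredients both carry the Other code)
        same = float(np.mean(i_cat == w_cat)) * 100.0
        # stricter variant: both on the very same object (same raw AOI)
        same_obj = float(
            np.mean(segments["i_aoi"].to_numpy()[both] == segments["w_aoi"].to_numpy()[both])
        ) * 100.0
    else:
        mutual = same = same_obj = float("nan")

    has_onset = "reference_onset_ms" in sequences.columns and sequences[
        "reference_onset_ms"
    ].notna().all()
    leads, latencies, counts = [], [], []
    if has_onset and len(sequences):
        fix_groups = {
            key: g
            for key, g in fixations.groupby(["dyad_id", "interaction_id", "role"], sort=False)
        }
        for _, seq in sequences.iterrows():
            onset = int(seq["reference_onset_ms"])
            seq_start = int(seq["pre_reference_start_ms"])
            seq_end = int(seq["post_action_end_ms"])
            gi = fix_groups.get((seq["dyad_id"], seq["interaction_id"], "instructor"))
            gw = fix_groups.get((seq["dyad_id"], seq["interaction_id"], "worker"))
            if gi is not None:
                m = (
                    (gi["aoi_raw"] == seq["referent_id"])
                    & (gi["t_start_ms"] >= seq_start)
                    & (gi["t_start_ms"] < onset)
                )
                counts.append(int(m.sum()))
                if m.any():
                    leads.append((onset - int(gi.loc[m, "t_start_ms"].iloc[0])) / 1000.0)
            if gw is not None:
                m = (
                    (gw["aoi_raw"] == seq["referent_id"])
                    & (gw["t_start_ms"] >= onset)
                    & (gw["t_start_ms"] < seq_end)
                )
                if m.any():
                    latencies.append((int(gw.loc[m, "t_start_ms"].iloc[0]) - onset) / 1000.0)

    return DescriptiveStats(
        mutual_gaze_pct=mutual,
        same_target_pct=same,
        same_object_pct=same_obj,
        instructor_ref_lead_s=float(np.mean(leads)) if leads else float("nan"),
        worker_ref_latency_s=float(np.mean(latencies)) if latencies else float("nan"),
        instructor_ref_fix_count=float(np.mean(counts)) if counts else float("nan"),
        n_segments=int(len(segments)),
        n_segments_both_coded=n_both,
        n_sequences=int(len(sequences)),
    )
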