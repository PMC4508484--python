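"""Fixation IO, sequence-relative coding, discretisation and descriptives."""

import numpy as np
import pandas as pd
import pytest
from types import SimpleNamespace

import gazecoord as gc
from gazecoord.gaze_model import (
    CATEGORIES,
    PHASES,
    UNCODED,
    ValidationError,
    categorize_aoi,
    descriptive_stats,
    discretize,
    map_code,
    read_fixations,
    segments_to_indicators,
    write_fixations,
)
from conftest import fix_table, seq_row, seq_table


class TestFixationIO:
    def test_roundtrip_is_identity(self, tmp_path, small_corpus):
        path = tmp_path / "fx.tsv"
        write_fixations(small_corpus.fixations, path)
        back = read_fixations(path)  # returned in canonical participant/onset order
        expected = small_corpus.fixations.sort_values(
            ["dyad_id", "interaction_id", "role", "t_start_ms"], kind="mergesort"
        ).reset_index(drop=True)
        pd.testing.assert_frame_equal(back, expected, check_dtype=False)

    def test_empty_file_gives_empty_collection(self, tmp_path):
        path = tmp_path / "fx.csv"
        path.write_text("dyad_id,interaction_id,role,t_start_ms,t_end_ms,aoi_raw\n")
        assert len(read_fixations(path)) == 0

    def test_sorted_by_onset(self, tmp_path):
        df = fix_table([(300, 400, "ing01"), (0, 100, "ing02"), (150, 250, "partner")])
        path = tmp_path / "fx.csv"
        df.to_csv(path, index=False)
        out = read_fixations(path)
        assert list(out["t_start_ms"]) == [0, 150, 300]

    def test_overlapping_fixations_rejected_with_rows(self, tmp_path):
        df = fix_table([(0, 200, "ing01"), (150, 300, "ing02")], role="worker")
        path = tmp_path / "fx.csv"
        df.to_csv(path, index=False)
        with pytest.raises(ValidationError, match="overlapping"):
            read_fixations(path)

    def test_unknown_role_rejected(self, tmp_path):
        df = fix_table([(0, 100, "ing01")], role="observer")
        path = tmp_path / "fx.csv"
        df.to_csv(path, index=False)
        with pytest.raises(ValidationError, match="role"):
            read_fixations(path)

    def test_nonpositive_interval_rejected(self, tmp_path):
        df = fix_table([(100, 100, "ing01")])
        path = tmp_path / "fx.csv"
        df.to_csv(path, index=False)
        with pytest.raises(ValidationError):
            read_fixations(path)


class TestCoding:
    seq = SimpleNamespace(referent_id="ing05")

    @pytest.mark.parametrize(
        "role,aoi,expected",
        [
            ("instructor", "ing05", "I.Gaze_Reference"),
            ("worker", "target_bread", "W.Gaze_Target"),
            ("worker", "partner", "W.Gaze_Person"),
            ("instructor", "ing17", "I.Gaze_Other"),
            ("worker", "unmapped", None),
        ],
    )
    def test_code_definitions(self, role, aoi, expected):
        fix = SimpleNamespace(role=role, aoi_raw=aoi)
        assert map_code(fix, self.seq) == expected

    def test_referent_identity_is_sequence_relative(self):
        # the same physical ingredient is Reference in one sequence, Other in the next
        assert categorize_aoi("ing05", "ing05") == 0
        assert categorize_aoi("ing05", "ing09") == 1


class TestDiscretize:
    def test_instructor_only_fixation_fills_segments(self):
        sequences = seq_table(seq_row())
        fx = fix_table([(0, 100, "ing01")])  # 100 ms on the referent
        seg = discretize(fx, sequences)
        active = seg[seg["i_cat"] == 0]
        assert list(active["t_mid_ms"]) == [25, 75]
        assert (active["w_cat"] == UNCODED).all()

    def test_both_on_bread_gives_three_joint_segments(self):
        sequences = seq_table(seq_row())
        fx = pd.concat([
            fix_table([(0, 150, "target_bread")], role="instructor"),
            fix_table([(0, 150, "target_bread")], role="worker"),
        ])
        seg = discretize(fx, sequences)
        joint = seg[(seg["i_cat"] == 2) & (seg["w_cat"] == 2)]
        assert len(joint) == 3

    def test_fixation_ending_at_midpoint_does_not_cover_it(self):
        # half-open [start, end): ending exactly at a midpoint leaves it uncoded
        sequences = seq_table(seq_row())
        fx = fix_table([(0, 125, "ing01")])
        seg = discretize(fx, sequences)
        assert seg.loc[seg["t_mid_ms"] == 75, "i_cat"].iloc[0] == 0
        assert seg.loc[seg["t_mid_ms"] == 125, "i_cat"].iloc[0] == UNCODED

    def test_phase_assignment_by_midpoint(self):
        sequences = seq_table(seq_row(bounds=(0, 1000, 2000, 3000, 4000, 5000)))
        seg = discretize(fix_table([(0, 5000, "ing01")]), sequences)
        # 20 segments per 1000-ms phase, phases indexed in order
        assert seg.groupby("phase").size().tolist() == [20, 20, 20, 20, 20]

    @pytest.mark.parametrize("bounds", [
        (0, 930, 2110, 2870, 4520, 5230),
        (0, 130, 180, 230, 340, 420),
        (1000, 2400, 3470, 3980, 5210, 6000),
    ])
    def test_segment_count_within_one_of_duration_ratio(self, bounds):
        sequences = seq_table(seq_row(bounds=bounds))
        seg = discretize(fix_table([(bounds[0], bounds[-1], "ing01")]), sequences)
        counts = seg.groupby("phase").size()
        for k in range(5):
            dur = bounds[k + 1] - bounds[k]
            assert abs(counts.get(k, 0) - dur / 50) <= 1

    def test_zero_length_phase_warns_and_contributes_nothing(self):
        sequences = seq_table(seq_row(bounds=(0, 1000, 1000, 2000, 3000, 4000)))
        with pytest.warns(UserWarning, match="zero-length"):
            seg = discretize(fix_table([(0, 4000, "ing01")]), sequences)
        assert 1 not in set(seg["phase"])

    def test_at_most_one_code_per_participant(self, small_segments):
        ind = segments_to_indicators(small_segments)
        i_cols = [c for c in ind.columns if c.startswith("I.")]
        w_cols = [c for c in ind.columns if c.startswith("W.")]
        assert (ind[i_cols].sum(axis=1) <= 1).all()
        assert (ind[w_cols].sum(axis=1) <= 1).all()


# ---------------------------------------------------------------------------
# descriptives
# ---------------------------------------------------------------------------

def _brute_force_descriptives(fixations, sequences, segment_ms=50):
    """Independent re-computation scanning fixations directly."""
    same = mutual = both = 0
    leads, lats, counts = [], [], []
    for _, seq in sequences.iterrows():
        start = seq["pre_reference_start_ms"]
        end = seq["post_action_end_ms"]
        onset = seq["reference_onset_ms"]
        streams = {}
        for role in ("instructor", "worker"):
            fx = fixations[
                (fixations.dyad_id == seq.dyad_id)
                & (fixations.interaction_id == seq.interaction_id)
                & (fixations.role == role)
            ]
            streams[role] = list(fx[["t_start_ms", "t_end_ms", "aoi_raw"]].itertuples(index=False))
        mid = start + segment_ms // 2
        while mid < end:
            cats = {}
            for role, fl in streams.items():
                cats[role] = None
                for t0, t1, aoi in fl:
                    if t0 <= mid < t1:
                        c = gc.gaze_model.categorize_aoi(aoi, seq.referent_id)
                        cats[role] = None if c == UNCODED else c
            if cats["instructor"] is not None and cats["worker"] is not None:
                both += 1
                same += cats["instructor"] == cats["worker"]
                mutual += cats["instructor"] == 3 and cats["worker"] == 3
            mid += segment_ms
        ref_i = [t0 for t0, _, aoi in streams["instructor"] if aoi == seq.referent_id and start <= t0 < onset]
        counts.append(len(ref_i))
        if ref_i:
            leads.append((onset - ref_i[0]) / 1000)
        ref_w = [t0 for t0, _, aoi in streams["worker"] if aoi == seq.referent_id and onset <= t0 < end]
        if ref_w:
            lats.append((ref_w[0] - onset) / 1000)
    return {
        "same": 100 * same / both,
        "mutual": 100 * mutual / both,
        "lead": np.mean(leads),
        "lat": np.mean(lats),
        "count": np.mean(counts),
    }


class TestDescriptives:
    def test_identical_streams_never_on_partner(self):
        sequences = seq_table(seq_row())
        spans = [(0, 2500, "ing01"), (2500, 5000, "target_bread")]
        fx = pd.concat([fix_table(spans, role="instructor"), fix_table(spans, role="worker")])
        st = descriptive_stats(fx, sequences)
        assert st.mutual_gaze_pct == 0.0
        assert st.same_target_pct == 100.0
        assert st.same_object_pct == 100.0

    def test_constructed_worker_latency(self):
        rows, fxs = [], []
        for k in range(5):
            offset = 6000 * k
            rows.append(seq_row(seq=k, bounds=tuple(offset + b for b in (0, 1000, 2000, 3000, 4000, 5000))))
            fxs.append((offset, offset + 900, "ing17"))
            fxs.append((offset + 2000, offset + 2400, "ing01"))  # 1000 ms after onset
        st = descriptive_stats(fix_table(fxs, role="worker"), seq_table(*rows))
        assert st.worker_ref_latency_s == pytest.approx(1.0)

    def test_matches_brute_force_oracle(self, small_corpus, small_segments):
        st = descriptive_stats(small_corpus.fixations, small_corpus.sequences, small_segments)
        bf = _brute_force_descriptives(small_corpus.fixations, small_corpus.sequences)
        assert st.same_target_pct == pytest.approx(bf["same"], abs=1e-9)
        assert st.mutual_gaze_pct == pytest.approx(bf["mutual"], abs=1e-9)
        assert st.instructor_ref_lead_s == pytest.approx(bf["lead"], abs=1e-9)
        assert st.worker_ref_latency_s == pytest.approx(bf["lat"], abs=1e-9)
        assert st.instructor_ref_fix_count == pytest.approx(bf["count"], abs=1e-9)

    def test_missing_onsets_yield_nan_latencies(self, small_corpus):
        sequences = small_corpus.sequences.copy()
        sequences["reference_onset_ms"] = np.nan
        st = descriptive_stats(small_corpus.fixations, sequences)
        assert np.isnan(st.worker_ref_latency_s)
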