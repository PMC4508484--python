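"""ENA mathematics: accumulation, normalisation, space fitting, node layout,
group summaries and the centroid t-test."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from gazecoord import ena_core
from gazecoord.gaze_model import CodeSet, UNCODED


def _random_segments(n, rng, n_cat=4):
    return pd.DataFrame(
        {
            "i_cat": rng.integers(-1, n_cat, n).astype(np.int8),
            "w_cat": rng.integers(-1, n_cat, n).astype(np.int8),
        }
    )


class TestAccumulate:
    def test_counting_example(self):
        # segments (I.Ref, W.Ref) x2 and (I.Other, W.Target) x1
        seg = pd.DataFrame({"i_cat": [0, 0, 1], "w_cat": [0, 0, 2]})
        U = ena_core.accumulate(seg)
        cs = CodeSet.eight_codes()
        expected = np.zeros(16, dtype=int)
        expected[cs.pair_index("I.Gaze_Reference", "W.Gaze_Reference")] = 2
        expected[cs.pair_index("I.Gaze_Other", "W.Gaze_Target")] = 1
        assert (U == expected).all()

    def test_half_coded_segment_contributes_nothing(self):
        seg = pd.DataFrame({"i_cat": [0, UNCODED], "w_cat": [UNCODED, 2]})
        assert ena_core.accumulate(seg).sum() == 0

    def test_equals_brute_force_on_ten_thousand_segments(self):
        rng = np.random.default_rng(5)
        seg = _random_segments(10_000, rng)
        U = ena_core.accumulate(seg)
        # independent oracle: double loop over segments and pairs
        oracle = np.zeros(16, dtype=int)
        for i, w in zip(seg["i_cat"], seg["w_cat"]):
            for a in range(4):
                for b in range(4):
                    if i == a and w == b:
                        oracle[a * 4 + b] += 1
        assert (U == oracle).all()

    def test_accumulate_units_matches_per_unit_accumulate(self, small_segments):
        units = ena_core.accumulate_units(small_segments)
        for key, group in small_segments.groupby(["dyad_id", "interaction_id", "phase"]):
            U = ena_core.accumulate(group)
            if U.sum() == 0:
                assert key not in units.index
            else:
                assert (units.loc[key].to_numpy() == U).all()


class TestNormalize:
    def test_arithmetic_example(self):
        U = np.zeros(16)
        U[0], U[1] = 2, 1
        nU = ena_core.normalize(U)
        assert nU[0] == pytest.approx(0.8944, abs=1e-4)
        assert nU[1] == pytest.approx(0.4472, abs=1e-4)

    @settings(derandomize=True, max_examples=30)
    @given(
        st.lists(st.integers(0, 1000), min_size=4, max_size=16).filter(lambda v: any(v)),
        st.floats(0.01, 100.0),
    )
    def test_unit_norm_and_scale_invariance(self, counts, c):
        U = np.asarray(counts, dtype=float)
        nU = ena_core.normalize(U)
        assert np.linalg.norm(nU) == pytest.approx(1.0, abs=1e-9)
        assert np.allclose(ena_core.normalize(c * U), nU, atol=1e-9)

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError, match="empty unit"):
            ena_core.normalize(np.zeros(16))


def _unit_frame(X, n_i=4, n_w=4):
    cs = CodeSet.eight_codes() if (n_i, n_w) == (4, 4) else CodeSet(
        tuple(f"I{c}" for c in range(n_i)), tuple(f"W{c}" for c in range(n_w))
    )
    return pd.DataFrame(X, columns=cs.pair_labels()), cs


class TestBuildSpace:
    def test_collinear_units_put_nearly_all_variance_on_dim1(self):
        # counts on a line in pair space; the sphere normalisation bends the
        # line slightly, so dimension 1 carries almost (not exactly) all
        # variance and dominates dimension 2 by orders of magnitude
        rng = np.random.default_rng(0)
        base = rng.random(16)
        direction = rng.random(16)
        X = np.array([base + t * direction for t in np.linspace(1, 4, 8)])
        units, _ = _unit_frame(X)
        space = ena_core.build_space(units)
        assert space.variance_explained[0] > 0.99
        assert space.variance_explained[0] > 100 * space.variance_explained[1]

    def test_projection_reconstructs_centered_units_at_kept_rank(self):
        rng = np.random.default_rng(1)
        units, _ = _unit_frame(rng.random((12, 16)))
        d = 5
        space = ena_core.build_space(units, d=d)
        nU = ena_core.normalize(units.to_numpy(float))
        Xc = nU - space.mean
        recon = space.projections @ space.loadings.T
        # reconstruction error equals the optimal rank-d truncation error
        err = np.linalg.norm(Xc - recon)
        s = np.linalg.svd(Xc, compute_uv=False)
        assert err == pytest.approx(np.sqrt((s[d:] ** 2).sum()), rel=1e-9)

    def test_unit_order_invariance(self):
        rng = np.random.default_rng(2)
        units, _ = _unit_frame(rng.random((10, 16)))
        perm = rng.permutation(10)
        s1 = ena_core.build_space(units)
        s2 = ena_core.build_space(units.iloc[perm])
        assert np.allclose(s1.mean, s2.mean)
        assert np.allclose(s1.loadings, s2.loadings)
        assert np.allclose(s1.projections[perm], s2.projections)

    def test_deterministic_sign_convention(self):
        # repeated fits agree to round-off (the SVD itself is deterministic
        # up to memory-layout-dependent 1-ulp noise) and every kept loading
        # has its largest-magnitude entry positive
        rng = np.random.default_rng(3)
        units, _ = _unit_frame(rng.random((10, 16)))
        s1 = ena_core.build_space(units)
        s2 = ena_core.build_space(units.copy())
        assert np.allclose(s1.loadings, s2.loadings, atol=1e-12)
        for j in range(s1.d):
            k = np.argmax(np.abs(s1.loadings[:, j]))
            assert s1.loadings[k, j] > 0

    def test_training_projections_are_zero_mean_and_idempotent(self):
        rng = np.random.default_rng(4)
        units, _ = _unit_frame(rng.integers(0, 20, (9, 16)).astype(float) + 0.1)
        space = ena_core.build_space(units)
        assert np.allclose(space.projections.mean(axis=0), 0, atol=1e-12)
        reproj = ena_core.project(space, units.to_numpy(float))
        assert np.allclose(reproj, space.projections, atol=1e-12)

    def test_degenerate_inputs_rejected(self):
        units, _ = _unit_frame(np.tile(np.arange(16.0) + 1, (5, 1)))
        with pytest.raises(ValueError, match="degenerate"):
            ena_core.build_space(units)
        with pytest.raises(ValueError, match="at least 2"):
            ena_core.build_space(units.iloc[:1])


class TestPositionNodes:
    def test_disjoint_pairs_solved_analytically(self):
        # 2 codes per participant, two units each with one active pair:
        # unit 1 -> (I0, W0), unit 2 -> (I1, W1).  The least-squares layout
        # puts each pair's two nodes at their unit's projection (min-norm).
        X = np.zeros((2, 4))
        X[0, 0] = 1.0  # pair (I0, W0)
        X[1, 3] = 1.0  # pair (I1, W1)
        units, cs = _unit_frame(X, n_i=2, n_w=2)
        space = ena_core.build_space(units, d=2, code_set=cs)
        pos, residual, unconstrained = ena_core.position_nodes(space, units)
        P = space.projections
        assert residual == pytest.approx(0.0, abs=1e-18)
        assert np.allclose(pos[0], P[0], atol=1e-9) and np.allclose(pos[2], P[0], atol=1e-9)
        assert np.allclose(pos[1], P[1], atol=1e-9) and np.allclose(pos[3], P[1], atol=1e-9)
        assert unconstrained == []

    def test_beats_1000_random_layouts(self, small_segments):
        units = ena_core.accumulate_units(small_segments)
        space = ena_core.build_space(units)
        _, residual, _ = ena_core.position_nodes(space, units)
        nU = ena_core.normalize(units.to_numpy(float))
        A = ena_core._centroid_design(nU, space.code_set)
        rng = np.random.default_rng(7)
        for _ in range(1000):
            X = rng.uniform(-1, 1, (8, 2))
            obj = np.sum((space.projections - A @ X) ** 2)
            assert residual <= obj + 1e-12

    def test_translation_equivariance(self):
        rng = np.random.default_rng(8)
        units, _ = _unit_frame(rng.integers(1, 30, (40, 16)).astype(float))
        space = ena_core.build_space(units)
        pos, _, _ = ena_core.position_nodes(space, units)
        shift = np.array([0.3, -0.7])
        space2 = ena_core.build_space(units)
        space2.projections = space2.projections + shift
        pos2, _, _ = ena_core.position_nodes(space2, units)
        assert np.allclose(pos2, pos + shift, atol=1e-8)

    def test_never_cooccurring_code_flagged_at_origin(self):
        rng = np.random.default_rng(9)
        X = rng.integers(1, 20, (10, 16)).astype(float)
        cs = CodeSet.eight_codes()
        for w in range(4):  # W.Gaze_Person never co-occurs
            X[:, cs.pair_index(cs.instructor_codes[w], "W.Gaze_Person")] = 0.0
        units, _ = _unit_frame(X)
        space = ena_core.build_space(units)
        pos, _, unconstrained = ena_core.position_nodes(space, units)
        assert unconstrained == ["W.Gaze_Person"]
        k = cs.labels.index("W.Gaze_Person")
        assert np.allclose(pos[k], 0.0, atol=1e-9)


class TestGroupSummaries:
    def test_identical_units_mean_equals_member_with_zero_ci(self):
        X = np.tile(np.arange(16.0) + 1, (4, 1))
        units, _ = _unit_frame(X)
        proj = np.zeros((4, 2))
        summ = ena_core.mean_network(units, proj)
        assert np.allclose(summ.mean_network, ena_core.normalize(X[0]))
        assert np.allclose(summ.ci_half_width, 0.0)

    def test_two_unit_centroid_is_midpoint(self):
        rng = np.random.default_rng(10)
        units, _ = _unit_frame(rng.random((2, 16)) + 0.1)
        proj = np.array([[1.0, 2.0], [3.0, -4.0]])
        summ = ena_core.mean_network(units, proj)
        assert np.allclose(summ.centroid, [2.0, -1.0])
        assert np.all(np.isfinite(summ.ci_half_width))

    def test_single_unit_ci_undefined(self):
        units, _ = _unit_frame(np.arange(16.0)[None, :] + 1)
        summ = ena_core.mean_network(units, np.zeros((1, 2)))
        assert np.isnan(summ.ci_half_width).all()

    def test_mean_network_linearity_over_partition(self):
        rng = np.random.default_rng(11)
        units, _ = _unit_frame(rng.integers(1, 50, (12, 16)).astype(float))
        proj = rng.random((12, 2))
        whole = ena_core.mean_network(units, proj).mean_network
        part_a = ena_core.mean_network(units.iloc[:5], proj[:5]).mean_network
        part_b = ena_core.mean_network(units.iloc[5:], proj[5:]).mean_network
        recombined = (5 * part_a + 7 * part_b) / 12
        assert np.allclose(recombined, whole, atol=1e-12)


class TestCompareGroups:
    def test_identical_groups(self):
        proj = np.tile([[1.0, 2.0]], (5, 1))
        cmp = ena_core.compare_groups(proj, proj.copy())
        assert (cmp.t, cmp.p, cmp.cohens_d) == (0.0, 1.0, 0.0)

    def test_one_pooled_sd_offset_gives_d_of_one(self):
        rng = np.random.default_rng(12)
        a = rng.normal(0, 1, (26, 2))
        pooled_sd = np.sqrt(
            ((a[:, 1].std(ddof=1) ** 2) * 25 + (a[:, 1].std(ddof=1) ** 2) * 25) / 50
        )
        b = a + np.array([0.0, pooled_sd])
        cmp = ena_core.compare_groups(b, a, dimension=1)
        assert cmp.cohens_d == pytest.approx(1.0, abs=1e-9)

    def test_matches_scipy_and_welch_flag(self):
        rng = np.random.default_rng(13)
        a = rng.normal(0, 1, (20, 2))
        b = rng.normal(0.5, 2, (15, 2))
        cmp = ena_core.compare_groups(a, b, dimension=0, welch=True)
        ref = sps.ttest_ind(a[:, 0], b[:, 0], equal_var=False)
        assert cmp.t == pytest.approx(ref.statistic)
        assert cmp.p == pytest.approx(ref.pvalue)

    def test_small_groups_rejected(self):
        with pytest.raises(ValueError):
            ena_core.compare_groups(np.zeros((1, 2)), np.zeros((5, 2)))


class TestExport:
    def test_space_json_and_graphml(self, tmp_path, small_segments):
        import json
        import networkx as nx

        units = ena_core.accumulate_units(small_segments)
        space = ena_core.build_space(units)
        ena_core.position_nodes(space, units)
        payload = json.loads(ena_core.space_to_json(space, tmp_path / "space.json"))
        assert len(payload["loadings"]) == 16
        summ = ena_core.mean_network(units, space.projections)
        ena_core.network_to_graphml(summ.mean_network, tmp_path / "net.graphml",
                                    positions=space.node_positions)
        g = nx.read_graphml(tmp_path / "net.graphml")
        assert set(g.nodes) == set(space.code_set.labels)
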