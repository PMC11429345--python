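import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from hsb import (
    build_cohort,
    complete_linkage,
    cut_clusters,
    flag_all,
    grouping_agreement,
    phi,
    phi_matrix,
)
from _oracles import oracle_ari, oracle_complete_linkage, oracle_phi


class TestPhi:
    def test_identical_vectors_give_one(self):
        x = [0, 1, 1, 0, 1]
        val, _ = phi(x, x)
        assert val == pytest.approx(1.0)

    def test_hand_counted_contingency_table(self):
        x = [1] * 50 + [0] * 50
        y = [1] * 40 + [0] * 10 + [1] * 10 + [0] * 40
        val, counts = phi(x, y)
        assert counts == {"n11": 40, "n10": 10, "n01": 10, "n00": 40}
        assert val == pytest.approx((1600 - 100) / 2500)

    def test_constant_vector_is_undefined_not_an_error(self):
        val, counts = phi([1, 1, 1], [0, 1, 0])
        assert val is None
        assert counts["n10"] + counts["n11"] == 3

    @settings(derandomize=True, max_examples=200, deadline=None)
    @given(st.integers(0, 2**31 - 1), st.sampled_from([0.05, 0.3, 0.5, 0.9]))
    def test_phi_equals_pearson_on_binary_data(self, seed, p):
        rng = np.random.default_rng(seed)
        x = (rng.random(60) < p).astype(int)
        y = (rng.random(60) < 0.4).astype(int)
        val, _ = phi(x, y)
        if x.std() == 0 or y.std() == 0:
            assert val is None
        else:
            assert val == pytest.approx(np.corrcoef(x, y)[0, 1], abs=1e-12)
            assert val == pytest.approx(oracle_phi(x, y), abs=1e-12)


class TestPhiMatrix:
    def test_symmetric_with_unit_diagonal(self, small_sim, small_cohort, catalogue, codelists):
        mf = flag_all(small_cohort, small_sim.events, catalogue, codelists)
        pm = phi_matrix(mf)
        m = pm.matrix.to_numpy()
        assert np.array_equal(m, m.T)
        assert np.allclose(np.diag(m), 1.0)
        assert (np.abs(m) <= 1.0 + 1e-12).all()

    def test_matrix_entries_match_scalar_phi(self, small_sim, small_cohort, catalogue, codelists):
        mf = flag_all(small_cohort, small_sim.events, catalogue, codelists)
        pm = phi_matrix(mf)
        a, b = "gp_visits", "blood_pressure"
        val, counts = phi(mf.flags[a], mf.flags[b])
        assert pm.matrix.loc[a, b] == pytest.approx(val, abs=1e-12)
        assert pm.counts[(a, b)] == counts

    def test_opposite_sex_marker_dropped_on_sex_subset(self, catalogue, codelists):
        from conftest import strict_config
        from hsb.simulate import simulate

        res = simulate(strict_config(600, seed=11))
        cohort = build_cohort(res.patients)
        mf = flag_all(cohort, res.events, catalogue, codelists)
        males = mf.flags.index.isin(
            cohort.patients.loc[cohort.patients["sex"] == "male", "patient_id"])
        pm = phi_matrix(mf, males)
        # female-programme markers have zero variance among men at leak 0
        assert "breast_screen" in pm.dropped
        assert "cervical_screen" in pm.dropped
        assert "breast_screen" not in pm.markers


def _dist(d):
    labels = [chr(97 + i) for i in range(len(d))]
    return pd.DataFrame(np.asarray(d, float), index=labels, columns=labels)


class TestCompleteLinkage:
    def test_two_markers_single_merge(self):
        dend = complete_linkage(_dist([[0, 0.4], [0.4, 0]]))
        assert dend.merges == [(0, 1, 0.4, 2)]

    def test_three_marker_hand_agglomeration(self):
        d = [[0, 0.1, 0.9], [0.1, 0, 0.9], [0.9, 0.9, 0]]
        dend = complete_linkage(_dist(d))
        assert dend.merges == [(0, 1, 0.1, 3), (2, 3, 0.9, 4)]
        assert cut_clusters(dend, 2) == {"a": 0, "b": 0, "c": 1}

    def test_all_equal_distances_use_lowest_index_pair(self):
        d = np.full((4, 4), 0.5)
        np.fill_diagonal(d, 0.0)
        dend = complete_linkage(_dist(d))
        assert dend.merges[0][:2] == (0, 1)
        assert dend.merges[1][:2] == (2, 3)
        assert dend.merges[2][:2] == (4, 5)

    def test_heights_non_decreasing_on_random_instances(self):
        rng = np.random.default_rng(0)
        for _ in range(30):
            n = rng.integers(2, 9)
            d = rng.random((n, n))
            d = (d + d.T) / 2
            np.fill_diagonal(d, 0.0)
            h = complete_linkage(_dist(d)).heights()
            assert all(a <= b + 1e-12 for a, b in zip(h, h[1:]))

    def test_matches_from_scratch_agglomeration(self):
        rng = np.random.default_rng(1)
        for _ in range(25):
            n = int(rng.integers(2, 9))
            d = np.round(rng.random((n, n)), 1)  # rounding forces ties
            d = (d + d.T) / 2
            np.fill_diagonal(d, 0.0)
            got = complete_linkage(_dist(d)).merges
            assert got == [(a, b, pytest.approx(h), i)
                           for a, b, h, i in oracle_complete_linkage(d)]

    def test_matches_scipy_on_tie_free_instances(self):
        from scipy.cluster.hierarchy import fcluster, linkage
        from scipy.spatial.distance import squareform

        rng = np.random.default_rng(2)
        for _ in range(10):
            n = int(rng.integers(3, 9))
            d = rng.random((n, n)) + 0.01
            d = (d + d.T) / 2
            np.fill_diagonal(d, 0.0)
            dend = complete_linkage(_dist(d))
            z = linkage(squareform(d), method="complete")
            assert dend.heights() == pytest.approx(list(z[:, 2]))
            for k in range(1, n + 1):
                ours = cut_clusters(dend, k)
                theirs = fcluster(z, k, criterion="maxclust")
                labels = [chr(97 + i) for i in range(n)]
                assert oracle_ari([ours[m] for m in labels], list(theirs)) == pytest.approx(1.0)

    def test_invariant_to_input_order(self):
        rng = np.random.default_rng(3)
        n = 7
        d = rng.random((n, n)) + 0.01
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0.0)
        base = _dist(d)
        part_a = cut_clusters(complete_linkage(base), 3)
        perm = rng.permutation(n)
        shuffled = base.iloc[perm, perm]
        part_b = cut_clusters(complete_linkage(shuffled), 3)
        labels = list(base.columns)
        assert oracle_ari([part_a[m] for m in labels],
                          [part_b[m] for m in labels]) == pytest.approx(1.0)

    def test_leaf_order_is_a_permutation_of_labels(self):
        rng = np.random.default_rng(4)
        d = rng.random((6, 6))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0.0)
        dend = complete_linkage(_dist(d))
        assert sorted(dend.leaf_order) == sorted(dend.labels)
        assert dend.leaf_order[0] in dend.labels


class TestCutClusters:
    def test_k_one_and_k_n(self):
        d = np.full((5, 5), 0.5)
        np.fill_diagonal(d, 0.0)
        dend = complete_linkage(_dist(d))
        assert set(cut_clusters(dend, 1).values()) == {0}
        assert len(set(cut_clusters(dend, 5).values())) == 5

    def test_k_out_of_range(self):
        dend = complete_linkage(_dist([[0, 0.4], [0.4, 0]]))
        with pytest.raises(ValueError):
            cut_clusters(dend, 0)
        with pytest.raises(ValueError):
            cut_clusters(dend, 3)


class TestGroupingAgreement:
    def test_identical_partitions(self):
        p = {"a": 0, "b": 0, "c": 1}
        assert grouping_agreement(p, {"a": "x", "b": "x", "c": "y"}) == pytest.approx(1.0)

    def test_singletons_vs_one_cluster(self):
        p = {"a": 0, "b": 1, "c": 2}
        g = {"a": "x", "b": "x", "c": "x"}
        assert grouping_agreement(p, g) == pytest.approx(0.0)

    def test_crossed_pairs_match_contingency_formula(self):
        p = {"a": 0, "b": 0, "c": 1, "d": 1}
        g = {"a": "x", "b": "y", "c": "x", "d": "y"}
        keys = sorted(p)
        expected = oracle_ari([p[k] for k in keys], [g[k] for k in keys])
        assert grouping_agreement(p, g) == pytest.approx(expected)

    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(st.lists(st.integers(0, 3), min_size=2, max_size=12),
           st.integers(0, 2**31 - 1))
    def test_matches_brute_force_formula(self, labels_a, seed):
        rng = np.random.default_rng(seed)
        labels_b = rng.integers(0, 4, len(labels_a)).tolist()
        keys = [f"m{i}" for i in range(len(labels_a))]
        p = dict(zip(keys, labels_a))
        g = dict(zip(keys, [str(x) for x in labels_b]))
        assert grouping_agreement(p, g) == pytest.approx(
            oracle_ari(labels_a, labels_b), abs=1e-9)

    def test_disjoint_marker_sets_rejected(self):
        with pytest.raises(ValueError):
            grouping_agreement({"a": 0}, {"b": "x"})
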