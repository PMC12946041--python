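import numpy as np
import pytest

from spnlab.cluster_perm import (
    ClusterGeometry,
    TMap,
    exhaustive_null,
    form_clusters,
    permutation_test,
    permutation_test_trial_level,
    pointwise_paired_t,
)
from spnlab.epoching import SubjectERP, average_conditions
from spnlab.montage import ElectrodeMontage, build_neighbor_graph
from tests.conftest import make_epochs


def chain_graph(labels=("A", "B", "C"), spacing=30.0):
    coords = np.zeros((len(labels), 3))
    coords[:, 0] = np.arange(len(labels)) * spacing
    return build_neighbor_graph(ElectrodeMontage(tuple(labels), coords), 35.0)


def make_erps(diffs: np.ndarray, channels=None) -> SubjectERP:
    """SubjectERP whose S - A difference equals ``diffs`` (P, C, S)."""
    P, C, S = diffs.shape
    erp = np.zeros((P, 2, C, S))
    erp[:, 0] = diffs
    return SubjectERP(
        erp=erp,
        counts=np.ones((P, 2), dtype=int),
        condition_order=("S", "A"),
        participants=tuple(range(P)),
        channels=channels or tuple("ABCDEFGH"[:C]),
        times_ms=np.arange(S) * 1000.0 / 256.0,
        fs_hz=256.0,
    )


class TestPointwiseT:
    def test_identical_conditions_give_zero(self):
        diffs = np.zeros((4, 2, 8))
        with pytest.warns(UserWarning, match="zero variance"):
            tmap = pointwise_paired_t(make_erps(diffs))
        np.testing.assert_array_equal(tmap.t, 0.0)
        assert tmap.df == 3

    def test_hand_computed_value(self):
        # differences {1, 2, 3}: t = 2 / (1 / sqrt(3)) = 3.464
        diffs = np.zeros((3, 1, 2))
        diffs[:, 0, 0] = [1.0, 2.0, 3.0]
        diffs[:, 0, 1] = [1.0, 2.0, 4.0]  # avoid an all-zero-variance column
        tmap = pointwise_paired_t(make_erps(diffs))
        assert tmap.t[0, 0] == pytest.approx(2 * np.sqrt(3), abs=1e-9)

    def test_antisymmetry(self):
        rng = np.random.default_rng(0)
        diffs = rng.standard_normal((5, 3, 10))
        t_pos = pointwise_paired_t(make_erps(diffs)).t
        t_neg = pointwise_paired_t(make_erps(-diffs)).t
        np.testing.assert_allclose(t_neg, -t_pos, atol=1e-12)


class TestFormClusters:
    def tmap_from(self, values):
        values = np.asarray(values, dtype=float)
        return TMap(
            t=values, df=10, channels=("A", "B", "C"),
            times_ms=np.arange(values.shape[1]) * 4.0,
        )

    def test_all_zero_map_has_no_clusters(self):
        assert form_clusters(self.tmap_from(np.zeros((3, 4))), chain_graph()) == []

    def test_spatiotemporal_connectivity(self):
        # suprathreshold at A@t1, B@t1 (spatial) and B@t2 (temporal)
        t = np.zeros((3, 4))
        t[0, 1] = t[1, 1] = t[1, 2] = 3.0
        (cluster,) = form_clusters(self.tmap_from(t), chain_graph())
        assert cluster.size == 3
        assert cluster.mass == pytest.approx(9.0)
        assert cluster.electrodes == ("A", "B")
        assert cluster.max_spatial_extent == (4.0, 2)

    def test_non_adjacent_channels_stay_separate(self):
        t = np.zeros((3, 4))
        t[0, 1] = t[2, 1] = 3.0  # A and C are not neighbors
        clusters = form_clusters(self.tmap_from(t), chain_graph())
        assert len(clusters) == 2
        assert all(c.size == 1 for c in clusters)

    def test_opposite_signs_never_merge(self):
        t = np.zeros((3, 4))
        t[0, 1], t[1, 1] = 3.0, -3.0
        clusters = form_clusters(self.tmap_from(t), chain_graph())
        assert len(clusters) == 2
        assert {c.sign for c in clusters} == {1, -1}

    def test_diagonal_connectivity_excluded(self):
        # neighbor channel AND adjacent sample is not a connection
        t = np.zeros((3, 4))
        t[0, 1] = t[1, 2] = 3.0
        clusters = form_clusters(self.tmap_from(t), chain_graph())
        assert len(clusters) == 2

    def test_mass_exceeds_threshold_times_size(self):
        rng = np.random.default_rng(2)
        diffs = rng.standard_normal((8, 3, 16)) + 0.6
        erps = make_erps(diffs, channels=("A", "B", "C"))
        tmap = pointwise_paired_t(erps)
        thr = tmap.critical_value(0.05)
        for c in form_clusters(tmap, chain_graph()):
            assert abs(c.mass) >= thr * c.size


class TestPermutationTest:
    def test_identity_permutation_reproduces_observed_mass(self):
        rng = np.random.default_rng(4)
        diffs = rng.standard_normal((8, 3, 16)) - 0.5
        erps = make_erps(diffs, channels=("A", "B", "C"))
        graph = chain_graph()
        tmap = pointwise_paired_t(erps)
        clusters = form_clusters(tmap, graph)
        geometry = ClusterGeometry(tmap.channels, 16, graph)
        observed_max = geometry.max_abs_mass(
            tmap.t.ravel(), tmap.critical_value(0.05)
        )
        assert observed_max == pytest.approx(max(abs(c.mass) for c in clusters))

    def test_negation_swaps_signs_and_preserves_p(self):
        rng = np.random.default_rng(5)
        diffs = rng.standard_normal((8, 3, 16)) - 0.4
        graph = chain_graph()
        a = permutation_test(make_erps(diffs, ("A", "B", "C")), graph,
                             n_perm=200, seed=9)
        b = permutation_test(make_erps(-diffs, ("A", "B", "C")), graph,
                             n_perm=200, seed=9)
        assert len(a) == len(b)
        for ca, cb in zip(a, b):
            assert ca.sign == -cb.sign
            assert ca.mass == pytest.approx(-cb.mass)
            assert ca.p_corrected == cb.p_corrected

    def test_channel_reordering_invariance(self):
        rng = np.random.default_rng(6)
        diffs = rng.standard_normal((6, 3, 10)) + 0.5
        graph = chain_graph()
        order = [2, 0, 1]
        a = form_clusters(pointwise_paired_t(make_erps(diffs, ("A", "B", "C"))), graph)
        b = form_clusters(
            pointwise_paired_t(
                make_erps(diffs[:, order], tuple(np.array(["A", "B", "C"])[order]))
            ),
            graph,
        )
        members_a = {
            frozenset((c.electrodes[0] if len(c.electrodes) == 1 else e, s)
                      for e, s in zip([ "ABC"[i] for i in c.chan_idx], c.samp_idx))
            for c in a
        }
        members_b = {
            frozenset((np.array(["C", "A", "B"])[i], s)
                      for i, s in zip(c.chan_idx, c.samp_idx))
            for c in b
        }
        assert members_a == members_b

    def test_trial_level_variant_runs_and_agrees_qualitatively(self, graph16, montage16, small_dataset):
        behavior, epochs = small_dataset
        clusters = permutation_test_trial_level(
            epochs, graph16, n_perm=50, seed=0
        )
        assert all(0 < c.p_corrected <= 1 for c in clusters)


class TestExhaustiveOracle:
    def toy_instance(self, n=8, seed=11):
        rng = np.random.default_rng(seed)
        diffs = rng.standard_normal((n, 3, 12)) * 0.8
        diffs[:, :2, 4:8] -= 1.0  # moderate localized effect
        return make_erps(diffs, ("A", "B", "C")), chain_graph()

    def test_discrete_support_at_n3(self):
        rng = np.random.default_rng(1)
        erps = make_erps(rng.standard_normal((3, 3, 8)) + 1.0, ("A", "B", "C"))
        clusters = exhaustive_null(erps, chain_graph())
        assert clusters
        for c in clusters:
            assert (c.p_corrected * 8) == pytest.approx(round(c.p_corrected * 8))

    def test_monte_carlo_matches_exact(self):
        erps, graph = self.toy_instance()
        exact = exhaustive_null(erps, graph)
        mc = permutation_test(erps, graph, n_perm=5000, seed=2)
        assert len(exact) == len(mc)
        for ce, cm in zip(exact, mc):
            assert cm.p_corrected == pytest.approx(ce.p_corrected, abs=0.02)

    def test_monte_carlo_converges_with_permutations(self):
        erps, graph = self.toy_instance(seed=13)
        exact = {round(c.mass, 9): c.p_corrected for c in exhaustive_null(erps, graph)}
        err = {}
        for B in (500, 5000):
            clusters = permutation_test(erps, graph, n_perm=B, seed=3)
            err[B] = max(
                abs(c.p_corrected - exact[round(c.mass, 9)]) for c in clusters
            )
        assert err[5000] <= 0.02
        assert err[500] <= 0.06

    def test_zero_difference_subject_halves_collapse(self):
        rng = np.random.default_rng(21)
        diffs = rng.standard_normal((6, 3, 10)) + 0.8
        diffs[3] = 0.0  # this subject's sign cannot matter
        clusters = exhaustive_null(make_erps(diffs, ("A", "B", "C")), chain_graph())
        for c in clusters:
            count = c.p_corrected * 2**6
            assert count == pytest.approx(round(count))
            assert round(count) % 2 == 0

    def test_refuses_large_cohorts(self):
        diffs = np.random.default_rng(0).standard_normal((17, 3, 4))
        with pytest.raises(ValueError, match="16"):
            exhaustive_null(make_erps(diffs, ("A", "B", "C")), chain_graph())
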