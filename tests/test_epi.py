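"""Cross-sectional EPI measures: D1, D2 and the modularity Q."""

import numpy as np
import networkx as nx
import pytest

from keystone import (
    Cohort,
    TooFewTaxaError,
    UndefinedEPIError,
    build_similarity_network,
    epi_d1,
    epi_d2,
    epi_modularity,
    epi_screen,
    split_by_presence,
)
from keystone.epi import SampleSimilarityNetwork
from tests.conftest import random_cohort


def brute_force_modularity(B, s):
    """Literal double loop over all ordered node pairs (independent oracle)."""
    B = np.asarray(B, dtype=float)
    d = B.sum(axis=1)
    two_w = d.sum()
    Q = 0.0
    n = len(s)
    for a in range(n):
        for b in range(n):
            Q += (B[a, b] - d[a] * d[b] / two_w) * (s[a] * s[b] + 1) / 2.0
    return Q / two_w


class TestSplitByPresence:
    def test_partition(self, toy_cohort):
        split = split_by_presence(toy_cohort, 0)
        assert list(split.present_samples) == [0, 2]
        assert list(split.absent_samples) == [1, 3]

    def test_reduced_profiles_sum_to_one(self, toy_cohort):
        split = split_by_presence(toy_cohort, 0)
        np.testing.assert_allclose(split.reduced_profiles.sum(axis=1), 1.0,
                                   atol=1e-12)

    def test_taxon_present_everywhere_undefined(self):
        abund = np.array([[0.5, 0.5], [0.5, 0.5]])
        cohort = Cohort(abund, ["a", "b"], ["s1", "s2"])
        with pytest.raises(UndefinedEPIError):
            split_by_presence(cohort, 0)


class TestDistanceMeasures:
    def test_hand_computed_toy_values(self, toy_cohort):
        split = split_by_presence(toy_cohort, 0)
        # all four cross pairs are BC([0.5,0.5],[0.25,0.75]) = 0.25
        assert epi_d1(split) == pytest.approx(0.25, abs=1e-12)
        assert epi_d2(split) == pytest.approx(0.25, abs=1e-12)

    def test_identical_samples_give_zero(self):
        abund = np.tile(np.array([[0.2], [0.3], [0.5]]), (1, 4))
        abund[0, 2:] = 0.0
        cohort = Cohort.from_counts(abund, ["a", "b", "c"], list("wxyz"))
        split = split_by_presence(cohort, 0)
        assert epi_d1(split) == pytest.approx(0.0, abs=1e-12)
        assert epi_d2(split) == pytest.approx(0.0, abs=1e-12)

    def test_single_pair_d1_equals_d2(self, rng):
        # taxon 0 present in exactly one of the two samples
        abund = rng.uniform(0.1, 1.0, (10, 2))
        abund[0, 0] = 0.0
        cohort = Cohort.from_counts(abund, [f"t{i}" for i in range(10)],
                                    ["s0", "s1"])
        split = split_by_presence(cohort, 0)
        assert epi_d1(split) == pytest.approx(epi_d2(split), abs=1e-12)

    def test_invariant_to_sample_order(self, rng):
        cohort = random_cohort(rng, 12, 20)
        perm = rng.permutation(20)
        shuffled = Cohort(cohort.abundances[:, perm], cohort.taxon_ids,
                          [cohort.sample_ids[k] for k in perm])
        for taxon in range(3):
            s1 = split_by_presence(cohort, taxon)
            s2 = split_by_presence(shuffled, taxon)
            assert epi_d1(s1) == pytest.approx(epi_d1(s2), abs=1e-12)
            assert epi_d2(s1) == pytest.approx(epi_d2(s2), abs=1e-12)


class TestSimilarityNetwork:
    def test_edge_fraction_near_quantile(self, rng):
        cohort = random_cohort(rng, 15, 30)
        net = build_similarity_network(cohort, 0, p_Q=0.1)
        n_pairs = 30 * 29 // 2
        n_edges = net.adjacency.sum() // 2
        assert abs(n_edges - 0.1 * n_pairs) <= 3  # ties at T admitted

    def test_symmetric_zero_diagonal(self, rng):
        cohort = random_cohort(rng, 10, 12)
        net = build_similarity_network(cohort, 1, p_Q=0.2)
        np.testing.assert_array_equal(net.adjacency, net.adjacency.T)
        assert not np.diag(net.adjacency).any()

    def test_labels_match_presence(self, rng):
        cohort = random_cohort(rng, 10, 12)
        net = build_similarity_network(cohort, 2, p_Q=0.2)
        np.testing.assert_array_equal(net.labels == 1, cohort.presence[2])


class TestModularity:
    def test_uniform_labels_give_zero(self, rng):
        B = (rng.random((12, 12)) < 0.3)
        B = np.triu(B, 1)
        B = (B | B.T).astype(float)
        net = SampleSimilarityNetwork(B, np.ones(12), 0.0, 0.0)
        assert epi_modularity(net) == pytest.approx(0.0, abs=1e-12)

    def test_two_disconnected_cliques_give_half(self):
        B = np.zeros((10, 10))
        B[:5, :5] = 1.0
        B[5:, 5:] = 1.0
        np.fill_diagonal(B, 0.0)
        labels = np.array([1] * 5 + [-1] * 5)
        net = SampleSimilarityNetwork(B, labels, 0.0, 0.0)
        assert epi_modularity(net) == pytest.approx(0.5, abs=1e-12)

    def test_matches_brute_force_and_networkx(self, rng):
        for _ in range(20):
            G = nx.gnp_random_graph(10, 0.4, seed=int(rng.integers(1e6)))
            while G.number_of_edges() == 0:
                G = nx.gnp_random_graph(10, 0.5, seed=int(rng.integers(1e6)))
            B = nx.to_numpy_array(G)
            s = rng.choice([-1, 1], size=10)
            net = SampleSimilarityNetwork(B, s, 0.0, 0.0)
            q = epi_modularity(net)
            assert q == pytest.approx(brute_force_modularity(B, s), abs=1e-12)
            parts = [{n for n in range(10) if s[n] == 1},
                     {n for n in range(10) if s[n] == -1}]
            parts = [p for p in parts if p]
            assert q == pytest.approx(
                nx.algorithms.community.modularity(G, parts), abs=1e-12)

    def test_edgeless_network_is_missing(self):
        net = SampleSimilarityNetwork(np.zeros((4, 4)), np.ones(4), 0.0, 0.0)
        with pytest.warns(UserWarning):
            assert np.isnan(epi_modularity(net))


class TestEPIScreen:
    def test_values_missing_outside_frequency_window(self, rng):
        cohort = random_cohort(rng, 25, 40, sparsity=0.5)
        table = epi_screen(cohort, freq_lo=0.25, freq_hi=0.75)
        outside = ~table.eligible
        for m in ("d1", "d2", "q"):
            assert np.isnan(table.values[m][outside]).all()
            assert np.isfinite(table.values[m][table.eligible]).all()

    def test_too_few_eligible_taxa(self):
        abund = np.tile(np.array([[0.25], [0.25], [0.25], [0.25]]), (1, 4))
        cohort = Cohort(abund, list("ABCD"), list("wxyz"))
        with pytest.raises(TooFewTaxaError):
            epi_screen(cohort)

    def test_null_cohort_flag_rate_is_small_and_unstable(self, rng):
        # i.i.d. profiles with independent presence: flags are rare tail
        # events and never the same taxon in every replicate
        always = None
        rates = []
        for seed in range(4):
            cohort = random_cohort(np.random.default_rng(seed), 40, 40,
                                   sparsity=0.4)
            table = epi_screen(cohort, freq_lo=0.0, freq_hi=1.0)
            any_flag = np.zeros(40, dtype=bool)
            for m in ("d1", "d2", "q"):
                rates.append(table.flags[m][table.eligible].mean())
                any_flag |= table.flags[m]
            always = any_flag if always is None else (always & any_flag)
        assert np.mean(rates) < 0.15
        assert always.sum() == 0

    def test_taxon_order_invariance(self, rng):
        cohort = random_cohort(rng, 12, 15)
        perm = rng.permutation(12)
        shuffled = Cohort(cohort.abundances[perm],
                          [cohort.taxon_ids[i] for i in perm],
                          cohort.sample_ids)
        t1 = epi_screen(cohort, freq_lo=0.0, freq_hi=1.0)
        t2 = epi_screen(shuffled, freq_lo=0.0, freq_hi=1.0)
        for m in ("d1", "d2", "q"):
            np.testing.assert_allclose(t1.values[m][perm], t2.values[m],
                                       atol=1e-12, equal_nan=True)
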