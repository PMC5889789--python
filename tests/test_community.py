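"""Signed modularity, Louvain, consensus clustering, planted recovery."""

import itertools

import networkx as nx
import numpy as np
import pytest

from efsubtype import (
    PlantedPartitionSpec,
    adjusted_rand,
    consensus_cluster,
    generate_planted_network,
    louvain,
    robustness_sweep,
    signed_modularity,
)
from efsubtype.community import CommunityError, Partition, signed_modularity_matrix


def two_clique_network():
    w = np.zeros((4, 4))
    w[0, 1] = w[1, 0] = 1.0
    w[2, 3] = w[3, 2] = 1.0
    return w


def set_partitions(n):
    """All set partitions of range(n) as label vectors (restricted growth)."""

    def rec(labels, i, k):
        if i == n:
            yield tuple(labels)
            return
        for c in range(k + 1):
            labels.append(c)
            yield from rec(labels, i + 1, max(k, c + 1))
            labels.pop()

    yield from rec([], 0, 0)


def exhaustive_best_q(w):
    return max(signed_modularity(w, np.array(p)) for p in set_partitions(len(w)))


class TestSignedModularity:
    def test_single_community_all_positive_is_zero(self, rng):
        w = np.abs(rng.normal(size=(6, 6)))
        w = (w + w.T) / 2
        np.fill_diagonal(w, 0)
        assert signed_modularity(w, np.zeros(6, dtype=int)) == pytest.approx(0.0)

    def test_two_disjoint_edges(self):
        # direct evaluation of the formula: Q+ = 2 * (2*(1 - 1/4)/4 - 2*(1/4)/4)
        assert signed_modularity(two_clique_network(), [0, 0, 1, 1]) == pytest.approx(
            0.5
        )

    def test_negative_edge_raises_quality_of_separation(self):
        w = two_clique_network()
        w[0, 2] = w[2, 0] = -1.0
        # Q+ = 0.5, Q- = -0.5, negative weight v-/(v+ + v-) = 1/3
        assert signed_modularity(w, [0, 0, 1, 1]) == pytest.approx(0.5 + 1.0 / 6.0)

    def test_reduces_to_newman_modularity_on_positive_networks(self, rng):
        # independent classic implementation as oracle
        for _ in range(5):
            g = nx.gnp_random_graph(12, 0.4, seed=int(rng.integers(1 << 30)))
            if g.number_of_edges() == 0:
                continue
            w = nx.to_numpy_array(g)
            labels = rng.integers(0, 3, size=12)
            communities = [
                set(np.nonzero(labels == c)[0]) for c in range(3)
            ]
            communities = [c for c in communities if c]
            expected = nx.algorithms.community.modularity(
                g, communities
            )
            assert signed_modularity(w, labels) == pytest.approx(expected, abs=1e-12)

    def test_empty_network_rejected(self):
        with pytest.raises(CommunityError, match="no edges"):
            signed_modularity(np.zeros((3, 3)), [0, 1, 2])

    def test_label_length_mismatch(self):
        with pytest.raises(CommunityError):
            signed_modularity(two_clique_network(), [0, 1])

    def test_matrix_total_is_quality_of_one_community(self, rng):
        w = rng.normal(size=(7, 7))
        w = (w + w.T) / 2
        np.fill_diagonal(w, 0)
        m = signed_modularity_matrix(w)
        assert m.sum() == pytest.approx(
            signed_modularity(w, np.zeros(7, dtype=int)), abs=1e-12
        )


class TestLouvain:
    def test_separates_two_cliques(self):
        part = louvain(two_clique_network(), seed=0)
        assert adjusted_rand(part.labels, [0, 0, 1, 1]) == 1.0
        assert part.q_value == pytest.approx(
            signed_modularity(two_clique_network(), part.labels)
        )

    def test_complete_uniform_graph_gains_nothing(self):
        w = np.ones((6, 6)) - np.eye(6)
        part = louvain(w, seed=3)
        assert part.q_value == pytest.approx(0.0, abs=1e-9)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_never_beats_exhaustive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        w = rng.normal(size=(7, 7)) * (rng.random((7, 7)) < 0.5)
        w = (w + w.T) / 2
        np.fill_diagonal(w, 0)
        if np.abs(w).sum() == 0:
            pytest.skip("empty draw")
        best = exhaustive_best_q(w)
        part = louvain(w, seed=seed)
        assert part.q_value <= best + 1e-10

    def test_exact_on_separable_planted_instances(self):
        net, truth = generate_planted_network(
            PlantedPartitionSpec(
                n_nodes=8, n_communities=2, p_within=1, p_between=0, seed=1
            )
        )
        part = louvain(net, seed=5)
        assert part.q_value == pytest.approx(exhaustive_best_q(net.weights), abs=1e-10)
        assert adjusted_rand(part.labels, truth) == 1.0

    def test_labels_contiguous_and_quality_self_consistent(self, rng):
        w = rng.normal(size=(20, 20))
        w = (w + w.T) / 2
        np.fill_diagonal(w, 0)
        part = louvain(w, seed=11)
        assert np.array_equal(
            np.unique(part.labels), np.arange(part.n_communities)
        )
        assert part.q_value == pytest.approx(
            signed_modularity(w, part.labels), abs=1e-12
        )


class TestConsensus:
    def test_separable_network_converges_in_one_round(self):
        net, truth = generate_planted_network(
            PlantedPartitionSpec(
                n_nodes=30, n_communities=3, p_within=1, p_between=0, seed=2
            )
        )
        result = consensus_cluster(net, runs=20, seed=0)
        assert result.n_rounds == 1
        assert adjusted_rand(result.partition.labels, truth) == 1.0

    def test_planted_recovery_with_noise(self):
        net, truth = generate_planted_network(
            PlantedPartitionSpec(
                n_nodes=120,
                n_communities=3,
                p_within=0.9,
                p_between=0.1,
                noise_sd=0.0,
                seed=7,
            )
        )
        result = consensus_cluster(net, runs=50, seed=1)
        assert adjusted_rand(result.partition.labels, truth) == 1.0
        assert result.partition.n_communities == 3

    def test_node_order_invariance(self, rng):
        net, truth = generate_planted_network(
            PlantedPartitionSpec(
                n_nodes=40, n_communities=2, p_within=0.9, p_between=0.1, seed=3
            )
        )
        perm = rng.permutation(40)
        permuted = net.weights[np.ix_(perm, perm)]
        a = consensus_cluster(net, runs=30, seed=4).partition.labels
        b = consensus_cluster(permuted, runs=30, seed=9).partition.labels
        assert adjusted_rand(a[perm], b) == 1.0

    def test_agreement_matrix_invariants(self):
        net, _ = generate_planted_network(
            PlantedPartitionSpec(n_nodes=20, n_communities=2, p_within=1, p_between=0)
        )
        result = consensus_cluster(net, runs=10, seed=0)
        a = result.agreement
        assert np.allclose(a, a.T)
        assert np.allclose(np.diag(a), 1.0)
        assert a.min() >= 0 and a.max() <= 1

    def test_quality_reported_on_original_network(self):
        net, _ = generate_planted_network(
            PlantedPartitionSpec(
                n_nodes=30, n_communities=3, p_within=0.8, p_between=0.2, seed=5
            )
        )
        result = consensus_cluster(net, runs=30, seed=2)
        assert result.partition.q_value == pytest.approx(
            signed_modularity(net.weights, result.partition.labels), abs=1e-12
        )


class TestAdjustedRand:
    def test_identical_partitions(self):
        assert adjusted_rand([0, 0, 1, 1], [1, 1, 0, 0]) == 1.0

    def test_singletons_vs_lump(self):
        assert adjusted_rand([0, 1, 2, 3], [0, 0, 0, 0]) == 0.0

    def test_matches_pair_counting_oracle(self, rng):
        def ari_bruteforce(a, b):
            n = len(a)
            pairs = list(itertools.combinations(range(n), 2))
            same_a = np.array([a[i] == a[j] for i, j in pairs])
            same_b = np.array([b[i] == b[j] for i, j in pairs])
            n11 = (same_a & same_b).sum()
            n00 = (~same_a & ~same_b).sum()
            n10 = (same_a & ~same_b).sum()
            n01 = (~same_a & same_b).sum()
            total = len(pairs)
            expected = ((n11 + n10) * (n11 + n01) + (n00 + n10) * (n00 + n01)) / total
            max_index = (n11 + n10 + n11 + n01) / 2 + (n00 + n10 + n00 + n01) / 2
            if max_index == expected:
                return 1.0
            return ((n11 + n00) - expected) / (max_index - expected)

        for _ in range(10):
            a = rng.integers(0, 3, size=12)
            b = rng.integers(0, 3, size=12)
            assert adjusted_rand(a, b) == pytest.approx(ari_bruteforce(a, b), abs=1e-12)

    def test_length_mismatch(self):
        with pytest.raises(CommunityError):
            adjusted_rand([0, 1], [0, 1, 2])


class TestRobustnessSweep:
    def test_sweep_behaviour(self):
        table = robustness_sweep(
            p_within_values=[0.9],
            p_between_values=[0.1],
            noise_values=[0.0, 1.0, 3.0],
            n_nodes=60,
            n_communities=3,
            reps=3,
            runs=20,
            seed=0,
        )
        assert len(table) == 3
        clean = table.loc[table["noise_sd"] == 0.0, "mean_ari"].item()
        assert clean == 1.0
        # recovery degrades with noise, allowing one small inversion
        aris = table.sort_values("noise_sd")["mean_ari"].to_numpy()
        assert all(b <= a + 0.05 for a, b in zip(aris, aris[1:]))

    def test_no_structure_gives_chance_ari(self):
        table = robustness_sweep(
            p_within_values=[0.5],
            p_between_values=[0.5],
            noise_values=[0.0],
            n_nodes=60,
            n_communities=3,
            reps=5,
            runs=20,
            seed=1,
        )
        assert abs(table["mean_ari"].item()) < 0.1


class TestPartitionType:
    def test_gap_labels_rejected(self):
        with pytest.raises(CommunityError):
            Partition(labels=np.array([0, 2, 2]), q_value=0.1)

    def test_sizes(self):
        part = Partition(labels=np.array([0, 0, 1, 2, 2, 2]), q_value=0.0)
        assert part.sizes().tolist() == [2, 1, 3]
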