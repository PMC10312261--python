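import numpy as np
import pytest

from spikenets.datatypes import ConfigError, FunctionalGraph
from spikenets.ensembles import (
    DetectParams,
    cluster_eigenspace,
    consensus_partition,
    detect_ensembles,
    deviation_matrix,
    expected_null_matrix,
    null_spectrum_bounds,
    partition_quality,
    reject_nodes,
    sample_sparse_wcm,
)
from spikenets.partitions import Partition, variation_of_information
from spikenets.synthetic import PlantedGraphConfig, generate_planted_graph


def _graph(weights):
    weights = np.asarray(weights, float)
    return FunctionalGraph(weights, np.arange(weights.shape[0]))


class TestExpectedNullMatrix:
    def test_two_nodes_formula(self):
        # s1 = s2 = w, 2m = 2w: <P>_12 = w*w / (2w) = w/2
        g = _graph([[0, 0.8], [0.8, 0]])
        p = expected_null_matrix(g)
        assert p[0, 1] == pytest.approx(0.8 * 0.8 / 1.6)

    def test_regular_graph_uniform_offdiagonal(self):
        w = np.full((5, 5), 0.3)
        np.fill_diagonal(w, 0.0)
        p = expected_null_matrix(_graph(w))
        off = p[~np.eye(5, dtype=bool)]
        assert np.allclose(off, off[0])

    def test_total_weight_conserved(self, planted_graph):
        graph, _ = planted_graph
        p = expected_null_matrix(graph)
        assert p.sum() == pytest.approx(2 * graph.total_weight, rel=1e-12)

    def test_empty_graph_raises(self):
        with pytest.raises(ConfigError):
            expected_null_matrix(_graph(np.zeros((3, 3))))


class TestDeviationMatrix:
    def test_shape_mismatch_raises(self):
        with pytest.raises(ConfigError):
            deviation_matrix(np.zeros((3, 3)), np.zeros((4, 4)))

    def test_w_equals_p_gives_zero(self):
        p = np.array([[0.1, 0.2], [0.2, 0.3]])
        b = deviation_matrix(p, p)
        assert np.allclose(b, 0)

    def test_trace_identity(self, planted_graph):
        """W has zero diagonal, so trace(B) = -trace(<P>), and the eigenvalue
        sum matches it."""
        graph, _ = planted_graph
        p = expected_null_matrix(graph)
        b = deviation_matrix(graph.weights, p)
        eigsum = np.linalg.eigvalsh(b).sum()
        assert eigsum == pytest.approx(-np.trace(p), rel=1e-9)

    def test_leading_eigenvector_splits_two_blocks(self):
        cfg = PlantedGraphConfig(
            block_sizes=(5, 5), within_weight_mean=1.0, between_weight_mean=0.05,
            edge_density_within=1.0, edge_density_between=0.3, seed=3,
        )
        graph, truth = generate_planted_graph(cfg)
        b = deviation_matrix(graph.weights, expected_null_matrix(graph))
        vals, vecs = np.linalg.eigh(b)
        leading = vecs[:, np.argmax(vals)]
        signs = np.sign(leading)
        assert len(np.unique(signs[truth.labels == 0])) == 1
        assert signs[truth.labels == 0][0] != signs[truth.labels == 1][0]


class TestSampleSparseWcm:
    def test_total_weight_exact(self, planted_graph):
        graph, _ = planted_graph
        for seed in range(5):
            sample = sample_sparse_wcm(graph, seed=seed)
            assert sample.total_weight == pytest.approx(
                graph.total_weight, rel=1e-12
            )
            # conservation is exact in quantum counts
            assert sample.meta["n_quanta"] == pytest.approx(
                round(graph.total_weight * 100)
            )

    def test_strengths_preserved_in_expectation(self, planted_graph):
        graph, _ = planted_graph
        rng = np.random.default_rng(5)
        acc = np.zeros((200, graph.n_nodes))
        for i in range(200):
            acc[i] = sample_sparse_wcm(graph, rng).strengths
        mean_s = acc.mean(0)
        se = acc.std(0, ddof=1) / np.sqrt(len(acc))
        z = (mean_s - graph.strengths) / se
        assert np.mean(np.abs(z) < 3) > 0.95

    def test_quanta_mode_uniform_graph_near_uniform_weights(self):
        """Multinomial quanta on a complete uniform graph: samples stay
        near-complete with near-uniform weights."""
        w = np.full((20, 20), 1.0)
        np.fill_diagonal(w, 0.0)
        g = _graph(w)
        sample = sample_sparse_wcm(g, seed=2, redistribute="quanta")
        iu = np.triu_indices(20, 1)
        vals = sample.weights[iu]
        assert (vals > 0).mean() > 0.9
        assert vals[vals > 0].std() / vals[vals > 0].mean() < 0.35

    def test_unknown_mode_raises(self, planted_graph):
        with pytest.raises(ConfigError):
            sample_sparse_wcm(planted_graph[0], seed=0, redistribute="bootstrap")


class TestNullSpectrumBounds:
    def test_bounds_ordering_and_shapes(self, planted_graph):
        graph, _ = planted_graph
        null = null_spectrum_bounds(graph, n_samples=20, seed=0)
        assert null.upper_bound >= null.lower_bound
        assert null.n_samples == 20
        assert null.eigvals.shape == (20, 60)

    def test_planted_graph_dimensions_detected(self, planted_graph):
        """Three planted blocks put at least two eigenvalues above the null
        upper bound."""
        graph, _ = planted_graph
        null = null_spectrum_bounds(graph, n_samples=50, seed=1)
        b = deviation_matrix(graph.weights, null.expected)
        d = int((np.linalg.eigvalsh(b) > null.upper_bound).sum())
        assert d >= 2


class TestRejectNodes:
    def test_isolated_node_rejected(self):
        cfg = PlantedGraphConfig(
            block_sizes=(8, 8), within_weight_mean=1.0, between_weight_mean=0.1,
            edge_density_within=1.0, edge_density_between=0.5, seed=0,
        )
        graph, _ = generate_planted_graph(cfg)
        w = np.zeros((17, 17))
        w[:16, :16] = graph.weights
        g = FunctionalGraph(w, np.arange(17))
        null = null_spectrum_bounds(g, n_samples=20, seed=3)
        b = deviation_matrix(g.weights, null.expected)
        signal, noise = reject_nodes(b, null, 1)
        assert 16 in noise

    def test_planted_members_all_signal(self, planted_graph):
        graph, _ = planted_graph
        null = null_spectrum_bounds(graph, n_samples=50, seed=4)
        b = deviation_matrix(graph.weights, null.expected)
        d = int((np.linalg.eigvalsh(b) > null.upper_bound).sum())
        signal, noise = reject_nodes(b, null, d)
        assert len(noise) == 0

    def test_weakly_attached_extras_rejected_more_often(self):
        """Five weakly, randomly attached nodes are rejected more often than
        planted block members."""
        rng = np.random.default_rng(6)
        rejected_extra, rejected_member = 0, 0
        for seed in range(5):
            graph, _ = generate_planted_graph(PlantedGraphConfig(
                block_sizes=(12, 12, 12), seed=seed,
            ))
            n0 = graph.n_nodes
            n = n0 + 5
            w = np.zeros((n, n))
            w[:n0, :n0] = graph.weights
            for extra in range(n0, n):
                targets = rng.choice(n0, 3, replace=False)
                for t in targets:
                    w[extra, t] = w[t, extra] = 0.02
            g = FunctionalGraph(w, np.arange(n))
            null = null_spectrum_bounds(g, n_samples=30, seed=seed)
            b = deviation_matrix(g.weights, null.expected)
            d = max(int((np.linalg.eigvalsh(b) > null.upper_bound).sum()), 1)
            _, noise = reject_nodes(b, null, d)
            rejected_extra += np.sum(noise >= n0)
            rejected_member += np.sum(noise < n0)
        assert rejected_extra / 5 > rejected_member / n0


class TestClusterEigenspace:
    def test_two_separated_clouds_always_split(self):
        w = np.zeros((12, 12))
        w[:6, :6] = 1.0
        w[6:, 6:] = 1.0
        np.fill_diagonal(w, 0.0)
        g = _graph(w)
        b = deviation_matrix(w, expected_null_matrix(g))
        parts, _ = cluster_eigenspace(b, d=1, n_repeats=20, seed=0)
        for labels in parts:
            assert len(np.unique(labels)) == 2
            assert len(np.unique(labels[:6])) == 1
            assert len(np.unique(labels[6:])) == 1

    def test_partitions_cover_all_nodes(self, planted_graph):
        graph, _ = planted_graph
        b = deviation_matrix(graph.weights, expected_null_matrix(graph))
        parts, quals = cluster_eigenspace(b, d=2, n_repeats=10, seed=1)
        assert len(parts) == 10 and len(quals) == 10
        for labels in parts:
            assert len(labels) == graph.n_nodes
            assert np.all(labels >= 0)

    def test_planted_quality_beats_label_permutation(self, planted_graph):
        graph, truth = planted_graph
        b = deviation_matrix(graph.weights, expected_null_matrix(graph))
        q_true = partition_quality(b, truth.labels)
        rng = np.random.default_rng(8)
        for _ in range(20):
            assert q_true >= partition_quality(b, rng.permutation(truth.labels))


class TestConsensusPartition:
    def test_identical_inputs_returned_unchanged(self):
        labels = np.array([0, 0, 1, 1, 2, 2, 2])
        out, converged = consensus_partition([labels] * 10, seed=0)
        assert converged
        # same grouping
        a = Partition(np.arange(7), out)
        b = Partition(np.arange(7), labels)
        assert variation_of_information(a, b) == 0.0

    def test_flaky_singleton_blocks_preserved(self):
        """Partitions agreeing on two blocks but shuffling one node's side:
        consensus keeps the two blocks."""
        rng = np.random.default_rng(4)
        base = np.array([0, 0, 0, 0, 0, 1, 1, 1, 1, 1])
        parts = []
        for _ in range(40):
            labels = base.copy()
            labels[4] = rng.integers(0, 2)  # node 4 flips sides
            parts.append(labels)
        out, _ = consensus_partition(parts, seed=1)
        assert len(np.unique(out[:4])) == 1
        assert len(np.unique(out[5:])) == 1
        assert out[0] != out[5]

    def test_order_invariance(self):
        rng = np.random.default_rng(12)
        parts = [rng.integers(0, 3, 15) for _ in range(20)]
        a, _ = consensus_partition(parts, seed=3)
        b, _ = consensus_partition(parts[::-1], seed=3)
        pa = Partition(np.arange(15), a)
        pb = Partition(np.arange(15), b)
        assert variation_of_information(pa, pb) == 0.0

    def test_requires_two_partitions(self):
        with pytest.raises(ConfigError):
            consensus_partition([np.array([0, 1])])


class TestDetectEnsembles:
    def test_planted_three_blocks_recovered(self, planted_graph):
        graph, truth = planted_graph
        result = detect_ensembles(graph, DetectParams(seed=0))
        assert result.d >= 2
        detected = result.consensus
        vi = variation_of_information(detected, truth.restrict(detected.node_ids))
        assert vi == 0.0

    def test_homogeneous_graph_single_community(self):
        graph, _ = generate_planted_graph(PlantedGraphConfig(
            block_sizes=(60,), within_weight_mean=0.3,
            edge_density_within=0.55, seed=9,
        ))
        hits = 0
        for seed in range(3):
            result = detect_ensembles(graph, DetectParams(seed=seed))
            hits += result.n_ensembles == 1
        assert hits >= 2

    def test_recovery_improves_with_block_contrast(self):
        """Stronger within-block weights recover the planted partition in at
        least as many runs (checked at 3 weight levels)."""
        recoveries = []
        for within_mean in (0.05, 0.12, 0.3):
            hits = 0
            for seed in range(4):
                graph, truth = generate_planted_graph(PlantedGraphConfig(
                    block_sizes=(20, 20, 20),
                    within_weight_mean=within_mean,
                    between_weight_mean=0.05,
                    edge_density_within=0.9,
                    edge_density_between=0.2,
                    seed=seed,
                ))
                result = detect_ensembles(
                    graph, DetectParams(seed=seed, n_null=50, n_repeats=30)
                )
                detected = result.consensus
                vi = variation_of_information(
                    detected, truth.restrict(detected.node_ids)
                )
                hits += vi == 0.0
            recoveries.append(hits)
        assert recoveries[0] <= recoveries[1] <= recoveries[2]
        assert recoveries[2] == 4

    def test_signal_noise_disjoint_cover(self, planted_graph):
        graph, _ = planted_graph
        result = detect_ensembles(graph, DetectParams(seed=2))
        merged = np.sort(np.concatenate([result.signal, result.noise]))
        assert np.array_equal(merged, np.arange(graph.n_nodes))

    def test_empty_graph_raises(self):
        with pytest.raises(ConfigError):
            detect_ensembles(_graph(np.zeros((4, 4))))

    def test_result_serialises(self, planted_graph):
        import json

        graph, _ = planted_graph
        result = detect_ensembles(graph, DetectParams(seed=1))
        payload = json.loads(result.to_json())
        assert payload["d"] == result.d
        assert len(payload["consensus"]) == len(result.signal)
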