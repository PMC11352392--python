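import numpy as np
import pytest

from idhypergraph import (
    ClusteringConfig,
    ModularityParams,
    Partition,
    build_incidence,
    cut_k,
    default_params,
    estimate_params,
    hmll,
    modularity,
    volume_term,
)
from idhypergraph._errors import ConfigError
from idhypergraph.hypergraph import Hypergraph

from conftest import iter_set_partitions, random_hypergraph


@pytest.fixture
def triangle():
    # edges {v0,v1}, {v0,v2}, {v1,v2}; degrees (2,2,2)
    return build_incidence([{0, 1}, {0, 2}, {1, 2}], n_vertices=3)


SPLIT = np.array([0, 0, 1])  # {v0,v1 | v2}


class TestCutK:
    def test_triangle_split(self, triangle):
        assert cut_k(triangle, SPLIT, 2) == 2  # {v0,v2} and {v1,v2} straddle

    def test_single_cluster_zero(self, triangle):
        assert cut_k(triangle, np.zeros(3, dtype=int), 2) == 0

    def test_absent_size_zero(self, triangle):
        assert cut_k(triangle, SPLIT, 3) == 0

    def test_conservation(self):
        rng = np.random.default_rng(0)
        for seed in range(5):
            G, _ = random_hypergraph(np.random.default_rng(seed))
            sizes = {len(e) for e in G.hyperedges}
            Z = rng.integers(0, 3, size=G.n_vertices)
            mass = G.weights * G.multiplicities
            for k in sizes:
                mk = sum(mass[j] for j, e in enumerate(G.hyperedges) if len(e) == k)
                interior = sum(
                    mass[j]
                    for j, e in enumerate(G.hyperedges)
                    if len(e) == k and len(set(Z[list(e)])) == 1
                )
                assert cut_k(G, Z, k) + interior == pytest.approx(mk)


class TestVolumeTerm:
    def test_triangle_split_squared(self, triangle):
        assert volume_term(triangle, SPLIT, 2) == 20  # 4^2 + 2^2

    def test_single_cluster_squared(self, triangle):
        assert volume_term(triangle, np.zeros(3, dtype=int), 2) == 36

    def test_k1_is_total_volume(self, triangle):
        for Z in ([0, 0, 0], [0, 1, 2], [0, 0, 1]):
            assert volume_term(triangle, np.array(Z), 1) == 6

    def test_exact_big_integers(self):
        # 20 vertices of degree 10 in one cluster at k = 12 overflows int64
        G = Hypergraph(
            n_vertices=20,
            hyperedges=[tuple(range(20))] * 10,
        )
        v = volume_term(G, np.zeros(20, dtype=int), 12)
        assert v == 200**12  # exact, no wraparound


class TestModularity:
    def test_two_vertex_example(self):
        G = build_incidence([{0, 1}], n_vertices=2)
        params = ModularityParams(beta={2: 1.0}, gamma={2: 0.1})
        together = modularity(G, np.array([0, 0]), params)
        apart = modularity(G, np.array([0, 1]), params)
        assert together == pytest.approx(-0.4)  # -(0 + 0.1 * 2^2)
        assert apart == pytest.approx(-1.2)  # -(1 + 0.1 * (1 + 1))
        assert together > apart  # beta_2 > 2 * gamma_2

    def test_triangle_merge_threshold(self, triangle):
        for g2 in (0.05, 0.2):
            params = ModularityParams(beta={2: 1.0}, gamma={2: g2})
            split_q = modularity(triangle, SPLIT, params)
            merged_q = modularity(triangle, np.zeros(3, dtype=int), params)
            assert split_q == pytest.approx(-(2 + 20 * g2))
            assert merged_q == pytest.approx(-36 * g2)
            assert (merged_q > split_q) == (2 > 16 * g2)

    def test_zero_params_zero_q(self, triangle):
        params = ModularityParams(beta={2: 0.0}, gamma={2: 0.0})
        for Z in ([0, 0, 0], [0, 1, 2]):
            assert modularity(triangle, np.array(Z), params) == 0.0

    def test_missing_size_raises(self, triangle):
        with pytest.raises(ConfigError):
            modularity(triangle, SPLIT, ModularityParams(beta={3: 1.0}, gamma={3: 0.1}))

    def test_relabeling_invariance(self):
        for seed in range(5):
            G, _ = random_hypergraph(np.random.default_rng(seed))
            params = default_params(G)
            rng = np.random.default_rng(seed + 50)
            Z = rng.integers(0, 3, size=G.n_vertices)
            perm = rng.permutation(Z.max() + 1)
            assert modularity(G, Z, params) == pytest.approx(
                modularity(G, perm[Z], params), rel=1e-12
            )


class TestHmll:
    def test_planted_bipartition_matches_enumeration(self):
        # both 4-vertex blocks carry all their size-3 edges, no cross edges
        edges = []
        for block in ([0, 1, 2, 3], [4, 5, 6, 7]):
            for i in range(4):
                edges.append(tuple(sorted(set(block) - {block[i]})))
        G = build_incidence(edges, n_vertices=8)
        params = ModularityParams(beta={3: 1.0}, gamma={3: 0.001})
        part = hmll(G, ClusteringConfig(params=params, n_restarts=5, seed=0))
        best_q = max(
            modularity(G, np.array(z), params) for z in iter_set_partitions(8)
        )
        assert part.quality == pytest.approx(best_q, abs=1e-9)
        assert part.n_clusters == 2
        assert len(set(part.labels[:4])) == 1 and len(set(part.labels[4:])) == 1

    def test_no_hyperedges_all_singletons(self):
        G = build_incidence([], n_vertices=6)
        part = hmll(G, ClusteringConfig(n_restarts=3, seed=0))
        assert part.n_clusters == 6

    def test_deterministic(self):
        G, _ = random_hypergraph(np.random.default_rng(3))
        cfg = ClusteringConfig(n_restarts=5, seed=7)
        p1 = hmll(G, cfg)
        p2 = hmll(G, cfg)
        np.testing.assert_array_equal(p1.labels, p2.labels)
        assert p1.quality == p2.quality

    def test_incremental_gain_matches_recompute(self):
        audits = []

        def audit(claimed, actual):
            audits.append((claimed, actual))

        for seed in range(5):
            G, _ = random_hypergraph(np.random.default_rng(seed + 20))
            hmll(G, ClusteringConfig(n_restarts=3, seed=seed), audit=audit)
        assert audits, "no moves were audited"
        for claimed, actual in audits:
            assert claimed == pytest.approx(actual, abs=1e-9)

    def test_estimate_mode_runs_and_improves_signal(self):
        edges = []
        for block in ([0, 1, 2, 3], [4, 5, 6, 7]):
            for i in range(4):
                edges.append(tuple(sorted(set(block) - {block[i]})))
        G = build_incidence(edges, n_vertices=8)
        part = hmll(G, ClusteringConfig(params="estimate", n_restarts=5, seed=0))
        assert part.n_clusters == 2
        assert part.params.beta[3] > 0

    def test_aggregate_matches_move_only(self):
        for seed in range(5):
            G, _ = random_hypergraph(np.random.default_rng(seed + 40))
            params = default_params(G)
            base = hmll(G, ClusteringConfig(params=params, n_restarts=10, seed=1))
            agg = hmll(
                G, ClusteringConfig(params=params, n_restarts=10, seed=1, aggregate=True)
            )
            assert agg.quality == pytest.approx(base.quality, abs=1e-9)

    def test_two_uniform_matches_direct_graph_objective(self):
        # independent dyadic implementation of the same objective
        rng = np.random.default_rng(9)
        n = 7
        edges = [
            (i, j) for i in range(n) for j in range(i + 1, n) if rng.random() < 0.5
        ]
        G = build_incidence(edges, n_vertices=n)
        params = ModularityParams(beta={2: 1.0}, gamma={2: 0.02})
        deg = np.zeros(n)
        for a, b in edges:
            deg[a] += 1
            deg[b] += 1
        for _ in range(10):
            Z = rng.integers(0, 3, size=n)
            cross = sum(1 for a, b in edges if Z[a] != Z[b])
            vols = [deg[Z == c].sum() for c in np.unique(Z)]
            direct = -(1.0 * cross + 0.02 * sum(v**2 for v in vols))
            assert modularity(G, Z, params) == pytest.approx(direct)


class TestEstimateParams:
    def _two_block_graph(self, p_cross: float, rng):
        edges = []
        for block in (range(0, 5), range(5, 10)):
            block = list(block)
            for i in range(len(block)):
                for j in range(i + 1, len(block)):
                    edges.append((block[i], block[j]))
        crosses = [(i, j) for i in range(5) for j in range(5, 10)]
        for e in crosses:
            if rng.random() < p_cross:
                edges.append(e)
        return build_incidence(edges, n_vertices=10)

    def test_all_interior_clamps(self):
        G = self._two_block_graph(0.0, np.random.default_rng(0))
        Z = np.array([0] * 5 + [1] * 5)
        params = estimate_params(G, Z)
        assert np.isfinite(params.beta[2])  # clamped, never inf
        assert params.beta[2] > 0
        assert params.gamma[2] > 0

    def test_equal_rates_beta_zero(self):
        # clusters {0,1} and {2,3}: interior mass 2, cut mass 2, vols 4 and 4
        # -> interior rate 2/32 equals exterior rate 2/(64-32); beta = log 1 = 0
        G = build_incidence([(0, 1), (2, 3), (0, 2), (1, 3)], n_vertices=4)
        params = estimate_params(G, np.array([0, 0, 1, 1]))
        assert params.beta[2] == pytest.approx(0.0, abs=1e-12)
        assert params.gamma[2] == pytest.approx(0.0, abs=1e-12)

    def test_mostly_interior_beta_positive(self):
        G = self._two_block_graph(0.25, np.random.default_rng(1))
        Z = np.array([0] * 5 + [1] * 5)
        params = estimate_params(G, Z)
        assert params.beta[2] > 0

    def test_single_cluster_falls_back_to_defaults(self):
        G = build_incidence([(0, 1), (1, 2)], n_vertices=3)
        params = estimate_params(G, np.zeros(3, dtype=int))
        ref = default_params(G)
        assert params.beta == ref.beta
        assert params.gamma == ref.gamma


class TestPartition:
    def test_compact_relabeling(self):
        p = Partition(np.array([5, 3, 5, 9]))
        c = p.compact()
        assert c.labels.tolist() == [0, 1, 0, 2]
        assert c.n_clusters == 3

    def test_one_based(self):
        p = Partition(np.array([2, 0, 2]))
        assert p.one_based().tolist() == [1, 2, 1]
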