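import networkx as nx
import numpy as np
import pytest

from cernet.rwr import (
    RWRConfig,
    column_normalize,
    degree_matched_permutation,
    rwr,
    rwr_significance,
)
from conftest import random_connected_graph


def linear_solve_oracle(W, nodes, seeds, r, normalize=True):
    """Direct solve of (I - (1-r)W) p = r p0."""
    n = len(nodes)
    p0 = np.zeros(n)
    idx = {v: i for i, v in enumerate(nodes)}
    for s in seeds:
        p0[idx[s]] = 1.0
    if normalize:
        p0 /= len(seeds)
    A = np.eye(n) - (1.0 - r) * W.toarray()
    return np.linalg.solve(A, r * p0)


class TestColumnNormalize:
    def test_single_edge(self):
        g = nx.Graph()
        g.add_edge("a", "b")
        W, nodes = column_normalize(g)
        assert nodes == ["a", "b"]
        assert W.toarray().tolist() == [[0.0, 1.0], [1.0, 0.0]]

    def test_star_columns(self):
        g = nx.Graph()
        g.add_edges_from(("hub", f"l{i}") for i in range(3))
        W, nodes = column_normalize(g)
        idx = {v: i for i, v in enumerate(nodes)}
        col_hub = W.toarray()[:, idx["hub"]]
        assert sorted(col_hub) == pytest.approx([0, 1 / 3, 1 / 3, 1 / 3])
        col_leaf = W.toarray()[:, idx["l0"]]
        assert col_leaf[idx["hub"]] == 1.0

    def test_columns_sum_to_one(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            g = random_connected_graph(20, rng)
            W, _ = column_normalize(g)
            assert np.allclose(np.asarray(W.sum(axis=0)).ravel(), 1.0)

    def test_isolated_node_rejected(self):
        g = nx.Graph()
        g.add_edge("a", "b")
        g.add_node("c")
        with pytest.raises(ValueError, match="c"):
            column_normalize(g)


class TestRwr:
    def test_restart_one_returns_p0(self):
        g = nx.Graph()
        g.add_edges_from([("a", "b"), ("b", "c")])
        W, nodes = column_normalize(g)
        p = rwr(W, nodes, ["a"], RWRConfig(restart_prob=1.0))
        assert p["a"] == 1.0 and p["b"] == 0.0

    def test_two_node_closed_form(self):
        g = nx.Graph()
        g.add_edge("a", "b")
        W, nodes = column_normalize(g)
        p = rwr(W, nodes, ["a"], RWRConfig(restart_prob=0.5))
        assert p["a"] == pytest.approx(2 / 3, abs=1e-9)
        assert p["b"] == pytest.approx(1 / 3, abs=1e-9)

    @pytest.mark.parametrize("r", [0.3, 0.5, 0.7, 0.9])
    def test_matches_linear_solve(self, r):
        rng = np.random.default_rng(int(r * 10))
        for _ in range(5):
            g = random_connected_graph(int(rng.integers(5, 40)), rng)
            W, nodes = column_normalize(g)
            seeds = [nodes[i] for i in rng.choice(len(nodes), 3, replace=False)]
            p = rwr(W, nodes, seeds, RWRConfig(restart_prob=r))
            expected = linear_solve_oracle(W, nodes, seeds, r)
            assert np.abs(p.to_numpy() - expected).max() < 1e-8

    def test_probability_mass_conserved(self):
        rng = np.random.default_rng(7)
        g = random_connected_graph(25, rng)
        W, nodes = column_normalize(g)
        p = rwr(W, nodes, nodes[:4], RWRConfig())
        assert p.sum() == pytest.approx(1.0, abs=1e-9)

    def test_absent_seed_rejected(self):
        g = nx.Graph()
        g.add_edge("a", "b")
        W, nodes = column_normalize(g)
        with pytest.raises(ValueError, match="ghost"):
            rwr(W, nodes, ["ghost"], RWRConfig())

    def test_convergence_faster_for_larger_restart(self):
        rng = np.random.default_rng(8)
        g = random_connected_graph(30, rng)
        W, nodes = column_normalize(g)

        def iterations(r):
            cfg = RWRConfig(restart_prob=r)
            p0 = np.zeros(len(nodes))
            p0[0] = 1.0
            p = p0.copy()
            for it in range(1, 10000):
                p_next = (1 - r) * (W @ p) + r * p0
                if np.abs(p_next - p).sum() < cfg.tolerance:
                    return it
                p = p_next

        assert iterations(0.9) <= iterations(0.5) <= iterations(0.2)


class TestDegreeMatchedPermutation:
    def test_degree_multiset_preserved(self, default_cerna):
        net = default_cerna["cerna"]
        truth = default_cerna["truth"]
        seeds = [s for s in truth.seed_genes if s in net.nodes]
        cfg = RWRConfig(n_permutations=50, rng_seed=0)
        real = sorted(net.degree(s) for s in seeds)
        for perm in degree_matched_permutation(net, seeds, cfg):
            assert len(set(perm)) == len(perm)  # without replacement
            assert sorted(net.degree(v) for v in perm) == real

    def test_fallback_fires_when_pool_exhausted(self, caplog):
        g = nx.Graph()
        g.add_edges_from([("a", "b"), ("c", "d"), ("c", "e")])
        # degree-1 pool = {a, b, d, e}; degree-2 pool = {c} only
        seeds = ["c"]
        cfg = RWRConfig(n_permutations=20, rng_seed=1)
        with caplog.at_level("INFO"):
            perms = degree_matched_permutation(g, seeds, cfg)
        # c is the sole degree-2 node; permutations must reuse it, no fallback
        assert all(p == ["c"] for p in perms)
        g2 = nx.Graph()
        g2.add_edges_from([("c", "d"), ("c", "e"), ("d", "e")])
        # all nodes degree 2; two seeds exhaust nothing, three would
        with caplog.at_level("INFO"):
            perms = degree_matched_permutation(
                g2, ["c", "d", "e"], RWRConfig(n_permutations=5, rng_seed=2))
        assert all(sorted(p) == ["c", "d", "e"] for p in perms)

    def test_reproducible_under_seed(self, default_cerna):
        net = default_cerna["cerna"]
        seeds = [s for s in default_cerna["truth"].seed_genes
                 if s in net.nodes]
        cfg = RWRConfig(n_permutations=10, rng_seed=42)
        assert degree_matched_permutation(net, seeds, cfg) == \
            degree_matched_permutation(net, seeds, cfg)

    def test_network_smaller_than_seeds_rejected(self):
        g = nx.Graph()
        g.add_edge("a", "b")
        with pytest.raises(ValueError):
            degree_matched_permutation(g, ["a", "b", "x"],
                                       RWRConfig(n_permutations=1))


class TestSignificance:
    def test_p_is_m_over_n_and_zero_for_top_scorer(self, default_cerna):
        net = default_cerna["cerna"]
        truth = default_cerna["truth"]
        seeds = [s for s in truth.seed_genes if s in net.nodes]
        lncs = sorted(v for v, k in net.nodes(data="kind") if k == "lncRNA")
        cfg = RWRConfig(n_permutations=100, rng_seed=3)
        res = rwr_significance(net, seeds, lncs, cfg)
        assert (res["p"] == res["m"] / res["n"]).all()
        assert res.loc[truth.disease_lncrna, "p"] < 0.05
        # the disease lncRNA is adjacent to the seeds: hard to beat
        assert res["p"].min() == 0.0

    def test_empirical_p_invariant_to_monotone_rescaling(self):
        # p depends only on score comparisons, so feeding an identical
        # network with scaled p0 (unnormalized variant) keeps m unchanged
        g = nx.Graph()
        g.add_edges_from([("L1", "G1"), ("L1", "G2"), ("L2", "G2"),
                          ("L2", "G3"), ("L3", "G3"), ("G1", "L3")])
        for v in g.nodes:
            g.nodes[v]["kind"] = "lncRNA" if v.startswith("L") else "mRNA"
        lncs = ["L1", "L2", "L3"]
        a = rwr_significance(g, ["G1"], lncs,
                             RWRConfig(n_permutations=50, rng_seed=4))
        b = rwr_significance(g, ["G1"], lncs,
                             RWRConfig(n_permutations=50, rng_seed=4,
                                       normalize_p0=False))
        assert (a["m"] == b["m"]).all()
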