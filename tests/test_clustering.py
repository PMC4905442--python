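import networkx as nx
import numpy as np
import pandas as pd
import pytest

from cernet import clustering as cl
from cernet import synthetic_data as sd


def frame(rows, prefix="r"):
    rows = np.asarray(rows, dtype=float)
    return pd.DataFrame(rows, index=[f"{prefix}{i}" for i in range(len(rows))])


class TestHcluster:
    def test_identical_rows_merge_first(self):
        mat = frame([[0, 0], [10, 10], [0, 0], [50, 50]])
        dend = cl.hcluster(mat)
        first_merge = dend.linkage_matrix[0]
        merged = {int(first_merge[0]), int(first_merge[1])}
        assert merged == {0, 2}
        assert first_merge[2] == 0.0

    def test_two_tight_pairs_top_split(self):
        mat = frame([[0.0], [0.1], [10.0], [10.1]])
        dend = cl.hcluster(mat)
        assign = cl.cut_modules(dend, 2)
        assert assign["r0"] == assign["r1"]
        assert assign["r2"] == assign["r3"]
        assert assign["r0"] != assign["r2"]

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(0)
        mat = frame(rng.normal(size=(12, 5)))
        perm = rng.permutation(12)
        permuted = mat.iloc[perm]
        a = cl.cut_modules(cl.hcluster(mat), 3)
        b = cl.cut_modules(cl.hcluster(permuted), 3)
        # same partition of labels, cluster numbering may differ
        parts_a = {}
        parts_b = {}
        for lbl in mat.index:
            parts_a.setdefault(a[lbl], set()).add(lbl)
            parts_b.setdefault(b[lbl], set()).add(lbl)
        assert set(map(frozenset, parts_a.values())) == \
            set(map(frozenset, parts_b.values()))

    def test_constant_row_rejected_under_correlation(self):
        mat = frame([[1, 1, 1], [1, 2, 3], [3, 2, 1]])
        with pytest.raises(ValueError, match="r0"):
            cl.hcluster(mat, metric="one_minus_pearson")

    def test_complete_linkage_no_height_inversions(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            mat = frame(rng.normal(size=(15, 4)))
            dend = cl.hcluster(mat, linkage="complete")
            heights = dend.heights
            assert (np.diff(heights) >= -1e-12).all()

    def test_column_axis(self):
        mat = frame([[0, 10, 0], [0, 10, 0]]).T
        dend = cl.hcluster(frame([[0, 0], [10, 10], [0, 0]]), axis=1)
        assert len(dend.labels) == 2


class TestCutModules:
    def test_k_extremes(self):
        mat = frame(np.arange(8).reshape(4, 2))
        dend = cl.hcluster(mat)
        one = cl.cut_modules(dend, 1)
        assert len(set(one.values())) == 1
        singles = cl.cut_modules(dend, 4)
        assert len(set(singles.values())) == 4

    def test_two_block_matrix_recovered(self):
        rng = np.random.default_rng(2)
        block = np.vstack([rng.normal(0, 0.1, size=(5, 6)),
                           rng.normal(8, 0.1, size=(5, 6))])
        assign = cl.cut_modules(cl.hcluster(frame(block)), 2)
        a = {assign[f"r{i}"] for i in range(5)}
        b = {assign[f"r{i}"] for i in range(5, 10)}
        assert len(a) == 1 and len(b) == 1 and a != b


def planted_two_block_network(noise=0.0, seed=0):
    """Bipartite graph: two disjoint dense lncRNA x mRNA blocks."""
    rng = np.random.default_rng(seed)
    g = nx.Graph()
    lncs = [f"L{i}" for i in range(6)]
    mrnas = [f"G{i}" for i in range(12)]
    for v in lncs:
        g.add_node(v, kind="lncRNA")
    for v in mrnas:
        g.add_node(v, kind="mRNA")
    for i, l in enumerate(lncs):
        for j, m in enumerate(mrnas):
            same_block = (i < 3) == (j < 6)
            p_edge = 0.95 if same_block else noise
            if rng.random() < p_edge:
                g.add_edge(l, m)
    return g, set(lncs[:3]), set(mrnas[:6])


class TestBiclusters:
    def test_planted_blocks_found(self):
        g, lnc_block, mrna_block = planted_two_block_network(seed=3)
        bics = cl.bicluster_modules(g, 2, 2)
        top2 = bics[:2]
        found = {(frozenset(b.lncrnas), frozenset(b.mrnas)) for b in top2}
        assert (frozenset(lnc_block), frozenset(mrna_block)) in found

    def test_densities_in_unit_interval_and_deterministic(self):
        g, _, _ = planted_two_block_network(noise=0.2, seed=4)
        a = cl.bicluster_modules(g, 2, 2)
        b = cl.bicluster_modules(g, 2, 2)
        assert [x.density for x in a] == [x.density for x in b]
        for bic in a:
            assert 0.0 <= bic.density <= 1.0

    def test_random_graph_top_density_near_global(self):
        rng = np.random.default_rng(5)
        g = nx.Graph()
        lncs = [f"L{i}" for i in range(10)]
        mrnas = [f"G{i}" for i in range(20)]
        p_edge = 0.4
        for v in lncs:
            g.add_node(v, kind="lncRNA")
        for v in mrnas:
            g.add_node(v, kind="mRNA")
        for l in lncs:
            for m in mrnas:
                if rng.random() < p_edge:
                    g.add_edge(l, m)
        bics = cl.bicluster_modules(g, 2, 2)
        top = bics[0]
        cell = len(top.lncrnas) * len(top.mrnas)
        sd3 = 3 * np.sqrt(p_edge * (1 - p_edge) / max(cell, 1))
        assert top.density - p_edge < sd3 + 0.15  # small-cell slack

    def test_subnetwork_induced(self):
        g, _, _ = planted_two_block_network(seed=6)
        bic = cl.bicluster_modules(g, 2, 2)[0]
        sub = cl.bicluster_subnetwork(g, bic)
        assert set(sub.nodes) <= bic.lncrnas | bic.mrnas
        assert set(map(frozenset, sub.edges)) <= set(map(frozenset, g.edges))


class TestCoexpressionModule:
    def test_planted_module_recovered(self):
        hits = 0
        for seed in range(20):
            cfg = sd.SynthConfig(module_factor_sd=2.0, noise_sd=0.1,
                                 rng_seed=seed)
            _, _, truth = sd.generate_interactions(cfg)
            expr, _ = sd.generate_expression(cfg, truth)
            mod = truth.module_members[2]
            outsiders = [g for g in expr.gene_ids
                         if g.startswith("MRNA")][-10:]
            neighbors = mod["mrnas"] + outsiders
            got = cl.coexpression_module(expr, mod["lncrna"], neighbors)
            ok = set(mod["mrnas"]) <= got and not (set(outsiders) & got)
            hits += ok
        assert hits >= 18

    def test_lncrna_always_member(self):
        cfg = sd.SynthConfig(rng_seed=8)
        _, _, truth = sd.generate_interactions(cfg)
        expr, _ = sd.generate_expression(cfg, truth)
        mod = truth.module_members[1]
        got = cl.coexpression_module(expr, mod["lncrna"], mod["mrnas"])
        assert mod["lncrna"] in got

    def test_independent_noise_cut_uninformative(self):
        sizes = []
        for seed in range(10):
            rng = np.random.default_rng(100 + seed)
            mat = pd.DataFrame(rng.normal(size=(21, 6)),
                               index=[f"g{i}" for i in range(21)],
                               columns=[f"s{i}" for i in range(6)])

            class FakeExpr:
                values = mat

            got = cl.coexpression_module(FakeExpr(), "g0",
                                         [f"g{i}" for i in range(1, 21)],
                                         k=2)
            sizes.append(len(got))
        # on pure noise the fixed two-way cut is arbitrary: average size
        # sits well inside the interior, away from both extremes
        assert 3 < np.mean(sizes) < 18
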