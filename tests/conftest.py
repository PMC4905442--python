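import networkx as nx
import numpy as np
import pytest

from cernet import cerna_network as cn
from cernet import diffexpr as de
from cernet import synthetic_data as sd


@pytest.fixture(scope="session")
def default_config():
    return sd.SynthConfig(rng_seed=0)


@pytest.fixture(scope="session")
def default_dataset(default_config):
    """One default synthetic dataset: interactions, expression, truth."""
    mi_mrna, mi_lncrna, truth = sd.generate_interactions(default_config)
    expr, de_truth = sd.generate_expression(default_config, truth)
    return {"mi_mrna": mi_mrna, "mi_lncrna": mi_lncrna, "truth": truth,
            "expr": expr, "de_truth": de_truth, "config": default_config}


@pytest.fixture(scope="session")
def default_cerna(default_dataset):
    """ceRNA network built from the default dataset through the DE stage."""
    res = de.sam_test(default_dataset["expr"], rng_seed=0)
    hits = set(res.index[res["p"] < 0.01])
    net = cn.merge_triple(default_dataset["mi_mrna"],
                          [default_dataset["mi_lncrna"]])
    mm, ml = cn.map_de_genes(net,
                             [g for g in hits if g.startswith("MRNA")],
                             [g for g in hits if g.startswith("LNC")])
    cerna = cn.build_cerna_network(net, mm, ml)
    return {"triple": net, "cerna": cerna, "mapped_mrnas": mm,
            "mapped_lncrnas": ml, "de_hits": hits,
            "truth": default_dataset["truth"]}


def random_connected_graph(n_nodes: int, rng: np.random.Generator) -> nx.Graph:
    """Random connected undirected graph: spanning tree plus extra edges."""
    g = nx.Graph()
    nodes = [f"n{i:02d}" for i in range(n_nodes)]
    g.add_nodes_from(nodes)
    order = rng.permutation(n_nodes)
    for i in range(1, n_nodes):
        g.add_edge(nodes[order[i]], nodes[order[int(rng.integers(i))]])
    n_extra = int(rng.integers(0, n_nodes))
    for _ in range(n_extra):
        u, v = rng.integers(0, n_nodes, size=2)
        if u != v:
            g.add_edge(nodes[u], nodes[v])
    return g
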