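"""Bicluster modules of the ceRNA network and gene-set enrichment.

The binary lncRNA x mRNA adjacency is clustered along both axes; the
densest row-cluster x column-cluster cell is the top ceRNA module. Its
mRNA members are then tested for over-representation in gene-set
collections with the upper-tail hypergeometric test.
"""

from cernet import cerna_network as cn
from cernet import synthetic_data as sd
from cernet.clustering import bicluster_modules, coexpression_module
from cernet.enrichment import enrich

config = sd.SynthConfig(rng_seed=0)
mi_mrna, mi_lncrna, truth = sd.generate_interactions(config)
expr, _ = sd.generate_expression(config, truth)
triple = cn.merge_triple(mi_mrna, [mi_lncrna])
mm, ml = cn.map_de_genes(triple,
                         [g for g in truth.de_genes if g.startswith("MRNA")],
                         [g for g in truth.de_genes if g.startswith("LNC")])
cerna = cn.build_cerna_network(triple, mm, ml)

bics = bicluster_modules(cerna, k_rows=2, k_cols=2)
top = bics[0]
print(f"top bicluster: {len(top.lncrnas)} lncRNAs x {len(top.mrnas)} mRNAs, "
      f"edge density {top.density:.2f}")

# co-expression check: which partner mRNAs cluster with a module lncRNA
mod = truth.module_members[1]
coexpr = coexpression_module(expr, mod["lncrna"], mod["mrnas"])
print(f"expression cluster around {mod['lncrna']}: {sorted(coexpr)}")

# enrichment of the top module's mRNAs against the gene-set collection
gmt = sd.generate_gene_sets(config, truth)
universe = sorted(v for v, k in cerna.nodes(data="kind") if k == "mRNA")
res = enrich(sorted(top.mrnas), gmt, universe, alpha=0.05)
print("\ntop gene sets (p = upper-tail hypergeometric, q = BH-adjusted):")
print(res.head(5).to_string(index=False))
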