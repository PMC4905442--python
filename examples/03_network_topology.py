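"""Centrality analysis of the ceRNA network: find the hub lncRNAs.

Degree, betweenness, and closeness are computed on the bipartite
lncRNA-mRNA network; lncRNAs in the top-10 of all three metrics are the
candidate master regulators.
"""

from cernet import cerna_network as cn
from cernet import synthetic_data as sd
from cernet import topology as tp

config = sd.SynthConfig(rng_seed=0)
mi_mrna, mi_lncrna, truth = sd.generate_interactions(config)
triple = cn.merge_triple(mi_mrna, [mi_lncrna])
mm, ml = cn.map_de_genes(triple,
                         [g for g in truth.de_genes if g.startswith("MRNA")],
                         [g for g in truth.de_genes if g.startswith("LNC")])
cerna = cn.build_cerna_network(triple, mm, ml)

table = tp.centrality_table(cerna)
lnc_table = table[table["kind"] == "lncRNA"]
print("lncRNA centralities (top 5 by degree):")
print(lnc_table.sort_values("degree", ascending=False).head(5).round(6))

hubs = tp.intersect_top_k(table, k=10)
print(f"\nnodes in the top-10 of degree AND betweenness AND closeness: "
      f"{sorted(hubs)}")
print(f"planted hub lncRNA: {truth.hub_lncrna} "
      f"({'found' if truth.hub_lncrna in hubs else 'missed'})")

# a hub's ceRNA module: its partner mRNAs plus the mediating miRNAs
partners = tp.first_neighbors(cerna, truth.hub_lncrna)
module = tp.extract_cerna_module(triple, truth.hub_lncrna, partners)
kinds = [k for _, k in module.nodes(data="kind")]
print(f"hub ceRNA module: {kinds.count('mRNA')} mRNAs mediated by "
      f"{kinds.count('miRNA')} miRNAs")
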