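"""SAM-style differential expression on a 3-vs-3 two-group design.

The moderated statistic d = (mean difference) / (s_i + s0) is compared
to a permutation null pooled across genes; with 3+3 samples all 20
distinct group relabelings are enumerated, so the result is exact and
deterministic.
"""

from cernet import diffexpr as de
from cernet import synthetic_data as sd

config = sd.SynthConfig(rng_seed=0)  # 5-sigma planted effects
_, _, truth = sd.generate_interactions(config)
expr, de_truth = sd.generate_expression(config, truth)

s0 = de.choose_s0(expr, "tusher")
print(f"{len(expr.gene_ids)} genes, fudge factor s0 = {s0:.3f}")

results = de.sam_test(expr, rng_seed=0)
classes = sd.gene_classes(config)
hits, counts = de.select_de(results, alpha=0.01, classes=classes)
print(f"genes with p < 0.01: {counts}")

true = set(de_truth)
tp = len(set(hits) & true)
print(f"planted regulators recovered: {tp}/{len(true)} "
      f"(false positives: {len(hits) - tp})")
# the planted genes carry a 2.0 log-unit shift over noise sd 0.4; the
# pooled null gives p-value resolution far below 1/20 despite only 20
# distinct relabelings
print(results.loc[sorted(true)[:5]].round(4))
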