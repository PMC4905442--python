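# Methods

## Scope and model

`cernet` analyzes competing-endogenous-RNA (ceRNA) regulation: a
lncRNA and an mRNA targeted by the same miRNAs can buffer each other's
degradation, so lncRNA–mRNA pairs sharing unexpectedly many miRNAs are
candidate regulatory couples. The pipeline takes (i) miRNA→mRNA and
miRNA→lncRNA interaction tables, (ii) sequence-level miRNA–lncRNA
predictions with alignment score and duplex energy, (iii) a two-group
genes × samples expression matrix, and (iv) a seed list of known
disease genes, and produces a significance-filtered bipartite
lncRNA–mRNA network plus three prioritizations of its lncRNAs
(centrality, module membership, random-walk proximity to the seeds).

## Probe re-annotation

Array probes are re-assigned to transcripts from BLAST-tabular hits.
A hit is *perfect* when identity ≥ `min_identity` (default 100%) over
the full probe length (default 25 nt; relaxable). The filter is
sequential: (1) probes hitting both a coding and a non-coding
transcript are discarded and the rest split by class; (2) within each
class, probes hitting more than one transcript are discarded; (3)
transcripts retaining more than three (i.e. ≥4) perfect probes are
kept. The order matters — a transcript can lose probes at step 2 and
then fail step 3 — and is fixed as above. Probe-level expression is
summarized per transcript by mean (default) or median.

## Differential expression

The SAM-style statistic is d_i = (x̄_case − x̄_ctrl)/(s_i + s₀), with
s_i the pooled standard error of the mean difference and s₀ a fudge
factor guarding against spuriously large d at small s_i. Two s₀ rules
are provided: the median of s_i, and the default "tusher" rule — the
s_i percentile minimizing the coefficient of variation of the
d-statistic spread across s_i windows, which is the classical SAM
tuning and is noticeably more powerful at very small sample counts
(the variance of a 4-df standard error otherwise dominates the
denominator).

The null distribution pools |d| recomputed under group-label
permutations across *all* genes. For designs of ≤20 samples where the
permutation budget covers them, all C(n₁+n₂, n₁) distinct relabelings
are enumerated (20 for 3 + 3), making p-values deterministic; pooling
gives resolution far finer than 1/20. The per-gene p-value is the
fraction of pooled null values *strictly* greater than the observed
|d|; strictness means a gene is not floored by its own copy under the
identity relabeling, and for continuous data the two conventions
differ only at that tie. Selection uses raw p < α (default 0.01), no
multiple-testing correction by default; Benjamini–Hochberg q-values
are available (`bh_adjust`).

## Network construction

miRanda-style predictions are kept when score > 160 and energy < −20
kcal/mol, both strict. Interaction sources are merged into a
tripartite graph (miRNA/lncRNA/mRNA node classes, edges only between a
miRNA and a target; an identifier claimed by two classes is an error).
For every mapped differentially expressed (lncRNA, mRNA) pair, the
shared-miRNA count r is scored with the upper-tail hypergeometric
probability given neighborhood sizes t (mRNA) and n (lncRNA) in a
universe of m miRNAs. The kernel uses exact integer arithmetic
(`math.comb` tail sums divided via `Fraction`), so results are
correctly rounded floats at any network scale — no log-space
approximation is needed.

The universe rule `m_rule="network"` (default) takes m as the number
of distinct miRNAs in the merged triple network — self-contained and
defensible when the input tables are comprehensive. With sparse or
zero-background inputs this estimator degenerates (every observed
miRNA touches a planted pair), so `m_rule="fixed"` accepts an external
genome-wide count; the construction tests use it. Edges require r ≥ 1
and p < α (default 0.01); nodes exist only through edges, so the final
network can be smaller than the mapped gene lists.

## Topology, modules, random walk

Centralities follow the textbook unweighted definitions: degree;
betweenness as the ordered-pair shortest-path fraction normalized by
(n−1)(n−2) (computed via networkx, whose undirected normalized variant
is algebraically identical); closeness as 1/Σ_j d(i,j) over *reachable*
nodes only — no component-size correction, so values are comparable
only within a component (isolated nodes score 0, with a warning).
Top-k lists break ties lexicographically; the three-way top-10
intersection flags hub lncRNAs.

Biclustering clusters the binary lncRNA × mRNA adjacency along both
axes (Euclidean distance, complete linkage — the defaults of common
heat-map tooling; a shared-miRNA-weighted variant is available) and
ranks all row-cluster × column-cluster cells by edge density.
Expression-space clustering uses 1 − Pearson with average linkage.
`coexpression_module` returns the tight cluster around a lncRNA by
cutting at the largest relative jump in merge height along the
lncRNA's path to the dendrogram root; with only six samples, chance
correlations (sd ≈ 0.45) make a fixed two-way cut absorb unrelated
genes, while the height-gap rule isolates the planted module reliably.
A fixed k-cluster cut remains available via `k=`.

Random walk with restart iterates p^{t+1} = (1−r)·W·p^t + r·p⁰ with W
the column-normalized adjacency, until the L1 change drops below 1e-10.
The restart probability r is not something published analyses usually
state; the default is 0.7, the common choice in network-propagation
work, and it is an explicit config field. p⁰ puts 1/|seeds| on each
seed (an unnormalized 0/1 variant is a flag; scores scale linearly so
ranks and empirical p-values are identical). Significance: n
(default 3000) permuted seed sets, each replacing every seed by a
distinct node of identical degree (nearest degree as a logged fallback
when a pool is exhausted; ties prefer the smaller degree, then
lexicographic order), walks re-run on the same W, and p = m/n with m
the number of permutations whose score strictly exceeds the real one.
The (m+1)/(n+1) anti-zero correction is available but off by default.

Gene-set enrichment is the standard upper-tail hypergeometric
over-representation test (equivalent to one-sided Fisher), reusing the
same exact kernel, with BH q-values reported alongside raw p.

## Synthetic data: what it emulates, and what it does not

The generator plants hub-centered ceRNA modules: each module is one
lncRNA plus several mRNAs wired to one module-specific miRNA group
(disjoint across modules, so the planted truth is unambiguous);
module 0's lncRNA is additionally wired into every other module's
group, making it a cross-module hub — real ceRNA hubs touch a large
fraction of the network's mRNAs and keep it connected, which matters
for closeness comparability. Module 1 is the disease module: its
mRNAs are the seed list and its lncRNA is the planted prioritization
target. Background miRNA→target edges are independent Bernoulli draws.

Expression is Gaussian on the log scale: per-gene baseline N(8, 1),
within-group noise N(0, noise_sd), a ±de_effect shift in the case
group for planted regulators (one sign per module so the shift does
not cancel the co-expression), and a per-sample latent factor
N(0, module_factor_sd) shared by module members.

Defaults (the study conditions of every simulation-based test):
150 miRNAs, 600 mRNAs, 60 lncRNAs; 30 planted pairs in one 10-pair hub
module plus four 5-pair modules, 8 shared miRNAs each; background
density 0.02; 3 + 3 samples; noise_sd 0.4 with de_effect 2.0 (five
noise SDs — the regime where a 3-vs-3 design has high but not
saturated power); module_factor_sd 0.3, a co-expression signal
deliberately subdominant to noise so the factor does not mask planted
effects (the co-expression tests raise it to 2.0 explicitly);
10 extra differentially expressed mRNAs, keeping the DE fraction near
7% so the pooled permutation null is not dominated by the DE genes'
own relabelings. All generators are pure functions of
(config, rng_seed) with independent child RNG streams per generator.

What the generator does *not* model: realistic degree distributions of
interaction databases, intensity-dependent array noise, probe-level
expression (the re-annotation stage is exercised on a branch-covering
hits fixture with hand-built truth), and identifier-conversion chaos.
Passing tests therefore demonstrate correctness of the algorithms and
their calibration under a clean generative model, not performance on
any particular real dataset.

## Numerical and determinism notes

- Hypergeometric and enrichment p-values: exact integer arithmetic.
- Permutation p-values: strict ">" comparisons throughout (DE null,
  RWR null).
- Hierarchical clustering delegates to scipy; merge-tie ordering
  follows scipy's deterministic convention given input order.
- The CLI pipeline is a pure function of (inputs, config, rng_seed):
  stage reports are JSON with sorted keys, floats at fixed precision,
  LF endings — reruns are byte-identical.
- Degenerate inputs: empty interaction tables load with a warning;
  betweenness on n < 3 returns zeros with a warning; a constant row
  under the correlation metric raises, naming the row; zero-degree
  nodes make column normalization an error, naming the node.

## Known limitations

- Closeness across disconnected components is intentionally not
  comparable (reachable-only definition); interpret rankings within
  the giant component.
- With 3 + 3 samples the permutation null has only 20 distinct
  relabelings; the pooled null makes p < 0.01 attainable but per-gene
  resolution still rests on cross-gene exchangeability.
- The network-universe m rule underestimates the miRNA genome when
  input tables are sparse, which is conservative for dense planted
  structure but can inflate significance when t, n approach m.
- Enrichment on real annotation collections depends on the chosen
  background; the default universe (network genes present in the
  collection) is one defensible choice among several.
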