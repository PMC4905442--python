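"""Synthetic pipeline inputs with planted ground truth.

Every external input of the pipeline can be generated here with known
truth, so each downstream stage is testable without any downloads:

* miRNA->mRNA and miRNA->lncRNA interaction tables with planted ceRNA
  pairs (a lncRNA and an mRNA wired to a common miRNA subset) on top of
  independent background edges;
* a two-group genes x samples log-intensity matrix with planted
  differentially expressed genes and per-module latent co-expression
  factors;
* a probe->transcript alignment-hit table covering every branch of the
  re-annotation filter;
* miRanda-style prediction records straddling the score/energy
  thresholds;
* gene-set collections enriched for planted module members.

Planted pairs are organized into hub-centered modules: one lncRNA with
several partner mRNAs sharing one miRNA group, which matches the
hub-and-module structure the analysis is meant to recover. Module 0 is
oversized (the "hub" lncRNA); module 1 is the designated disease
module whose mRNAs serve as the seed list for the random-walk stage.

All generators are pure functions of (config, rng_seed): each one
derives its own child RNG stream, so outputs do not depend on call
order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from cernet.cerna_network import MirandaRecord
from cernet.io_formats import (
    ExpressionMatrix,
    GeneSetCollection,
    Interaction,
    InteractionSet,
)
from cernet.reannotation import ProbeHit


@dataclass
class SynthConfig:
    """Study-condition parameters of the synthetic dataset.

    Defaults emulate the desk-scale shape of the real analysis: a few
    hundred miRNAs/mRNAs, dozens of lncRNAs, and a 3-vs-3 two-group
    expression design. ``de_effect`` is the mean log-intensity shift of
    planted differentially expressed genes in the case group (default
    five noise standard deviations); ``module_factor_sd`` scales the
    per-sample latent factor shared by co-expression module members.
    """

    n_mirna: int = 150
    n_mrna: int = 600
    n_lncrna: int = 60
    n_planted_edges: int = 30
    shared_planted: int = 8
    background_density: float = 0.02
    n_samples_per_group: int = 3
    de_effect: float = 2.0
    noise_sd: float = 0.4
    module_factor_sd: float = 0.3
    rng_seed: int = 0
    # module layout: module 0 (the hub lncRNA) takes hub_pairs planted
    # pairs, the rest are chunks of module_size
    module_size: int = 5
    hub_pairs: int = 10
    n_extra_de_mrnas: int = 10

    def __post_init__(self) -> None:
        if self.shared_planted > self.n_mirna:
            raise ValueError("shared_planted cannot exceed n_mirna")
        if not 0.0 <= self.background_density <= 1.0:
            raise ValueError("background_density must be in [0, 1]")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if self.n_samples_per_group < 2:
            raise ValueError("need >=2 samples per group")
        n_modules = 1 + math.ceil(
            max(self.n_planted_edges - self.hub_pairs, 0) / self.module_size)
        if n_modules > self.n_lncrna:
            raise ValueError("not enough lncRNAs for the planted modules")
        if self.n_planted_edges + self.n_extra_de_mrnas > self.n_mrna:
            raise ValueError("not enough mRNAs for planted pairs and extra DE genes")

    def mirna_ids(self) -> list[str]:
        return [f"miR-{i:04d}" for i in range(self.n_mirna)]

    def mrna_ids(self) -> list[str]:
        return [f"MRNA{i:04d}" for i in range(self.n_mrna)]

    def lncrna_ids(self) -> list[str]:
        return [f"LNC{i:03d}" for i in range(self.n_lncrna)]


@dataclass
class PlantedTruth:
    """Ground truth planted into one synthetic dataset."""

    planted_pairs: list[tuple[str, str, tuple[str, ...]]] = field(default_factory=list)
    de_genes: dict[str, float] = field(default_factory=dict)  # id -> signed effect
    module_members: list[dict] = field(default_factory=list)  # lncrna/mrnas/mirnas
    seed_genes: list[str] = field(default_factory=list)
    disease_lncrna: str = ""
    hub_lncrna: str = ""

    @property
    def planted_pair_set(self) -> set[tuple[str, str]]:
        return {(l, m) for l, m, _ in self.planted_pairs}


def _rng(config: SynthConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(
        entropy=config.rng_seed, spawn_key=(stream,)))


def _module_layout(config: SynthConfig) -> list[int]:
    """Planted-pair counts per module (module 0 is the hub)."""
    sizes = [min(config.hub_pairs, config.n_planted_edges)]
    remaining = config.n_planted_edges - sizes[0]
    while remaining > 0:
        take = min(config.module_size, remaining)
        sizes.append(take)
        remaining -= take
    return sizes


def generate_interactions(config: SynthConfig
                          ) -> tuple[InteractionSet, InteractionSet, PlantedTruth]:
    """Interaction tables with planted ceRNA modules over background edges.

    Background miRNA->target edges are independent Bernoulli draws with
    ``background_density``. Each planted module wires its lncRNA and all
    its mRNAs to one common random miRNA subset of size
    ``shared_planted``, so every planted (lncRNA, mRNA) pair shares at
    least that many miRNAs.
    """
    rng = _rng(config, 0)
    mirnas = config.mirna_ids()
    mrnas = config.mrna_ids()
    lncs = config.lncrna_ids()

    sizes = _module_layout(config)
    if len(sizes) * config.shared_planted > config.n_mirna:
        raise ValueError("not enough miRNAs for disjoint planted module groups")
    # disjoint miRNA groups per module keep the planted truth unambiguous:
    # cross-module pairs share miRNAs only through background edges
    pool = list(rng.choice(mirnas, size=len(sizes) * config.shared_planted,
                           replace=False))
    truth = PlantedTruth()
    mrna_cursor = 0
    mi_mrna_pairs: set[tuple[str, str]] = set()
    mi_lnc_pairs: set[tuple[str, str]] = set()
    for mod_i, n_pairs in enumerate(sizes):
        lnc = lncs[mod_i]
        members = mrnas[mrna_cursor:mrna_cursor + n_pairs]
        mrna_cursor += n_pairs
        group = tuple(sorted(pool[mod_i * config.shared_planted:
                                  (mod_i + 1) * config.shared_planted]))
        for mi in group:
            mi_lnc_pairs.add((mi, lnc))
            for mr in members:
                mi_mrna_pairs.add((mi, mr))
        for mr in members:
            truth.planted_pairs.append((lnc, mr, group))
        truth.module_members.append(
            {"lncrna": lnc, "mrnas": list(members), "mirnas": list(group)})
    truth.hub_lncrna = truth.module_members[0]["lncrna"]
    # The hub lncRNA is additionally wired into every other module's
    # miRNA group, making it a cross-module hub (real ceRNA hubs touch
    # a large fraction of the network's mRNAs) and keeping the planted
    # lncRNA-mRNA network connected, so closeness ranks are comparable.
    for mod in truth.module_members[1:]:
        for mi in mod["mirnas"]:
            mi_lnc_pairs.add((mi, truth.hub_lncrna))
        for mr in mod["mrnas"]:
            truth.planted_pairs.append(
                (truth.hub_lncrna, mr, tuple(mod["mirnas"])))
    if len(truth.module_members) > 1:
        truth.disease_lncrna = truth.module_members[1]["lncrna"]
        truth.seed_genes = list(truth.module_members[1]["mrnas"])
    else:
        truth.disease_lncrna = truth.hub_lncrna
        truth.seed_genes = list(truth.module_members[0]["mrnas"])

    if config.background_density > 0:
        mask = rng.random((config.n_mirna, config.n_mrna)) < config.background_density
        for i, j in zip(*np.nonzero(mask)):
            mi_mrna_pairs.add((mirnas[i], mrnas[j]))
        mask = rng.random((config.n_mirna, config.n_lncrna)) < config.background_density
        for i, j in zip(*np.nonzero(mask)):
            mi_lnc_pairs.add((mirnas[i], lncs[j]))

    mi_mrna = InteractionSet([Interaction(mi, mr, "mRNA", "synthetic")
                              for mi, mr in sorted(mi_mrna_pairs)])
    mi_lncrna = InteractionSet([Interaction(mi, l, "lncRNA", "synthetic")
                                for mi, l in sorted(mi_lnc_pairs)])

    # DE truth: all planted module members plus extra DE mRNAs.
    # Same sign within a module so the latent-factor co-expression is
    # not cancelled by opposing group shifts.
    rng_de = _rng(config, 1)
    for mod in truth.module_members:
        sign = 1.0 if rng_de.random() < 0.5 else -1.0
        truth.de_genes[mod["lncrna"]] = sign * config.de_effect
        for mr in mod["mrnas"]:
            truth.de_genes[mr] = sign * config.de_effect
    extra = mrnas[mrna_cursor:mrna_cursor + config.n_extra_de_mrnas]
    for mr in extra:
        sign = 1.0 if rng_de.random() < 0.5 else -1.0
        truth.de_genes[mr] = sign * config.de_effect
    return mi_mrna, mi_lncrna, truth


def generate_expression(config: SynthConfig, truth: PlantedTruth
                        ) -> tuple[ExpressionMatrix, dict[str, float]]:
    """Two-group log-intensity matrix with planted DE and module factors.

    Per gene: baseline ~ N(8, 1); within-group noise N(0, noise_sd);
    planted DE genes are shifted by their signed effect in the case
    group; members of a planted module additionally share a per-sample
    latent factor N(0, module_factor_sd), inducing positive pairwise
    correlation within the module.
    """
    rng = _rng(config, 2)
    genes = config.mrna_ids() + config.lncrna_ids()
    nper = config.n_samples_per_group
    samples = [f"ctrl_{i+1}" for i in range(nper)] + \
              [f"case_{i+1}" for i in range(nper)]
    group_of = {s: ("control" if s.startswith("ctrl") else "case")
                for s in samples}
    g_index = {g: i for i, g in enumerate(genes)}

    baseline = rng.normal(8.0, 1.0, size=len(genes))
    X = baseline[:, None] + rng.normal(0.0, config.noise_sd,
                                       size=(len(genes), 2 * nper))
    case_cols = np.arange(nper, 2 * nper)
    for gene, eff in truth.de_genes.items():
        X[g_index[gene], case_cols] += eff
    for mod in truth.module_members:
        factor = rng.normal(0.0, config.module_factor_sd, size=2 * nper)
        for gene in (mod["lncrna"], *mod["mrnas"]):
            X[g_index[gene]] += factor
    expr = ExpressionMatrix(pd.DataFrame(X, index=genes, columns=samples),
                            group_of)
    return expr, dict(truth.de_genes)


def gene_classes(config: SynthConfig) -> dict[str, str]:
    """Transcript class per synthetic gene id."""
    out = {g: "mRNA" for g in config.mrna_ids()}
    out.update({g: "lncRNA" for g in config.lncrna_ids()})
    return out


@dataclass
class AnnotationTruth:
    """Which probe->transcript pairs must survive the re-annotation filter."""

    coding_pairs: dict[str, str] = field(default_factory=dict)
    noncoding_pairs: dict[str, str] = field(default_factory=dict)
    removed_probes: dict[str, str] = field(default_factory=dict)  # probe -> reason


def generate_probe_hits(config: SynthConfig
                        ) -> tuple[list[ProbeHit], AnnotationTruth]:
    """Alignment-hit fixture covering every branch of the filter.

    Emits probes that map uniquely, probes hitting both a coding and a
    noncoding transcript, probes hitting multiple transcripts of one
    class, imperfect hits, and transcripts with 2..5 perfect probes —
    including a transcript that starts with enough probes but drops
    below four after the unique-probe step. The returned truth is built
    by hand alongside the fixture, never by running the filter.
    """
    L = 25
    hits: list[ProbeHit] = []
    truth = AnnotationTruth()

    def perfect(probe, tx, cls):
        hits.append(ProbeHit(probe, tx, cls, 100.0, L, L))

    def survivors(cls, tx, probes):
        for p in probes:
            perfect(p, tx, cls)
            if cls == "coding":
                truth.coding_pairs[p] = tx
            else:
                truth.noncoding_pairs[p] = tx

    # transcripts with 5 and 4 perfect probes: survive
    survivors("coding", "CT_A", [f"pa{i}" for i in range(5)])
    survivors("coding", "CT_B", [f"pb{i}" for i in range(4)])
    survivors("noncoding", "NT_A", [f"na{i}" for i in range(4)])
    # 3 and 2 perfect probes: transcript dropped ("more than three" rule)
    for tx, prefix, n, cls in [("CT_C", "pc", 3, "coding"),
                               ("CT_D", "pd", 2, "coding"),
                               ("NT_B", "nb", 3, "noncoding")]:
        for i in range(n):
            perfect(f"{prefix}{i}", tx, cls)
            truth.removed_probes[f"{prefix}{i}"] = "transcript_below_4_probes"
    # multi-transcript probes within one class: CT_E starts with 5
    # probes, 2 of them shared with CT_F -> both lose those probes and
    # CT_E falls to 3, failing the probe-count rule
    for i in range(5):
        perfect(f"pe{i}", "CT_E", "coding")
    for i in range(2):
        perfect(f"pe{i}", "CT_F", "coding")
        truth.removed_probes[f"pe{i}"] = "multi_transcript_within_class"
    for i in range(2, 5):
        truth.removed_probes[f"pe{i}"] = "transcript_below_4_probes"
    # cross-class probe: hits one coding and one noncoding transcript
    perfect("px0", "CT_X", "coding")
    perfect("px0", "NT_C", "noncoding")
    truth.removed_probes["px0"] = "cross_class"
    # NT_C keeps 4 other unique perfect probes and survives
    survivors("noncoding", "NT_C", [f"nc{i}" for i in range(1, 5)])
    # imperfect hits: identity below 100 or partial alignment; these
    # must not count anywhere (CT_G keeps exactly its 4 perfect probes)
    survivors("coding", "CT_G", [f"pg{i}" for i in range(4)])
    hits.append(ProbeHit("pg_bad1", "CT_G", "coding", 96.0, L, L))
    hits.append(ProbeHit("pg_bad2", "CT_G", "coding", 100.0, L - 1, L))
    truth.removed_probes["pg_bad1"] = "imperfect_identity"
    truth.removed_probes["pg_bad2"] = "imperfect_length"
    return hits, truth


def generate_miranda_records(config: SynthConfig
                             ) -> tuple[list[MirandaRecord], set[tuple[str, str]]]:
    """miRanda-like records straddling the (160, -20) thresholds.

    Returns (records, kept truth) where the truth is the set of
    (miRNA, lncRNA) pairs constructed to pass the strict score>160 and
    energy<-20 filter. Includes one record exactly at each boundary
    (removed by strictness).
    """
    rng = _rng(config, 3)
    mirnas = config.mirna_ids()
    lncs = config.lncrna_ids()
    records: list[MirandaRecord] = []
    kept: set[tuple[str, str]] = set()

    def pick():
        return (mirnas[int(rng.integers(len(mirnas)))],
                lncs[int(rng.integers(len(lncs)))])

    used: set[tuple[str, str]] = set()

    def fresh():
        pair = pick()
        while pair in used:
            pair = pick()
        used.add(pair)
        return pair

    for _ in range(40):  # clear keepers
        mi, l = fresh()
        records.append(MirandaRecord(mi, l, float(rng.uniform(161, 200)),
                                     float(rng.uniform(-35, -20.5))))
        kept.add((mi, l))
    for _ in range(25):  # fail on score
        mi, l = fresh()
        records.append(MirandaRecord(mi, l, float(rng.uniform(100, 159.5)),
                                     float(rng.uniform(-35, -20.5))))
    for _ in range(25):  # fail on energy
        mi, l = fresh()
        records.append(MirandaRecord(mi, l, float(rng.uniform(161, 200)),
                                     float(rng.uniform(-19.5, -5))))
    mi, l = fresh()  # exactly on the score boundary: removed (strict >)
    records.append(MirandaRecord(mi, l, 160.0, -30.0))
    mi, l = fresh()  # exactly on the energy boundary: removed (strict <)
    records.append(MirandaRecord(mi, l, 180.0, -20.0))
    return records, kept


def generate_gene_sets(config: SynthConfig, truth: PlantedTruth,
                       n_random_sets: int = 15,
                       set_size: int = 20) -> GeneSetCollection:
    """Gene-set collection with one set per planted module plus noise sets."""
    rng = _rng(config, 4)
    mrnas = config.mrna_ids()
    sets: dict[str, tuple[str, tuple[str, ...]]] = {}
    for i, mod in enumerate(truth.module_members):
        pad = [m for m in rng.choice(mrnas, size=set_size, replace=False)
               if m not in set(mod["mrnas"])]
        members = tuple(dict.fromkeys([*mod["mrnas"], *pad]))[:set_size]
        sets[f"MODULE{i}_TARGETS"] = (f"planted module {i} members", members)
    for i in range(n_random_sets):
        members = tuple(sorted(rng.choice(mrnas, size=set_size, replace=False)))
        sets[f"RANDOM{i:02d}"] = ("random background set", members)
    return GeneSetCollection(sets)
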