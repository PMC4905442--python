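"""Triple-network assembly and hypergeometric ceRNA edge testing.

A ceRNA (competing endogenous RNA) pair is a lncRNA and an mRNA that
share significantly many miRNA regulators. From a tripartite
miRNA/lncRNA/mRNA interaction graph (the "global triple network"),
each candidate (lncRNA, mRNA) pair is scored with the upper-tail
hypergeometric probability of drawing at least r shared miRNAs when n
of m miRNAs touch the lncRNA and t of m touch the mRNA:

    P(X >= r) = sum_{i=r}^{min(t,n)} C(t,i) C(m-t, n-i) / C(m,n)

Pairs with p below alpha (and at least one shared miRNA) become edges
of the bipartite lncRNA-mRNA ceRNA network; candidates that gain no
edge are excluded, so node counts can shrink relative to the mapped
differential-expression lists.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from fractions import Fraction
from functools import lru_cache
from typing import Iterable, Sequence

import networkx as nx

from cernet.io_formats import Interaction, InteractionSet

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class MirandaRecord:
    """One miRanda prediction: alignment score and duplex energy (kcal/mol)."""

    mirna_id: str
    lncrna_id: str
    score: float
    energy: float


def filter_miranda(records: Iterable[MirandaRecord], score_min: float = 160.0,
                   energy_max: float = -20.0,
                   source_tag: str = "miranda") -> InteractionSet:
    """Keep predictions with score > score_min and energy < energy_max.

    Both inequalities are strict; records exactly on a threshold are
    removed. Survivors are emitted as deduplicated miRNA->lncRNA
    interactions.
    """
    kept = [Interaction(r.mirna_id, r.lncrna_id, "lncRNA", source_tag)
            for r in records if r.score > score_min and r.energy < energy_max]
    return InteractionSet(kept)


def merge_triple(mi_mrna: InteractionSet,
                 mi_lncrna_sets: Sequence[InteractionSet]) -> nx.Graph:
    """Merge miRNA->mRNA and miRNA->lncRNA sets into the global triple network.

    Nodes carry a ``kind`` attribute in {miRNA, lncRNA, mRNA}; edges join
    a miRNA to a non-miRNA only. Duplicate pairs across sources collapse.
    An id that appears as both an mRNA and a lncRNA target is an error.
    """
    mrna_ids = mi_mrna.targets()
    lnc_ids: set[str] = set()
    for s in mi_lncrna_sets:
        lnc_ids |= s.targets()
    clash = mrna_ids & lnc_ids
    if clash:
        raise ValueError(f"ids appear as both mRNA and lncRNA: {sorted(clash)[:5]}")
    mirna_clash = (mrna_ids | lnc_ids) & (
        mi_mrna.regulators() | set().union(*(s.regulators() for s in mi_lncrna_sets))
        if mi_lncrna_sets else mi_mrna.regulators())
    if mirna_clash:
        raise ValueError(f"ids appear as both miRNA and target: {sorted(mirna_clash)[:5]}")

    net = nx.Graph()
    n_mrna_pairs = 0
    for rec in mi_mrna.records:
        net.add_node(rec.regulator_id, kind="miRNA")
        net.add_node(rec.target_id, kind="mRNA")
        net.add_edge(rec.regulator_id, rec.target_id)
        n_mrna_pairs += 1
    lnc_pairs: set[tuple[str, str]] = set()
    per_source = []
    for s in mi_lncrna_sets:
        per_source.append(len(s))
        for rec in s.records:
            net.add_node(rec.regulator_id, kind="miRNA")
            net.add_node(rec.target_id, kind="lncRNA")
            net.add_edge(rec.regulator_id, rec.target_id)
            lnc_pairs.add((rec.regulator_id, rec.target_id))
    net.graph["report"] = {
        "mi_mrna_pairs": n_mrna_pairs,
        "mi_lncrna_pairs_per_source": per_source,
        "mi_lncrna_pairs_merged": len(lnc_pairs),
        "n_mirna": sum(1 for _, k in net.nodes(data="kind") if k == "miRNA"),
        "n_mrna": sum(1 for _, k in net.nodes(data="kind") if k == "mRNA"),
        "n_lncrna": sum(1 for _, k in net.nodes(data="kind") if k == "lncRNA"),
        "n_edges": net.number_of_edges(),
    }
    logger.info("merged triple network: %s", net.graph["report"])
    return net


def map_de_genes(net: nx.Graph, de_mrnas: Iterable[str],
                 de_lncrnas: Iterable[str]) -> tuple[list[str], list[str]]:
    """Intersect differential-expression lists with the network's node classes.

    Returns sorted (mapped mRNA ids, mapped lncRNA ids); mapped and
    unmapped counts are logged.
    """
    kinds = dict(net.nodes(data="kind"))
    de_mrnas, de_lncrnas = list(de_mrnas), list(de_lncrnas)
    mm = sorted(g for g in set(de_mrnas) if kinds.get(g) == "mRNA")
    ml = sorted(g for g in set(de_lncrnas) if kinds.get(g) == "lncRNA")
    logger.info("mapped %d/%d DE mRNAs and %d/%d DE lncRNAs into the network",
                len(mm), len(set(de_mrnas)), len(ml), len(set(de_lncrnas)))
    return mm, ml


@lru_cache(maxsize=200_000)
def hypergeom_p(m: int, t: int, n: int, r: int) -> float:
    """Upper-tail hypergeometric probability P(X >= r).

    Probability that at least r of n draws without replacement from m
    items fall among the t marked items. Computed with exact integer
    arithmetic (the tail sum is an integer ratio converted to float via
    Fraction), so the result is correctly rounded for any network-scale
    input.
    """
    if not (0 <= r <= min(t, n)):
        raise ValueError(f"need 0 <= r <= min(t, n); got m={m} t={t} n={n} r={r}")
    if t > m or n > m:
        raise ValueError(f"need t, n <= m; got m={m} t={t} n={n}")
    if r == 0:
        return 1.0
    num = sum(math.comb(t, i) * math.comb(m - t, n - i)
              for i in range(r, min(t, n) + 1))
    return float(Fraction(num, math.comb(m, n)))


def build_cerna_network(net: nx.Graph, mapped_mrnas: Sequence[str],
                        mapped_lncrnas: Sequence[str], m_rule: str = "network",
                        alpha: float = 0.01,
                        m_value: int | None = None) -> nx.Graph:
    """Extract the bipartite ceRNA lncRNA-mRNA network from the triple network.

    For every (lncRNA, mRNA) candidate pair, t and n are the sizes of
    the mRNA's and lncRNA's miRNA neighborhoods in the full triple
    network, r their overlap, and m the miRNA universe size given by
    ``m_rule``: "network" (default) uses the number of distinct miRNAs
    in the triple network; "fixed" uses ``m_value``. An edge is added
    iff r >= 1 and p < alpha; candidates left without edges do not
    appear as nodes.
    """
    if not mapped_mrnas or not mapped_lncrnas:
        raise ValueError("mapped mRNA and lncRNA lists must be nonempty")
    if m_rule == "network":
        m = sum(1 for _, k in net.nodes(data="kind") if k == "miRNA")
    elif m_rule == "fixed":
        if m_value is None:
            raise ValueError("m_rule='fixed' requires m_value")
        m = int(m_value)
    else:
        raise ValueError(f"unknown m_rule {m_rule!r}")

    neigh = {g: set(net.neighbors(g)) for g in (*mapped_mrnas, *mapped_lncrnas)}
    cerna = nx.Graph()
    for lnc in mapped_lncrnas:
        n_l = len(neigh[lnc])
        for mr in mapped_mrnas:
            t_m = len(neigh[mr])
            if m < max(t_m, n_l):
                raise ValueError(
                    f"m_rule gives m={m} < max(t={t_m}, n={n_l}) for ({lnc}, {mr})"
                )
            shared = neigh[lnc] & neigh[mr]
            r = len(shared)
            if r < 1:
                continue
            p = hypergeom_p(m, t_m, n_l, r)
            if p < alpha:
                cerna.add_node(lnc, kind="lncRNA")
                cerna.add_node(mr, kind="mRNA")
                cerna.add_edge(lnc, mr, m=m, t=t_m, n=n_l, r=r,
                               shared_ids=tuple(sorted(shared)), p=p)
    rep = {
        "n_lncrna": sum(1 for _, k in cerna.nodes(data="kind") if k == "lncRNA"),
        "n_mrna": sum(1 for _, k in cerna.nodes(data="kind") if k == "mRNA"),
        "n_edges": cerna.number_of_edges(),
        "m": m,
        "alpha": alpha,
    }
    cerna.graph["report"] = rep
    logger.info("ceRNA network: %s", rep)
    return cerna
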