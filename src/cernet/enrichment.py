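"""Hypergeometric over-representation analysis against gene-set collections.

For a query list of n_q genes inside a universe of N genes, a set with
K members in the universe and k members in the query is scored with
the upper-tail hypergeometric probability P(X >= k) — equivalent to a
one-sided Fisher exact test on the 2x2 table. Benjamini-Hochberg
q-values are reported alongside the raw p.
"""

from __future__ import annotations

import logging
from typing import Iterable

import pandas as pd

from cernet.cerna_network import hypergeom_p
from cernet.diffexpr import bh_adjust
from cernet.io_formats import GeneSetCollection

logger = logging.getLogger(__name__)


def enrich(query: Iterable[str], sets: GeneSetCollection,
           universe: Iterable[str], alpha: float = 0.05) -> pd.DataFrame:
    """Over-representation of a query gene list against each gene set.

    Query genes outside the universe are dropped (count logged); each
    set is intersected with the universe first. Returns a DataFrame
    sorted ascending by p with columns set_name, k, K, n_q, N, p, q,
    significant (p < alpha, strict).
    """
    universe = set(universe)
    if not universe:
        raise ValueError("universe is empty")
    query = set(query)
    dropped = query - universe
    if dropped:
        logger.info("enrich: %d query genes outside universe dropped", len(dropped))
    query &= universe
    N, n_q = len(universe), len(query)

    rows = []
    for name, (_, members) in sets.sets.items():
        in_univ = set(members) & universe
        K = len(in_univ)
        if K == 0:
            continue
        k = len(in_univ & query)
        p = hypergeom_p(N, K, n_q, k) if k >= 1 else 1.0
        rows.append((name, k, K, n_q, N, p))
    df = pd.DataFrame(rows, columns=["set_name", "k", "K", "n_q", "N", "p"])
    if len(df):
        df["q"] = bh_adjust(df["p"].to_numpy())
        df["significant"] = df["p"] < alpha
        df = df.sort_values(["p", "set_name"], kind="mergesort",
                            ignore_index=True)
    else:
        df["q"] = pd.Series(dtype=float)
        df["significant"] = pd.Series(dtype=bool)
    return df
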