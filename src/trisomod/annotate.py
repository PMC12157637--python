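"""Over-representation analysis of module top genes against gene-set collections.

For each module the top fraction of genes by absolute loading (default 5%,
ceiling count, boundary ties broken by gene identifier) is tested for overlap
with every gene set via the one-sided hypergeometric upper tail, with BH
correction across all (module, set) pairs of a run. The universe is the set
of quantified genes.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .differential import benjamini_hochberg
from .errors import InvalidInputError

logger = logging.getLogger(__name__)


def top_genes(Z: pd.DataFrame, lv: str, frac: float = 0.05) -> set[str]:
    """The ceil(frac * g) genes with largest |loading| in module ``lv``.

    Ties are broken by lexicographic gene identifier so the selection is
    deterministic and independent of input row order.
    """
    if not 0.0 < frac <= 1.0:
        raise InvalidInputError("frac must lie in (0,1]")
    col = Z[lv]
    n_top = math.ceil(frac * len(col))
    ranking = pd.DataFrame({"neg_abs": -col.abs(), "gene": col.index.astype(str)})
    ranking = ranking.sort_values(["neg_abs", "gene"], kind="stable")
    return set(ranking.index[:n_top])


def ora_test(query: set[str], gene_set: set[str], universe: set[str]) -> dict:
    """Hypergeometric upper-tail over-representation of ``query`` in ``gene_set``.

    p = P(X >= overlap) for X ~ Hypergeom(universe, set, query); the gene set
    is intersected with the universe before testing.
    """
    if not universe:
        raise InvalidInputError("universe must be non-empty")
    universe = set(universe)
    if not set(query) <= universe:
        raise InvalidInputError("query must be a subset of the universe")
    members = set(gene_set) & universe
    overlap = len(set(query) & members)
    M, K, N = len(universe), len(members), len(query)
    p = float(hypergeom.sf(overlap - 1, M, K, N))
    fold = (overlap / N) / (K / M) if N > 0 and K > 0 else float("nan")
    return {"overlap_count": overlap, "query_size": N, "set_size": K,
            "universe_size": M, "fold_enrichment": fold, "pvalue": min(p, 1.0)}


def annotate_modules(Z: pd.DataFrame, gene_sets: dict[str, list[str]],
                     universe: set[str] | None = None, frac: float = 0.05,
                     fdr_threshold: float = 0.05) -> pd.DataFrame:
    """ORA of every module's top genes against every gene set.

    Returns one row per (lv, gene_set) with overlap counts, fold enrichment,
    hypergeometric p, BH FDR across all pairs, and a significance flag. Sets
    with no gene in the universe are skipped with a log record.
    """
    if not gene_sets:
        raise InvalidInputError("gene_sets must be non-empty")
    universe = set(Z.index.astype(str)) if universe is None else set(universe)
    usable = {}
    for name, members in gene_sets.items():
        inter = set(members) & universe
        if not inter:
            logger.info("gene set %s skipped: no member in universe", name)
            continue
        usable[name] = inter
    rows = []
    for lv in Z.columns:
        query = top_genes(Z, lv, frac) & universe
        for name, members in usable.items():
            row = ora_test(query, members, universe)
            row.update({"lv": lv, "gene_set": name})
            rows.append(row)
    cols = ["lv", "gene_set", "overlap_count", "query_size", "set_size",
            "universe_size", "fold_enrichment", "pvalue"]
    table = pd.DataFrame(rows, columns=cols)
    if len(table):
        table["fdr"] = benjamini_hochberg(table["pvalue"].to_numpy())
    else:
        table["fdr"] = pd.Series(dtype=float)
    table["significant"] = table["fdr"] < fdr_threshold
    return table
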