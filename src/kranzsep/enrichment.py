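"""Functional-category enrichment with hierarchical (dot-path) categories."""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .cross_study import fisher_two_sided_p
from .diffexpr import bh_fdr


def expand_ancestors(category: str) -> list[str]:
    """A dot-path category and all its parents, most specific first.

    ``"protein.synthesis.ribosomal"`` contributes to itself, to
    ``"protein.synthesis"`` and to ``"protein"``.
    """
    parts = category.split(".")
    return [".".join(parts[: i + 1]) for i in range(len(parts) - 1, -1, -1)]


def category_members(category_map: pd.DataFrame, universe: set) -> dict[str, set]:
    """Gene sets per category, with genes propagated to parent categories.

    ``category_map`` has columns (gene_id, category); a gene may carry
    several categories.  Only universe genes count.
    """
    members: dict[str, set] = {}
    for gene_id, category in category_map[["gene_id", "category"]].itertuples(index=False):
        if gene_id not in universe:
            continue
        for cat in expand_ancestors(str(category)):
            members.setdefault(cat, set()).add(gene_id)
    return members


def fisher_enrichment(
    gene_set,
    category_map: pd.DataFrame,
    universe,
    min_category: int = 1,
) -> pd.DataFrame:
    """Two-sided Fisher enrichment of a gene list in every category.

    For each category with at least ``min_category`` universe members:
    k = |set ∩ category|, K = category size, n = set size, N = universe
    size; p from the Fisher exact test on the 2x2 table, odds ratio by
    conditional MLE, BH FDR across all tested categories of this query.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    gene_set = set(gene_set)
    stray = gene_set - universe
    if stray:
        raise ValueError(f"gene set not contained in universe, e.g. {sorted(stray)[:3]}")
    members = category_members(category_map, universe)
    n = len(gene_set)
    N = len(universe)
    rows = []
    for cat in sorted(members):
        cat_genes = members[cat]
        K = len(cat_genes)
        if K < min_category:
            continue
        k = len(gene_set & cat_genes)
        table = np.array([[k, n - k], [K - k, N - n - K + k]], dtype=np.int64)
        p = fisher_two_sided_p(table)
        odds = float(stats.contingency.odds_ratio(table, kind="conditional").statistic)
        rows.append(
            {"category": cat, "k": k, "K": K, "n": n, "N": N, "odds_ratio": odds, "p_value": p}
        )
    out = pd.DataFrame(rows, columns=["category", "k", "K", "n", "N", "odds_ratio", "p_value"])
    if len(out):
        out["fdr"] = bh_fdr(out["p_value"].to_numpy())
    else:
        out["fdr"] = pd.Series(dtype=float)
    return out
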