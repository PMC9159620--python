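"""Over-representation analysis with fold-enrichment/count filtering.

Given a query gene list (e.g. genes with down-regulated translation
efficiency), a background universe and a gene-set annotation, each term is
scored by the hypergeometric upper tail of its overlap with the query and
by fold enrichment FE = (k/n)/(K/N).  Results from two annotation sources
can be intersected and ranked to mimic the common practice of keeping only
terms that replicate across enrichment tools, and the per-gene frequency
among the top terms identifies genes recurrently implicated.
"""
from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .containers import AnnotationSet
from .diffexpr import bh_adjust

logger = logging.getLogger(__name__)

DEFAULT_MIN_FOLD = 1.2
DEFAULT_MIN_COUNT = 15
DEFAULT_TOP = 10

_COLUMNS = ["term_id", "term_name", "k", "n", "K", "N", "fold_enrichment", "p", "q", "genes"]


def enrich(query: list[str], universe: list[str], annotation: AnnotationSet) -> pd.DataFrame:
    """Hypergeometric over-representation of annotation terms in a query list.

    For a term with K members in the universe of size N and k members among
    the n query genes, p = P(X >= k) for X ~ Hypergeometric(N, K, n).
    Annotation genes outside the universe are dropped (the count is logged).
    Only terms with at least one query member are reported; BH adjustment is
    applied across the reported terms.
    """
    if not query or not universe:
        raise ValueError("query and universe must be nonempty")
    uni = set(universe)
    qset = set(query)
    if not qset <= uni:
        raise ValueError("query genes must be a subset of the universe")
    N = len(uni)
    n = len(qset)
    rows = []
    dropped = 0
    for term_id, (name, members) in annotation:
        mem = set(members)
        dropped += len(mem - uni)
        mem &= uni
        K = len(mem)
        hits = sorted(mem & qset)
        k = len(hits)
        if k == 0:
            continue
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        fe = (k / n) / (K / N)
        rows.append((term_id, name, k, n, K, N, fe, min(p, 1.0), np.nan, hits))
    if dropped:
        logger.info("dropped %d annotation gene memberships outside the universe", dropped)
    table = pd.DataFrame(rows, columns=_COLUMNS)
    if len(table):
        table["q"] = bh_adjust(table["p"].to_numpy())
        table = table.sort_values(["p", "term_id"], kind="mergesort").reset_index(drop=True)
    return table


def filter_terms(
    table: pd.DataFrame,
    min_fold: float = DEFAULT_MIN_FOLD,
    min_count: int = DEFAULT_MIN_COUNT,
) -> pd.DataFrame:
    """Keep terms with fold enrichment strictly above ``min_fold`` and
    query-member count ``k >= min_count`` (defaults 1.2 and 15)."""
    if min_fold < 0 or min_count < 0:
        raise ValueError("thresholds must be nonnegative")
    if not len(table):
        return table.copy()
    keep = (table["fold_enrichment"] > min_fold) & (table["k"] >= min_count)
    return table.loc[keep].reset_index(drop=True)


def intersect_top(
    table_a: pd.DataFrame,
    table_b: pd.DataFrame,
    k: int = DEFAULT_TOP,
) -> pd.DataFrame:
    """Top-k terms present in both enrichment tables.

    Terms are matched by id and ranked by the worse (larger) of the two
    p-values ascending, ties broken by larger fold enrichment (the larger of
    the two) then lexical term id.  Member gene lists are the union of the
    two sources' query hits.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if not len(table_a) or not len(table_b):
        return pd.DataFrame(
            columns=["term_id", "term_name", "worse_p", "p_a", "p_b", "fold_enrichment", "genes"]
        )
    merged = table_a.merge(table_b, on="term_id", suffixes=("_a", "_b"))
    if not len(merged):
        return pd.DataFrame(
            columns=["term_id", "term_name", "worse_p", "p_a", "p_b", "fold_enrichment", "genes"]
        )
    out = pd.DataFrame(
        {
            "term_id": merged["term_id"],
            "term_name": merged["term_name_a"],
            "worse_p": np.maximum(merged["p_a"], merged["p_b"]),
            "p_a": merged["p_a"],
            "p_b": merged["p_b"],
            "fold_enrichment": np.maximum(merged["fold_enrichment_a"], merged["fold_enrichment_b"]),
            "genes": [
                sorted(set(ga) | set(gb))
                for ga, gb in zip(merged["genes_a"], merged["genes_b"])
            ],
        }
    )
    out = out.sort_values(
        ["worse_p", "fold_enrichment", "term_id"],
        ascending=[True, False, True],
        kind="mergesort",
    ).reset_index(drop=True)
    return out.head(k).reset_index(drop=True)


def term_frequency(top_terms: pd.DataFrame, gene: str) -> int:
    """Number of terms whose member gene list contains ``gene``."""
    if not len(top_terms):
        return 0
    return int(sum(gene in genes for genes in top_terms["genes"]))
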