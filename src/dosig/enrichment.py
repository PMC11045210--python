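"""Disease-term over-representation analysis and DEG filtering.

A query gene list (the DEGs) is tested against every disease term with a
one-sided hypergeometric (upper-tail) test inside a fixed gene universe;
term p-values are Benjamini-Hochberg adjusted and the DEG list is
restricted to genes belonging to at least one significantly enriched term.
"""

from __future__ import annotations

import logging
from pathlib import Path

import networkx as nx
import pandas as pd
from scipy import stats

from .diffexpr import bh_adjust
from .io import AnnotationMap

logger = logging.getLogger(__name__)

RESULT_COLUMNS = [
    "term_id", "term_name", "k", "K", "n_query", "N", "p_raw", "p_adj", "member_genes",
]


def hypergeom_upper_tail(k: int, K: int, n_query: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n_query).

    ``k`` overlap, ``K`` term size, ``n_query`` query size, ``N`` universe.
    """
    for name, v in (("k", k), ("K", K), ("n_query", n_query), ("N", N)):
        if int(v) != v or v < 0:
            raise ValueError(f"{name} must be a non-negative integer, got {v!r}")
    k, K, n_query, N = int(k), int(K), int(n_query), int(N)
    if K > N or n_query > N or k > min(K, n_query):
        raise ValueError(
            f"inconsistent arguments k={k}, K={K}, n_query={n_query}, N={N}"
        )
    if k == 0:
        return 1.0
    # sf(k-1) is the upper tail at k; scipy evaluates in log space internally
    return float(stats.hypergeom.sf(k - 1, N, K, n_query))


def propagate_annotations(amap: AnnotationMap) -> AnnotationMap:
    """Propagate gene annotations up the ``is_a`` DAG.

    After propagation each term carries the union of its own genes and all
    genes annotated to its descendants. Terms appearing only in edges
    (external parents without direct annotations) are ignored.
    """
    if not amap.dag_edges:
        return AnnotationMap(dict(amap.term_to_genes), dict(amap.term_names), amap.dag_edges)
    graph = nx.DiGraph(list(amap.dag_edges))  # child -> parent
    if not nx.is_directed_acyclic_graph(graph):
        cycle = nx.find_cycle(graph)
        raise ValueError(f"is_a relation contains a cycle: {cycle}")
    out: dict[str, set[str]] = {t: set(g) for t, g in amap.term_to_genes.items()}
    for term in out:
        if term not in graph:
            continue
        for desc in nx.ancestors(graph, term):  # nodes with a path *to* term
            if desc in amap.term_to_genes:
                out[term] |= amap.term_to_genes[desc]
    return AnnotationMap(
        {t: frozenset(g) for t, g in out.items()}, dict(amap.term_names), amap.dag_edges
    )


def enrich(
    query,
    amap: AnnotationMap,
    universe,
    min_term_size: int = 2,
    p_cut: float = 0.05,
) -> pd.DataFrame:
    """Hypergeometric over-representation of ``query`` in every term.

    Returns one row per tested term (columns :data:`RESULT_COLUMNS`),
    sorted by adjusted p then term id. ``p_cut`` is carried by callers;
    all tested terms are returned regardless of significance.
    """
    universe = frozenset(universe)
    if not universe:
        raise ValueError("empty universe")
    query = frozenset(query)
    if not query:
        logger.info("empty query gene list: no enrichment computed")
        return pd.DataFrame(columns=RESULT_COLUMNS)
    stray = query - universe
    if stray:
        raise ValueError(f"query genes outside the universe: {sorted(stray)[:5]}")

    N = len(universe)
    n_query = len(query)
    rows = []
    for term, genes in amap.term_to_genes.items():
        in_universe = genes & universe
        K = len(in_universe)
        if K < min_term_size:
            continue
        members = in_universe & query
        k = len(members)
        p = hypergeom_upper_tail(k, K, n_query, N)
        rows.append((term, amap.name_of(term), k, K, n_query, N, p, members))
    if not rows:
        return pd.DataFrame(columns=RESULT_COLUMNS)
    df = pd.DataFrame(
        rows, columns=["term_id", "term_name", "k", "K", "n_query", "N", "p_raw", "member_genes"]
    )
    df["p_adj"] = bh_adjust(df["p_raw"].to_numpy())
    df["member_genes"] = df["member_genes"].map(lambda s: frozenset(s))
    df = df[RESULT_COLUMNS].sort_values(["p_adj", "term_id"], kind="mergesort")
    return df.reset_index(drop=True)


def filter_genes_by_enrichment(deg_genes, results: pd.DataFrame, p_cut: float = 0.05) -> list[str]:
    """Subsequence of ``deg_genes`` annotated to >= 1 significant term."""
    if results is None or len(results) == 0:
        return []
    significant = results[results["p_adj"] < p_cut]
    keep: set[str] = set()
    for members in significant["member_genes"]:
        keep |= set(members)
    return [g for g in deg_genes if g in keep]


def write_enrichment_tsv(results: pd.DataFrame, path) -> None:
    out = results.copy()
    out["member_genes"] = out["member_genes"].map(lambda s: ",".join(sorted(s)))
    out.to_csv(Path(path), sep="\t", index=False)
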