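"""Over-representation testing and kappa-similarity enrichment networks.

Raw p-values are upper-tail hypergeometric probabilities P(X >= k) for an
overlap of k between a query gene set and a term's annotated set within a
common universe; multiple testing is corrected with Benjamini-Hochberg by
default (Bonferroni available).  Significant terms become network nodes,
connected when the chance-corrected agreement (Cohen's kappa) of their
gene memberships exceeds a threshold (default 0.3, strict).
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests


@dataclass
class EnrichmentResult:
    term: str
    overlap: int  # k
    term_size: int  # K
    query_size: int  # n
    universe_size: int  # N
    p_raw: float
    p_corrected: float
    significant: bool
    genes: frozenset


def hypergeom_enrich(
    query: set[str],
    terms: dict[str, set[str]],
    universe: set[str],
    alpha: float = 0.01,
    method: str = "fdr_bh",
) -> list[EnrichmentResult]:
    """Hypergeometric over-representation of ``query`` in each term's gene set."""
    if not query or not universe:
        raise ValueError("query and universe must be non-empty")
    if not query <= universe:
        raise ValueError(f"query genes outside universe: {sorted(query - universe)[:5]}")
    N, n = len(universe), len(query)
    names, raw, meta = [], [], []
    for term, genes in terms.items():
        genes = genes & universe
        k = len(query & genes)
        K = len(genes)
        # P(X >= k) for X ~ Hypergeom(N, K, n)
        p = float(hypergeom.sf(k - 1, N, K, n))
        names.append(term)
        raw.append(min(p, 1.0))
        meta.append((k, K, query & genes))
    if not names:
        return []
    _, corrected, _, _ = multipletests(raw, method=method)
    corrected = [max(c, r) for c, r in zip(corrected, raw)]
    results = [
        EnrichmentResult(
            term=t,
            overlap=k,
            term_size=K,
            query_size=n,
            universe_size=N,
            p_raw=r,
            p_corrected=c,
            significant=c < alpha,
            genes=frozenset(g),
        )
        for t, r, c, (k, K, g) in zip(names, raw, corrected, meta)
    ]
    return sorted(results, key=lambda r: (r.p_raw, r.term))


def kappa_similarity(term_a: set[str], term_b: set[str], universe: set[str]) -> float:
    """Cohen's kappa of two gene-membership indicators over the universe.

    Can be negative for worse-than-chance agreement; degenerate marginals
    (expected agreement 1) give 0 by convention.
    """
    if not term_a <= universe or not term_b <= universe:
        raise ValueError("term gene sets must be subsets of the universe")
    N = len(universe)
    a = len(term_a & term_b)
    b = len(term_a - term_b)
    c = len(term_b - term_a)
    d = N - a - b - c
    p_o = (a + d) / N
    p_e = ((a + b) * (a + c) + (c + d) * (b + d)) / (N * N)
    if p_e == 1.0:
        return 0.0
    return (p_o - p_e) / (1.0 - p_e)


def build_enrichment_network(
    results: list[EnrichmentResult],
    terms: dict[str, set[str]],
    universe: set[str],
    kappa_min: float = 0.3,
) -> tuple[nx.Graph, pd.DataFrame, pd.DataFrame]:
    """Network of significant terms linked when kappa strictly exceeds
    ``kappa_min``; negative kappas are floored at 0 on edge weights.

    Returns (graph, node table, edge table).
    """
    if not results:
        raise ValueError("no enrichment results supplied")
    sig = [r for r in results if r.significant]
    graph = nx.Graph()
    for r in sig:
        graph.add_node(r.term, overlap=r.overlap, p_corrected=r.p_corrected)
    names = sorted(graph.nodes)
    for i, t1 in enumerate(names):
        for t2 in names[i + 1 :]:
            kap = kappa_similarity(terms[t1] & universe, terms[t2] & universe, universe)
            if kap > kappa_min:
                graph.add_edge(t1, t2, kappa=max(kap, 0.0))
    nodes = pd.DataFrame(
        [(t, d["overlap"], d["p_corrected"]) for t, d in graph.nodes(data=True)],
        columns=["term", "overlap", "p_corrected"],
    ).sort_values("term", ignore_index=True)
    edges = pd.DataFrame(
        [(u, v, d["kappa"]) for u, v, d in graph.edges(data=True)],
        columns=["term_a", "term_b", "kappa"],
    )
    if not edges.empty:
        swap = edges["term_a"] > edges["term_b"]
        edges.loc[swap, ["term_a", "term_b"]] = edges.loc[swap, ["term_b", "term_a"]].values
        edges = edges.sort_values(["term_a", "term_b"], ignore_index=True)
    return graph, nodes, edges


def results_table(results: list[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (r.term, r.overlap, r.term_size, r.query_size, r.universe_size, r.p_raw, r.p_corrected, r.significant)
            for r in results
        ],
        columns=["term", "overlap", "term_size", "query_size", "universe_size", "p_raw", "p_corrected", "significant"],
    )
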