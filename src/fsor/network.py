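"""Interaction-network screens: connectivity filter and MCC hub ranking.

Consumes a STRING-export-style edge list (two gene columns plus a combined
confidence score), keeps candidate genes with at least one interaction
among themselves, and ranks hubs by maximal clique centrality
MCC(v) = sum over maximal cliques C containing v of (|C| - 1)!.
Maximal cliques are enumerated exactly (Bron-Kerbosch with pivoting, via
networkx); isolated nodes score 0 by convention.
"""

from __future__ import annotations

import logging
import math

import networkx as nx
import pandas as pd

__all__ = [
    "read_interaction_edges",
    "connected_candidates",
    "mcc_scores",
    "top_central",
]

logger = logging.getLogger(__name__)


def read_interaction_edges(
    path,
    score_cutoff: float = 0.0,
    score_scale: str = "auto",
) -> nx.Graph:
    """Load an undirected scored edge list from a TSV file.

    The score column is auto-detected as 0-1000 when any value exceeds 1
    and divided down to [0, 1] (override with ``score_scale`` = 'unit' or
    'thousand').  Self-loops are dropped with a warning and symmetric
    duplicates collapse to a single edge.  Edges below ``score_cutoff``
    (on the unit scale) are discarded.
    """
    df = pd.read_csv(path, sep="\t", dtype={0: str, 1: str})
    if df.shape[1] < 3:
        raise ValueError("edge list needs two node columns and a score column")
    nodes1, nodes2 = df.iloc[:, 0], df.iloc[:, 1]
    scores = pd.to_numeric(df.iloc[:, 2], errors="raise").astype(float)
    if score_scale == "auto":
        score_scale = "thousand" if (scores > 1.0).any() else "unit"
    if score_scale == "thousand":
        scores = scores / 1000.0
    elif score_scale != "unit":
        raise ValueError(f"unknown score scale: {score_scale!r}")
    if ((scores < 0) | (scores > 1)).any():
        raise ValueError("combined scores outside [0, 1] after scaling")

    graph = nx.Graph()
    for a, b, s in zip(nodes1, nodes2, scores):
        if a == b:
            logger.warning("self-loop on %r dropped", a)
            continue
        if s < score_cutoff:
            continue
        if graph.has_edge(a, b):
            graph[a][b]["combined_score"] = max(graph[a][b]["combined_score"], s)
        else:
            graph.add_edge(a, b, combined_score=float(s))
    return graph


def connected_candidates(graph: nx.Graph, genes) -> set[str]:
    """Genes with at least one edge inside the subgraph induced on ``genes``."""
    genes = list(genes)
    if not genes:
        raise ValueError("empty gene set")
    sub = graph.subgraph([g for g in genes if g in graph])
    return {g for g in sub.nodes if sub.degree(g) >= 1}


def mcc_scores(graph: nx.Graph, max_nodes: int = 5000) -> pd.DataFrame:
    """Maximal clique centrality per node.

    MCC(v) = sum over maximal cliques C with v in C of (|C| - 1)!.
    Exact enumeration; refuse graphs above ``max_nodes`` nodes, where the
    clique count can explode.
    """
    if graph.number_of_nodes() > max_nodes:
        raise ValueError(
            f"graph has {graph.number_of_nodes()} nodes (> {max_nodes}); "
            "exact clique enumeration refused"
        )
    scores = {v: 0 for v in graph.nodes}
    for clique in nx.find_cliques(graph):
        if len(clique) < 2:
            continue  # isolated nodes score 0 by convention
        contrib = math.factorial(len(clique) - 1)
        for v in clique:
            scores[v] += contrib
    out = pd.DataFrame(
        {"node": list(scores), "mcc": [scores[v] for v in scores]}
    ).sort_values(["mcc", "node"], ascending=[False, True], kind="stable")
    out["rank"] = range(1, len(out) + 1)
    return out.reset_index(drop=True)


def top_central(
    scores: pd.DataFrame, k: int, predictors=None
) -> tuple[list[str], dict]:
    """Top-k nodes by MCC (ties broken lexicographically).

    When a ``predictors`` set is supplied, also reports how many of them
    fall inside the central set ("x out of y predictors are central").
    """
    n = len(scores)
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}]")
    ordered = scores.sort_values(
        ["mcc", "node"], ascending=[False, True], kind="stable"
    )
    central = ordered["node"].head(k).tolist()
    report: dict = {"k": k}
    if predictors is not None:
        predictors = list(predictors)
        overlap = [g for g in predictors if g in set(central)]
        report.update(
            n_predictors=len(predictors),
            n_central_predictors=len(overlap),
            central_predictors=sorted(overlap),
        )
    return central, report
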