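"""Target screening and protein-interaction network topology.

Implements the drug-disease target funnel: relevance-score filtering of
disease gene lists, exact Venn accounting of drug-target versus disease-gene
sets, construction of an undirected simple graph from a STRING-style scored
edge list (combined score strictly above a confidence threshold, default
0.4), removal of isolated nodes, per-node topology metrics and core-hub
selection by the "degree greater than twice the median" rule.

Metric conventions follow the Cytoscape NetworkAnalyzer definitions:

* degree — number of incident edges;
* closeness centrality — reciprocal of the mean shortest-path length to the
  nodes reachable from n (unweighted paths, computed within components);
* betweenness centrality — fraction of shortest paths passing through n,
  normalized by 2/((N-1)(N-2));
* topological coefficient — mean of J(n, m)/degree(n) over all nodes m that
  share at least one neighbor with n, where J(n, m) is the number of common
  neighbors plus one when n-m is itself an edge; 0 when no node shares a
  neighbor with n.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .errors import DomainError, FormatError

__all__ = [
    "IntersectionResult",
    "filter_by_relevance",
    "intersect_sets",
    "load_edge_list",
    "graph_from_edges",
    "remove_isolated_nodes",
    "node_metrics",
    "topological_coefficient",
    "average_degree",
    "select_core_targets",
    "top_hubs",
]


def _fold(symbols) -> set[str]:
    return {str(s).strip().casefold() for s in symbols if str(s).strip()}


@dataclass(frozen=True)
class IntersectionResult:
    """Exact Venn accounting of two case-folded symbol sets."""

    shared: frozenset
    left_only: frozenset
    right_only: frozenset

    @property
    def sizes(self) -> dict[str, int]:
        return {
            "shared": len(self.shared),
            "left_only": len(self.left_only),
            "right_only": len(self.right_only),
        }


def filter_by_relevance(scored, threshold: float = 10.0) -> set[str]:
    """Symbols whose relevance score is strictly greater than the threshold.

    ``scored`` is a mapping symbol -> score or an iterable of (symbol, score)
    pairs (e.g. a GeneCards-style scored disease-gene list).
    """
    if threshold < 0:
        raise DomainError("relevance threshold must be >= 0")
    items = scored.items() if hasattr(scored, "items") else scored
    return {str(s).strip().casefold() for s, score in items if float(score) > threshold}


def intersect_sets(left, right) -> IntersectionResult:
    """Venn decomposition of drug-target and disease-gene symbol sets."""
    l, r = _fold(left), _fold(right)
    shared = l & r
    return IntersectionResult(
        shared=frozenset(shared),
        left_only=frozenset(l - shared),
        right_only=frozenset(r - shared),
    )


def graph_from_edges(edges, min_score: float = 0.4) -> nx.Graph:
    """Build a simple undirected graph from (node_a, node_b, score) triples.

    Scores on a 0-1000 scale (any score > 1) are divided by 1000.  Edges with
    score strictly greater than ``min_score`` are kept; A-B/B-A duplicates
    collapse keeping the maximum score; self-loops are dropped.
    """
    triples = [(str(a).strip(), str(b).strip(), float(s)) for a, b, s in edges]
    if triples and max(s for _, _, s in triples) > 1.0:
        triples = [(a, b, s / 1000.0) for a, b, s in triples]
    g = nx.Graph()
    for a, b, s in triples:
        if a == b:
            continue
        if s > min_score:
            if g.has_edge(a, b):
                g[a][b]["score"] = max(g[a][b]["score"], s)
            else:
                g.add_edge(a, b, score=s)
    return g


def load_edge_list(path, min_score: float = 0.4) -> nx.Graph:
    """Read a STRING-style TSV (node_a, node_b, combined_score) into a graph."""
    triples = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter="\t")
        for lineno, row in enumerate(reader, start=1):
            if not row or all(not c.strip() for c in row):
                continue
            if len(row) < 3:
                raise FormatError(f"{path}: line {lineno} has fewer than 3 columns")
            if lineno == 1 and not _is_number(row[2]):
                continue  # header line
            if not _is_number(row[2]):
                raise FormatError(f"{path}: malformed score at line {lineno}: {row[2]!r}")
            triples.append((row[0], row[1], float(row[2])))
    return graph_from_edges(triples, min_score=min_score)


def _is_number(s: str) -> bool:
    try:
        float(s)
        return True
    except ValueError:
        return False


def remove_isolated_nodes(g: nx.Graph) -> nx.Graph:
    """Copy of the graph without degree-zero nodes."""
    out = g.copy()
    out.remove_nodes_from(list(nx.isolates(out)))
    return out


def topological_coefficient(g: nx.Graph) -> dict:
    """NetworkAnalyzer-style topological coefficient per node."""
    tc = {}
    neighbors = {n: set(g.neighbors(n)) for n in g.nodes}
    for n in g.nodes:
        nbrs = neighbors[n]
        if not nbrs:
            tc[n] = 0.0
            continue
        # candidate partners: nodes (other than n) within two hops via a shared neighbor
        partners = set()
        for u in nbrs:
            partners.update(neighbors[u])
        partners.discard(n)
        scores = []
        for m in partners:
            common = len(nbrs & neighbors[m])
            if common == 0:
                continue  # m does not actually share a neighbor with n
            scores.append(common + (1 if m in nbrs else 0))
        tc[n] = (sum(scores) / len(scores)) / len(nbrs) if scores else 0.0
    return tc


def node_metrics(g: nx.Graph) -> pd.DataFrame:
    """Degree, closeness, betweenness and topological coefficient per node.

    Requires a graph of at least two nodes with isolates already removed.
    Closeness and betweenness are computed within connected components;
    cross-component pairs contribute nothing.
    """
    if g.number_of_nodes() < 2:
        raise DomainError("node metrics require a graph with at least 2 nodes")
    closeness = nx.closeness_centrality(g, wf_improved=False)
    betweenness = nx.betweenness_centrality(g, normalized=True)
    tc = topological_coefficient(g)
    df = pd.DataFrame(
        {
            "node": list(g.nodes),
            "degree": [g.degree(n) for n in g.nodes],
            "closeness": [closeness[n] for n in g.nodes],
            "betweenness": [betweenness[n] for n in g.nodes],
            "topological_coefficient": [tc[n] for n in g.nodes],
        }
    )
    return df.sort_values("node", kind="stable").reset_index(drop=True)


def average_degree(g: nx.Graph) -> float:
    """2|E| / |V|; raises on an empty graph."""
    n = g.number_of_nodes()
    if n == 0:
        raise DomainError("average degree of an empty graph is undefined")
    return 2.0 * g.number_of_edges() / n


def select_core_targets(metrics: pd.DataFrame) -> set[str]:
    """Nodes whose degree is strictly greater than twice the median degree."""
    if metrics.empty:
        return set()
    degrees = metrics["degree"].to_numpy(dtype=float)
    threshold = 2.0 * float(np.median(degrees))
    return set(metrics.loc[metrics["degree"] > threshold, "node"])


def top_hubs(metrics: pd.DataFrame, k: int) -> list[str]:
    """Top-k nodes by degree; ties by closeness descending, then symbol."""
    if k < 1:
        raise DomainError("k must be >= 1")
    if k > len(metrics):
        warnings.warn(
            f"requested top {k} hubs from a {len(metrics)}-node graph; returning all",
            stacklevel=2,
        )
    ranked = metrics.sort_values(
        by=["degree", "closeness", "node"],
        ascending=[False, False, True],
        kind="stable",
    )
    return list(ranked["node"].head(k))
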