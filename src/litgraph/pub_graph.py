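"""Entity graphs, graph statistics and the path-based related-article
index.

The entity graph collapses statement types: one undirected edge per term
pair, weighted by the maximum statement weight.  The related-article
index propagates edge weights along entity paths of bounded length
(product aggregation, max over paths) into a publication-to-publication
ranking.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import numpy as np

from .kb_builder import KBStatement, KnowledgeBase

__all__ = [
    "GraphStats",
    "build_entity_graph",
    "build_mesh_baseline_graph",
    "related_article_index",
    "graph_statistics",
    "write_edge_list_tsv",
    "write_graphml",
    "write_related_index_tsv",
    "read_related_index_tsv",
]


def build_entity_graph(kb: KnowledgeBase | Iterable[KBStatement]) -> nx.Graph:
    """One edge per term pair, weight = max over that pair's statements."""
    statements = kb.statements if isinstance(kb, KnowledgeBase) else kb
    g = nx.Graph()
    for st in statements:
        existing = g.get_edge_data(st.term_a, st.term_b)
        if existing is None or existing["weight"] < st.weight:
            g.add_edge(st.term_a, st.term_b, weight=st.weight)
    return g


def build_mesh_baseline_graph(annotations: Mapping[str, Iterable[str]]) -> nx.Graph:
    """Clique per document over its annotated terms, all weights 1.0,
    union across documents; single-term documents give isolated nodes."""
    g = nx.Graph()
    for doc_id in sorted(annotations):
        terms = sorted(set(annotations[doc_id]))
        for t in terms:
            g.add_node(t)
        for i, a in enumerate(terms):
            for b in terms[i + 1 :]:
                g.add_edge(a, b, weight=1.0)
    return g


def _max_product_paths(g: nx.Graph, nodes: list[str], max_path_len: int) -> np.ndarray:
    """best[i, j] = max over paths of 1..max_path_len edges of the product
    of edge weights.  Computed on the (max, *) semiring; with weights in
    (0, 1] walks never beat the simple path they contain, so the closure
    equals the simple-path optimum."""
    n = len(nodes)
    pos = {v: i for i, v in enumerate(nodes)}
    adj = np.zeros((n, n))
    for a, b, data in g.edges(data=True):
        adj[pos[a], pos[b]] = data.get("weight", 1.0)
        adj[pos[b], pos[a]] = data.get("weight", 1.0)
    best = adj.copy()
    power = adj.copy()
    for _ in range(max_path_len - 1):
        # (max, *) "product" of power and adj
        power = np.max(power[:, :, None] * adj[None, :, :], axis=1)
        np.fill_diagonal(power, 0.0)
        best = np.maximum(best, power)
    np.fill_diagonal(best, 0.0)
    return best


def related_article_index(
    graph: nx.Graph,
    prov: Mapping[str, Iterable[str]],
    max_path_len: int = 3,
    prune: float = 0.1,
) -> dict[str, list[tuple[str, float]]]:
    """Publication -> descending-weight list of related publications.

    For every entity pair connected by a path of at most ``max_path_len``
    edges, the path weight (product of edge weights, max over paths)
    links every source publication of one endpoint to every source
    publication of the other.  Entries below ``prune`` are dropped;
    self-pairs are excluded.
    """
    nodes = sorted(graph.nodes)
    if not nodes:
        return {}
    best = _max_product_paths(graph, nodes, max_path_len)
    m_p: dict[tuple[str, str], float] = {}
    for i, a in enumerate(nodes):
        prov_a = sorted(set(prov.get(a, ())))
        if not prov_a:
            continue
        for j in range(i + 1, len(nodes)):
            w = best[i, j]
            if w <= 0:
                continue
            for p in prov_a:
                for q in set(prov.get(nodes[j], ())):
                    if p == q:
                        continue
                    key = (p, q) if p < q else (q, p)
                    if m_p.get(key, 0.0) < w:
                        m_p[key] = w

    index: dict[str, list[tuple[str, float]]] = {}
    for (p, q), w in m_p.items():
        if w < prune:
            continue
        index.setdefault(p, []).append((q, w))
        index.setdefault(q, []).append((p, w))
    for p in index:
        index[p].sort(key=lambda t: (-t[1], t[0]))
    return index


@dataclass(frozen=True)
class GraphStats:
    n_nodes: int
    n_edges: int
    edges_per_node: float
    density: float
    diameter: float              # component-size-weighted mean of longest shortest paths
    avg_shortest_path: float     # same weighting
    n_components: int


def graph_statistics(graph: nx.Graph) -> GraphStats:
    """Structural statistics; shortest paths are hop counts.  Diameter
    and average shortest path are arithmetic means over connected
    components, weighted by component size in nodes."""
    n = graph.number_of_nodes()
    if n == 0:
        raise ValueError("graph statistics undefined for an empty graph")
    e = graph.number_of_edges()
    density = 2 * e / (n * (n - 1)) if n > 1 else 0.0
    diam_sum = 0.0
    aspl_sum = 0.0
    n_components = 0
    for comp in nx.connected_components(graph):
        n_components += 1
        size = len(comp)
        if size > 1:
            sub = graph.subgraph(comp)
            diam_sum += size * nx.diameter(sub)
            aspl_sum += size * nx.average_shortest_path_length(sub)
    return GraphStats(
        n_nodes=n,
        n_edges=e,
        edges_per_node=e / n,
        density=density,
        diameter=diam_sum / n,
        avg_shortest_path=aspl_sum / n,
        n_components=n_components,
    )


# --- exports ---------------------------------------------------------------

def write_edge_list_tsv(graph: nx.Graph, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["term_a", "term_b", "weight"])
        for a, b, data in sorted(graph.edges(data=True)):
            writer.writerow([a, b, f"{data.get('weight', 1.0):.12g}"])


def write_graphml(graph: nx.Graph, path: str | Path) -> None:
    nx.write_graphml(graph, str(path))


def write_related_index_tsv(
    index: Mapping[str, list[tuple[str, float]]], path: str | Path
) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["pmid", "related_pmid", "weight"])
        for pmid in sorted(index):
            for related, weight in index[pmid]:
                writer.writerow([pmid, related, f"{weight:.12g}"])


def read_related_index_tsv(path: str | Path) -> dict[str, list[tuple[str, float]]]:
    index: dict[str, list[tuple[str, float]]] = {}
    with open(path, encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        next(reader, None)
        for row in reader:
            if not row:
                continue
            index.setdefault(row[0], []).append((row[1], float(row[2])))
    for p in index:
        index[p].sort(key=lambda t: (-t[1], t[0]))
    return index
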