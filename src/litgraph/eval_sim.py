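"""Taxonomy-grounded evaluation: MeSH-style tree-code similarity,
heuristic random walks, coherence/entropy/structure measures and
related-article index comparison.

Tree codes are dot-separated segment paths of increasing specificity
(``C10.228.662``); similarity of two terms is the best

    2 * depth(least common subsumer) / (depth(code_x) + depth(code_y))

over their code pairs.  Walks select successors by sorting the neighbour
list under a heuristic and accepting the k-th candidate with
geometrically decaying probability.
"""

from __future__ import annotations

import csv
import logging
import math
import re
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np

from ._text import lemma_phrase, word_tokens

logger = logging.getLogger(__name__)

__all__ = [
    "MeshTaxonomy",
    "ClusterAssignment",
    "WalkConfig",
    "Walk",
    "MeasureReport",
    "load_mesh_ascii",
    "load_mesh_xml",
    "assign_clusters",
    "mesh_similarity",
    "select_next_node",
    "random_walk",
    "envelope",
    "coherence_measures",
    "cluster_entropy",
    "entropy_measures",
    "structure_measures",
    "auxiliary_measures",
    "walk_measures",
    "run_simulation_batch",
    "write_measure_report_tsv",
    "related_precision_recall",
    "read_gold_index_tsv",
]

MEASURE_KEYS = tuple("ABCDEFGHIJKLMNOPQRST")


# --- taxonomy --------------------------------------------------------------

class MeshTaxonomy:
    """Term -> tree-code-set mapping with a lemmatised lookup layer."""

    def __init__(self, term_codes: Mapping[str, Iterable[str]] | None = None):
        self._codes: dict[str, frozenset[str]] = {}
        self._by_lemma: dict[str, set[str]] = {}
        self._assign_cache: dict[str, "ClusterAssignment"] = {}
        if term_codes:
            for term, codes in term_codes.items():
                self.add(term, codes)

    def add(self, term: str, codes: Iterable[str]) -> None:
        codes = frozenset(c.strip() for c in codes if c and c.strip())
        if not codes:
            logger.warning("term %r has no tree codes; skipped", term)
            return
        for code in codes:
            if any(not seg for seg in code.split(".")):
                raise ValueError(f"malformed tree code {code!r}")
        key = term.strip().lower()
        self._codes[key] = self._codes.get(key, frozenset()) | codes
        self._by_lemma.setdefault(lemma_phrase(key), set()).add(key)
        self._assign_cache.clear()

    def add_synonym(self, synonym: str, canonical: str) -> None:
        codes = self._codes.get(canonical.strip().lower())
        if codes:
            self.add(synonym, codes)

    def codes(self, term: str) -> frozenset[str]:
        return self._codes.get(term.strip().lower(), frozenset())

    def terms(self) -> list[str]:
        return sorted(self._codes)

    def lemma_lookup(self, phrase: str) -> frozenset[str]:
        """Union of tree codes over terms whose lemmatised form matches."""
        matched = self._by_lemma.get(lemma_phrase(phrase), ())
        out: set[str] = set()
        for term in matched:
            out |= self._codes[term]
        return frozenset(out)

    def __len__(self) -> int:
        return len(self._codes)

    def __contains__(self, term: str) -> bool:
        return term.strip().lower() in self._codes


def load_mesh_ascii(path: str | Path) -> MeshTaxonomy:
    """Read the ASCII descriptor format (``*NEWRECORD`` records with
    ``MH =``, ``ENTRY =`` / ``PRINT ENTRY =`` and ``MN =`` fields).
    Records without tree numbers are skipped with a warning."""
    tax = MeshTaxonomy()
    heading: str | None = None
    entries: list[str] = []
    codes: list[str] = []

    def flush():
        nonlocal heading, entries, codes
        if heading is not None:
            if codes:
                tax.add(heading, codes)
                for entry in entries:
                    tax.add(entry, codes)
            else:
                logger.warning("descriptor %r has no tree numbers; skipped", heading)
        heading, entries, codes = None, [], []

    for line in Path(path).read_text(encoding="utf-8").splitlines():
        line = line.strip()
        if line == "*NEWRECORD":
            flush()
        elif line.startswith("MH = "):
            heading = line[5:].strip()
        elif line.startswith("ENTRY = ") or line.startswith("PRINT ENTRY = "):
            term = line.split("= ", 1)[1]
            # entries may carry pipe-delimited qualifiers; the term is first
            entries.append(term.split("|")[0].strip())
        elif line.startswith("MN = "):
            codes.append(line[5:].strip())
    flush()
    return tax


def load_mesh_xml(path: str | Path) -> MeshTaxonomy:
    """Read the XML ``DescriptorRecordSet`` format (DescriptorName,
    TreeNumberList/TreeNumber, Concept/TermList/Term)."""
    tax = MeshTaxonomy()
    root = ET.parse(str(path)).getroot()
    for record in root.iter("DescriptorRecord"):
        name_el = record.find("DescriptorName/String")
        name = (name_el.text or "").strip() if name_el is not None else ""
        codes = [
            (tn.text or "").strip()
            for tn in record.findall("TreeNumberList/TreeNumber")
        ]
        codes = [c for c in codes if c]
        if not codes:
            logger.warning("descriptor %r has no tree numbers; skipped", name)
            continue
        if name:
            tax.add(name, codes)
        for term_el in record.findall(".//TermList/Term/String"):
            term = (term_el.text or "").strip()
            if term:
                tax.add(term, codes)
    return tax


# --- cluster assignment and similarity -------------------------------------

@dataclass(frozen=True)
class ClusterAssignment:
    """Abstract clusters = top-level code segments; specific clusters =
    full codes."""

    abstract: frozenset[str]
    specific: frozenset[str]

    @property
    def empty(self) -> bool:
        return not self.specific

    @staticmethod
    def from_codes(codes: Iterable[str]) -> "ClusterAssignment":
        codes = frozenset(codes)
        return ClusterAssignment(
            abstract=frozenset(c.split(".")[0] for c in codes), specific=codes
        )


def assign_clusters(entity: str, taxonomy: MeshTaxonomy) -> ClusterAssignment:
    """Exact lemmatised match first, then the longest contiguous token
    sub-phrase with a match (longest first, then leftmost); no match
    yields an empty assignment."""
    cached = taxonomy._assign_cache.get(entity)
    if cached is not None:
        return cached
    codes = taxonomy.lemma_lookup(entity)
    if not codes:
        tokens = word_tokens(entity)
        found = False
        for n in range(len(tokens) - 1, 0, -1):
            for start in range(0, len(tokens) - n + 1):
                sub = " ".join(tokens[start : start + n])
                codes = taxonomy.lemma_lookup(sub)
                if codes:
                    found = True
                    break
            if found:
                break
    assignment = ClusterAssignment.from_codes(codes)
    taxonomy._assign_cache[entity] = assignment
    return assignment


def _code_similarity(cx: str, cy: str) -> float:
    sx, sy = cx.split("."), cy.split(".")
    common = 0
    for a, b in zip(sx, sy):
        if a != b:
            break
        common += 1
    if common == 0:
        return 0.0
    return 2.0 * common / (len(sx) + len(sy))


def mesh_similarity(x: str, y: str, taxonomy: MeshTaxonomy) -> float:
    """Best least-common-subsumer similarity over the two terms' code
    pairs; 0 when either assignment is empty or no pair shares a root."""
    ax = assign_clusters(x, taxonomy)
    ay = assign_clusters(y, taxonomy)
    if ax.empty or ay.empty:
        return 0.0
    return max(
        (_code_similarity(cx, cy) for cx in ax.specific for cy in ay.specific),
        default=0.0,
    )


# --- random walks ----------------------------------------------------------

@dataclass(frozen=True)
class WalkConfig:
    heuristic: int = 1          # 1: unvisited, 2: edge weight, 3: similar, 4: dissimilar
    length: int = 5             # edges
    radius: int = 1             # envelope radius
    repetitions: int = 100
    acceptance_base: float = 0.9

    def __post_init__(self):
        if self.heuristic not in {1, 2, 3, 4}:
            raise ValueError("heuristic must be 1..4")
        if self.length < 1:
            raise ValueError("length must be >= 1")
        if self.radius < 0:
            raise ValueError("radius must be >= 0")
        if not 0 < self.acceptance_base < 1:
            raise ValueError("acceptance base must be in (0, 1)")


@dataclass(frozen=True)
class Walk:
    nodes: tuple

    @property
    def node_set(self) -> frozenset:
        return frozenset(self.nodes)

    @property
    def steps(self) -> list[tuple]:
        return list(zip(self.nodes, self.nodes[1:]))


def _sorted_neighbours(
    current,
    visited: set,
    graph: nx.Graph,
    heuristic: int,
    taxonomy: MeshTaxonomy | None,
) -> list:
    # stable lexicographic base order makes heuristic ties deterministic
    neighbours = sorted(graph.neighbors(current), key=str)
    if heuristic == 1:
        return sorted(neighbours, key=lambda u: u in visited)
    if heuristic == 2:
        return sorted(
            neighbours, key=lambda u: -graph[current][u].get("weight", 1.0)
        )
    if taxonomy is None:
        raise ValueError("heuristics 3 and 4 need a taxonomy")
    sign = -1.0 if heuristic == 3 else 1.0
    return sorted(
        neighbours, key=lambda u: sign * mesh_similarity(str(current), str(u), taxonomy)
    )


def select_next_node(
    current,
    visited: set,
    graph: nx.Graph,
    heuristic: int,
    acceptance_base: float,
    rng: np.random.Generator,
    taxonomy: MeshTaxonomy | None = None,
):
    """Scan the heuristic-sorted neighbour list, accepting candidate k
    with probability threshold e_i^(k+1); fall through to a uniform
    choice."""
    ordered = _sorted_neighbours(current, visited, graph, heuristic, taxonomy)
    if not ordered:
        raise ValueError(f"node {current!r} has no neighbours")
    e = acceptance_base
    for u in ordered:
        if rng.random() <= e:
            return u
        e *= acceptance_base
    return ordered[rng.integers(len(ordered))]


def random_walk(
    graph: nx.Graph,
    start,
    config: WalkConfig,
    rng: np.random.Generator,
    taxonomy: MeshTaxonomy | None = None,
) -> Walk:
    """Walk of ``config.length`` edges (shorter if stuck at a dead end)."""
    if start not in graph:
        raise ValueError(f"start node {start!r} not in graph")
    nodes = [start]
    visited = {start}
    for _ in range(config.length):
        current = nodes[-1]
        if graph.degree(current) == 0:
            break
        nxt = select_next_node(
            current, visited, graph, config.heuristic,
            config.acceptance_base, rng, taxonomy,
        )
        nodes.append(nxt)
        visited.add(nxt)
    return Walk(nodes=tuple(nodes))


def envelope(graph: nx.Graph, walk: Walk | Iterable, radius: int) -> frozenset:
    """All nodes within hop distance <= radius of any path node
    (includes the path itself)."""
    path_nodes = walk.nodes if isinstance(walk, Walk) else tuple(walk)
    out: set = set(path_nodes)
    if radius > 0:
        for node in set(path_nodes):
            out.update(
                nx.single_source_shortest_path_length(graph, node, cutoff=radius)
            )
    return frozenset(out)


# --- measures --------------------------------------------------------------

def coherence_measures(
    walk: Walk, taxonomy: MeshTaxonomy
) -> tuple[float, float, float]:
    """(A) source-target similarity, (B) product of step similarities,
    (C) sum of step similarities divided by the node count.  A one-node
    walk has B = 1 (empty product) and C = 0 by convention."""
    nodes = walk.nodes
    a = mesh_similarity(str(nodes[0]), str(nodes[-1]), taxonomy)
    sims = [
        mesh_similarity(str(u), str(v), taxonomy) for u, v in walk.steps
    ]
    b = math.prod(sims) if sims else 1.0
    c = sum(sims) / len(nodes) if sims else 0.0
    return a, b, c


def cluster_entropy(counts: Iterable[int]) -> float:
    """Shannon entropy (bits) of cluster mention counts; zero clusters
    give 0 by convention."""
    counts = [c for c in counts if c > 0]
    total = sum(counts)
    if total == 0:
        return 0.0
    return -sum((c / total) * math.log2(c / total) for c in counts)


def _mesh_cluster_counts(
    nodes: Iterable, taxonomy: MeshTaxonomy, specific: bool
) -> dict[str, int]:
    counts: dict[str, int] = {}
    for node in nodes:
        assignment = assign_clusters(str(node), taxonomy)
        clusters = assignment.specific if specific else assignment.abstract
        for c in clusters:
            counts[c] = counts.get(c, 0) + 1
    return counts


def _bicomponent_counts(subgraph: nx.Graph) -> list[int]:
    return [len(comp) for comp in nx.biconnected_components(subgraph)]


def entropy_measures(
    walk: Walk,
    env: frozenset,
    taxonomy: MeshTaxonomy,
    graph: nx.Graph,
) -> tuple[float, float, float, float, float]:
    """(D, E) path entropies over abstract/specific clusters, (F, G) the
    same over path plus envelope, (H) entropy over biconnected components
    of the envelope subgraph."""
    path = walk.node_set
    d = cluster_entropy(_mesh_cluster_counts(path, taxonomy, specific=False).values())
    e = cluster_entropy(_mesh_cluster_counts(path, taxonomy, specific=True).values())
    f = cluster_entropy(_mesh_cluster_counts(env, taxonomy, specific=False).values())
    g = cluster_entropy(_mesh_cluster_counts(env, taxonomy, specific=True).values())
    h = cluster_entropy(_bicomponent_counts(graph.subgraph(env)))
    return d, e, f, g, h


def structure_measures(
    envelope_subgraph: nx.Graph,
) -> tuple[float, float, float, float]:
    """(I) envelope size in nodes, (J) number of biconnected components,
    (K) their average node count, (L) average local clustering
    coefficient (degree < 2 contributes 0)."""
    i = envelope_subgraph.number_of_nodes()
    comps = list(nx.biconnected_components(envelope_subgraph))
    j = len(comps)
    k = sum(len(c) for c in comps) / j if j else 0.0
    l = nx.average_clustering(envelope_subgraph) if i else 0.0
    return float(i), float(j), k, l


def auxiliary_measures(
    walk: Walk, env: frozenset, taxonomy: MeshTaxonomy
) -> tuple[float, ...]:
    """(M..T) cluster counts and average sizes for abstract/specific
    clusters over the path and the envelope."""
    out: list[float] = []
    for nodes in (walk.node_set, env):
        for specific in (False, True):
            counts = _mesh_cluster_counts(nodes, taxonomy, specific=specific)
            n_clusters = len(counts)
            avg_size = sum(counts.values()) / n_clusters if n_clusters else 0.0
            out.append(float(n_clusters))
            out.append(avg_size)
    # order: M, N (abstract/path), Q, R (specific/path), O, P, S, T (envelope)
    m, n_, q, r, o, p, s, t = out
    return m, n_, o, p, q, r, s, t


def walk_measures(
    graph: nx.Graph, walk: Walk, radius: int, taxonomy: MeshTaxonomy
) -> dict[str, float]:
    """All measures A..T for one walk."""
    env = envelope(graph, walk, radius)
    sub = graph.subgraph(env)
    a, b, c = coherence_measures(walk, taxonomy)
    d, e, f, g, h = entropy_measures(walk, env, taxonomy, graph)
    i, j, k, l = structure_measures(sub)
    m, n_, o, p, q, r, s, t = auxiliary_measures(walk, env, taxonomy)
    values = (a, b, c, d, e, f, g, h, i, j, k, l, m, n_, o, p, q, r, s, t)
    return dict(zip(MEASURE_KEYS, values))


@dataclass(frozen=True)
class MeasureReport:
    heuristic: int
    length: int
    radius: int
    repetitions: int
    means: dict[str, float]


def run_simulation_batch(
    graph: nx.Graph,
    taxonomy: MeshTaxonomy,
    heuristics: Sequence[int] = (1, 2, 3, 4),
    lengths: Sequence[int] = (2, 5, 10, 50),
    radii: Sequence[int] = (0, 1, 2),
    repetitions: int = 100,
    acceptance_base: float = 0.9,
    seed: int = 0,
) -> list[MeasureReport]:
    """Arithmetic-mean measure report per (heuristic, length, radius)
    combination; start nodes drawn uniformly.  The per-combination RNG is
    derived from (seed, heuristic, length, radius), so reports are
    bit-identical across reruns and independent of grid order."""
    nodes = sorted(graph.nodes, key=str)
    if not nodes:
        raise ValueError("cannot walk an empty graph")
    reports: list[MeasureReport] = []
    for h in heuristics:
        for length in lengths:
            for radius in radii:
                rng = np.random.default_rng([seed, h, length, radius])
                config = WalkConfig(
                    heuristic=h, length=length, radius=radius,
                    repetitions=repetitions, acceptance_base=acceptance_base,
                )
                sums = {key: 0.0 for key in MEASURE_KEYS}
                for _ in range(repetitions):
                    start = nodes[rng.integers(len(nodes))]
                    walk = random_walk(graph, start, config, rng, taxonomy)
                    for key, value in walk_measures(
                        graph, walk, radius, taxonomy
                    ).items():
                        sums[key] += value
                means = {key: sums[key] / repetitions for key in MEASURE_KEYS}
                reports.append(
                    MeasureReport(h, length, radius, repetitions, means)
                )
    return reports


def write_measure_report_tsv(
    reports: Iterable[MeasureReport], path: str | Path
) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["H", "L", "r", "repetitions", *MEASURE_KEYS])
        for rep in reports:
            writer.writerow(
                [rep.heuristic, rep.length, rep.radius, rep.repetitions]
                + [f"{rep.means[k]:.10g}" for k in MEASURE_KEYS]
            )


# --- related-article index comparison --------------------------------------

def read_gold_index_tsv(path: str | Path) -> dict[str, list[str]]:
    """Gold related-article index: ``pmid<TAB>related_pmid<TAB>rank`` rows
    (header line); lists ordered by ascending rank, ties by PMID."""
    rows: dict[str, list[tuple[float, str]]] = {}
    with open(path, encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        next(reader, None)
        for row in reader:
            if not row:
                continue
            rows.setdefault(row[0], []).append((float(row[2]), row[1]))
    return {
        pmid: [rid for _, rid in sorted(entries)]
        for pmid, entries in rows.items()
    }


def _as_ranked_ids(entries) -> list[str]:
    return [e[0] if isinstance(e, tuple) else e for e in entries]


def related_precision_recall(
    candidate: Mapping[str, Sequence],
    gold: Mapping[str, Sequence],
    top_k: int | None = None,
) -> tuple[float, float, float]:
    """Average precision/recall over shared keys (lists truncated to
    ``top_k``) and the fraction of keys whose shared-item rank vectors
    have Pearson correlation >= 0.7 (keys with fewer than two shared
    items are skipped for the correlation)."""
    shared = sorted(set(candidate) & set(gold))
    if not shared:
        raise ValueError("candidate and gold indices share no keys")
    precisions: list[float] = []
    recalls: list[float] = []
    n_corr = 0
    n_corr_high = 0
    for key in shared:
        cand_ids = _as_ranked_ids(candidate[key])[:top_k]
        gold_ids = _as_ranked_ids(gold[key])[:top_k]
        inter = set(cand_ids) & set(gold_ids)
        precisions.append(len(inter) / len(cand_ids) if cand_ids else 0.0)
        recalls.append(len(inter) / len(gold_ids) if gold_ids else 0.0)
        if len(inter) >= 2:
            items = sorted(inter)
            r_cand = [cand_ids.index(i) for i in items]
            r_gold = [gold_ids.index(i) for i in items]
            with np.errstate(invalid="ignore"):
                corr = np.corrcoef(r_cand, r_gold)[0, 1]
            if np.isnan(corr):
                continue
            n_corr += 1
            if corr >= 0.7:
                n_corr_high += 1
    pre_avg = sum(precisions) / len(precisions)
    rec_avg = sum(recalls) / len(recalls)
    corr_fraction = n_corr_high / n_corr if n_corr else 0.0
    return pre_avg, rec_avg, corr_fraction
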