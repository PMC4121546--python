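"""Corpus-wide knowledge base construction.

Two statement layers are derived from the per-document basic statements:

* ``cooc`` — frequency-scaled pointwise mutual information, percentile
  normalised into (0, 1];
* ``sim`` — cosine similarity of co-occurrence context vectors, kept
  when it reaches a threshold (0.25 by default).

The PMI distributions are the raw per-pair / per-term score sums divided
by the total number of basic statements, so

    fpmi(x, y) = F(x, y) * log2( joint(x, y) * |T| / (marg(x) * marg(y)) ).
"""

from __future__ import annotations

import csv
import logging
import math
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .cooc_extraction import BasicStatement

logger = logging.getLogger(__name__)

__all__ = [
    "AggregationStats",
    "KBStatement",
    "KnowledgeBase",
    "aggregate_statements",
    "fpmi",
    "nearest_rank_percentile",
    "normalize_scores",
    "build_cooc_layer",
    "cooc_vectors",
    "cosine",
    "cosine_similarity",
    "build_sim_layer",
    "build_knowledge_base",
    "write_kb_tsv",
    "read_kb_tsv",
]


@dataclass
class AggregationStats:
    """Sums needed by the PMI computation, aggregated over documents."""

    joint_weight: dict[tuple[str, str], float]
    marginal_weight: dict[str, float]
    pair_doc_frequency: dict[tuple[str, str], int]
    n_basic: int


@dataclass(frozen=True)
class KBStatement:
    term_a: str
    term_b: str
    relation: str  # "cooc" | "sim"
    weight: float

    def __post_init__(self):
        if self.relation not in {"cooc", "sim"}:
            raise ValueError(f"unknown relation {self.relation!r}")
        if not 0 < self.weight <= 1:
            raise ValueError("KB statement weight must be in (0, 1]")
        if self.term_a > self.term_b:
            a, b = self.term_b, self.term_a
            object.__setattr__(self, "term_a", a)
            object.__setattr__(self, "term_b", b)

    @property
    def pair(self) -> tuple[str, str]:
        return (self.term_a, self.term_b)

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.term_a, self.relation, self.term_b)


@dataclass
class KnowledgeBase:
    """Statement list plus per-statement provenance (source doc ids)."""

    statements: list[KBStatement]
    provenance: dict[tuple[str, str, str], frozenset[str]]

    @property
    def cooc_statements(self) -> list[KBStatement]:
        return [s for s in self.statements if s.relation == "cooc"]

    @property
    def sim_statements(self) -> list[KBStatement]:
        return [s for s in self.statements if s.relation == "sim"]


def aggregate_statements(statements: Iterable[BasicStatement]) -> AggregationStats:
    # canonical summation order makes the aggregation exactly invariant
    # under shuffling of the input (float addition is not associative)
    statements = sorted(
        statements, key=lambda s: (s.term_a, s.term_b, s.doc_id, s.score)
    )
    joint: dict[tuple[str, str], float] = defaultdict(float)
    marginal: dict[str, float] = defaultdict(float)
    freq: dict[tuple[str, str], int] = defaultdict(int)
    n = 0
    for st in statements:
        joint[st.pair] += st.score
        marginal[st.term_a] += st.score
        marginal[st.term_b] += st.score
        freq[st.pair] += 1
        n += 1
    return AggregationStats(dict(joint), dict(marginal), dict(freq), n)


def fpmi(x: str, y: str, stats: AggregationStats) -> float:
    """Frequency-scaled PMI of an aggregated pair."""
    pair = (x, y) if x <= y else (y, x)
    joint = stats.joint_weight.get(pair, 0.0)
    if joint <= 0:
        raise ValueError(f"pair {pair} has no joint weight")
    mx = stats.marginal_weight.get(x, 0.0)
    my = stats.marginal_weight.get(y, 0.0)
    if mx <= 0 or my <= 0:
        raise ValueError("zero marginal weight")
    f = stats.pair_doc_frequency.get(pair, 0)
    return f * math.log2(joint * stats.n_basic / (mx * my))


def nearest_rank_percentile(values: Sequence[float], p: int) -> float:
    """Nearest-rank P-th percentile of a non-empty value collection."""
    if not values:
        raise ValueError("percentile of an empty collection")
    ordered = sorted(values)
    rank = max(1, math.ceil(p / 100 * len(ordered)))
    return ordered[min(rank, len(ordered)) - 1]


def normalize_scores(
    fpmi_values: Mapping[tuple[str, str], float], p: int = 95
) -> dict[tuple[str, str], float]:
    """Drop non-positive scores, divide by the nearest-rank P-th
    percentile of the survivors, clip to 1."""
    positives = {pair: v for pair, v in fpmi_values.items() if v > 0}
    if not positives:
        logger.warning("no positive fPMI values; co-occurrence layer is empty")
        return {}
    constant = nearest_rank_percentile(list(positives.values()), p)
    return {pair: min(v / constant, 1.0) for pair, v in positives.items()}


def build_cooc_layer(
    basic_statements: Sequence[BasicStatement], p: int = 95
) -> list[KBStatement]:
    if not basic_statements:
        return []
    stats = aggregate_statements(basic_statements)
    scores = {pair: fpmi(pair[0], pair[1], stats) for pair in stats.joint_weight}
    weights = normalize_scores(scores, p)
    return [
        KBStatement(a, b, "cooc", w)
        for (a, b), w in sorted(weights.items())
    ]


# --- similarity layer ------------------------------------------------------

def cooc_vectors(cooc_layer: Iterable[KBStatement]) -> dict[str, dict[str, float]]:
    """Co-occurrence context vector per term: co-occurring term -> weight."""
    vectors: dict[str, dict[str, float]] = defaultdict(dict)
    for st in cooc_layer:
        vectors[st.term_a][st.term_b] = st.weight
        vectors[st.term_b][st.term_a] = st.weight
    return dict(vectors)


def cosine(dot: float, norm_a: float, norm_b: float) -> float:
    """The cosine formula itself; zero norms map to 0 by convention."""
    if norm_a == 0 or norm_b == 0:
        logger.warning("zero-norm vector in cosine similarity; returning 0")
        return 0.0
    return dot / (norm_a * norm_b)


def cosine_similarity(a: Mapping[str, float], b: Mapping[str, float]) -> float:
    """Cosine of two sparse component maps; norms over the full vectors."""
    if len(b) < len(a):
        a, b = b, a
    dot = sum(w * b[t] for t, w in a.items() if t in b)
    norm_a = math.sqrt(sum(w * w for w in a.values()))
    norm_b = math.sqrt(sum(w * w for w in b.values()))
    return cosine(dot, norm_a, norm_b)


def build_sim_layer(
    vectors: Mapping[str, Mapping[str, float]], threshold: float = 0.25
) -> list[KBStatement]:
    """Similarity statements for unordered term pairs with cosine >=
    ``threshold``.  Candidates are blocked on shared nonzero components,
    which is lossless for positive cosines."""
    by_component: dict[str, list[str]] = defaultdict(list)
    for owner, comps in vectors.items():
        for comp in comps:
            by_component[comp].append(owner)
    candidates: set[tuple[str, str]] = set()
    for owners in by_component.values():
        owners = sorted(owners)
        for i, a in enumerate(owners):
            for b in owners[i + 1 :]:
                candidates.add((a, b))
    out: list[KBStatement] = []
    for a, b in sorted(candidates):
        s = cosine_similarity(vectors[a], vectors[b])
        if s >= threshold:
            out.append(KBStatement(a, b, "sim", min(s, 1.0)))
    return out


def build_knowledge_base(
    basic_statements: Sequence[BasicStatement],
    p: int = 95,
    sim_threshold: float = 0.25,
) -> KnowledgeBase:
    """Full KB: cooc layer, sim layer and per-statement provenance.

    Provenance of a cooc statement is the set of documents contributing a
    basic statement for the pair; provenance of a sim statement is the
    union of the two terms' cooc provenances (the documents its evidence
    was drawn from).
    """
    cooc_layer = build_cooc_layer(basic_statements, p)
    vectors = cooc_vectors(cooc_layer)
    sim_layer = build_sim_layer(vectors, sim_threshold)

    pair_docs: dict[tuple[str, str], set[str]] = defaultdict(set)
    term_docs: dict[str, set[str]] = defaultdict(set)
    for st in basic_statements:
        pair_docs[st.pair].add(st.doc_id)
        term_docs[st.term_a].add(st.doc_id)
        term_docs[st.term_b].add(st.doc_id)

    provenance: dict[tuple[str, str, str], frozenset[str]] = {}
    for st in cooc_layer:
        provenance[st.key] = frozenset(pair_docs[st.pair])
    for st in sim_layer:
        provenance[st.key] = frozenset(term_docs[st.term_a] | term_docs[st.term_b])
    return KnowledgeBase(statements=cooc_layer + sim_layer, provenance=provenance)


# --- persistence -----------------------------------------------------------

def write_kb_tsv(kb: KnowledgeBase, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["term_a", "relation", "term_b", "weight", "sources"])
        for st in kb.statements:
            sources = ",".join(sorted(kb.provenance.get(st.key, frozenset())))
            writer.writerow([st.term_a, st.relation, st.term_b, f"{st.weight:.12g}", sources])


def read_kb_tsv(path: str | Path) -> KnowledgeBase:
    statements: list[KBStatement] = []
    provenance: dict[tuple[str, str, str], frozenset[str]] = {}
    with open(path, encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        next(reader, None)
        for row in reader:
            if not row:
                continue
            st = KBStatement(row[0], row[2], row[1], float(row[3]))
            statements.append(st)
            sources = frozenset(s for s in row[4].split(",") if s) if len(row) > 4 else frozenset()
            provenance[st.key] = sources
    return KnowledgeBase(statements=statements, provenance=provenance)
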