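"""Per-document distance-weighted co-occurrence scoring.

Each unordered entity pair in a document receives the score

    sum over mention pairs (i, j), |i - j| <= window, of 1 / (|i - j| + 1)

where i, j are 1-based sentence indices of the two entities' mentions.
The window defaults to 3 sentences; both the window and the distance
kernel are configurable.
"""

from __future__ import annotations

import csv
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

from .mention_extraction import Mention

__all__ = [
    "CoocParams",
    "BasicStatement",
    "document_cooc_score",
    "extract_basic_statements",
    "group_mentions_by_document",
    "write_basic_statements_tsv",
    "read_basic_statements_tsv",
]


def _inverse_distance(d: int) -> float:
    return 1.0 / (d + 1)


@dataclass(frozen=True)
class CoocParams:
    max_sentence_distance: int = 3
    distance_weight: Callable[[int], float] = _inverse_distance

    def __post_init__(self):
        if self.max_sentence_distance < 0:
            raise ValueError("max_sentence_distance must be >= 0")


@dataclass(frozen=True)
class BasicStatement:
    """Per-document co-occurrence statement; the pair is stored in
    canonical (lexicographic) order."""

    term_a: str
    term_b: str
    score: float
    doc_id: str

    def __post_init__(self):
        if self.term_a == self.term_b:
            raise ValueError("a statement needs two distinct terms")
        if self.score <= 0:
            raise ValueError("statement score must be positive")
        if self.term_a > self.term_b:
            a, b = self.term_b, self.term_a
            object.__setattr__(self, "term_a", a)
            object.__setattr__(self, "term_b", b)

    @property
    def pair(self) -> tuple[str, str]:
        return (self.term_a, self.term_b)


def document_cooc_score(
    mentions_a: Iterable[int],
    mentions_b: Iterable[int],
    params: CoocParams = CoocParams(),
) -> float:
    """Distance-weighted score over all mention pairs of two entities in
    one document; sentence-index multisets in, non-negative real out."""
    score = 0.0
    positions_b = list(mentions_b)
    for i in mentions_a:
        for j in positions_b:
            d = abs(i - j)
            if d <= params.max_sentence_distance:
                score += params.distance_weight(d)
    return score


def group_mentions_by_document(
    mentions: Iterable[Mention],
) -> dict[str, dict[str, list[int]]]:
    """doc_id -> term -> sentence-index multiset (as a list)."""
    grouped: dict[str, dict[str, list[int]]] = defaultdict(lambda: defaultdict(list))
    for m in mentions:
        grouped[m.doc_id][m.term].append(m.sentence_idx)
    return {d: dict(t) for d, t in grouped.items()}


def extract_basic_statements(
    corpus_mentions: Mapping[str, Mapping[str, Sequence[int]]] | Iterable[Mention],
    params: CoocParams = CoocParams(),
) -> list[BasicStatement]:
    """One statement per unordered entity pair per document with a
    positive score.  Accepts either mentions grouped by document
    (``doc_id -> term -> positions``) or a flat iterable of mentions."""
    if not isinstance(corpus_mentions, Mapping):
        corpus_mentions = group_mentions_by_document(corpus_mentions)
    statements: list[BasicStatement] = []
    for doc_id in sorted(corpus_mentions):
        term_positions = corpus_mentions[doc_id]
        terms = sorted(term_positions)
        for i, ta in enumerate(terms):
            for tb in terms[i + 1 :]:
                score = document_cooc_score(
                    term_positions[ta], term_positions[tb], params
                )
                if score > 0:
                    statements.append(BasicStatement(ta, tb, score, doc_id))
    return statements


def write_basic_statements_tsv(
    statements: Iterable[BasicStatement], path: str | Path
) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["term_a", "term_b", "score", "doc_id"])
        for st in statements:
            writer.writerow([st.term_a, st.term_b, f"{st.score:.12g}", st.doc_id])


def read_basic_statements_tsv(path: str | Path) -> list[BasicStatement]:
    statements: list[BasicStatement] = []
    with open(path, encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        next(reader, None)
        for row in reader:
            if not row:
                continue
            statements.append(
                BasicStatement(row[0], row[1], float(row[2]), row[3])
            )
    return statements
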