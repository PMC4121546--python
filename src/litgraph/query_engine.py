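"""Fuzzy boolean querying over the knowledge-base indices.

Atomic queries resolve through the full-text index to canonical terms
and fetch their term-index rows as fuzzy sets; boolean operators map to
fuzzy set operations (min / max / 1-x).  The term result set expands to
ranked statements (mean of the member-term degrees) and to ranked
provenance identifiers (max-normalised weighted sums).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

from ._boolparse import QuerySyntaxError, QueryTree, parse_boolean
from .kb_builder import KBStatement
from .kb_index import KBIndices

__all__ = [
    "FuzzySet",
    "ResultBundle",
    "QuerySyntaxError",
    "QueryTree",
    "parse_query",
    "eval_atomic",
    "eval_tree",
    "statements_for_terms",
    "provenance_for_statements",
    "run_query",
]


class FuzzySet:
    """Element -> membership degree in [0, 1]; absent element has degree 0."""

    def __init__(self, degrees: Mapping | Iterable[tuple] | None = None):
        self._d: dict = {}
        if degrees:
            items = degrees.items() if isinstance(degrees, Mapping) else degrees
            for k, v in items:
                v = float(v)
                if not 0.0 <= v <= 1.0:
                    raise ValueError(f"membership degree {v} outside [0, 1]")
                if v > 0.0:
                    self._d[k] = v

    def degree(self, element) -> float:
        return self._d.get(element, 0.0)

    def items(self) -> Iterator[tuple]:
        return iter(self._d.items())

    def __len__(self) -> int:
        return len(self._d)

    def __bool__(self) -> bool:
        return bool(self._d)

    def __contains__(self, element) -> bool:
        return element in self._d

    def __eq__(self, other) -> bool:
        return isinstance(other, FuzzySet) and self._d == other._d

    def __repr__(self) -> str:
        return f"FuzzySet({self._d!r})"

    def union(self, other: "FuzzySet") -> "FuzzySet":
        out = dict(self._d)
        for k, v in other._d.items():
            out[k] = max(out.get(k, 0.0), v)
        return FuzzySet(out)

    def intersection(self, other: "FuzzySet") -> "FuzzySet":
        return FuzzySet(
            {k: min(v, other._d[k]) for k, v in self._d.items() if k in other._d}
        )

    def complement(self, universe: Iterable) -> "FuzzySet":
        return FuzzySet({k: 1.0 - self.degree(k) for k in universe})

    def ranked(self) -> list[tuple]:
        """Elements by descending degree, ties in element order."""
        return sorted(self._d.items(), key=lambda kv: (-kv[1], kv[0]))

    def top(self, k: int | None) -> "FuzzySet":
        if k is None:
            return FuzzySet(self._d)
        return FuzzySet(self.ranked()[:k])


@dataclass
class ResultBundle:
    terms: FuzzySet
    statements: FuzzySet        # keyed by statement index position
    sources: FuzzySet
    indices: KBIndices = field(repr=False)

    def ranked_statements(self) -> list[tuple[KBStatement, float]]:
        return [
            (self.indices.statements[j], w) for j, w in self.statements.ranked()
        ]

    def to_json(self) -> str:
        return json.dumps(
            {
                "terms": [
                    {"term": t, "degree": w} for t, w in self.terms.ranked()
                ],
                "statements": [
                    {
                        "id": self.indices.statement_ids[j],
                        "relation": self.indices.statements[j].relation,
                        "term_a": self.indices.statements[j].term_a,
                        "term_b": self.indices.statements[j].term_b,
                        "degree": w,
                    }
                    for j, w in self.statements.ranked()
                ],
                "sources": [
                    {"source": s, "degree": w} for s, w in self.sources.ranked()
                ],
            },
            indent=1,
        )

    def to_tsv(self) -> str:
        lines = ["kind\tkey\tdegree"]
        for t, w in self.terms.ranked():
            lines.append(f"term\t{t}\t{w:.6g}")
        for j, w in self.statements.ranked():
            st = self.indices.statements[j]
            lines.append(f"statement\t{st.term_a}|{st.relation}|{st.term_b}\t{w:.6g}")
        for s, w in self.sources.ranked():
            lines.append(f"source\t{s}\t{w:.6g}")
        return "\n".join(lines)


def parse_query(text: str) -> QueryTree:
    """Parse a fuzzy boolean query (NOT > AND > OR, parentheses nest)."""
    return parse_boolean(text)


def eval_atomic(term: str, indices: KBIndices) -> FuzzySet:
    """Element-wise max of the term-index rows of every canonical term
    matched by the full-text lookup."""
    out = FuzzySet()
    for matched in sorted(indices.fulltext_match(term)):
        out = out.union(FuzzySet(indices.term_row(matched)))
    return out


def eval_tree(tree: QueryTree, indices: KBIndices) -> FuzzySet:
    """min/max/complement evaluation; NOT complements over the universe
    of indexed terms."""
    if tree.op == "atom":
        return eval_atomic(tree.term, indices)
    if tree.op == "NOT":
        return eval_tree(tree.children[0], indices).complement(indices.terms)
    results = [eval_tree(c, indices) for c in tree.children]
    out = results[0]
    for r in results[1:]:
        out = out.union(r) if tree.op == "OR" else out.intersection(r)
    return out


def statements_for_terms(
    r_t: FuzzySet, indices: KBIndices, top_k_terms: int | None = 5
) -> FuzzySet:
    """Statement degrees from the top term degrees.

    Each statement column has exactly two nonzero entries, so the
    normalised dot product with normalisation 1/2 equals the arithmetic
    mean of its two terms' degrees.  Zero-degree statements are dropped.
    """
    restricted = r_t.top(top_k_terms)
    degrees = {}
    for j, st in enumerate(indices.statements):
        w = (restricted.degree(st.term_a) + restricted.degree(st.term_b)) / 2.0
        if w > 0:
            degrees[j] = w
    return FuzzySet(degrees)


def provenance_for_statements(
    r_s: FuzzySet, indices: KBIndices, top_k_statements: int | None = 7
) -> FuzzySet:
    """Source degrees: weighted sum of statement degrees through the
    provenance index, normalised by the maximum."""
    restricted = r_s.top(top_k_statements)
    sums: dict[str, float] = {}
    for j, w_s in restricted.items():
        row = indices.provenance_matrix.getrow(j)
        for col, p in zip(row.indices, row.data):
            src = indices.sources[col]
            sums[src] = sums.get(src, 0.0) + w_s * float(p)
    if not sums:
        return FuzzySet()
    peak = max(sums.values())
    if peak <= 0:
        return FuzzySet()
    return FuzzySet({s: v / peak for s, v in sums.items()})


def run_query(
    text: str,
    indices: KBIndices,
    top_terms: int | None = 5,
    top_statements: int | None = 7,
) -> ResultBundle:
    """Parse, evaluate and expand a query into ranked terms, statements
    and sources."""
    tree = parse_query(text)
    r_t = eval_tree(tree, indices)
    r_s = statements_for_terms(r_t, indices, top_terms)
    r_p = provenance_for_statements(r_s, indices, top_statements)
    return ResultBundle(terms=r_t, statements=r_s, sources=r_p, indices=indices)
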