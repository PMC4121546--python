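"""Knowledge-base indices: term, statement and provenance matrices plus a
lemmatised full-text term lookup.

* term index — square sparse matrix; entry = max weight among statements
  of all types between two terms (zero diagonal, symmetric);
* statement index — binary terms x statements matrix, two nonzero
  entries per statement column;
* provenance index — statements x sources matrix; a nonzero entry equals
  the statement's weight;
* full-text index — lemmatised phrase lookup with prefix wildcards and
  boolean combinations.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import scipy.sparse as sp

from ._boolparse import QueryTree, parse_boolean
from ._text import lemma_phrase
from .kb_builder import KBStatement, KnowledgeBase

__all__ = [
    "FullTextTermIndex",
    "KBIndices",
    "statement_id",
    "build_indices",
    "save_indices_json",
    "load_indices_json",
    "export_indices_tsv",
]

INDEX_FORMAT_VERSION = 1


def statement_id(statement: KBStatement) -> str:
    """Stable content-hash identifier of a statement."""
    key = f"{statement.term_a}|{statement.relation}|{statement.term_b}"
    return hashlib.sha1(key.encode("utf-8")).hexdigest()[:12]


class FullTextTermIndex:
    """Maps lemmatised phrase variants to canonical terms.

    Lookup strings support stemming (``parkinsonism`` matches
    ``parkinsonisms``), a trailing ``*`` prefix wildcard, and boolean
    AND/OR/NOT combinations.
    """

    def __init__(self, terms: Iterable[str]):
        self.terms: list[str] = sorted(set(terms))
        self._by_lemma: dict[str, set[str]] = {}
        for term in self.terms:
            self._by_lemma.setdefault(lemma_phrase(term), set()).add(term)

    def match(self, query: str) -> set[str]:
        """Canonical terms matching a full-text lookup expression."""
        tree = parse_boolean(query)
        return self._eval(tree)

    def _eval(self, tree: QueryTree) -> set[str]:
        if tree.op == "atom":
            return self._match_atom(tree.term)
        if tree.op == "NOT":
            return set(self.terms) - self._eval(tree.children[0])
        results = [self._eval(c) for c in tree.children]
        if tree.op == "AND":
            out = results[0]
            for r in results[1:]:
                out = out & r
            return out
        out = set()
        for r in results:
            out |= r
        return out

    def _match_atom(self, atom: str) -> set[str]:
        atom = atom.strip().lower()
        if atom.endswith("*"):
            prefix = atom[:-1]
            return {t for t in self.terms if t.startswith(prefix)}
        return set(self._by_lemma.get(lemma_phrase(atom), set()))


@dataclass
class KBIndices:
    """The three matrix indices plus the full-text lookup, with stable
    row/column orderings."""

    terms: list[str]
    statements: list[KBStatement]
    statement_ids: list[str]
    sources: list[str]
    term_matrix: sp.csr_matrix        # terms x terms, [0, 1], symmetric
    statement_matrix: sp.csr_matrix   # terms x statements, {0, 1}
    provenance_matrix: sp.csr_matrix  # statements x sources, [0, 1]
    fulltext: FullTextTermIndex

    def term_row(self, term: str) -> dict[str, float]:
        """Nonzero term-index row of ``term`` as a term -> weight map."""
        i = self.terms.index(term)
        row = self.term_matrix.getrow(i)
        return {self.terms[j]: float(v) for j, v in zip(row.indices, row.data)}

    def fulltext_match(self, query: str) -> set[str]:
        return self.fulltext.match(query)


def build_indices(
    kb: KnowledgeBase | Iterable[KBStatement],
    provenance_map: Mapping[tuple[str, str, str], Iterable[str]] | None = None,
    term_order: Iterable[str] | None = None,
    source_order: Iterable[str] | None = None,
) -> KBIndices:
    """Build the matrix indices from a knowledge base.

    ``provenance_map`` maps statement keys ``(term_a, relation, term_b)``
    to source identifiers; it defaults to the KB's own provenance.
    Row/column orderings default to first appearance (sources in sorted
    per-statement order) and can be pinned with ``term_order`` /
    ``source_order``.
    """
    if isinstance(kb, KnowledgeBase):
        statements = list(kb.statements)
        if provenance_map is None:
            provenance_map = kb.provenance
    else:
        statements = list(kb)
        if provenance_map is None:
            provenance_map = {}

    terms: list[str] = list(term_order) if term_order is not None else []
    term_pos: dict[str, int] = {t: i for i, t in enumerate(terms)}
    for st in statements:
        for t in (st.term_a, st.term_b):
            if t not in term_pos:
                term_pos[t] = len(terms)
                terms.append(t)

    sources: list[str] = list(source_order) if source_order is not None else []
    source_pos: dict[str, int] = {s: i for i, s in enumerate(sources)}
    for st in statements:
        for src in sorted(provenance_map.get(st.key, ())):
            if src not in source_pos:
                source_pos[src] = len(sources)
                sources.append(src)

    n, m, q = len(terms), len(statements), len(sources)

    term_mat = sp.dok_matrix((n, n))
    stmt_mat = sp.dok_matrix((n, m))
    prov_mat = sp.dok_matrix((m, q))
    for j, st in enumerate(statements):
        ia, ib = term_pos[st.term_a], term_pos[st.term_b]
        term_mat[ia, ib] = max(term_mat[ia, ib], st.weight)
        term_mat[ib, ia] = term_mat[ia, ib]
        stmt_mat[ia, j] = 1.0
        stmt_mat[ib, j] = 1.0
        for src in provenance_map.get(st.key, ()):
            if src not in source_pos:
                raise ValueError(f"statement references unknown source {src!r}")
            prov_mat[j, source_pos[src]] = st.weight

    return KBIndices(
        terms=terms,
        statements=statements,
        statement_ids=[statement_id(st) for st in statements],
        sources=sources,
        term_matrix=term_mat.tocsr(),
        statement_matrix=stmt_mat.tocsr(),
        provenance_matrix=prov_mat.tocsr(),
        fulltext=FullTextTermIndex(terms),
    )


# --- persistence -----------------------------------------------------------

def save_indices_json(indices: KBIndices, path: str | Path) -> None:
    """Persist the indices in a versioned JSON container; matrices are
    rebuilt on load from the statement list."""
    payload = {
        "format_version": INDEX_FORMAT_VERSION,
        "terms": indices.terms,
        "sources": indices.sources,
        "statements": [
            {
                "id": sid,
                "term_a": st.term_a,
                "relation": st.relation,
                "term_b": st.term_b,
                "weight": st.weight,
                "sources": sorted(
                    indices.sources[j]
                    for j in indices.provenance_matrix.getrow(i).indices
                ),
            }
            for i, (st, sid) in enumerate(
                zip(indices.statements, indices.statement_ids)
            )
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=1), encoding="utf-8")


def load_indices_json(path: str | Path) -> KBIndices:
    payload = json.loads(Path(path).read_text(encoding="utf-8"))
    version = payload.get("format_version")
    if version != INDEX_FORMAT_VERSION:
        raise ValueError(f"unsupported index format version {version!r}")
    statements = [
        KBStatement(rec["term_a"], rec["term_b"], rec["relation"], rec["weight"])
        for rec in payload["statements"]
    ]
    provenance = {
        st.key: frozenset(rec["sources"])
        for st, rec in zip(statements, payload["statements"])
    }
    return build_indices(statements, provenance)


def export_indices_tsv(indices: KBIndices, directory: str | Path) -> None:
    """Audit export: one TSV per matrix."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)

    def dump(name: str, rows: list[str], cols: list[str], matrix: sp.csr_matrix):
        lines = ["\t".join([name] + cols)]
        dense = matrix.toarray()
        for label, row in zip(rows, dense):
            lines.append("\t".join([label] + [f"{v:.6g}" for v in row]))
        (directory / f"{name}.tsv").write_text("\n".join(lines) + "\n", encoding="utf-8")

    dump("term_index", indices.terms, indices.terms, indices.term_matrix)
    dump("statement_index", indices.terms, indices.statement_ids, indices.statement_matrix)
    dump("provenance_index", indices.statement_ids, indices.sources, indices.provenance_matrix)
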