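"""Corpus input/output: Medline XML and plain-text readers, sentence
segmentation and corpus-level statistics.

Documents are sentence-segmented abstracts carrying a provenance
identifier (a PubMed ID string or a file stem).  Sentence indices are
1-based and contiguous, which is what every downstream distance
computation relies on.
"""

from __future__ import annotations

import logging
import re
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from ._text import ABBREVIATIONS, count_tokens

logger = logging.getLogger(__name__)

__all__ = [
    "Document",
    "CorpusStats",
    "MedlineParseError",
    "read_medline_xml",
    "read_plaintext",
    "write_plaintext",
    "segment_sentences",
    "corpus_statistics",
    "write_corpus_stats_tsv",
]


@dataclass(frozen=True)
class Document:
    """A sentence-segmented abstract with a provenance identifier."""

    doc_id: str
    sentences: tuple[str, ...]
    title: str | None = None

    def sentence(self, idx: int) -> str:
        """Return the sentence at 1-based index ``idx``."""
        if not 1 <= idx <= len(self.sentences):
            raise IndexError(f"sentence index {idx} out of range for {self.doc_id}")
        return self.sentences[idx - 1]

    @property
    def text(self) -> str:
        return " ".join(self.sentences)


class MedlineParseError(ValueError):
    """Raised for malformed Medline XML; carries the byte offset."""

    def __init__(self, message: str, offset: int | None = None):
        super().__init__(message)
        self.offset = offset


# --- sentence segmentation -------------------------------------------------

_BOUNDARY_RE = re.compile(r"[.!?]+(?=\s)")


def _is_boundary(text: str, end: int) -> bool:
    # `end` points just past the punctuation run; the following char is space.
    after = text[end:].lstrip()
    if not after:
        return True
    if not (after[0].isupper() or after[0].isdigit() or after[0] in "(\"'["):
        return False
    # abbreviation guard: look at the word immediately before the period
    before = text[:end].rstrip(".!?")
    m = re.search(r"([A-Za-z][A-Za-z.\-]*)$", before)
    if m:
        word = m.group(1).lower().rstrip(".")
        if word in ABBREVIATIONS:
            return False
    return True


def segment_sentences(text: str) -> list[str]:
    """Split ``text`` into sentences, 1-based contiguous numbering.

    Rule-based: a run of ``.!?`` followed by whitespace ends a sentence
    unless the preceding word is a known abbreviation or a single-letter
    initial, or the next character does not look like a sentence start.
    """
    text = text.strip()
    if not text:
        return []
    sentences: list[str] = []
    start = 0
    for m in _BOUNDARY_RE.finditer(text):
        if _is_boundary(text, m.end()):
            chunk = text[start : m.end()].strip()
            if chunk:
                sentences.append(re.sub(r"\s+", " ", chunk))
            start = m.end()
    tail = text[start:].strip()
    if tail:
        sentences.append(re.sub(r"\s+", " ", tail))
    return sentences


# --- readers ---------------------------------------------------------------

def read_medline_xml(path: str | Path) -> list[Document]:
    """Read a ``PubmedArticleSet`` export; one Document per citation with a
    non-empty abstract.  Citations without abstracts are skipped with a
    logged warning.  A whitespace-only file yields an empty list."""
    path = Path(path)
    raw = path.read_bytes()
    if not raw.strip():
        return []
    try:
        root = ET.fromstring(raw)
    except ET.ParseError as exc:
        line, col = exc.position
        offset = _line_col_to_offset(raw, line, col)
        raise MedlineParseError(
            f"malformed Medline XML in {path}: {exc} (byte offset {offset})",
            offset=offset,
        ) from exc

    docs: list[Document] = []
    for citation in root.iter("MedlineCitation"):
        pmid_el = citation.find("PMID")
        pmid = (pmid_el.text or "").strip() if pmid_el is not None else ""
        article = citation.find("Article")
        if article is None:
            logger.warning("citation %s has no Article element; skipped", pmid)
            continue
        title_el = article.find("ArticleTitle")
        title = (title_el.text or "").strip() if title_el is not None else None
        abstract_el = article.find("Abstract")
        parts: list[str] = []
        if abstract_el is not None:
            for at in abstract_el.findall("AbstractText"):
                txt = "".join(at.itertext()).strip()
                if txt:
                    parts.append(txt)
        abstract = " ".join(parts).strip()
        if not abstract:
            logger.warning("citation %s has no abstract; skipped", pmid)
            continue
        docs.append(Document(doc_id=pmid, sentences=tuple(segment_sentences(abstract)), title=title))
    return docs


def _line_col_to_offset(raw: bytes, line: int, col: int) -> int:
    lines = raw.split(b"\n")
    return sum(len(l) + 1 for l in lines[: line - 1]) + col


def read_plaintext(directory: str | Path) -> list[Document]:
    """Read one abstract per ``*.txt`` file; doc_id = file stem;
    deterministic lexicographic ordering.  Unreadable or whitespace-only
    files are logged and skipped."""
    directory = Path(directory)
    docs: list[Document] = []
    for path in sorted(directory.glob("*.txt")):
        try:
            text = path.read_text(encoding="utf-8")
        except (UnicodeDecodeError, OSError) as exc:
            logger.warning("skipping unreadable file %s: %s", path, exc)
            continue
        if not text.strip():
            logger.warning("skipping whitespace-only file %s", path)
            continue
        docs.append(Document(doc_id=path.stem, sentences=tuple(segment_sentences(text))))
    return docs


def write_plaintext(docs: Iterable[Document], directory: str | Path) -> None:
    """Write each document as ``<doc_id>.txt``, one sentence per line."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for doc in docs:
        (directory / f"{doc.doc_id}.txt").write_text(
            "\n".join(doc.sentences) + "\n", encoding="utf-8"
        )


# --- statistics ------------------------------------------------------------

@dataclass(frozen=True)
class CorpusStats:
    n_sources: int
    n_tokens: int
    n_basic_statements: int
    lexicon_size: int
    n_kb_cooc: int
    n_kb_sim: int
    tokens_per_source: float = field(init=False)
    statements_per_source: float = field(init=False)
    lexicon_per_token: float = field(init=False)
    sim_fraction: float = field(init=False)
    kb_per_source: float = field(init=False)
    kb_per_lexicon: float = field(init=False)

    def __post_init__(self):
        if self.n_sources == 0:
            raise ValueError("corpus statistics undefined for an empty corpus")
        kb = self.n_kb_cooc + self.n_kb_sim
        object.__setattr__(self, "tokens_per_source", self.n_tokens / self.n_sources)
        object.__setattr__(
            self, "statements_per_source", self.n_basic_statements / self.n_sources
        )
        object.__setattr__(
            self,
            "lexicon_per_token",
            self.lexicon_size / self.n_tokens if self.n_tokens else 0.0,
        )
        object.__setattr__(self, "sim_fraction", self.n_kb_sim / kb if kb else 0.0)
        object.__setattr__(self, "kb_per_source", kb / self.n_sources)
        object.__setattr__(
            self, "kb_per_lexicon", kb / self.lexicon_size if self.lexicon_size else 0.0
        )


def corpus_statistics(
    corpus: Sequence[Document],
    basic_statements: Sequence,
    kb_statements: Sequence = (),
) -> CorpusStats:
    """Counts and derived ratios for a corpus / knowledge-base pair.

    ``basic_statements`` are per-document co-occurrence statements
    (anything with ``term_a``/``term_b`` attributes); ``kb_statements``
    carry a ``relation`` attribute in ``{"cooc", "sim"}``.
    """
    if not corpus:
        raise ValueError("corpus statistics undefined for an empty corpus")
    n_tokens = sum(count_tokens(doc.text) for doc in corpus)
    lexicon: set[str] = set()
    for st in basic_statements:
        lexicon.add(st.term_a)
        lexicon.add(st.term_b)
    n_cooc = sum(1 for st in kb_statements if st.relation == "cooc")
    n_sim = sum(1 for st in kb_statements if st.relation == "sim")
    return CorpusStats(
        n_sources=len(corpus),
        n_tokens=n_tokens,
        n_basic_statements=len(basic_statements),
        lexicon_size=len(lexicon),
        n_kb_cooc=n_cooc,
        n_kb_sim=n_sim,
    )


_STATS_COLUMNS = (
    "SRC", "TOK", "BC", "LEX", "KB_cooc", "KB_sim",
    "T/S", "B/S", "L/T", "SM/KB", "KB/S", "KB/L",
)


def write_corpus_stats_tsv(stats: CorpusStats, path: str | Path) -> None:
    values = (
        stats.n_sources, stats.n_tokens, stats.n_basic_statements,
        stats.lexicon_size, stats.n_kb_cooc, stats.n_kb_sim,
        stats.tokens_per_source, stats.statements_per_source,
        stats.lexicon_per_token, stats.sim_fraction,
        stats.kb_per_source, stats.kb_per_lexicon,
    )
    lines = ["\t".join(_STATS_COLUMNS), "\t".join(repr(v) for v in values)]
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
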