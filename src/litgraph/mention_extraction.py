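"""Entity mention extraction behind a pluggable extractor interface.

Three built-in modes:

* ``dictionary`` — gazetteer with longest-match-wins semantics,
* ``chunker`` — a cheap noun-phrase chunker (maximal non-stopword runs),
* ``external-annotations`` — load mentions produced by an external NER
  from a TSV file (``doc_id<TAB>sentence_idx<TAB>term``).

A mention is emitted once per surface occurrence, so a term appearing
twice in one sentence yields two mentions; multiplicity is what the
per-document co-occurrence arithmetic counts.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from ._text import word_tokens
from .corpus_io import Document

__all__ = [
    "Mention",
    "ExtractorConfig",
    "normalize_term",
    "extract_mentions",
    "load_annotations_tsv",
    "write_annotations_tsv",
]


@dataclass(frozen=True, order=True)
class Mention:
    term: str
    doc_id: str
    sentence_idx: int


_STOPWORDS = frozenset(
    """a an the and or but of in on at to for with by from as is are was were be
    been being this that these those it its their his her we our they i you he
    she which who whom whose what when where how not no nor than then there some
    any all both each few more most other such only own same so very can will
    just should now during between into through after before above below again
    two three has have had do does did""".split()
)


@dataclass
class ExtractorConfig:
    """Exactly one extraction mode is active at a time."""

    mode: str = "dictionary"
    dictionary: Iterable[str] | None = None
    annotation_path: str | Path | None = None

    def __post_init__(self):
        if self.mode not in {"dictionary", "chunker", "external-annotations"}:
            raise ValueError(f"unknown extractor mode: {self.mode!r}")
        if self.mode == "dictionary" and self.dictionary is None:
            raise ValueError("dictionary mode requires a term list")
        if self.mode == "external-annotations" and self.annotation_path is None:
            raise ValueError("external-annotations mode requires annotation_path")


def normalize_term(surface: str) -> str:
    """Canonicalise a surface form: lower-case, collapse internal
    whitespace, strip surrounding punctuation.  Idempotent; an
    all-punctuation input yields the empty string (caller must discard)."""
    s = surface.lower().strip()
    s = re.sub(r"\s+", " ", s)
    s = s.strip("\"'()[]{}<>.,;:!?*%#—–")
    # hyphens are meaningful inside terms but not at the edges
    s = s.strip("- ")
    return s


def extract_mentions(doc: Document, config: ExtractorConfig) -> list[Mention]:
    """One Mention per surface occurrence, per the active mode."""
    if config.mode == "dictionary":
        return _gazetteer_mentions(doc, config.dictionary or ())
    if config.mode == "chunker":
        return _chunker_mentions(doc)
    annotations = load_annotations_tsv(config.annotation_path)
    return [m for m in annotations if m.doc_id == doc.doc_id]


def _gazetteer_mentions(doc: Document, dictionary: Iterable[str]) -> list[Mention]:
    entries: dict[tuple[str, ...], str] = {}
    for raw in dictionary:
        canonical = normalize_term(raw)
        if not canonical:
            continue
        entries[tuple(word_tokens(canonical))] = canonical
    if not entries:
        return []
    max_len = max(len(k) for k in entries)
    mentions: list[Mention] = []
    for idx, sentence in enumerate(doc.sentences, start=1):
        tokens = [t.lower() for t in word_tokens(sentence)]
        i = 0
        while i < len(tokens):
            matched = False
            for n in range(min(max_len, len(tokens) - i), 0, -1):
                gram = tuple(tokens[i : i + n])
                if gram in entries:
                    mentions.append(Mention(entries[gram], doc.doc_id, idx))
                    i += n  # consume — longest match wins, no nested emission
                    matched = True
                    break
            if not matched:
                i += 1
    return mentions


def _chunker_mentions(doc: Document) -> list[Mention]:
    """Maximal runs of non-stopword, non-numeric tokens as noun-phrase
    approximations."""
    mentions: list[Mention] = []
    for idx, sentence in enumerate(doc.sentences, start=1):
        run: list[str] = []
        for tok in word_tokens(sentence) + [""]:
            low = tok.lower()
            if low and low not in _STOPWORDS and not low.isdigit():
                run.append(low)
            else:
                if run:
                    term = normalize_term(" ".join(run))
                    if term:
                        mentions.append(Mention(term, doc.doc_id, idx))
                run = []
    return mentions


def load_annotations_tsv(path: str | Path) -> list[Mention]:
    """Read externally produced mentions: header line then
    ``doc_id<TAB>sentence_idx<TAB>term`` rows."""
    mentions: list[Mention] = []
    with open(path, encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header is None:
            return []
        for row in reader:
            if not row or all(not c.strip() for c in row):
                continue
            doc_id, sentence_idx, term = row[0], int(row[1]), normalize_term(row[2])
            if term:
                mentions.append(Mention(term, doc_id, sentence_idx))
    return mentions


def write_annotations_tsv(mentions: Iterable[Mention], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["doc_id", "sentence_idx", "term"])
        for m in mentions:
            writer.writerow([m.doc_id, m.sentence_idx, m.term])
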