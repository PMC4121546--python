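"""Shared lexical helpers: tokenisation, normalisation and a light stemmer.

The stemmer is intentionally small — it only strips regular English
plural/derivational endings so that spelling variants such as
``parkinsonism``/``parkinsonisms`` collapse to the same key.  It is not a
full Porter stemmer and does not try to be.
"""

from __future__ import annotations

import re

_WORD_RE = re.compile(r"[A-Za-z0-9]+(?:[-'/][A-Za-z0-9]+)*")

#: words that never end a sentence even when followed by a period
ABBREVIATIONS = frozenset(
    {
        "e.g", "i.e", "etc", "cf", "vs", "al", "ca", "approx", "resp",
        "fig", "figs", "eq", "eqs", "no", "nos", "dr", "prof", "st",
        "sp", "spp", "mr", "mrs", "ms", "jr", "sr", "inc", "dept",
    }
)


def word_tokens(text: str) -> list[str]:
    """Alphanumeric tokens (internal hyphen/apostrophe/slash kept)."""
    return _WORD_RE.findall(text)


def count_tokens(text: str) -> int:
    """Whitespace-delimited tokens that contain at least one alphanumeric
    character after stripping surrounding punctuation."""
    n = 0
    for raw in text.split():
        stripped = raw.strip("\"'()[]{}<>.,;:!?*%#—–-")
        if any(ch.isalnum() for ch in stripped):
            n += 1
    return n


def stem(token: str) -> str:
    """Light plural/variant stripper; lower-cases its input."""
    t = token.lower()
    if len(t) > 4 and t.endswith("sses"):
        return t[:-2]
    if len(t) > 4 and t.endswith("ies"):
        return t[:-3] + "y"
    if (
        len(t) > 3
        and t.endswith("s")
        and not t.endswith("ss")
        and not t.endswith("us")
        and not t.endswith("is")
    ):
        return t[:-1]
    return t


def lemma_phrase(phrase: str) -> str:
    """Canonical lemmatised form of a multi-word phrase."""
    return " ".join(stem(tok) for tok in word_tokens(phrase))
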