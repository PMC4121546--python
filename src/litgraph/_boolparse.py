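"""A tiny recursive-descent parser for boolean term expressions.

Grammar (NOT binds tightest, then AND, then OR; operators are
case-insensitive keywords):

    expr   := orseq
    orseq  := andseq ( OR andseq )*
    andseq := unary ( AND unary )*
    unary  := NOT unary | '(' expr ')' | atom
    atom   := quoted string | run of consecutive plain words

Consecutive plain words form a single multi-word atom, so
``magnetic resonance parkinsonism index`` parses as one leaf.
AND/OR nodes are n-ary and flattened.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

__all__ = ["QueryTree", "QuerySyntaxError", "parse_boolean"]


class QuerySyntaxError(ValueError):
    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (at position {position})")
        self.position = position


@dataclass(frozen=True)
class QueryTree:
    """Leaf: ``op == "atom"`` with ``term`` set.  Internal node:
    ``op in {"AND", "OR", "NOT"}`` with children."""

    op: str
    term: str | None = None
    children: tuple["QueryTree", ...] = ()

    def __post_init__(self):
        if self.op == "atom":
            if not self.term:
                raise ValueError("atom needs a term")
        elif self.op == "NOT":
            if len(self.children) != 1:
                raise ValueError("NOT is unary")
        elif self.op in {"AND", "OR"}:
            if len(self.children) < 2:
                raise ValueError(f"{self.op} needs at least two children")
        else:
            raise ValueError(f"unknown operator {self.op!r}")


_TOKEN_RE = re.compile(
    r"""\s*(?:
        (?P<lparen>\() |
        (?P<rparen>\)) |
        (?P<quoted>"[^"]*"|'[^']*') |
        (?P<word>[^\s()"']+)
    )""",
    re.VERBOSE,
)

_KEYWORDS = {"and": "AND", "or": "OR", "not": "NOT"}


def _tokenize(text: str) -> list[tuple[str, str, int]]:
    tokens: list[tuple[str, str, int]] = []
    pos = 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if m is None:
            break
        pos = m.end()
        start = m.start(m.lastgroup)
        if m.lastgroup == "lparen":
            tokens.append(("(", "(", start))
        elif m.lastgroup == "rparen":
            tokens.append((")", ")", start))
        elif m.lastgroup == "quoted":
            tokens.append(("atomword", m.group("quoted")[1:-1], start))
        else:
            word = m.group("word")
            kw = _KEYWORDS.get(word.lower())
            if kw:
                tokens.append((kw, word, start))
            else:
                tokens.append(("word", word, start))
    return tokens


class _Parser:
    def __init__(self, text: str):
        self.text = text
        self.tokens = _tokenize(text)
        self.i = 0

    def peek(self) -> tuple[str, str, int] | None:
        return self.tokens[self.i] if self.i < len(self.tokens) else None

    def advance(self) -> tuple[str, str, int]:
        tok = self.tokens[self.i]
        self.i += 1
        return tok

    def fail(self, message: str) -> None:
        pos = self.tokens[self.i][2] if self.i < len(self.tokens) else len(self.text)
        raise QuerySyntaxError(message, pos)

    def parse(self) -> QueryTree:
        if not self.tokens:
            self.fail("empty query")
        tree = self.or_seq()
        if self.peek() is not None:
            self.fail(f"unexpected token {self.peek()[1]!r}")
        return tree

    def or_seq(self) -> QueryTree:
        parts = [self.and_seq()]
        while self.peek() and self.peek()[0] == "OR":
            self.advance()
            parts.append(self.and_seq())
        if len(parts) == 1:
            return parts[0]
        return QueryTree("OR", children=tuple(_flatten("OR", parts)))

    def and_seq(self) -> QueryTree:
        parts = [self.unary()]
        while self.peek() and self.peek()[0] == "AND":
            self.advance()
            parts.append(self.unary())
        if len(parts) == 1:
            return parts[0]
        return QueryTree("AND", children=tuple(_flatten("AND", parts)))

    def unary(self) -> QueryTree:
        tok = self.peek()
        if tok is None:
            self.fail("dangling operator")
        kind, value, pos = tok
        if kind == "NOT":
            self.advance()
            return QueryTree("NOT", children=(self.unary(),))
        if kind == "(":
            self.advance()
            inner = self.or_seq()
            closing = self.peek()
            if closing is None or closing[0] != ")":
                raise QuerySyntaxError("unbalanced parentheses", pos)
            self.advance()
            return inner
        return self.atom()

    def atom(self) -> QueryTree:
        words: list[str] = []
        while True:
            tok = self.peek()
            if tok is None or tok[0] not in {"word", "atomword"}:
                break
            words.append(self.advance()[1])
        if not words:
            self.fail("expected a query term")
        return QueryTree("atom", term=" ".join(words))


def _flatten(op: str, parts: list[QueryTree]) -> list[QueryTree]:
    out: list[QueryTree] = []
    for p in parts:
        if p.op == op:
            out.extend(p.children)
        else:
            out.append(p)
    return out


def parse_boolean(text: str) -> QueryTree:
    """Parse ``text`` into a QueryTree; raises QuerySyntaxError with the
    character position on malformed input."""
    if not text or not text.strip():
        raise QuerySyntaxError("empty query", 0)
    return _Parser(text).parse()
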