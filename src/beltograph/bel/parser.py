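"""Recursive-descent parser for the supported BEL statement subset.

The grammar (whitespace-insensitive between tokens)::

    statement    := term relation term
    term         := FUNCTION "(" args ")"
    args         := arg ("," arg)*
    arg          := term | modification | namespace_id | token
    modification := MODKIND "(" args ")"
    namespace_id := IDENT ":" (IDENT | QUOTED)
    token        := IDENT | QUOTED

Function and relation vocabularies are closed and case-sensitive;
namespaces are checked against a configurable allow-list.  Each error
class is distinct so callers can react differently to a typo in a
function name versus a hallucinated namespace, and every error carries
the character offset where parsing failed.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from .model import (
    DEFAULT_NAMESPACES,
    ENTITY_FUNCTIONS,
    FUNCTIONS,
    MODIFICATIONS,
    RELATIONS,
    BelModification,
    BelStatement,
    BelTerm,
    NamespaceId,
)


class BelParseError(ValueError):
    """Base class for all BEL parsing failures."""

    def __init__(self, message: str, offset: int) -> None:
        super().__init__(f"{message} (at offset {offset})")
        self.offset = offset


class BelSyntaxError(BelParseError):
    """Malformed surface syntax: unbalanced parentheses, bad tokens, trailing text."""


class UnknownFunctionError(BelParseError):
    """An identifier used as a function/modification is not in the closed vocabulary."""


class UnknownRelationError(BelParseError):
    """The predicate between subject and object is not a supported relation."""


class UnknownNamespaceError(BelParseError):
    """A namespace prefix is not in the configured allow-list."""


@dataclass(frozen=True)
class _Token:
    kind: str  # IDENT | QUOTED | LPAR | RPAR | COMMA | COLON
    value: str
    offset: int


_TOKEN_RE = re.compile(
    r"""
    (?P<WS>\s+)
  | (?P<IDENT>\w+)
  | (?P<QUOTED>"(?:[^"\\]|\\.)*")
  | (?P<LPAR>\()
  | (?P<RPAR>\))
  | (?P<COMMA>,)
  | (?P<COLON>:)
    """,
    re.VERBOSE,
)


def _tokenize(text: str) -> list[_Token]:
    tokens: list[_Token] = []
    pos = 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if m is None:
            raise BelSyntaxError(f"unexpected character {text[pos]!r}", pos)
        kind = m.lastgroup or ""
        if kind != "WS":
            value = m.group()
            if kind == "QUOTED":
                value = value[1:-1].replace('\\"', '"').replace("\\\\", "\\")
            tokens.append(_Token(kind, value, pos))
        pos = m.end()
    return tokens


class _Parser:
    def __init__(self, tokens: list[_Token], text_len: int, namespaces: frozenset[str]):
        self.tokens = tokens
        self.pos = 0
        self.text_len = text_len
        self.namespaces = namespaces

    # -- token helpers -------------------------------------------------
    def _peek(self, ahead: int = 0) -> _Token | None:
        i = self.pos + ahead
        return self.tokens[i] if i < len(self.tokens) else None

    def _next(self) -> _Token:
        tok = self._peek()
        if tok is None:
            raise BelSyntaxError("unexpected end of input", self.text_len)
        self.pos += 1
        return tok

    def _expect(self, kind: str, what: str) -> _Token:
        tok = self._peek()
        if tok is None:
            raise BelSyntaxError(f"expected {what}, got end of input", self.text_len)
        if tok.kind != kind:
            raise BelSyntaxError(f"expected {what}, got {tok.value!r}", tok.offset)
        return self._next()

    # -- grammar productions -------------------------------------------
    def parse_statement(self) -> BelStatement:
        subject = self.parse_term()
        rel_tok = self._expect("IDENT", "a relation")
        if rel_tok.value not in RELATIONS:
            raise UnknownRelationError(f"unknown relation {rel_tok.value!r}", rel_tok.offset)
        obj = self.parse_term()
        trailing = self._peek()
        if trailing is not None:
            raise BelSyntaxError(f"trailing input {trailing.value!r}", trailing.offset)
        return BelStatement(subject=subject, relation=rel_tok.value, object=obj)

    def parse_term(self) -> BelTerm:
        tok = self._expect("IDENT", "a BEL function")
        nxt = self._peek()
        if nxt is None or nxt.kind != "LPAR":
            offset = nxt.offset if nxt is not None else self.text_len
            raise BelSyntaxError("expected '(' after function name", offset)
        if tok.value not in FUNCTIONS:
            raise UnknownFunctionError(f"unknown BEL function {tok.value!r}", tok.offset)
        self._next()  # consume '('
        args = self._parse_args()
        self._expect("RPAR", "')'")
        return self._assemble_term(tok, args)

    def _parse_args(self) -> list[object]:
        args: list[object] = []
        if self._peek() is not None and self._peek().kind == "RPAR":
            return args
        while True:
            args.append(self._parse_arg())
            tok = self._peek()
            if tok is not None and tok.kind == "COMMA":
                self._next()
                continue
            return args

    def _parse_arg(self) -> object:
        tok = self._peek()
        if tok is None:
            raise BelSyntaxError("unexpected end of input in argument list", self.text_len)
        if tok.kind == "QUOTED":
            self._next()
            return tok.value
        if tok.kind == "IDENT":
            nxt = self._peek(1)
            if nxt is not None and nxt.kind == "LPAR":
                if tok.value in MODIFICATIONS:
                    self._next()
                    self._next()
                    args = self._parse_args()
                    self._expect("RPAR", "')'")
                    return self._assemble_modification(tok, args)
                return self.parse_term()
            if nxt is not None and nxt.kind == "COLON":
                self._next()
                self._next()
                name_tok = self._peek()
                if name_tok is None or name_tok.kind not in ("IDENT", "QUOTED"):
                    offset = name_tok.offset if name_tok is not None else self.text_len
                    raise BelSyntaxError("expected identifier or quoted name after ':'", offset)
                self._next()
                if tok.value.upper() not in self.namespaces:
                    raise UnknownNamespaceError(
                        f"unknown namespace {tok.value!r}", tok.offset
                    )
                return NamespaceId(tok.value, name_tok.value)
            self._next()
            return tok.value
        raise BelSyntaxError(f"unexpected {tok.value!r} in argument list", tok.offset)

    # -- term assembly with structural checks ---------------------------
    def _assemble_modification(self, tok: _Token, args: list[object]) -> BelModification:
        clean: list[object] = []
        for a in args:
            if isinstance(a, BelTerm):
                raise BelSyntaxError(
                    f"modification {tok.value!r} cannot contain a term", tok.offset
                )
            clean.append(a)
        if not clean:
            raise BelSyntaxError(f"modification {tok.value!r} requires arguments", tok.offset)
        if tok.value == "pmod" and not 1 <= len(clean) <= 3:
            raise BelSyntaxError("pmod takes 1-3 arguments", tok.offset)
        return BelModification(kind=tok.value, args=tuple(clean))  # type: ignore[arg-type]

    def _assemble_term(self, tok: _Token, args: list[object]) -> BelTerm:
        function = tok.value
        entity: NamespaceId | None = None
        inner: list[BelTerm] = []
        mods: list[BelModification] = []
        for a in args:
            if isinstance(a, BelTerm):
                inner.append(a)
            elif isinstance(a, BelModification):
                mods.append(a)
            elif isinstance(a, NamespaceId):
                if entity is not None:
                    raise BelSyntaxError(
                        f"{function}() takes at most one entity", tok.offset
                    )
                entity = a
            else:
                raise BelSyntaxError(
                    f"bare token {a!r} not allowed as {function}() argument", tok.offset
                )
        if function in ENTITY_FUNCTIONS and entity is None:
            raise BelSyntaxError(f"{function}() requires a namespace:id entity", tok.offset)
        if function in ENTITY_FUNCTIONS and inner:
            raise BelSyntaxError(f"{function}() cannot contain inner terms", tok.offset)
        if function == "act":
            if len(inner) != 1 or entity is not None:
                raise BelSyntaxError("act() requires exactly one inner term", tok.offset)
            if sum(1 for m in mods if m.kind == "ma") > 1:
                raise BelSyntaxError("act() takes at most one ma() modification", tok.offset)
        if function in ("deg", "tloc") and (len(inner) != 1 or entity is not None):
            raise BelSyntaxError(f"{function}() requires exactly one inner term", tok.offset)
        if function == "complex" and entity is None and len(inner) < 2:
            raise BelSyntaxError(
                "complex() requires an entity or at least two inner terms", tok.offset
            )
        return BelTerm(
            function=function,
            entity=entity,
            inner_terms=tuple(inner),
            modifications=tuple(mods),
        )


def parse_bel(
    text: str, namespaces: frozenset[str] | set[str] = DEFAULT_NAMESPACES
) -> BelStatement:
    """Parse a BEL statement string into a :class:`BelStatement`.

    Whitespace and quoting are normalized; namespaces are upper-cased.
    Raises :class:`BelSyntaxError`, :class:`UnknownFunctionError`,
    :class:`UnknownRelationError` or :class:`UnknownNamespaceError`, each
    carrying the character offset of the failure.
    """
    if not text or not text.strip():
        raise BelSyntaxError("empty statement", 0)
    ns = frozenset(n.upper() for n in namespaces)
    parser = _Parser(_tokenize(text), len(text), ns)
    return parser.parse_statement()


def parse_term(
    text: str, namespaces: frozenset[str] | set[str] = DEFAULT_NAMESPACES
) -> BelTerm:
    """Parse a single BEL term (no relation), e.g. ``p(HGNC:TP53)``."""
    if not text or not text.strip():
        raise BelSyntaxError("empty term", 0)
    ns = frozenset(n.upper() for n in namespaces)
    parser = _Parser(_tokenize(text), len(text), ns)
    term = parser.parse_term()
    trailing = parser._peek()
    if trailing is not None:
        raise BelSyntaxError(f"trailing input {trailing.value!r}", trailing.offset)
    return term
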