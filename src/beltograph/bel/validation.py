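"""Structural and grounding validation of BEL statements.

Validation returns machine-readable violation records rather than
raising: an extracted statement with a hallucinated identifier is data
the reviewer workflow needs to see, not an exception.  Each violation is
``{code, path, message}`` where ``path`` locates the offending component
(``subject``, ``object``, or a dotted path into the term tree).
"""

from __future__ import annotations

from dataclasses import dataclass

from .model import (
    ENTITY_FUNCTIONS,
    MAX_TERM_DEPTH,
    BelStatement,
    BelTerm,
    NamespaceId,
)


@dataclass(frozen=True)
class Violation:
    """A single validation finding; ``code`` is stable for programmatic handling."""

    code: str
    path: str
    message: str

    def to_dict(self) -> dict[str, str]:
        return {"code": self.code, "path": self.path, "message": self.message}


def _check_term(term: BelTerm, path: str, out: list[Violation]) -> None:
    fn = term.function
    if fn in ENTITY_FUNCTIONS and term.entity is None:
        out.append(
            Violation("missing-entity", path, f"{fn}() requires a namespace:id entity")
        )
    if fn == "act":
        if len(term.inner_terms) != 1:
            out.append(
                Violation("bad-arity", path, "act() requires exactly one inner term")
            )
        if sum(1 for m in term.modifications if m.kind == "ma") > 1:
            out.append(
                Violation("bad-arity", path, "act() takes at most one ma() modification")
            )
    if fn in ("deg", "tloc") and len(term.inner_terms) != 1:
        out.append(
            Violation("bad-arity", path, f"{fn}() requires exactly one inner term")
        )
    if fn == "complex" and term.entity is None and len(term.inner_terms) < 2:
        out.append(
            Violation(
                "bad-arity", path, "complex() requires an entity or >=2 inner terms"
            )
        )
    for mod in term.modifications:
        if mod.kind == "pmod":
            if not 1 <= len(mod.args) <= 3:
                out.append(
                    Violation("bad-arity", f"{path}.pmod", "pmod takes 1-3 arguments")
                )
            if len(mod.args) == 3:
                pos = mod.args[2]
                if isinstance(pos, str) and not (pos.isdigit() and int(pos) > 0):
                    out.append(
                        Violation(
                            "bad-position",
                            f"{path}.pmod",
                            f"pmod position must be a positive integer, got {pos!r}",
                        )
                    )
    for i, inner in enumerate(term.inner_terms):
        _check_term(inner, f"{path}.{i}", out)


def validate_statement(
    statement: BelStatement, allowed: set[NamespaceId] | frozenset[NamespaceId] = frozenset()
) -> list[Violation]:
    """Validate a statement structurally and, optionally, against an allow-list.

    When ``allowed`` is non-empty, every grounded entity in the statement
    must appear in it; entities outside the allow-list yield
    ``ungrounded-entity`` violations (the guard against LLM-invented
    identifiers).  An empty ``allowed`` skips the grounding check.
    Returns an empty list iff the statement is fully valid.
    """
    out: list[Violation] = []
    for side in ("subject", "object"):
        term: BelTerm = getattr(statement, side)
        _check_term(term, side, out)
        if term.depth() > MAX_TERM_DEPTH:
            out.append(
                Violation(
                    "too-deep",
                    side,
                    f"term depth {term.depth()} exceeds maximum {MAX_TERM_DEPTH}",
                )
            )
        if allowed:
            for entity in term.all_entities():
                if entity not in allowed:
                    out.append(
                        Violation(
                            "ungrounded-entity",
                            side,
                            f"{entity.to_bel()} is not in the pre-annotated entity list",
                        )
                    )
    return out
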