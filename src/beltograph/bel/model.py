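"""Core BEL data model.

Biological Expression Language (BEL) encodes causal and correlative
biological relationships as subject-predicate-object statements whose
subject and object are functionally composed terms, e.g.::

    act(p(HGNC:AKT1),ma(GO:"kinase activity")) directlyIncreases
        p(HGNC:HSF1,pmod(Ph,Ser,326))

meaning the kinase activity of AKT1 directly increases the abundance of
HSF1 phosphorylated at serine 326.  This module defines the term tree,
relation vocabulary and statement types for the BEL subset this package
extracts, plus the canonical serializer used for node identity and
statement comparison.

The canonical surface form is deterministic: no whitespace, namespaces
upper-case, entity names double-quoted exactly when they contain
characters outside ``[A-Za-z0-9_]``, arguments in grammar order.  Two
terms are structurally equal iff their canonical strings are equal.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Union

#: Term functions of the supported BEL subset.
FUNCTIONS = frozenset({"p", "g", "r", "a", "complex", "bp", "path", "act", "deg", "tloc"})

#: Functions whose first argument is a grounded entity.
ENTITY_FUNCTIONS = frozenset({"p", "g", "r", "a", "bp", "path"})

#: Modification functions (arguments of entity/activity terms).
MODIFICATIONS = frozenset({"pmod", "ma", "frag", "loc"})

#: Causal/correlative relations of the supported subset (case-sensitive).
RELATIONS = frozenset(
    {
        "increases",
        "decreases",
        "directlyIncreases",
        "directlyDecreases",
        "association",
        "regulates",
    }
)

#: Default namespace allow-list; extensible via the ``namespaces=`` parameter
#: of the parser.  Covers the vocabularies commonly emitted by grounding
#: services for genes, processes, chemicals and protein families.
DEFAULT_NAMESPACES = frozenset(
    {
        "HGNC",
        "GO",
        "CHEBI",
        "MESH",
        "UNIPROT",
        "NCBIGENE",
        "MGI",
        "RGD",
        "FPLX",
        "DOID",
        "HP",
        "EFO",
        "PUBCHEM",
        "INTERPRO",
        "TEXT",
    }
)

_WORD_RE = re.compile(r"^\w+$")
MAX_TERM_DEPTH = 4


def _quote_if_needed(name: str) -> str:
    """Quote ``name`` iff it contains non-word characters; escape embedded quotes."""
    if _WORD_RE.match(name):
        return name
    escaped = name.replace("\\", "\\\\").replace('"', '\\"')
    return f'"{escaped}"'


@dataclass(frozen=True)
class NamespaceId:
    """A grounded entity reference, e.g. ``HGNC:AKT1`` or ``GO:"kinase activity"``.

    The namespace code is upper-cased on construction so that structural
    equality matches canonical-string equality; the identifier/name is
    preserved verbatim.
    """

    namespace: str
    name: str

    def __post_init__(self) -> None:
        if not self.namespace:
            raise ValueError("namespace must be non-empty")
        if not self.name:
            raise ValueError("identifier/name must be non-empty")
        object.__setattr__(self, "namespace", self.namespace.upper())

    def to_bel(self) -> str:
        return f"{self.namespace}:{_quote_if_needed(self.name)}"

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.to_bel()


ModArg = Union[str, NamespaceId]


@dataclass(frozen=True)
class BelModification:
    """A modification argument such as ``pmod(Ph,Ser,326)`` or ``ma(GO:"kinase activity")``.

    ``kind`` is one of pmod/ma/frag/loc; ``args`` are plain tokens or
    namespace references in grammar order.
    """

    kind: str
    args: tuple[ModArg, ...]

    def __post_init__(self) -> None:
        if self.kind not in MODIFICATIONS:
            raise ValueError(f"unknown modification kind: {self.kind!r}")
        object.__setattr__(self, "args", tuple(self.args))

    def to_bel(self) -> str:
        rendered = ",".join(
            a.to_bel() if isinstance(a, NamespaceId) else _quote_if_needed(a)
            for a in self.args
        )
        return f"{self.kind}({rendered})"


@dataclass(frozen=True)
class BelTerm:
    """A functional BEL term: a function applied to an entity, inner terms and modifications.

    Examples: ``p(HGNC:TP53)``; ``act(p(HGNC:AKT1),ma(GO:"kinase activity"))``;
    ``complex(p(HGNC:JUN),p(HGNC:FOS))``.
    """

    function: str
    entity: NamespaceId | None = None
    inner_terms: tuple["BelTerm", ...] = field(default_factory=tuple)
    modifications: tuple[BelModification, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.function not in FUNCTIONS:
            raise ValueError(f"unknown BEL function: {self.function!r}")
        object.__setattr__(self, "inner_terms", tuple(self.inner_terms))
        object.__setattr__(self, "modifications", tuple(self.modifications))

    def depth(self) -> int:
        if not self.inner_terms:
            return 1
        return 1 + max(t.depth() for t in self.inner_terms)

    def primary_entity(self) -> NamespaceId | None:
        """First grounded entity in depth-first order (used for namespace-level comparison)."""
        if self.entity is not None:
            return self.entity
        for inner in self.inner_terms:
            found = inner.primary_entity()
            if found is not None:
                return found
        return None

    def all_entities(self) -> list[NamespaceId]:
        out: list[NamespaceId] = []
        if self.entity is not None:
            out.append(self.entity)
        for inner in self.inner_terms:
            out.extend(inner.all_entities())
        for mod in self.modifications:
            out.extend(a for a in mod.args if isinstance(a, NamespaceId))
        return out

    def to_bel(self) -> str:
        parts: list[str] = []
        if self.entity is not None:
            parts.append(self.entity.to_bel())
        parts.extend(t.to_bel() for t in self.inner_terms)
        parts.extend(m.to_bel() for m in self.modifications)
        return f"{self.function}({','.join(parts)})"


@dataclass(frozen=True)
class BelStatement:
    """A subject-predicate-object BEL statement."""

    subject: BelTerm
    relation: str
    object: BelTerm

    def __post_init__(self) -> None:
        if self.relation not in RELATIONS:
            raise ValueError(f"unknown BEL relation: {self.relation!r}")

    def to_bel(self) -> str:
        return f"{self.subject.to_bel()} {self.relation} {self.object.to_bel()}"


def serialize_bel(statement: BelStatement) -> str:
    """Render a statement in canonical form.

    The canonical string is deterministic and doubles as the statement's
    identity: no space after commas, a single space around the relation,
    names quoted only when they contain non-word characters.
    """
    return statement.to_bel()


def serialize_term(term: BelTerm) -> str:
    """Canonical form of a single term (the node-identity key in graphs)."""
    return term.to_bel()
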