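"""Deduplicated property graph built from evidence records.

Node identity is the canonical BEL term string, so ``p(HGNC:AKT1)`` and
``act(p(HGNC:AKT1),ma(...))`` are distinct nodes — BEL distinguishes an
entity from its activity.  One edge exists per distinct
(subject, relation, object) triple; repeated extractions of the same
triple merge their evidence onto that edge.  Numeric ids are assigned in
first-appearance order starting at 0, which makes graph construction
deterministic given record order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .bel import BelTerm, parse_term, serialize_term
from .extraction import EvidenceRecord


@dataclass(frozen=True)
class EvidenceRef:
    """One piece of evidence attached to an edge."""

    sentence: str
    source_id: str
    paragraph_index: int


@dataclass(frozen=True)
class KGNode:
    """A graph node keyed by its canonical BEL term."""

    node_id: int
    canonical_term: str
    label: str
    namespace: str
    identifier: str


@dataclass(frozen=True)
class KGEdge:
    """A deduplicated interaction edge with merged evidence."""

    edge_id: int
    source: int
    target: int
    relation: str
    evidence: tuple[EvidenceRef, ...]
    bel: str

    def __post_init__(self) -> None:
        if not self.evidence:
            raise ValueError("edge evidence must be non-empty")


@dataclass
class KnowledgeGraph:
    """Nodes + edges + network-level attributes."""

    name: str = "knowledge-graph"
    nodes: list[KGNode] = field(default_factory=list)
    edges: list[KGEdge] = field(default_factory=list)
    attributes: dict[str, object] = field(default_factory=dict)

    def node_by_term(self, canonical_term: str) -> KGNode | None:
        for node in self.nodes:
            if node.canonical_term == canonical_term:
                return node
        return None

    def validate(self) -> None:
        """Check structural invariants: unique ids, unique terms, no orphan edges."""
        node_ids = [n.node_id for n in self.nodes]
        if len(set(node_ids)) != len(node_ids):
            raise ValueError("duplicate node ids")
        terms = [n.canonical_term for n in self.nodes]
        if len(set(terms)) != len(terms):
            raise ValueError("duplicate canonical terms across nodes")
        edge_ids = [e.edge_id for e in self.edges]
        if len(set(edge_ids)) != len(edge_ids):
            raise ValueError("duplicate edge ids")
        known = set(node_ids)
        for e in self.edges:
            if e.source not in known or e.target not in known:
                raise ValueError(f"edge {e.edge_id} references a missing node")


def _node_display(term: BelTerm) -> tuple[str, str, str]:
    """(label, namespace, identifier) for a term; falls back to the canonical string."""
    entity = term.primary_entity()
    if entity is None:
        canonical = serialize_term(term)
        return canonical, "", ""
    return entity.name, entity.namespace, entity.name


def statements_to_graph(
    records: list[EvidenceRecord],
    name: str = "knowledge-graph",
    dedup_edges: bool = True,
) -> KnowledgeGraph:
    """Build a deduplicated knowledge graph from evidence records.

    A node is created per distinct canonical subject/object term, an
    edge per distinct (subject, relation, object) triple with evidence
    lists merged in record order.  With ``dedup_edges=False`` every
    record gets its own edge (one-edge-per-evidence mode).
    """
    graph = KnowledgeGraph(name=name)
    term_to_id: dict[str, int] = {}
    triple_to_edge: dict[tuple[int, str, int], int] = {}
    edge_evidence: dict[int, list[EvidenceRef]] = {}

    def intern_node(term: BelTerm) -> int:
        canonical = serialize_term(term)
        if canonical in term_to_id:
            return term_to_id[canonical]
        node_id = len(graph.nodes)
        label, ns, ident = _node_display(term)
        graph.nodes.append(
            KGNode(
                node_id=node_id,
                canonical_term=canonical,
                label=label,
                namespace=ns,
                identifier=ident,
            )
        )
        term_to_id[canonical] = node_id
        return node_id

    pending: list[tuple[int, tuple[int, str, int], str]] = []
    sources: list[str] = []
    for rec in records:
        s = intern_node(rec.statement.subject)
        t = intern_node(rec.statement.object)
        triple = (s, rec.statement.relation, t)
        ref = EvidenceRef(
            sentence=rec.evidence_sentence,
            source_id=rec.source_id,
            paragraph_index=rec.paragraph_index,
        )
        if rec.source_id not in sources:
            sources.append(rec.source_id)
        if dedup_edges and triple in triple_to_edge:
            edge_evidence[triple_to_edge[triple]].append(ref)
            continue
        edge_id = len(pending)
        if dedup_edges:
            triple_to_edge[triple] = edge_id
        edge_evidence[edge_id] = [ref]
        pending.append((edge_id, triple, rec.bel))

    for edge_id, (s, rel, t), bel in pending:
        graph.edges.append(
            KGEdge(
                edge_id=edge_id,
                source=s,
                target=t,
                relation=rel,
                evidence=tuple(edge_evidence[edge_id]),
                bel=bel,
            )
        )
    graph.attributes = {"sources": sources, "generator": "beltograph"}
    graph.validate()
    return graph


def graph_statement_strings(graph: KnowledgeGraph) -> list[str]:
    """Canonical BEL statement strings of every edge (sanity/round-trip aid)."""
    return [e.bel for e in graph.edges]


def node_term(node: KGNode) -> BelTerm:
    """Parse a node's canonical term back into a :class:`BelTerm`."""
    return parse_term(node.canonical_term)
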