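"""CX2 (Cytoscape Exchange v2) reading and writing.

CX2 is the aspect-oriented JSON interchange format of the Cytoscape
ecosystem: a document is a JSON array of single-key aspect objects
(CXVersion header, attributeDeclarations, networkAttributes, nodes,
edges, status).  The writer emits a stable key order and sorted keys so
the same graph always produces byte-identical output; the reader is
tolerant of foreign CX2 (missing BEL attributes degrade to label-only
nodes) but raises a typed error naming the malformed aspect.

Attribute layout on this tool's output:
  nodes:  name, bel, namespace, identifier
  edges:  interaction, bel, evidence (list_of_string), source
"""

from __future__ import annotations

import json
from pathlib import Path

from .graph import EvidenceRef, KGEdge, KGNode, KnowledgeGraph


class CX2Error(ValueError):
    """Malformed CX2 document; the message names the offending aspect."""


_ATTRIBUTE_DECLARATIONS = {
    "networkAttributes": {
        "name": {"d": "string"},
        "sources": {"d": "list_of_string"},
        "generator": {"d": "string"},
    },
    "nodes": {
        "name": {"d": "string"},
        "bel": {"d": "string"},
        "namespace": {"d": "string"},
        "identifier": {"d": "string"},
    },
    "edges": {
        "interaction": {"d": "string"},
        "bel": {"d": "string"},
        "evidence": {"d": "list_of_string"},
        "source": {"d": "list_of_string"},
    },
}


def _evidence_strings(edge: KGEdge) -> list[str]:
    # evidence entries are packed "source_id|paragraph_index|sentence" so the
    # round-trip through list_of_string is lossless
    return [
        f"{ref.source_id}|{ref.paragraph_index}|{ref.sentence}" for ref in edge.evidence
    ]


def _parse_evidence_string(raw: str) -> EvidenceRef:
    parts = raw.split("|", 2)
    if len(parts) != 3:
        return EvidenceRef(sentence=raw, source_id="", paragraph_index=-1)
    source_id, index_str, sentence = parts
    try:
        index = int(index_str)
    except ValueError:
        index = -1
    return EvidenceRef(sentence=sentence, source_id=source_id, paragraph_index=index)


def graph_to_cx2(graph: KnowledgeGraph) -> list[dict]:
    """Serialize a knowledge graph to a CX2 aspect list."""
    graph.validate()
    network_attrs: dict[str, object] = {"name": graph.name}
    for key in ("sources", "generator"):
        if key in graph.attributes:
            network_attrs[key] = graph.attributes[key]
    nodes = [
        {
            "id": n.node_id,
            "v": {
                "name": n.label,
                "bel": n.canonical_term,
                "namespace": n.namespace,
                "identifier": n.identifier,
            },
        }
        for n in graph.nodes
    ]
    edges = [
        {
            "id": e.edge_id,
            "s": e.source,
            "t": e.target,
            "v": {
                "interaction": e.relation,
                "bel": e.bel,
                "evidence": _evidence_strings(e),
                "source": sorted({ref.source_id for ref in e.evidence if ref.source_id}),
            },
        }
        for e in graph.edges
    ]
    return [
        {"CXVersion": "2.0", "hasFragments": False},
        {"attributeDeclarations": [_ATTRIBUTE_DECLARATIONS]},
        {"networkAttributes": [network_attrs]},
        {"nodes": nodes},
        {"edges": edges},
        {"status": [{"error": "", "success": True}]},
    ]


def cx2_to_json(doc: list[dict]) -> str:
    """Deterministic text rendering of a CX2 document (sorted keys, 1-space indent)."""
    return json.dumps(doc, indent=1, sort_keys=True)


def write_cx2(graph: KnowledgeGraph, path: str | Path) -> None:
    Path(path).write_text(cx2_to_json(graph_to_cx2(graph)))


def _collect_aspect(doc: list, name: str) -> list | None:
    found = None
    for aspect in doc:
        if isinstance(aspect, dict) and name in aspect:
            payload = aspect[name]
            if not isinstance(payload, list):
                raise CX2Error(f"aspect {name!r} must hold a list")
            found = payload if found is None else found + payload
    return found


def cx2_to_graph(doc: list[dict] | str) -> KnowledgeGraph:
    """Parse a CX2 document (aspect list or JSON text) into a knowledge graph.

    Inverse of :func:`graph_to_cx2` on this tool's own output.  Foreign
    CX2 without ``bel`` attributes is accepted: nodes fall back to their
    ``name`` attribute as the canonical term, edges to an empty ``bel``
    field and a placeholder evidence entry.
    """
    if isinstance(doc, str):
        try:
            doc = json.loads(doc)
        except json.JSONDecodeError as exc:
            raise CX2Error(f"document is not valid JSON: {exc}") from exc
    if not isinstance(doc, list):
        raise CX2Error("a CX2 document must be a JSON array of aspects")
    nodes_aspect = _collect_aspect(doc, "nodes")
    edges_aspect = _collect_aspect(doc, "edges")
    if nodes_aspect is None:
        raise CX2Error("missing required aspect 'nodes'")
    network_attrs: dict[str, object] = {}
    for entry in _collect_aspect(doc, "networkAttributes") or []:
        if isinstance(entry, dict):
            network_attrs.update(entry)

    graph = KnowledgeGraph(name=str(network_attrs.pop("name", "knowledge-graph")))
    graph.attributes = network_attrs
    for raw in nodes_aspect:
        try:
            node_id = int(raw["id"])
        except (KeyError, TypeError, ValueError) as exc:
            raise CX2Error(f"aspect 'nodes': bad node entry {raw!r}") from exc
        values = raw.get("v", {})
        label = str(values.get("name", f"node-{node_id}"))
        graph.nodes.append(
            KGNode(
                node_id=node_id,
                canonical_term=str(values.get("bel") or label),
                label=label,
                namespace=str(values.get("namespace", "")),
                identifier=str(values.get("identifier", "")),
            )
        )
    for raw in edges_aspect or []:
        try:
            edge_id = int(raw["id"])
            source = int(raw["s"])
            target = int(raw["t"])
        except (KeyError, TypeError, ValueError) as exc:
            raise CX2Error(f"aspect 'edges': bad edge entry {raw!r}") from exc
        values = raw.get("v", {})
        evidence_raw = values.get("evidence") or []
        evidence = tuple(_parse_evidence_string(s) for s in evidence_raw) or (
            EvidenceRef(sentence="", source_id="", paragraph_index=-1),
        )
        graph.edges.append(
            KGEdge(
                edge_id=edge_id,
                source=source,
                target=target,
                relation=str(values.get("interaction", "association")),
                evidence=evidence,
                bel=str(values.get("bel", "")),
            )
        )
    graph.validate()
    return graph


def read_cx2(path: str | Path) -> KnowledgeGraph:
    return cx2_to_graph(Path(path).read_text())
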