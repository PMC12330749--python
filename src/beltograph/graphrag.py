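"""GraphRAG: k-hop neighborhood retrieval and prompt-context construction.

Instead of retrieving text passages, a GraphRAG query retrieves the
k-hop neighborhood of seed genes from a BEL knowledge graph, serializes
that subgraph as CX2 JSON, and injects it into the LLM prompt together
with the user's question.  Traversal is undirected by default (a gene is
"near" an interaction whichever side it sits on); a directed mode
follows edge direction only.  Knowledge graphs from different papers can
be merged first, so a question spanning two processes (say, metabolism
and DNA damage response) is answered from their union.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx

from .cx2 import cx2_to_json, graph_to_cx2
from .graph import KGEdge, KGNode, KnowledgeGraph
from .llm import BackendError, LLMBackend


@dataclass(frozen=True)
class NeighborhoodQuery:
    """Seed genes + hop count + whether the LLM may use internal knowledge."""

    gene_symbols: tuple[str, ...]
    hops: int = 1
    use_internal_knowledge: bool = False

    def __post_init__(self) -> None:
        if not self.gene_symbols:
            raise ValueError("gene list must be non-empty")
        if self.hops < 1:
            raise ValueError("hops must be >= 1")
        object.__setattr__(self, "gene_symbols", tuple(self.gene_symbols))


def _seed_nodes(graph: KnowledgeGraph, symbols: tuple[str, ...]) -> set[int]:
    """Nodes whose label or identifier equals a seed symbol (case-insensitive, exact)."""
    wanted = {s.lower() for s in symbols}
    return {
        n.node_id
        for n in graph.nodes
        if n.label.lower() in wanted or n.identifier.lower() in wanted
    }


def neighborhood(
    graph: KnowledgeGraph, query: NeighborhoodQuery, directed: bool = False
) -> KnowledgeGraph:
    """Induced subgraph of the seeds plus all nodes within ``query.hops`` steps.

    Seeds are matched against node labels and identifiers; seeds absent
    from the graph contribute nothing, and an empty result is valid.
    The result is an induced subgraph: every edge of the input whose two
    endpoints are both retained is included.  Node and edge ids are
    preserved.
    """
    seeds = _seed_nodes(graph, query.gene_symbols)
    g = nx.DiGraph() if directed else nx.Graph()
    g.add_nodes_from(n.node_id for n in graph.nodes)
    g.add_edges_from((e.source, e.target) for e in graph.edges)
    included: set[int] = set()
    for seed in seeds:
        lengths = nx.single_source_shortest_path_length(g, seed, cutoff=query.hops)
        included.update(lengths)
    nodes = [n for n in graph.nodes if n.node_id in included]
    edges = [e for e in graph.edges if e.source in included and e.target in included]
    sub = KnowledgeGraph(
        name=f"{graph.name}|neighborhood({','.join(query.gene_symbols)},hops={query.hops})",
        nodes=nodes,
        edges=edges,
        attributes=dict(graph.attributes),
    )
    sub.validate()
    return sub


def merge_graphs(graphs: list[KnowledgeGraph], name: str = "merged") -> KnowledgeGraph:
    """Union of graphs with node dedup by canonical term and edge dedup by triple.

    Evidence lists of coinciding edges are concatenated in input order;
    a ``provenance`` attribute records which source network contributed
    each node and edge.
    """
    if not graphs:
        raise ValueError("merge_graphs requires at least one graph")
    merged = KnowledgeGraph(name=name)
    term_to_id: dict[str, int] = {}
    node_provenance: dict[int, list[str]] = {}
    triple_to_idx: dict[tuple[str, str, str], int] = {}
    pending_edges: list[dict] = []
    for g in graphs:
        id_map: dict[int, int] = {}
        for n in g.nodes:
            if n.canonical_term not in term_to_id:
                new_id = len(merged.nodes)
                term_to_id[n.canonical_term] = new_id
                merged.nodes.append(
                    KGNode(
                        node_id=new_id,
                        canonical_term=n.canonical_term,
                        label=n.label,
                        namespace=n.namespace,
                        identifier=n.identifier,
                    )
                )
                node_provenance[new_id] = []
            mapped = term_to_id[n.canonical_term]
            id_map[n.node_id] = mapped
            if g.name not in node_provenance[mapped]:
                node_provenance[mapped].append(g.name)
        term_of = {n.node_id: n.canonical_term for n in g.nodes}
        for e in g.edges:
            triple = (term_of[e.source], e.relation, term_of[e.target])
            if triple in triple_to_idx:
                entry = pending_edges[triple_to_idx[triple]]
                entry["evidence"].extend(e.evidence)
                if g.name not in entry["provenance"]:
                    entry["provenance"].append(g.name)
            else:
                triple_to_idx[triple] = len(pending_edges)
                pending_edges.append(
                    {
                        "source": id_map[e.source],
                        "target": id_map[e.target],
                        "relation": e.relation,
                        "evidence": list(e.evidence),
                        "bel": e.bel,
                        "provenance": [g.name],
                    }
                )
    for i, entry in enumerate(pending_edges):
        merged.edges.append(
            KGEdge(
                edge_id=i,
                source=entry["source"],
                target=entry["target"],
                relation=entry["relation"],
                evidence=tuple(entry["evidence"]),
                bel=entry["bel"],
            )
        )
    merged.attributes = {
        "sources": sorted({g.name for g in graphs}),
        "generator": "beltograph",
        "provenance": {
            "nodes": {str(k): v for k, v in node_provenance.items()},
            "edges": [e["provenance"] for e in pending_edges],
        },
    }
    merged.validate()
    return merged


_CONTEXT_WITH_KG = """\
You are answering a biological question using a knowledge graph of BEL
statements extracted from the literature, given below in CX2 JSON.

Knowledge graph ({n_nodes} nodes, {n_edges} edges):
{cx2_block}

{knowledge_instruction}

Question: {question}
"""

_ONLY_GRAPH = (
    "Answer ONLY from the relationships present in the knowledge graph; if the "
    "graph does not support an answer, say so."
)
_WITH_INTERNAL = (
    "Combine the knowledge graph with your own biological knowledge; make clear "
    "which claims are supported by graph statements."
)

_CONTEXT_NO_KG = """\
You are answering a biological question from your own knowledge; no
knowledge graph is provided.

Question: {question}
"""


def build_context(
    subgraph: KnowledgeGraph, query: NeighborhoodQuery, question: str
) -> str:
    """Build the deterministic prompt embedding the subgraph as CX2 JSON.

    The ``use_internal_knowledge`` flag toggles exactly one instruction
    block; an empty subgraph is stated as such rather than silently
    embedding an empty aspect list.
    """
    if not subgraph.nodes:
        cx2_block = "(the retrieved knowledge graph is empty)"
    else:
        cx2_block = cx2_to_json(graph_to_cx2(subgraph))
    instruction = _WITH_INTERNAL if query.use_internal_knowledge else _ONLY_GRAPH
    return _CONTEXT_WITH_KG.format(
        n_nodes=len(subgraph.nodes),
        n_edges=len(subgraph.edges),
        cx2_block=cx2_block,
        knowledge_instruction=instruction,
        question=question,
    )


@dataclass
class DemoEntry:
    """One variation of the demo query: which graph, which mode, what came back."""

    variation: str
    prompt: str
    response: str | None
    error: str | None = None


def run_demo(
    graphs: tuple[KnowledgeGraph, KnowledgeGraph],
    question: str,
    backend: LLMBackend,
    seeds: tuple[str, ...],
    hops: int = 1,
) -> list[DemoEntry]:
    """Pose one question under seven retrieval variations.

    {graph A, graph B, merged(A,B)} x {graph-only, graph+internal
    knowledge}, plus a no-graph baseline — the standard demonstration of
    how retrieved knowledge-graph context changes an LLM's answer.
    Backend failures are recorded per variation, never aborting the run.
    """
    graph_a, graph_b = graphs
    merged = merge_graphs([graph_a, graph_b], name="merged")
    entries: list[DemoEntry] = []
    for g in (graph_a, graph_b, merged):
        for internal in (False, True):
            query = NeighborhoodQuery(
                gene_symbols=seeds, hops=hops, use_internal_knowledge=internal
            )
            prompt = build_context(neighborhood(g, query), query, question)
            label = f"{g.name}|{'with' if internal else 'without'}-internal"
            try:
                entries.append(DemoEntry(label, prompt, backend.complete(prompt)))
            except BackendError as exc:
                entries.append(DemoEntry(label, prompt, None, error=str(exc)))
    prompt = _CONTEXT_NO_KG.format(question=question)
    try:
        entries.append(DemoEntry("no-kg", prompt, backend.complete(prompt)))
    except BackendError as exc:
        entries.append(DemoEntry("no-kg", prompt, None, error=str(exc)))
    return entries
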