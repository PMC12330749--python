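"""GraphRAG: neighborhood retrieval, graph merging, prompt contexts, demo."""

import itertools

import pytest

from beltograph import parse_bel
from beltograph.cx2 import cx2_to_graph
from beltograph.extraction import EvidenceRecord
from beltograph.graph import statements_to_graph
from beltograph.graphrag import (
    NeighborhoodQuery,
    build_context,
    merge_graphs,
    neighborhood,
    run_demo,
)
from beltograph.llm import ScriptedBackend
from beltograph.synthetic import make_dna_damage_graph, make_metabolism_graph


def path_graph(symbols):
    """A path graph A-B-C-... built from plain protein statements."""
    records = [
        EvidenceRecord(
            parse_bel(f"p(HGNC:{a}) increases p(HGNC:{b})"), f"{a} to {b}.", i, "path"
        )
        for i, (a, b) in enumerate(itertools.pairwise(symbols))
    ]
    return statements_to_graph(records, name="path")


def bfs_oracle(graph, seeds, hops):
    """Hand-rolled undirected BFS, independent of the networkx-backed code."""
    adjacency = {n.node_id: set() for n in graph.nodes}
    for e in graph.edges:
        adjacency[e.source].add(e.target)
        adjacency[e.target].add(e.source)
    frontier = set(seeds)
    seen = set(seeds)
    for _ in range(hops):
        frontier = {m for n in frontier for m in adjacency[n]} - seen
        seen |= frontier
    return seen


def seed_ids(graph, symbols):
    wanted = {s.lower() for s in symbols}
    return {n.node_id for n in graph.nodes if n.label.lower() in wanted}


class TestNeighborhood:
    def test_absent_seed_yields_empty_subgraph(self):
        graph = path_graph(["A1", "B1", "C1"])
        sub = neighborhood(graph, NeighborhoodQuery(("NOPE",)))
        assert sub.nodes == [] and sub.edges == []

    def test_one_hop_from_center_of_path(self):
        graph = path_graph(["A1", "B1", "C1", "D1", "E1"])
        sub = neighborhood(graph, NeighborhoodQuery(("C1",), hops=1))
        assert {n.label for n in sub.nodes} == {"B1", "C1", "D1"}
        assert len(sub.edges) == 2

    def test_matches_bfs_oracle_on_fixture_graphs(self):
        for graph in (make_dna_damage_graph(), make_metabolism_graph()):
            for seed_symbol in ("TP53", "NAD", "SIRT1"):
                for hops in (1, 2, 3):
                    sub = neighborhood(graph, NeighborhoodQuery((seed_symbol,), hops=hops))
                    expected = bfs_oracle(graph, seed_ids(graph, (seed_symbol,)), hops)
                    assert {n.node_id for n in sub.nodes} == expected

    def test_hops_at_diameter_returns_connected_component(self):
        graph = path_graph(["A1", "B1", "C1", "D1", "E1"])
        sub = neighborhood(graph, NeighborhoodQuery(("A1",), hops=10))
        assert len(sub.nodes) == 5 and len(sub.edges) == 4

    def test_result_is_induced_subgraph(self):
        graph = make_dna_damage_graph()
        sub = neighborhood(graph, NeighborhoodQuery(("TP53",), hops=1))
        ids = {n.node_id for n in sub.nodes}
        assert all(e.source in ids and e.target in ids for e in sub.edges)
        # every in-graph edge between included nodes is present
        included = [
            e for e in graph.edges if e.source in ids and e.target in ids
        ]
        assert len(sub.edges) == len(included)

    def test_hop_monotonicity(self):
        graph = make_metabolism_graph()
        previous: set[int] = set()
        for hops in (1, 2, 3, 4):
            current = {
                n.node_id
                for n in neighborhood(graph, NeighborhoodQuery(("NAD",), hops=hops)).nodes
            }
            assert previous <= current
            previous = current

    def test_seed_matching_is_exact_case_insensitive(self):
        graph = path_graph(["AKT1", "HSF1"])
        assert neighborhood(graph, NeighborhoodQuery(("akt1",), hops=1)).nodes
        # no substring matching: "AKT" must not match "AKT1"
        assert neighborhood(graph, NeighborhoodQuery(("AKT",), hops=1)).nodes == []

    def test_directed_mode_follows_edge_direction(self):
        graph = path_graph(["A1", "B1", "C1"])
        down = neighborhood(graph, NeighborhoodQuery(("B1",), hops=1), directed=True)
        assert {n.label for n in down.nodes} == {"B1", "C1"}

    def test_query_validation(self):
        with pytest.raises(ValueError):
            NeighborhoodQuery(())
        with pytest.raises(ValueError):
            NeighborhoodQuery(("A",), hops=0)


class TestMergeGraphs:
    def test_self_merge_idempotent(self):
        g = make_dna_damage_graph()
        merged = merge_graphs([g, g])
        assert [n.canonical_term for n in merged.nodes] == [
            n.canonical_term for n in g.nodes
        ]
        assert [(e.source, e.relation, e.target) for e in merged.edges] == [
            (e.source, e.relation, e.target) for e in g.edges
        ]

    def test_disjoint_graphs_sum_counts(self):
        a = path_graph(["A1", "B1"])
        b = path_graph(["C1", "D1"])
        merged = merge_graphs([a, b])
        assert len(merged.nodes) == 4 and len(merged.edges) == 2

    def test_overlap_matches_set_union_oracle(self):
        a, b = make_dna_damage_graph(), make_metabolism_graph()
        merged = merge_graphs([a, b])
        expected_terms = {n.canonical_term for n in a.nodes} | {
            n.canonical_term for n in b.nodes
        }
        term_of_a = {n.node_id: n.canonical_term for n in a.nodes}
        term_of_b = {n.node_id: n.canonical_term for n in b.nodes}
        expected_triples = {
            (term_of_a[e.source], e.relation, term_of_a[e.target]) for e in a.edges
        } | {(term_of_b[e.source], e.relation, term_of_b[e.target]) for e in b.edges}
        assert {n.canonical_term for n in merged.nodes} == expected_terms
        term_of_m = {n.node_id: n.canonical_term for n in merged.nodes}
        assert {
            (term_of_m[e.source], e.relation, term_of_m[e.target]) for e in merged.edges
        } == expected_triples
        # the two graphs genuinely share bridge nodes
        assert len(merged.nodes) < len(a.nodes) + len(b.nodes)

    def test_commutative_up_to_relabeling(self):
        a, b = make_dna_damage_graph(), make_metabolism_graph()
        ab, ba = merge_graphs([a, b]), merge_graphs([b, a])
        assert {n.canonical_term for n in ab.nodes} == {n.canonical_term for n in ba.nodes}
        term_ab = {n.node_id: n.canonical_term for n in ab.nodes}
        term_ba = {n.node_id: n.canonical_term for n in ba.nodes}
        triples = lambda g, t: {(t[e.source], e.relation, t[e.target]) for e in g.edges}
        assert triples(ab, term_ab) == triples(ba, term_ba)

    def test_associative_up_to_relabeling(self):
        a, b = make_dna_damage_graph(), make_metabolism_graph()
        c = path_graph(["TP53", "FOXO3"])
        left = merge_graphs([merge_graphs([a, b]), c])
        right = merge_graphs([a, merge_graphs([b, c])])
        assert {n.canonical_term for n in left.nodes} == {
            n.canonical_term for n in right.nodes
        }

    def test_provenance_recorded(self):
        a, b = make_dna_damage_graph(), make_metabolism_graph()
        merged = merge_graphs([a, b])
        prov = merged.attributes["provenance"]
        nad_node = next(n for n in merged.nodes if n.canonical_term == "a(CHEBI:NAD)")
        assert set(prov["nodes"][str(nad_node.node_id)]) == {"dna-damage", "metabolism"}


class TestBuildContext:
    def test_empty_subgraph_stated_in_prompt(self):
        from beltograph.graph import KnowledgeGraph

        query = NeighborhoodQuery(("TP53",))
        prompt = build_context(KnowledgeGraph(name="empty"), query, "Q?")
        assert "empty" in prompt and "Q?" in prompt

    def test_internal_knowledge_flag_toggles_one_block(self):
        graph = make_dna_damage_graph()
        q_only = NeighborhoodQuery(("TP53",), use_internal_knowledge=False)
        q_both = NeighborhoodQuery(("TP53",), use_internal_knowledge=True)
        sub = neighborhood(graph, q_only)
        p_only = build_context(sub, q_only, "Q?")
        p_both = build_context(sub, q_both, "Q?")
        assert "Answer ONLY from the relationships" in p_only
        assert "Combine the knowledge graph" in p_both
        # the prompts differ only in the instruction block
        assert p_only.replace("Answer ONLY from the relationships present in the "
                              "knowledge graph; if the graph does not support an "
                              "answer, say so.", "") == \
               p_both.replace("Combine the knowledge graph with your own biological "
                              "knowledge; make clear which claims are supported by "
                              "graph statements.", "")

    def test_embedded_cx2_parses_back_to_subgraph(self):
        graph = make_metabolism_graph()
        query = NeighborhoodQuery(("SIRT1",), hops=1)
        sub = neighborhood(graph, query)
        prompt = build_context(sub, query, "Q?")
        start = prompt.index("[\n")
        end = prompt.rindex("]") + 1
        back = cx2_to_graph(prompt[start:end])
        assert back.nodes == sub.nodes and back.edges == sub.edges


class TestRunDemo:
    def test_seven_variations_produced(self):
        backend = ScriptedBackend(default="stub answer")
        entries = run_demo(
            (make_dna_damage_graph(), make_metabolism_graph()),
            "How does metabolism affect DNA damage response?",
            backend,
            seeds=("NAD", "SIRT1", "TP53"),
        )
        assert len(entries) == 7
        assert [e.variation for e in entries] == [
            "dna-damage|without-internal", "dna-damage|with-internal",
            "metabolism|without-internal", "metabolism|with-internal",
            "merged|without-internal", "merged|with-internal", "no-kg",
        ]
        assert all(e.response == "stub answer" and e.error is None for e in entries)

    def test_merged_prompt_embeds_merged_neighborhood(self):
        a, b = make_dna_damage_graph(), make_metabolism_graph()
        backend = ScriptedBackend(default="x")
        entries = run_demo((a, b), "Q?", backend, seeds=("NAD",))
        merged_entry = next(e for e in entries if e.variation.startswith("merged|without"))
        query = NeighborhoodQuery(("NAD",), hops=1)
        expected = build_context(
            neighborhood(merge_graphs([a, b], name="merged"), query), query, "Q?"
        )
        assert merged_entry.prompt == expected

    def test_no_kg_prompt_has_no_graph(self):
        entries = run_demo(
            (make_dna_damage_graph(), make_metabolism_graph()),
            "Q?", ScriptedBackend(default="x"), seeds=("NAD",),
        )
        assert "CX2" not in entries[-1].prompt

    def test_backend_failure_recorded_not_raised(self):
        from beltograph.llm import FailingBackend

        entries = run_demo(
            (make_dna_damage_graph(), make_metabolism_graph()),
            "Q?", FailingBackend("down"), seeds=("NAD",),
        )
        assert len(entries) == 7
        assert all(e.response is None and e.error == "down" for e in entries)
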