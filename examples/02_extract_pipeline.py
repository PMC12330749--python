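"""Run the full offline pipeline: fixture article -> BEL records -> CX2 network.

Uses the packaged synthetic article and a scripted LLM backend, so the
run is deterministic and needs no network or credentials.  The printed
counts are paragraphs kept after filtering, extracted statements, and
the size of the deduplicated knowledge graph.
"""

from beltograph import (
    DictionaryGrounder,
    extract_document,
    fetch_article,
    filter_paragraphs,
    statements_to_graph,
    write_cx2,
)
from beltograph.synthetic import FIXTURE_PMCID, FixtureArticleClient, make_fixture_backend

doc = fetch_article(FIXTURE_PMCID, FixtureArticleClient())
print(f"fetched {doc.source_id!r}: {len(doc.paragraphs)} paragraphs")

doc = filter_paragraphs(doc, mode="rules")
print(f"after filtering boilerplate sections: {len(doc.paragraphs)} paragraphs")

records, report = extract_document(doc, DictionaryGrounder(), make_fixture_backend())
print(f"extracted {report.n_records} statements "
      f"({report.n_quarantined} quarantined, {report.n_repaired} repaired)")
for rec in records:
    flags = ",".join(v.code for v in rec.violations) or "clean"
    print(f"  [{flags}] {rec.bel}")

graph = statements_to_graph(records, name=doc.source_id)
print(f"knowledge graph: {len(graph.nodes)} nodes, {len(graph.edges)} edges")
write_cx2(graph, "network.cx2")
print("wrote network.cx2")
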