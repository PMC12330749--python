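# beltograph

Literature-derived molecular interaction knowledge graphs in
**Biological Expression Language (BEL)**, with CX2 export for the
Cytoscape ecosystem, a statement-comparison scorer, and GraphRAG-style
neighborhood retrieval.

## Who this is for

Researchers who want to turn individual publications into small,
reviewable causal networks — and to compare, merge, and query those
networks — without hand-curating BEL. The pipeline mirrors the design of
LLM-based extraction tools: every model- or service-dependent stage
(paragraph filtering, extraction, the similarity judge, GraphRAG
answering, grounding, article fetch, NDEx upload) sits behind a
swappable contract with deterministic offline implementations, so the
whole chain runs and tests with no network, API keys, or live model.

## The model

BEL encodes a biological claim as a *subject–predicate–object*
statement over functionally composed terms:

```
act(p(HGNC:AKT1), ma(GO:"kinase activity")) directlyIncreases p(HGNC:HSF1, pmod(Ph, Ser, 326))
```

— the kinase activity of AKT1 directly increases the abundance of HSF1
phosphorylated at Ser 326. Supported term functions:
`p g r a complex bp path act deg tloc`; modifications
`pmod ma frag loc`; relations `increases decreases directlyIncreases
directlyDecreases association regulates`. Entities are grounded in
standard vocabularies (HGNC, GO, CHEBI, ...).

The pipeline: article (PMC id or local file) → paragraphs → grounded
entity annotations → LLM extraction constrained to the annotation
allow-list → parsed/validated statements with evidence sentences →
deduplicated property graph (node identity = canonical BEL term, one
edge per distinct subject–relation–object triple with merged evidence)
→ CX2 JSON.

Two statement sets extracted from the same evidence are compared
component-wise on canonical forms. With weights
w_subj = 0.3, w_rel = 0.4, w_obj = 0.3, the score of a pair (A, B) is

```
score(A,B) = 0.3·[subj_A = subj_B] + 0.4·[rel_A = rel_B] + 0.3·[obj_A = obj_B]
```

so identical statements score 1, relation-only agreement scores 0.4 and
disjoint statements score 0. Namespace-level agreement is tracked
separately and unscored. An LLM-as-judge contract rates paired
statements Good / Medium / Bad for semantic similarity.

## Worked example

```
$ python examples/02_extract_pipeline.py
fetched 'PMC0000001': 5 paragraphs
after filtering boilerplate sections: 4 paragraphs
extracted 6 statements (0 quarantined, 0 repaired)
  [clean] act(p(HGNC:AKT1),ma(GO:"kinase activity")) directlyIncreases p(HGNC:HSF1,pmod(Ph,Ser,326))
  [clean] p(HGNC:SIRT1) decreases act(p(HGNC:TP53))
  [clean] a(CHEBI:NAD) increases act(p(HGNC:SIRT1),ma(GO:"deacetylase activity"))
  [clean] p(HGNC:PARP1) decreases a(CHEBI:NAD)
  [clean] p(HGNC:TP53) increases p(HGNC:MDM2)
  [clean] p(HGNC:MDM2) decreases p(HGNC:TP53)
knowledge graph: 9 nodes, 6 edges
wrote network.cx2
```

The packaged synthetic article yields 6 statements; the reference-list
paragraph is filtered out, every extracted entity is covered by the
paragraph allow-list (`clean`), and deduplication maps the 6 statements
onto 9 distinct terms (activity-wrapped and plain forms of a protein are
distinct nodes). `network.cx2` opens directly in Cytoscape.

Other examples: `01_parse_and_validate_bel.py` (parser, canonical form,
allow-list validation), `03_compare_statements.py` (scorer and agreement
report), `04_graphrag_demo.py` (seven retrieval variations of one
question over two mergeable toy graphs).

The same pipeline is scriptable from a shell:

```
beltograph extract --pmcid PMC0000001 --backend stub --out results.json --cx2 network.cx2
beltograph compare results.json results.json --report report.json
beltograph graphrag network.cx2 --genes TP53 --question "What regulates TP53?" --out context.txt
```

## Layout

- `src/beltograph/bel/` — BEL model, recursive-descent parser, canonical
  serializer, validator
- `src/beltograph/ingest.py` — PMC/BioC XML and local-file ingestion,
  paragraph filtering
- `src/beltograph/grounding.py` — entity grounding contract + offline
  dictionary grounder
- `src/beltograph/extraction.py` — prompt assembly, LLM extraction,
  repair/quarantine, BEL-as-JSON
- `src/beltograph/graph.py`, `cx2.py`, `ndex.py` — property graph, CX2
  read/write, NDEx upload contract
- `src/beltograph/evaluation.py` — comparison scorer, best-match
  pairing, agreement reports, LLM-as-judge
- `src/beltograph/graphrag.py` — k-hop neighborhoods, graph merging,
  prompt contexts
- `src/beltograph/synthetic.py` — packaged fixtures: article XML,
  scripted backends, toy graphs, random statement generator
- `src/beltograph/cli.py` — `beltograph fetch | extract | convert |
  compare | graphrag`

See `docs/methods.md` for design rationale and limitations.
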