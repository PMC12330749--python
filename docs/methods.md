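# Methods

## The BEL subset

The parser covers the fragment of BEL that LLM extraction of causal
molecular interactions actually produces: term functions
`p, g, r, a, complex, bp, path, act, deg, tloc`, modifications
`pmod, ma, frag, loc`, and relations `increases, decreases,
directlyIncreases, directlyDecreases, association, regulates`. Full BEL
2.x (reactions, fusions, translocation arguments, document headers) is
out of scope. Functions and relations are case-sensitive closed
vocabularies; namespaces are checked against a configurable allow-list
(default: HGNC, GO, CHEBI, MESH, UNIPROT, NCBIGENE, MGI, RGD, FPLX,
DOID, HP, EFO, PUBCHEM, INTERPRO, TEXT) and upper-cased on
canonicalization. Each failure mode is a distinct exception type with a
character offset, because downstream repair logic reacts differently to
a malformed string than to a hallucinated namespace.

Canonical form: no whitespace after commas, one space around the
relation, names double-quoted exactly when they contain characters
outside `[A-Za-z0-9_]`, inner quotes backslash-escaped. Namespace codes
are upper-cased at construction, so dataclass equality, structural
equality and canonical-string equality coincide — the property the node
dedup and the comparison scorer both rely on. Quoted names are preserved
verbatim (a name rendered without its internal space, as typesetting
sometimes does, parses but is a *different* name; no respacing is
guessed). Structural invariants: entity functions require a grounded
entity; `act`/`deg`/`tloc` take exactly one inner term; `act` at most
one `ma`; `complex` an entity or ≥ 2 inner terms; `pmod` 1–3 arguments
with a positive-integer position; term depth ≤ 4.

## Ingestion and filtering

BioC-style XML is read with lxml: passage `section_type` infons become
section labels, document-global annotation offsets are rebased onto
passage text, and annotations whose span no longer reproduces their
declared text (e.g. after NFC normalization and whitespace collapsing)
are dropped rather than emitted broken. Empty passages are dropped and
indices re-packed. Local text/markdown is split on blank lines;
single-line headings (markdown `#` or short ALL-CAPS lines) set the
section label and are not emitted as paragraphs.

Boilerplate filtering defaults to *rules* mode — drop paragraphs whose
section label or leading line matches a configurable blocklist
(references, acknowledgments, funding, author contributions, competing
interests, supplements) — because it is deterministic and auditable. An
*llm* mode delegates per-paragraph keep/drop to a backend for sources
without section metadata. Filtering never reorders retained paragraphs.

## Grounding

Entities are grounded *before* extraction and the resulting
namespace:identifier allow-list is embedded in the prompt and enforced
at validation; this is the main defense against invented identifiers.
The grounder is a contract; the offline `DictionaryGrounder` does
word-boundary-anchored longest-match lookup over a small packaged
lexicon (exact match 1.0, case-insensitive 0.8 — crude but ordered
scores, enough for overlap resolution). Overlapping candidate spans are
resolved greedily: highest score, ties to the longest span, then left
position. Both full-paragraph grounding and pass-through of
pre-annotations from the source XML are supported and merged, since
either may be the only source available.

## Extraction

The prompt is deterministic given the paragraph and its annotations: a
BEL syntax guide with one worked example, the allow-list rendered one
`NAMESPACE:ID  (name)` line per distinct grounding, and the paragraph.
Backends reply with a JSON array of
`{"bel_statement", "evidence"}` objects, schema-validated with pydantic.
Unparseable statements get exactly one repair round-trip with the parser
error appended (one, to bound cost and prevent loops); a second failure
quarantines the raw payload with its error. Statements with
out-of-allow-list entities are retained and flagged
(`ungrounded-entity`) rather than dropped — reviewers need to see them,
and whether to discard is a policy decision the data should not
pre-empt. Evidence fidelity: the reported sentence must match some
paragraph sentence at ≥ 0.9 normalized similarity
(case/whitespace-insensitive difflib ratio; substring containment counts
as 1.0), else a `paraphrased-evidence` violation is recorded. The run
report maintains raw = records + quarantined per run, and per-paragraph
failures are isolated so one bad paragraph never aborts a document.

## Graph construction and CX2

Node identity is the canonical BEL term string, so `p(X)` and
`act(p(X))` are distinct nodes — BEL semantics distinguish an entity
from its activity, and collapsing them loses the distinction
irreversibly (a collapsed view is cheap to derive later; the reverse is
not). One edge per distinct (subject, relation, object) triple with
evidence merged in record order; an edge-per-evidence mode is a flag.
Ids are assigned in first-appearance order from 0.

CX2 output is the aspect array (CXVersion header,
attributeDeclarations, networkAttributes, nodes `{id, v}`, edges
`{id, s, t, v}`, status) with sorted keys and fixed aspect order, so
identical graphs serialize byte-identically. Edge evidence is packed
`source_id|paragraph_index|sentence` into a `list_of_string` attribute
to survive the CX2 type system losslessly. The reader is tolerant of
foreign CX2 (nodes fall back to their `name`, edges to empty `bel`) but
raises a typed error naming the malformed aspect.

## Comparison scoring

Only the relation sub-score (0.4) and the extremes (0 for nothing
matching, 1 for everything) are fixed by the scoring scheme this
implements; the remaining 0.6 is split evenly between subject and
object (0.3 each), and the weight table is a parameter. Component
equality is canonical-string equality of sub-terms — strict by design:
near-miss credit is what the LLM-as-judge is for. Namespace-level
agreement (primary entity of subject/object grounded in the same
vocabulary, where the primary entity is the first grounded entity in
depth-first order) is reported separately and never scored, because it
measures something categorically weaker. Best-match pairing is argmax
of the total score with first-wins tie-breaking; agreement fractions
are undefined (None), not zero, over an empty pair set, and are
reported as percentages rounded to one decimal.

The judge prompt embeds the three-category rubric (Good: same
relationship; Medium: related but differing in specificity; Bad:
different relationships) and any label outside the vocabulary is a
typed error, never coerced.

## GraphRAG

Neighborhood retrieval is undirected by default (a gene is relevant to
an interaction whichever side it is on); a directed mode follows edge
direction. Seeds match node label or identifier, case-insensitive,
exact token — substring matching would conflate gene symbols that
prefix each other. The result is the induced subgraph of all nodes
within `hops` steps of any seed; seeds absent from the graph contribute
nothing and an empty result is valid. Merging deduplicates nodes by
canonical term and edges by triple, concatenates evidence, and records
per-node/per-edge provenance. The prompt context embeds the subgraph as
CX2 JSON together with the question and one instruction block toggled
by the internal-knowledge flag; the demonstration runs seven variations
({graph A, graph B, merged} × {with, without internal knowledge} + a
no-graph baseline).

## Synthetic fixtures: what they do and do not show

The fixture module generates every external input shape the pipeline
consumes: a BioC-style article with annotation offsets, scripted
backend replies keyed to its paragraphs, two toy knowledge graphs
sharing NAD/SIRT1 bridge nodes, a seeded random statement generator
(valid-by-construction trees, depth ≤ 3, ~12 entities), and a
comparison corpus engineered to exact per-component match counts
(pair *i* matches on a component iff *i* is below that component's
target count, so the tallies are known by construction). These exercise
segmentation, offsets, schemas, determinism, dedup and retrieval logic
at desk scale — problem sizes of 5 paragraphs, 6 statements, ~10-node
graphs, 200-statement round-trip batches, chosen as the smallest sizes
that exercise every code path. They do not emulate the linguistic
ambiguity of real articles, live-model output noise, or real grounding
errors, so passing tests certify the machinery around the model, not
extraction quality from real literature — which is precisely the part
the swappable contracts exist to isolate.

## Numerical and degenerate-input choices

Weights must sum to 1 (tolerance 1e-9). Scores are exact multiples of
the weights; float comparison in tests uses pytest.approx. Empty
record lists produce valid empty graphs; empty paragraphs and empty
allow-lists are legal (an empty allow-list skips the grounding check
rather than flagging everything). The evidence-similarity threshold of
0.9 tolerates minor whitespace/casing drift while catching genuine
paraphrase; it is a module constant, not config, until real-data tuning
justifies otherwise.

## Known limitations

- The BEL grammar subset omits reactions, fusions and location
  arguments; statements using them quarantine as unknown-function
  errors.
- The dictionary grounder has no disambiguation and a tiny lexicon; it
  is a contract reference implementation, not an NER system.
- Sentence splitting for evidence checking is regex-based and can
  mis-split on abbreviations, which the 0.9 threshold partly absorbs.
- Live article fetch and NDEx upload are thin contracts; retry/backoff
  policy is left to client implementations.
- `aggregate_agreement` percentages round half-even via Python's
  `round`, which matters only at exact .x5 boundaries.
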