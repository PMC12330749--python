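"""Synthetic fixtures: articles, scripted extractions, demo graphs, random BEL.

Everything the pipeline consumes from the outside world has a generated
stand-in here, so the full fetch → ground → extract → graph → compare →
GraphRAG chain runs offline and deterministically:

* a BioC-style article (paragraph-segmented XML with entity annotation
  spans) about a small DNA-damage/metabolism narrative, plus a
  fixture-backed article client;
* scripted LLM replies matching that article, for the deterministic
  extraction backend;
* two toy knowledge graphs (DNA-damage-themed and metabolism-themed)
  sharing bridge nodes, for the GraphRAG merge demonstration;
* a seeded random BEL statement generator for round-trip and
  property testing;
* a synthetic comparison corpus with exact per-component match counts,
  for exercising agreement reporting.

These fixtures emulate the *shapes* of real inputs (segmentation,
annotation offsets, reply schemas), not the linguistic richness of real
articles or the noise of a live model.
"""

from __future__ import annotations

import json
import random

from .bel.model import (
    BelModification,
    BelStatement,
    BelTerm,
    NamespaceId,
)
from .extraction import EvidenceRecord
from .graph import KnowledgeGraph, statements_to_graph
from .llm import ScriptedBackend

FIXTURE_PMCID = "PMC0000001"

# ---------------------------------------------------------------------------
# BioC-style article fixture
# ---------------------------------------------------------------------------

_FIXTURE_PARAGRAPHS = [
    ("TITLE", "NAD metabolism couples SIRT1 to the DNA damage response"),
    (
        "INTRO",
        "The DNA damage response protects genome integrity. "
        "NAD availability links cellular metabolism to DNA repair.",
    ),
    (
        "RESULTS",
        "AKT1 phosphorylates HSF1 at serine 326. "
        "The kinase activity of AKT1 directly increases phosphorylated HSF1.",
    ),
    (
        "RESULTS",
        "SIRT1 deacetylates TP53 and decreases TP53 activity. "
        "NAD increases the deacetylase activity of SIRT1. "
        "PARP1 consumes NAD during DNA repair.",
    ),
    (
        "DISCUSS",
        "TP53 increases MDM2 expression, and MDM2 in turn decreases TP53, "
        "forming a negative feedback loop.",
    ),
    ("REF", "1. Author A et al. A previous study. Journal of Examples, 2020."),
]

# (paragraph text substring, namespace, identifier) — turned into offset
# annotations when the XML is generated
_FIXTURE_MENTIONS = {
    2: [("AKT1", "HGNC", "AKT1"), ("HSF1", "HGNC", "HSF1")],
    3: [
        ("SIRT1", "HGNC", "SIRT1"),
        ("TP53", "HGNC", "TP53"),
        ("NAD", "CHEBI", "NAD"),
        ("PARP1", "HGNC", "PARP1"),
    ],
    4: [("TP53", "HGNC", "TP53"), ("MDM2", "HGNC", "MDM2")],
}


def _xml_escape(s: str) -> str:
    return s.replace("&", "&amp;").replace("<", "&lt;").replace(">", "&gt;")


def make_fixture_bioc_xml(pmcid: str = FIXTURE_PMCID) -> bytes:
    """Render the fixture article as BioC-style XML bytes.

    Passages carry ``section_type`` infons and document-global offsets;
    entity mentions become ``<annotation>`` elements with offset/length
    locations, the dialect :func:`beltograph.ingest.parse_bioc_xml`
    reads.
    """
    parts = ['<?xml version="1.0" encoding="UTF-8"?>', "<collection>", "<document>"]
    parts.append(f"<id>{pmcid}</id>")
    offset = 0
    for index, (section, text) in enumerate(_FIXTURE_PARAGRAPHS):
        parts.append("<passage>")
        parts.append(f'<infon key="section_type">{section}</infon>')
        parts.append(f"<offset>{offset}</offset>")
        parts.append(f"<text>{_xml_escape(text)}</text>")
        for mention, ns, ident in _FIXTURE_MENTIONS.get(index, []):
            start = text.find(mention)
            if start < 0:
                continue
            parts.append("<annotation>")
            parts.append(f'<infon key="namespace">{ns}</infon>')
            parts.append(f'<infon key="identifier">{ident}</infon>')
            parts.append(f'<location offset="{offset + start}" length="{len(mention)}"/>')
            parts.append(f"<text>{_xml_escape(mention)}</text>")
            parts.append("</annotation>")
        parts.append("</passage>")
        offset += len(text) + 1
    parts.extend(["</document>", "</collection>"])
    return "\n".join(parts).encode("utf-8")


class FixtureArticleClient:
    """Article-service client serving the packaged synthetic article."""

    def __init__(self, articles: dict[str, bytes] | None = None) -> None:
        self.articles = articles or {FIXTURE_PMCID: make_fixture_bioc_xml()}

    def get_article_xml(self, pmcid: str) -> bytes:
        from .ingest import ArticleNotFoundError

        if pmcid not in self.articles:
            raise ArticleNotFoundError(f"no fixture article for {pmcid}")
        return self.articles[pmcid]


# ---------------------------------------------------------------------------
# Scripted extraction replies matching the fixture article
# ---------------------------------------------------------------------------

#: Backend replies keyed by a distinctive substring of each paragraph,
#: mirroring what a well-behaved model would extract from it.
FIXTURE_EXTRACTIONS: dict[str, list[dict[str, str]]] = {
    "genome integrity": [],
    "phosphorylates HSF1": [
        {
            "bel_statement": 'act(p(HGNC:AKT1),ma(GO:"kinase activity")) '
            "directlyIncreases p(HGNC:HSF1,pmod(Ph,Ser,326))",
            "evidence": "AKT1 phosphorylates HSF1 at serine 326.",
        }
    ],
    "deacetylates TP53": [
        {
            "bel_statement": "p(HGNC:SIRT1) decreases act(p(HGNC:TP53))",
            "evidence": "SIRT1 deacetylates TP53 and decreases TP53 activity.",
        },
        {
            "bel_statement": 'a(CHEBI:NAD) increases act(p(HGNC:SIRT1),ma(GO:"deacetylase activity"))',
            "evidence": "NAD increases the deacetylase activity of SIRT1.",
        },
        {
            "bel_statement": "p(HGNC:PARP1) decreases a(CHEBI:NAD)",
            "evidence": "PARP1 consumes NAD during DNA repair.",
        },
    ],
    "negative feedback": [
        {
            "bel_statement": "p(HGNC:TP53) increases p(HGNC:MDM2)",
            "evidence": "TP53 increases MDM2 expression, and MDM2 in turn decreases "
            "TP53, forming a negative feedback loop.",
        },
        {
            "bel_statement": "p(HGNC:MDM2) decreases p(HGNC:TP53)",
            "evidence": "TP53 increases MDM2 expression, and MDM2 in turn decreases "
            "TP53, forming a negative feedback loop.",
        },
    ],
}


def make_fixture_backend() -> ScriptedBackend:
    """Deterministic extraction backend scripted for the fixture article."""
    return ScriptedBackend(
        keyed={key: json.dumps(value) for key, value in FIXTURE_EXTRACTIONS.items()},
        default="[]",
    )


# ---------------------------------------------------------------------------
# Demo knowledge graphs for GraphRAG
# ---------------------------------------------------------------------------


def _record(bel: str, evidence: str, source: str, index: int = 0) -> EvidenceRecord:
    from .bel import parse_bel

    return EvidenceRecord(
        statement=parse_bel(bel),
        evidence_sentence=evidence,
        paragraph_index=index,
        source_id=source,
    )


def make_dna_damage_graph() -> KnowledgeGraph:
    """Toy DNA-damage-response knowledge graph (synthetic stand-in for a
    literature-derived network)."""
    src = "synthetic:dna-damage"
    records = [
        _record("p(HGNC:ATM) increases act(p(HGNC:TP53))",
                "ATM activates TP53 after DNA damage.", src, 0),
        _record("p(HGNC:PARP1) increases bp(GO:\"DNA repair\")",
                "PARP1 promotes DNA repair.", src, 1),
        _record("p(HGNC:PARP1) decreases a(CHEBI:NAD)",
                "PARP1 consumes NAD during repair.", src, 2),
        _record("p(HGNC:TP53) increases p(HGNC:CDKN1A)",
                "TP53 induces CDKN1A.", src, 3),
        _record("p(HGNC:BRCA1) increases bp(GO:\"DNA repair\")",
                "BRCA1 supports homologous recombination repair.", src, 4),
    ]
    return statements_to_graph(records, name="dna-damage")


def make_metabolism_graph() -> KnowledgeGraph:
    """Toy metabolism knowledge graph sharing NAD/SIRT1 bridge nodes with the
    DNA-damage graph (synthetic stand-in)."""
    src = "synthetic:metabolism"
    records = [
        _record("p(HGNC:NAMPT) increases a(CHEBI:NAD)",
                "NAMPT is the rate-limiting enzyme of NAD salvage.", src, 0),
        _record("a(CHEBI:NAD) increases act(p(HGNC:SIRT1))",
                "NAD fuels SIRT1 deacetylase activity.", src, 1),
        _record("p(HGNC:SIRT1) increases act(p(HGNC:FOXO3))",
                "SIRT1 activates FOXO3.", src, 2),
        _record("a(CHEBI:glucose) increases bp(GO:\"glycolytic process\")",
                "Glucose availability drives glycolysis.", src, 3),
        _record("p(HGNC:SIRT1) decreases act(p(HGNC:TP53))",
                "SIRT1 deacetylates and inhibits TP53.", src, 4),
    ]
    return statements_to_graph(records, name="metabolism")


# ---------------------------------------------------------------------------
# Random BEL statement generator (round-trip / property testing)
# ---------------------------------------------------------------------------

_GEN_ENTITIES = [
    ("HGNC", "AKT1"), ("HGNC", "HSF1"), ("HGNC", "TP53"), ("HGNC", "MDM2"),
    ("HGNC", "SIRT1"), ("HGNC", "PARP1"), ("GO", "kinase activity"),
    ("GO", "DNA repair"), ("CHEBI", "NAD"), ("CHEBI", "resveratrol"),
    ("MESH", "Neoplasms"), ("HGNC", "BRCA1"),
]
_GEN_RELATIONS = [
    "increases", "decreases", "directlyIncreases", "directlyDecreases",
    "association", "regulates",
]
_GEN_RESIDUES = ["Ser", "Thr", "Tyr"]


def _random_entity(rng: random.Random) -> NamespaceId:
    ns, name = rng.choice(_GEN_ENTITIES)
    return NamespaceId(ns, name)


def _random_pmod(rng: random.Random) -> BelModification:
    n_args = rng.randint(1, 3)
    args: list[object] = ["Ph"]
    if n_args >= 2:
        args.append(rng.choice(_GEN_RESIDUES))
    if n_args == 3:
        args.append(str(rng.randint(1, 999)))
    return BelModification(kind="pmod", args=tuple(args))


def _random_simple_term(rng: random.Random) -> BelTerm:
    function = rng.choice(["p", "g", "r", "a"])
    mods: list[BelModification] = []
    if function == "p" and rng.random() < 0.3:
        mods.append(_random_pmod(rng))
    return BelTerm(function=function, entity=_random_entity(rng),
                   modifications=tuple(mods))


def random_term(rng: random.Random, max_depth: int = 3) -> BelTerm:
    """A random structurally valid BEL term, depth at most ``max_depth``."""
    if max_depth <= 1:
        return _random_simple_term(rng)
    roll = rng.random()
    if roll < 0.45:
        return _random_simple_term(rng)
    if roll < 0.60:
        inner = random_term(rng, max_depth - 1)
        mods: list[BelModification] = []
        if rng.random() < 0.5:
            mods.append(BelModification(kind="ma", args=(NamespaceId("GO", "kinase activity"),)))
        return BelTerm(function="act", inner_terms=(inner,), modifications=tuple(mods))
    if roll < 0.72:
        n = rng.randint(2, 3)
        inner = tuple(random_term(rng, max_depth - 1) for _ in range(n))
        return BelTerm(function="complex", inner_terms=inner)
    if roll < 0.82:
        return BelTerm(function="deg", inner_terms=(random_term(rng, max_depth - 1),))
    if roll < 0.92:
        return BelTerm(function=rng.choice(["bp", "path"]), entity=_random_entity(rng))
    return BelTerm(function="tloc", inner_terms=(random_term(rng, max_depth - 1),))


def random_statement(rng: random.Random, max_depth: int = 3) -> BelStatement:
    """A random structurally valid BEL statement (seeded via ``rng``)."""
    return BelStatement(
        subject=random_term(rng, max_depth),
        relation=rng.choice(_GEN_RELATIONS),
        object=random_term(rng, max_depth),
    )


# ---------------------------------------------------------------------------
# Synthetic comparison corpus with exact per-component match counts
# ---------------------------------------------------------------------------


def make_agreement_corpus(
    n_pairs: int = 29,
    subject_matches: int = 6,
    relation_matches: int = 11,
    object_matches: int = 8,
    seed: int = 0,
) -> list[tuple[BelStatement, BelStatement]]:
    """Statement pairs engineered to exact per-component match counts.

    Pair ``i`` has a matching subject iff ``i < subject_matches``, a
    matching relation iff ``i < relation_matches``, a matching object
    iff ``i < object_matches`` (components are made to match by copying
    and to differ by construction), so agreement tallies over the corpus
    are known exactly.  Used to exercise agreement reporting, not to
    model real extraction output.
    """
    if max(subject_matches, relation_matches, object_matches) > n_pairs:
        raise ValueError("match counts cannot exceed n_pairs")
    rng = random.Random(seed)
    pairs: list[tuple[BelStatement, BelStatement]] = []
    genes = ["AKT1", "HSF1", "TP53", "MDM2", "SIRT1", "PARP1", "BRCA1", "ATM"]
    for i in range(n_pairs):
        gene_s = genes[i % len(genes)]
        gene_o = genes[(i + 3) % len(genes)]
        a = BelStatement(
            subject=BelTerm("p", entity=NamespaceId("HGNC", gene_s)),
            relation=_GEN_RELATIONS[i % len(_GEN_RELATIONS)],
            object=BelTerm("p", entity=NamespaceId("HGNC", gene_o)),
        )
        subject = (
            a.subject
            if i < subject_matches
            else BelTerm("g", entity=NamespaceId("HGNC", gene_s))
        )
        relation = (
            a.relation
            if i < relation_matches
            else _GEN_RELATIONS[(i + 1) % len(_GEN_RELATIONS)]
        )
        obj = (
            a.object
            if i < object_matches
            else BelTerm("r", entity=NamespaceId("HGNC", gene_o))
        )
        b = BelStatement(subject=subject, relation=relation, object=obj)
        pairs.append((a, b))
    rng.shuffle(pairs)
    return pairs
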