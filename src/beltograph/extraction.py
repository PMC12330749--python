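"""BEL statement extraction from paragraphs via an LLM backend.

Each paragraph is sent to the backend with a prompt containing a BEL
syntax guide and the paragraph's pre-annotated entity allow-list (the
guard against invented identifiers).  The backend must reply with a JSON
array of ``{"bel_statement": ..., "evidence": ...}`` objects, validated
with pydantic.  Every returned statement is parsed; statements that fail
to parse get exactly one repair round-trip (the parser error is appended
to the prompt) and are quarantined with their error if the repair also
fails.  Grounding and evidence-fidelity problems are recorded as
violations on the kept record, never silently dropped, so a reviewer can
audit them.
"""

from __future__ import annotations

import difflib
import json
import re
from dataclasses import dataclass, field
from pathlib import Path

import pydantic

from .bel import (
    BelParseError,
    BelStatement,
    Violation,
    parse_bel,
    serialize_bel,
    validate_statement,
)
from .bel.model import NamespaceId
from .grounding import EntityAnnotation, build_allowlist
from .ingest import ArticleDocument, Paragraph
from .llm import BackendError, LLMBackend

#: Minimum normalized similarity between the reported evidence sentence and
#: the closest paragraph sentence before a "paraphrased-evidence" violation
#: is recorded.
EVIDENCE_SIMILARITY_THRESHOLD = 0.9

_BEL_GUIDE = """\
You extract molecular interactions from scientific text as statements in
Biological Expression Language (BEL).

A BEL statement is: SUBJECT RELATION OBJECT
 - Terms: p(NS:ID) protein, g(NS:ID) gene, r(NS:ID) RNA, a(NS:ID) chemical,
   bp(NS:ID) biological process, path(NS:ID) pathology,
   complex(p(...),p(...)), act(p(...),ma(GO:"activity")) molecular activity,
   deg(p(...)) degradation, tloc(p(...)) translocation.
 - Modifications: pmod(Ph,Ser,326) phosphorylation at Ser 326; ma(), frag(), loc().
 - Relations: increases, decreases, directlyIncreases, directlyDecreases,
   association, regulates.
Example:
 act(p(HGNC:AKT1),ma(GO:"kinase activity")) directlyIncreases p(HGNC:HSF1,pmod(Ph,Ser,326))

Use ONLY identifiers from the allowed entity list below; never invent
namespace identifiers. If no interaction is stated, return an empty list.

Reply with a JSON array of objects:
 [{"bel_statement": "<BEL>", "evidence": "<the exact sentence the interaction came from>"}]
"""


@dataclass(frozen=True)
class ExtractionPrompt:
    """Deterministic prompt for one paragraph: syntax guide + allow-list + text."""

    system_text: str
    paragraph_text: str
    annotations_rendered: str

    def render(self) -> str:
        return (
            f"{self.system_text}\n"
            f"Allowed entities:\n{self.annotations_rendered}\n\n"
            f"Paragraph:\n{self.paragraph_text}\n"
        )


class RawExtraction(pydantic.BaseModel):
    """Schema of one backend-returned extraction, validated with pydantic."""

    bel_statement: str = pydantic.Field(min_length=1)
    evidence: str = pydantic.Field(min_length=1)


@dataclass(frozen=True)
class EvidenceRecord:
    """A parsed, validated extraction with provenance.

    ``violations`` records grounding/structure/evidence-fidelity findings;
    a record with violations is retained for review, not discarded.
    """

    statement: BelStatement
    evidence_sentence: str
    paragraph_index: int
    source_id: str
    violations: tuple[Violation, ...] = field(default_factory=tuple)

    @property
    def bel(self) -> str:
        return serialize_bel(self.statement)


@dataclass
class QuarantinedExtraction:
    """A raw extraction that could not be parsed even after one repair round."""

    raw: dict
    error: str
    paragraph_index: int
    source_id: str


@dataclass
class RunReport:
    """Per-run accounting: raw extractions = records + quarantined, always."""

    n_paragraphs: int = 0
    n_raw: int = 0
    n_records: int = 0
    n_quarantined: int = 0
    n_repaired: int = 0
    paragraph_errors: list[tuple[int, str]] = field(default_factory=list)
    quarantined: list[QuarantinedExtraction] = field(default_factory=list)


def build_prompt(
    paragraph: Paragraph, annotations: list[EntityAnnotation]
) -> ExtractionPrompt:
    """Assemble the extraction prompt for one paragraph.

    The allow-list is rendered one entry per line as
    ``NAMESPACE:ID  (name)``, deduplicated, in first-appearance order;
    with no annotations the prompt says so explicitly and forbids
    inventing identifiers.
    """
    seen: set[NamespaceId] = set()
    lines: list[str] = []
    for ann in annotations:
        if ann.grounding in seen:
            continue
        seen.add(ann.grounding)
        lines.append(f"{ann.grounding.to_bel()}  ({ann.canonical_name})")
    rendered = (
        "\n".join(lines)
        if lines
        else "(no pre-annotated entities: extract only interactions whose entities "
        "you can ground with certainty; do not invent identifiers)"
    )
    return ExtractionPrompt(
        system_text=_BEL_GUIDE,
        paragraph_text=paragraph.text,
        annotations_rendered=rendered,
    )


def _parse_backend_reply(reply: str) -> list[RawExtraction]:
    """Decode and schema-validate a backend reply (JSON array of extractions)."""
    try:
        payload = json.loads(reply)
    except json.JSONDecodeError as exc:
        raise BackendError(f"backend reply is not valid JSON: {exc}") from exc
    if not isinstance(payload, list):
        raise BackendError("backend reply must be a JSON array")
    try:
        return [RawExtraction.model_validate(item) for item in payload]
    except pydantic.ValidationError as exc:
        raise BackendError(f"backend reply failed schema validation: {exc}") from exc


_SENTENCE_SPLIT = re.compile(r"(?<=[.!?])\s+")


def _normalize_sentence(s: str) -> str:
    return re.sub(r"\s+", " ", s).strip().lower()


def evidence_similarity(evidence: str, paragraph_text: str) -> float:
    """Best normalized similarity between ``evidence`` and any paragraph sentence.

    Case- and whitespace-insensitive; exact substring containment counts
    as 1.0.
    """
    ev = _normalize_sentence(evidence)
    para = _normalize_sentence(paragraph_text)
    if ev and ev in para:
        return 1.0
    best = 0.0
    for sent in _SENTENCE_SPLIT.split(paragraph_text):
        ratio = difflib.SequenceMatcher(None, ev, _normalize_sentence(sent)).ratio()
        best = max(best, ratio)
    return best


def _repair_prompt(prompt: ExtractionPrompt, bad_statement: str, error: str) -> str:
    return (
        f"{prompt.render()}\n"
        f"Your previous statement could not be parsed:\n"
        f"  statement: {bad_statement}\n"
        f"  error: {error}\n"
        f"Return a corrected JSON array for this paragraph."
    )


def extract_paragraph(
    paragraph: Paragraph,
    annotations: list[EntityAnnotation],
    backend: LLMBackend,
    report: RunReport | None = None,
) -> list[EvidenceRecord]:
    """Extract BEL statements from one paragraph through the backend.

    Each raw extraction is parsed with the BEL parser and validated
    against the paragraph's allow-list.  Unparseable statements get one
    repair round-trip; if the repaired reply still fails, the extraction
    is quarantined with its error.  Evidence sentences that do not match
    any paragraph sentence at >=0.9 normalized similarity are flagged
    with a ``paraphrased-evidence`` violation.
    """
    report = report if report is not None else RunReport()
    prompt = build_prompt(paragraph, annotations)
    raws = _parse_backend_reply(backend.complete(prompt.render()))
    report.n_raw += len(raws)
    allowlist = build_allowlist(annotations)
    records: list[EvidenceRecord] = []
    for raw in raws:
        statement: BelStatement | None = None
        parse_error = ""
        try:
            statement = parse_bel(raw.bel_statement)
        except BelParseError as first_error:
            parse_error = str(first_error)
            try:
                repaired = _parse_backend_reply(
                    backend.complete(_repair_prompt(prompt, raw.bel_statement, parse_error))
                )
                if repaired:
                    statement = parse_bel(repaired[0].bel_statement)
                    raw = repaired[0]
                    report.n_repaired += 1
            except (BelParseError, BackendError) as second_error:
                parse_error = f"{parse_error}; after repair: {second_error}"
        if statement is None:
            report.n_quarantined += 1
            report.quarantined.append(
                QuarantinedExtraction(
                    raw=raw.model_dump(),
                    error=parse_error or "unparseable statement",
                    paragraph_index=paragraph.index,
                    source_id=paragraph.source_id,
                )
            )
            continue
        violations = list(validate_statement(statement, allowlist))
        if evidence_similarity(raw.evidence, paragraph.text) < EVIDENCE_SIMILARITY_THRESHOLD:
            violations.append(
                Violation(
                    "paraphrased-evidence",
                    "evidence",
                    "evidence sentence does not match any paragraph sentence at "
                    f">={EVIDENCE_SIMILARITY_THRESHOLD} similarity",
                )
            )
        records.append(
            EvidenceRecord(
                statement=statement,
                evidence_sentence=raw.evidence,
                paragraph_index=paragraph.index,
                source_id=paragraph.source_id,
                violations=tuple(violations),
            )
        )
    report.n_records += len(records)
    return records


def extract_document(
    doc: ArticleDocument,
    grounder,
    backend: LLMBackend,
) -> tuple[list[EvidenceRecord], RunReport]:
    """Run grounding + extraction over every paragraph of a document.

    Paragraph failures are isolated: one bad paragraph (backend failure,
    grounder failure) never aborts the document; the failure is recorded
    in the run report and extraction continues.
    """
    from .grounding import ground_paragraph  # late import: module split

    report = RunReport(n_paragraphs=len(doc.paragraphs))
    records: list[EvidenceRecord] = []
    for para in doc.paragraphs:
        try:
            annotations = ground_paragraph(para, grounder)
            records.extend(extract_paragraph(para, annotations, backend, report))
        except (BackendError, Exception) as exc:  # noqa: BLE001 - isolation boundary
            report.paragraph_errors.append((para.index, str(exc)))
    return records, report


# ---------------------------------------------------------------------------
# BEL-as-JSON serialization (the pipeline's first output artifact)
# ---------------------------------------------------------------------------


def records_to_json(records: list[EvidenceRecord], doc: ArticleDocument | None = None) -> str:
    """Serialize records to the BEL-as-JSON dialect (deterministic text)."""
    paragraph_texts: dict[int, str] = {}
    if doc is not None:
        paragraph_texts = {p.index: p.text for p in doc.paragraphs}
    payload = [
        {
            "source_id": rec.source_id,
            "paragraph_index": rec.paragraph_index,
            "paragraph_text": paragraph_texts.get(rec.paragraph_index, ""),
            "bel_statement": rec.bel,
            "evidence": rec.evidence_sentence,
            "violations": [v.to_dict() for v in rec.violations],
        }
        for rec in records
    ]
    return json.dumps(payload, indent=1, sort_keys=True)


def save_records(
    records: list[EvidenceRecord], path: str | Path, doc: ArticleDocument | None = None
) -> None:
    Path(path).write_text(records_to_json(records, doc))
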