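"""Input resolution: PMC article XML or local text/markdown into paragraphs.

Articles fetched by PubMed Central identifier arrive as BioC-style XML
(passages with ``infon`` metadata and optional entity annotation spans),
already segmented into paragraphs; local files are split on blank lines
with a heading heuristic for section labels.  Both paths produce the
same :class:`ArticleDocument`, so everything downstream is agnostic to
where the text came from.

The article service is a contract (``ArticleClient``): tests and offline
runs use a fixture-backed client; :class:`PubTatorClient` does the live
HTTP fetch when a network is available.
"""

from __future__ import annotations

import re
import unicodedata
import urllib.request
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Protocol

from lxml import etree

from .bel.model import NamespaceId
from .grounding import EntityAnnotation

_PMCID_RE = re.compile(r"^PMC\d+$")

#: Section labels / leading lines dropped by rules-mode filtering.
DEFAULT_BLOCKLIST = (
    "REF",
    "REFERENCES",
    "ACK_FUNDING",
    "ACKNOWLEDGMENTS",
    "ACKNOWLEDGEMENTS",
    "FUNDING",
    "AUTH_CONT",
    "AUTHOR CONTRIBUTIONS",
    "COMP_INT",
    "COMPETING INTERESTS",
    "SUPPL",
)


class IngestError(RuntimeError):
    """Base class for input-resolution failures."""


class ArticleNotFoundError(IngestError):
    """The article service has no document for the requested identifier."""


class MalformedArticleError(IngestError):
    """The article payload could not be parsed as BioC-style XML."""


@dataclass(frozen=True)
class Paragraph:
    """One paragraph of an article, with section label and provenance.

    ``preannotations`` carries entity annotations present in the source
    XML (e.g. PubTator NER spans) through to the grounding stage.
    """

    text: str
    section: str
    index: int
    source_id: str
    preannotations: tuple[EntityAnnotation, ...] = field(default_factory=tuple)


@dataclass(frozen=True)
class ArticleDocument:
    """An ordered, paragraph-segmented article."""

    source_id: str
    title: str
    paragraphs: tuple[Paragraph, ...]


class ArticleClient(Protocol):
    """Contract for article services resolving a PMC id to BioC-style XML bytes."""

    def get_article_xml(self, pmcid: str) -> bytes: ...


class PubTatorClient:
    """Live client for the PubTator BioC full-text endpoint (network required)."""

    URL = "https://www.ncbi.nlm.nih.gov/research/pubtator3-api/publications/pmc_export/biocxml?pmcids={pmcid}"

    def __init__(self, timeout: float = 30.0) -> None:
        self.timeout = timeout

    def get_article_xml(self, pmcid: str) -> bytes:
        url = self.URL.format(pmcid=pmcid)
        try:
            with urllib.request.urlopen(url, timeout=self.timeout) as resp:
                return resp.read()
        except Exception as exc:  # noqa: BLE001 - network boundary
            raise IngestError(f"fetching {pmcid} failed: {exc}") from exc


def _normalize_text(text: str) -> str:
    """NFC-normalize, strip control characters, collapse internal whitespace."""
    text = unicodedata.normalize("NFC", text)
    text = "".join(c for c in text if unicodedata.category(c)[0] != "C" or c in "\n\t ")
    return re.sub(r"\s+", " ", text).strip()


def _parse_bioc_annotations(
    passage: etree._Element, passage_offset: int, text: str
) -> tuple[EntityAnnotation, ...]:
    """Extract annotation spans from a BioC passage, dropping unusable ones.

    BioC locations are document-global offsets; they are rebased onto the
    passage text.  Annotations whose span does not reproduce their
    declared text (e.g. after whitespace normalization) are dropped
    rather than emitted with a broken offset.
    """
    out: list[EntityAnnotation] = []
    for ann in passage.findall("annotation"):
        loc = ann.find("location")
        ann_text = ann.findtext("text") or ""
        if loc is None or not ann_text:
            continue
        try:
            start = int(loc.get("offset", "-1")) - passage_offset
            length = int(loc.get("length", "0"))
        except ValueError:
            continue
        end = start + length
        if not (0 <= start < end <= len(text)) or text[start:end] != ann_text:
            continue
        infons = {i.get("key"): (i.text or "") for i in ann.findall("infon")}
        ns = infons.get("namespace") or infons.get("type") or "TEXT"
        ident = infons.get("identifier") or ann_text
        try:
            grounding = NamespaceId(ns, ident)
        except ValueError:
            continue
        out.append(
            EntityAnnotation(
                matched_text=ann_text,
                start=start,
                end=end,
                grounding=grounding,
                canonical_name=infons.get("name", ann_text),
                score=1.0,
                source="bioc",
            )
        )
    return tuple(out)


def parse_bioc_xml(payload: bytes, source_id: str) -> ArticleDocument:
    """Parse BioC-style XML into an :class:`ArticleDocument`.

    Passage ``infon[@key='section_type']`` becomes the section label;
    empty passages are dropped and indices re-packed so they stay
    contiguous.  The first passage with section_type TITLE (or the first
    passage) supplies the document title.
    """
    try:
        root = etree.fromstring(payload)
    except etree.XMLSyntaxError as exc:
        raise MalformedArticleError(f"malformed XML for {source_id}: {exc}") from exc
    title = ""
    paragraphs: list[Paragraph] = []
    for passage in root.iter("passage"):
        infons = {i.get("key"): (i.text or "") for i in passage.findall("infon")}
        section = infons.get("section_type", infons.get("type", "UNKNOWN")).upper()
        raw_text = passage.findtext("text") or ""
        try:
            offset = int(passage.findtext("offset") or "0")
        except ValueError:
            offset = 0
        preanns = _parse_bioc_annotations(passage, offset, raw_text)
        text = _normalize_text(raw_text)
        if not text:
            continue
        # re-anchor preannotation spans if normalization changed the text
        if text != raw_text:
            preanns = tuple(a for a in preanns if text[a.start : a.end] == a.matched_text)
        if section == "TITLE" and not title:
            title = text
            continue
        paragraphs.append(
            Paragraph(
                text=text,
                section=section,
                index=len(paragraphs),
                source_id=source_id,
                preannotations=preanns,
            )
        )
    if not title and paragraphs:
        title = paragraphs[0].text[:120]
    return ArticleDocument(source_id=source_id, title=title, paragraphs=tuple(paragraphs))


def fetch_article(pmcid: str, client: ArticleClient) -> ArticleDocument:
    """Resolve a PMC identifier to a paragraph-segmented document via ``client``."""
    if not _PMCID_RE.match(pmcid):
        raise ValueError(f"invalid PMC identifier {pmcid!r}: expected 'PMC' + digits")
    payload = client.get_article_xml(pmcid)
    return parse_bioc_xml(payload, source_id=pmcid)


_HEADING_RE = re.compile(r"^(#{1,6}\s+|[A-Z][A-Z \d:&-]{2,60}$)")


def read_local(path: str | Path) -> ArticleDocument:
    """Read a plain-text or markdown file into an :class:`ArticleDocument`.

    Paragraphs are split on blank lines.  Markdown headings (and
    short ALL-CAPS lines) set the section label for subsequent
    paragraphs and are not themselves emitted as paragraphs.
    """
    path = Path(path)
    if not path.exists():
        raise IngestError(f"no such file: {path}")
    raw = path.read_bytes()
    if b"\x00" in raw:
        raise IngestError(f"{path} looks binary, not text")
    try:
        content = raw.decode("utf-8")
    except UnicodeDecodeError as exc:
        raise IngestError(f"{path} is not valid UTF-8 text") from exc
    blocks = re.split(r"\n\s*\n", content)
    section = "BODY"
    title = ""
    paragraphs: list[Paragraph] = []
    for block in blocks:
        stripped = block.strip()
        if not stripped:
            continue
        first_line = stripped.splitlines()[0].strip()
        if _HEADING_RE.match(first_line) and len(stripped.splitlines()) == 1:
            label = first_line.lstrip("# ").strip()
            if not title and first_line.startswith("#"):
                title = label
            section = label.upper()
            continue
        text = _normalize_text(stripped)
        if not text:
            continue
        paragraphs.append(
            Paragraph(text=text, section=section, index=len(paragraphs), source_id=str(path))
        )
    if not paragraphs:
        raise IngestError(f"{path} contains no text paragraphs")
    return ArticleDocument(
        source_id=str(path), title=title or path.name, paragraphs=tuple(paragraphs)
    )


def filter_paragraphs(
    doc: ArticleDocument,
    mode: str = "rules",
    backend: object | None = None,
    blocklist: tuple[str, ...] = DEFAULT_BLOCKLIST,
) -> ArticleDocument:
    """Drop boilerplate paragraphs (references, acknowledgments, funding, ...).

    ``rules`` mode drops paragraphs whose section label or leading line
    matches the blocklist; ``llm`` mode delegates the keep/drop decision
    per paragraph to an LLM backend (see :mod:`beltograph.llm`), the
    behavior of the original pipeline for local files.  Retained
    paragraphs keep their relative order and are re-indexed contiguously.
    """
    if mode not in ("rules", "llm"):
        raise ValueError(f"unknown filter mode {mode!r}")
    if mode == "llm" and backend is None:
        raise ValueError("llm filter mode requires a backend")
    kept: list[Paragraph] = []
    block_upper = tuple(b.upper() for b in blocklist)
    for para in doc.paragraphs:
        if mode == "rules":
            leading = para.text.split(".")[0].strip().upper()
            blocked = para.section.upper() in block_upper or leading in block_upper
            keep = not blocked
        else:
            from .llm import request_keep_drop  # local import avoids cycle

            try:
                keep = request_keep_drop(backend, para)
            except Exception as exc:  # noqa: BLE001 - surface with context
                raise IngestError(
                    f"llm filter failed on paragraph {para.index}: {exc}"
                ) from exc
        if keep:
            kept.append(replace(para, index=len(kept)))
    return ArticleDocument(source_id=doc.source_id, title=doc.title, paragraphs=tuple(kept))
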