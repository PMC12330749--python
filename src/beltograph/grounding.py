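"""Named-entity grounding: mapping text mentions to namespace identifiers.

Extraction quality hinges on the LLM using real identifiers rather than
invented ones, so each paragraph is annotated with grounded entity
mentions *before* extraction and the resulting allow-list constrains
statement validation.  The grounder is a pluggable contract: a live
service client (e.g. a Gilda HTTP client) and the offline
:class:`DictionaryGrounder` are interchangeable.

The offline grounder does exact and case-insensitive longest-match
lookup over a small packaged lexicon of HGNC symbols plus a few GO and
CHEBI names, which is enough to run the whole pipeline with no network.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import TYPE_CHECKING, Protocol

from .bel.model import NamespaceId

if TYPE_CHECKING:  # pragma: no cover
    from .ingest import Paragraph


class GroundingError(RuntimeError):
    """Grounder failure, tagged with the paragraph it occurred on."""

    def __init__(self, message: str, paragraph_index: int | None = None) -> None:
        super().__init__(message)
        self.paragraph_index = paragraph_index


@dataclass(frozen=True)
class EntityAnnotation:
    """A grounded mention: character span, namespace identifier, score, provenance.

    Offsets are 0-based half-open into the paragraph text; the substring
    invariant ``text[start:end] == matched_text`` always holds.
    """

    matched_text: str
    start: int
    end: int
    grounding: NamespaceId
    canonical_name: str
    score: float
    source: str

    def __post_init__(self) -> None:
        if not 0.0 <= self.score <= 1.0:
            raise ValueError(f"score must be in [0,1], got {self.score}")
        if self.end <= self.start:
            raise ValueError("annotation span must be non-empty")


class Grounder(Protocol):
    """Contract for grounding services: text in, candidate annotations out."""

    name: str

    def ground(self, text: str) -> list[EntityAnnotation]:
        """Return candidate annotations (possibly overlapping) for ``text``."""
        ...


#: Mini-lexicon for offline runs: surface form -> (namespace, id/name, canonical name).
#: HGNC symbols for the fixture genes plus a few GO activities/processes and
#: CHEBI chemicals that appear in the packaged demo articles.
DEFAULT_LEXICON: dict[str, tuple[str, str, str]] = {
    "AKT1": ("HGNC", "AKT1", "AKT1"),
    "HSF1": ("HGNC", "HSF1", "HSF1"),
    "TP53": ("HGNC", "TP53", "TP53"),
    "p53": ("HGNC", "TP53", "TP53"),
    "MDM2": ("HGNC", "MDM2", "MDM2"),
    "SIRT1": ("HGNC", "SIRT1", "SIRT1"),
    "PARP1": ("HGNC", "PARP1", "PARP1"),
    "ATM": ("HGNC", "ATM", "ATM"),
    "BRCA1": ("HGNC", "BRCA1", "BRCA1"),
    "NAMPT": ("HGNC", "NAMPT", "NAMPT"),
    "EGF": ("HGNC", "EGF", "EGF"),
    "EGFR": ("HGNC", "EGFR", "EGFR"),
    "FOXO3": ("HGNC", "FOXO3", "FOXO3"),
    "CDKN1A": ("HGNC", "CDKN1A", "CDKN1A"),
    "kinase activity": ("GO", "kinase activity", "kinase activity"),
    "deacetylase activity": ("GO", "deacetylase activity", "deacetylase activity"),
    "DNA repair": ("GO", "DNA repair", "DNA repair"),
    "apoptosis": ("GO", "apoptotic process", "apoptotic process"),
    "glycolysis": ("GO", "glycolytic process", "glycolytic process"),
    "NAD": ("CHEBI", "NAD", "NAD"),
    "resveratrol": ("CHEBI", "resveratrol", "resveratrol"),
    "glucose": ("CHEBI", "glucose", "glucose"),
}

_TOKEN_BOUNDARY = re.compile(r"\w+")


class DictionaryGrounder:
    """Offline longest-match dictionary grounder.

    Exact matches score 1.0; case-insensitive matches score 0.8.  Matches
    are anchored at word boundaries so ``EGF`` does not fire inside
    ``EGFR``.
    """

    def __init__(self, lexicon: dict[str, tuple[str, str, str]] | None = None) -> None:
        self.name = "dictionary"
        self.lexicon = dict(DEFAULT_LEXICON if lexicon is None else lexicon)
        # longest surface forms first so longest-match wins at equal start
        self._forms = sorted(self.lexicon, key=len, reverse=True)
        self._lower = {f.lower(): f for f in self._forms}

    def ground(self, text: str) -> list[EntityAnnotation]:
        out: list[EntityAnnotation] = []
        for form in self._forms:
            pattern = re.compile(
                r"(?<!\w)" + re.escape(form) + r"(?!\w)", re.IGNORECASE
            )
            for m in pattern.finditer(text):
                matched = m.group()
                exact = matched == form
                ns, ident, canonical = self.lexicon[form]
                out.append(
                    EntityAnnotation(
                        matched_text=matched,
                        start=m.start(),
                        end=m.end(),
                        grounding=NamespaceId(ns, ident),
                        canonical_name=canonical,
                        score=1.0 if exact else 0.8,
                        source=self.name,
                    )
                )
        return out


def resolve_overlaps(candidates: list[EntityAnnotation]) -> list[EntityAnnotation]:
    """Resolve overlapping candidate spans: highest score wins, ties to the longest span.

    Returns the retained annotations sorted by start offset.
    """
    # Order candidates by preference: score desc, span length desc, start asc.
    ranked = sorted(
        candidates, key=lambda a: (-a.score, -(a.end - a.start), a.start, a.grounding.to_bel())
    )
    kept: list[EntityAnnotation] = []
    for cand in ranked:
        if all(cand.end <= k.start or cand.start >= k.end for k in kept):
            kept.append(cand)
    return sorted(kept, key=lambda a: (a.start, a.end))


def ground_paragraph(paragraph: "Paragraph", grounder: Grounder) -> list[EntityAnnotation]:
    """Annotate a paragraph's text with grounded entity mentions.

    Candidates from the grounder are overlap-resolved (highest score,
    then longest span) and returned sorted by start offset.  Grounder
    failures are wrapped in :class:`GroundingError` carrying the
    paragraph index.  Pre-annotations already attached to the paragraph
    (e.g. from PubTator XML) are merged with the grounder's output.
    """
    try:
        candidates = list(grounder.ground(paragraph.text))
    except GroundingError:
        raise
    except Exception as exc:  # noqa: BLE001 - contract boundary
        raise GroundingError(
            f"grounder {getattr(grounder, 'name', '?')!r} failed: {exc}",
            paragraph_index=paragraph.index,
        ) from exc
    candidates.extend(getattr(paragraph, "preannotations", ()) or ())
    for ann in candidates:
        if paragraph.text[ann.start : ann.end] != ann.matched_text:
            raise GroundingError(
                f"annotation span mismatch at [{ann.start}:{ann.end}]",
                paragraph_index=paragraph.index,
            )
    return resolve_overlaps(candidates)


def build_allowlist(annotations: list[EntityAnnotation]) -> set[NamespaceId]:
    """Deduplicated set of groundings; the allow-list for statement validation."""
    return {ann.grounding for ann in annotations}
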