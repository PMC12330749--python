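"""Statement-comparison scoring, best-match pairing and the similarity judge.

Two BEL statements extracted from the same evidence text are compared
component-wise on their canonical forms: subject term, relation, object
term.  Each matching component earns its sub-score weight (default
subject 0.3, relation 0.4, object 0.3; the weights sum to 1), so two
identical statements score 1, statements sharing only the relation
score 0.4, and fully disjoint statements score 0.  Namespace-level
agreement of subject and object (same vocabulary grounding the primary
entity, regardless of the exact term) is tracked separately and never
scored, since it measures something weaker than component identity.

For pairing sets of statements, each query statement is matched to the
candidate with the highest total score (ties broken by candidate
order).  Because the score is a coarse structural measure and valid
alternative BEL representations exist for many interactions, a
complementary LLM-as-judge rates each pair Good (same relationship),
Medium (related but differing in specificity) or Bad (different
relationships).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

from .bel import BelParseError, BelStatement, parse_bel, serialize_term
from .extraction import EvidenceRecord
from .llm import BackendError, LLMBackend

#: Default sub-score weights; the relation weight is 0.4 and the remainder is
#: split evenly between subject and object.  Must sum to 1.
DEFAULT_WEIGHTS: dict[str, float] = {"subject": 0.3, "relation": 0.4, "object": 0.3}

JUDGE_CATEGORIES = ("Good", "Medium", "Bad")


class JudgeError(RuntimeError):
    """The judge backend returned a label outside Good/Medium/Bad."""


@dataclass(frozen=True)
class ComparisonResult:
    """Component-level comparison of two statements."""

    a: BelStatement
    b: BelStatement
    subject_match: bool
    relation_match: bool
    object_match: bool
    subject_ns_match: bool
    object_ns_match: bool
    total_score: float
    judge: str | None = None


@dataclass(frozen=True)
class AgreementReport:
    """Aggregate component agreement over a set of compared pairs.

    Fractions are ``count / n_pairs`` and ``None`` when there are no
    pairs (undefined, not zero).  ``percent()`` renders a fraction the
    way agreement is conventionally reported: percent, one decimal.
    """

    n_pairs: int
    subject_matches: int
    relation_matches: int
    object_matches: int
    subject_ns_matches: int
    object_ns_matches: int
    judge_counts: dict[str, int] = field(default_factory=dict)

    def fraction(self, component: str) -> float | None:
        if self.n_pairs == 0:
            return None
        return getattr(self, f"{component}_matches") / self.n_pairs

    def percent(self, component: str) -> float | None:
        frac = self.fraction(component)
        return None if frac is None else round(100.0 * frac, 1)

    def to_dict(self) -> dict:
        out: dict = {"n_pairs": self.n_pairs, "judge_counts": dict(self.judge_counts)}
        for comp in ("subject", "relation", "object", "subject_ns", "object_ns"):
            out[comp] = {
                "count": getattr(self, f"{comp}_matches"),
                "fraction": self.fraction(comp),
                "percent": self.percent(comp),
            }
        return out


def _check_weights(weights: dict[str, float]) -> None:
    if set(weights) != {"subject", "relation", "object"}:
        raise ValueError("weights must have exactly subject/relation/object keys")
    if not math.isclose(sum(weights.values()), 1.0, abs_tol=1e-9):
        raise ValueError(f"weights must sum to 1, got {sum(weights.values())}")


def _ns_of(statement_side) -> str | None:
    entity = statement_side.primary_entity()
    return entity.namespace if entity is not None else None


def compare_statements(
    a: BelStatement,
    b: BelStatement,
    weights: dict[str, float] = DEFAULT_WEIGHTS,
) -> ComparisonResult:
    """Score two statements by their matching components.

    Component equality is canonical-string equality of the subject
    terms, the relations, and the object terms; the total score is the
    sum of the weights of the matching scored components.  Namespace
    agreement (primary-entity vocabulary of subject/object) is reported
    but not scored.
    """
    _check_weights(weights)
    subject_match = serialize_term(a.subject) == serialize_term(b.subject)
    relation_match = a.relation == b.relation
    object_match = serialize_term(a.object) == serialize_term(b.object)
    ns_a_s, ns_b_s = _ns_of(a.subject), _ns_of(b.subject)
    ns_a_o, ns_b_o = _ns_of(a.object), _ns_of(b.object)
    total = (
        weights["subject"] * subject_match
        + weights["relation"] * relation_match
        + weights["object"] * object_match
    )
    return ComparisonResult(
        a=a,
        b=b,
        subject_match=subject_match,
        relation_match=relation_match,
        object_match=object_match,
        subject_ns_match=ns_a_s is not None and ns_a_s == ns_b_s,
        object_ns_match=ns_a_o is not None and ns_a_o == ns_b_o,
        total_score=total,
    )


def best_match(
    query: BelStatement,
    candidates: list[BelStatement],
    weights: dict[str, float] = DEFAULT_WEIGHTS,
) -> tuple[BelStatement, ComparisonResult]:
    """Return the candidate with the highest total score against ``query``.

    Ties break to the earliest candidate.  Raises on an empty candidate
    list.
    """
    if not candidates:
        raise ValueError("best_match requires at least one candidate")
    best_result: ComparisonResult | None = None
    best_candidate: BelStatement | None = None
    for cand in candidates:
        result = compare_statements(query, cand, weights)
        if best_result is None or result.total_score > best_result.total_score:
            best_result, best_candidate = result, cand
    assert best_candidate is not None and best_result is not None
    return best_candidate, best_result


def aggregate_agreement(pairs: list[ComparisonResult]) -> AgreementReport:
    """Tally per-component agreement counts and judge categories over pairs."""
    judge_counts: dict[str, int] = {}
    for p in pairs:
        if p.judge is not None:
            judge_counts[p.judge] = judge_counts.get(p.judge, 0) + 1
    return AgreementReport(
        n_pairs=len(pairs),
        subject_matches=sum(p.subject_match for p in pairs),
        relation_matches=sum(p.relation_match for p in pairs),
        object_matches=sum(p.object_match for p in pairs),
        subject_ns_matches=sum(p.subject_ns_match for p in pairs),
        object_ns_matches=sum(p.object_ns_match for p in pairs),
        judge_counts=judge_counts,
    )


_JUDGE_PROMPT = """\
Two tools extracted a BEL statement from the same evidence sentence.
Rate how similar the statements are, using exactly one of three labels:
 Good: the statements represent the same relationship.
 Medium: the statements are related but differ slightly in specificity.
 Bad: the statements describe different relationships.

Evidence: {evidence}
Statement 1: {a}
Statement 2: {b}

Answer with the single word Good, Medium or Bad.
"""


def judge_similarity(
    a: EvidenceRecord, b: EvidenceRecord, backend: LLMBackend
) -> str:
    """Rate the semantic similarity of two records sharing evidence text.

    Returns one of ``Good``/``Medium``/``Bad``.  Any other backend label
    raises :class:`JudgeError` — no silent coercion.
    """
    prompt = _JUDGE_PROMPT.format(evidence=a.evidence_sentence, a=a.bel, b=b.bel)
    reply = backend.complete(prompt).strip()
    if reply not in JUDGE_CATEGORIES:
        raise JudgeError(f"judge returned {reply!r}, expected one of {JUDGE_CATEGORIES}")
    return reply


def load_external_bel(path: str | Path) -> tuple[list[EvidenceRecord], list[dict]]:
    """Load a BEL-as-JSON file (e.g. another tool's converted output).

    Returns (records, quarantined): entries whose BEL fails to parse are
    quarantined individually with their error rather than aborting the
    load.
    """
    payload = json.loads(Path(path).read_text())
    if not isinstance(payload, list):
        raise ValueError("BEL-as-JSON file must contain a JSON array")
    records: list[EvidenceRecord] = []
    quarantined: list[dict] = []
    for entry in payload:
        try:
            statement = parse_bel(entry["bel_statement"])
        except (BelParseError, KeyError, TypeError) as exc:
            quarantined.append({"entry": entry, "error": str(exc)})
            continue
        records.append(
            EvidenceRecord(
                statement=statement,
                evidence_sentence=str(entry.get("evidence", "")),
                paragraph_index=int(entry.get("paragraph_index", -1)),
                source_id=str(entry.get("source_id", str(path))),
            )
        )
    return records, quarantined


def pair_by_evidence(
    ours: list[EvidenceRecord],
    theirs: list[EvidenceRecord],
    weights: dict[str, float] = DEFAULT_WEIGHTS,
    judge_backend: LLMBackend | None = None,
) -> list[ComparisonResult]:
    """Pair two record sets by shared evidence text and score best matches.

    For every evidence text present in both sets, each of our statements
    is paired with its best-scoring counterpart.  With a judge backend,
    each pair additionally gets a Good/Medium/Bad rating.
    """
    def norm(s: str) -> str:
        return " ".join(s.split()).lower()

    theirs_by_evidence: dict[str, list[EvidenceRecord]] = {}
    for rec in theirs:
        theirs_by_evidence.setdefault(norm(rec.evidence_sentence), []).append(rec)
    results: list[ComparisonResult] = []
    for rec in ours:
        pool = theirs_by_evidence.get(norm(rec.evidence_sentence))
        if not pool:
            continue
        _, result = best_match(rec.statement, [r.statement for r in pool], weights)
        if judge_backend is not None:
            matched = next(
                r for r in pool if serialize_term(r.statement.subject) ==
                serialize_term(result.b.subject) and r.statement.relation == result.b.relation
                and serialize_term(r.statement.object) == serialize_term(result.b.object)
            )
            try:
                label = judge_similarity(rec, matched, judge_backend)
            except (JudgeError, BackendError):
                label = None
            result = ComparisonResult(
                a=result.a,
                b=result.b,
                subject_match=result.subject_match,
                relation_match=result.relation_match,
                object_match=result.object_match,
                subject_ns_match=result.subject_ns_match,
                object_ns_match=result.object_ns_match,
                total_score=result.total_score,
                judge=label,
            )
        results.append(result)
    return results
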