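"""Statement comparison scoring, pairing, agreement aggregation, judge."""

import json
import random

import pytest

from beltograph import parse_bel
from beltograph.evaluation import (
    DEFAULT_WEIGHTS,
    JudgeError,
    aggregate_agreement,
    best_match,
    compare_statements,
    judge_similarity,
    load_external_bel,
    pair_by_evidence,
)
from beltograph.extraction import EvidenceRecord
from beltograph.llm import ScriptedBackend
from beltograph.synthetic import make_agreement_corpus, random_statement

AKT1_HSF1 = "p(HGNC:AKT1) increases p(HGNC:HSF1)"
TP53_MDM2 = "p(HGNC:TP53) increases p(HGNC:MDM2)"
WORKED = (
    'act(p(HGNC:AKT1),ma(GO:"kinase activity")) directlyIncreases '
    "p(HGNC:HSF1,pmod(Ph,Ser,326))"
)


class TestCompareStatements:
    def test_identical_statements_score_one(self):
        stmt = parse_bel(WORKED)
        result = compare_statements(stmt, stmt)
        assert result.total_score == pytest.approx(1.0)
        assert result.subject_match and result.relation_match and result.object_match

    def test_relation_only_match_scores_relation_weight(self):
        result = compare_statements(parse_bel(AKT1_HSF1), parse_bel(TP53_MDM2))
        assert result.total_score == pytest.approx(0.4)
        assert result.relation_match
        assert not result.subject_match and not result.object_match

    def test_fully_disjoint_statements_score_zero(self):
        a = parse_bel(AKT1_HSF1)
        b = parse_bel("p(HGNC:TP53) decreases p(HGNC:MDM2)")
        assert compare_statements(a, b).total_score == pytest.approx(0.0)

    def test_namespace_agreement_tracked_but_unscored(self):
        a = parse_bel(AKT1_HSF1)
        b = parse_bel("p(HGNC:TP53) decreases p(HGNC:MDM2)")
        result = compare_statements(a, b)
        assert result.subject_ns_match and result.object_ns_match
        assert result.total_score == pytest.approx(0.0)
        c = parse_bel("a(CHEBI:NAD) decreases bp(GO:\"DNA repair\")")
        result2 = compare_statements(a, c)
        assert not result2.subject_ns_match and not result2.object_ns_match

    def test_score_symmetry_on_random_pairs(self, rng):
        for _ in range(100):
            a, b = random_statement(rng), random_statement(rng)
            assert compare_statements(a, b).total_score == pytest.approx(
                compare_statements(b, a).total_score
            )

    def test_score_bounds_and_extremes(self, rng):
        for _ in range(100):
            a, b = random_statement(rng), random_statement(rng)
            r = compare_statements(a, b)
            assert 0.0 <= r.total_score <= 1.0
            all_match = r.subject_match and r.relation_match and r.object_match
            assert (r.total_score == pytest.approx(1.0)) == all_match
            none_match = not (r.subject_match or r.relation_match or r.object_match)
            assert (r.total_score == pytest.approx(0.0)) == none_match

    def test_custom_weights(self):
        weights = {"subject": 0.5, "relation": 0.2, "object": 0.3}
        result = compare_statements(
            parse_bel(AKT1_HSF1), parse_bel(TP53_MDM2), weights
        )
        assert result.total_score == pytest.approx(0.2)

    def test_weights_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            compare_statements(
                parse_bel(AKT1_HSF1), parse_bel(TP53_MDM2),
                {"subject": 0.5, "relation": 0.5, "object": 0.5},
            )


class TestBestMatch:
    def test_single_candidate_returned(self):
        query = parse_bel(AKT1_HSF1)
        cand = parse_bel(TP53_MDM2)
        chosen, result = best_match(query, [cand])
        assert chosen == cand and result.total_score == pytest.approx(0.4)

    def test_exact_duplicate_wins(self):
        query = parse_bel(WORKED)
        candidates = [parse_bel(TP53_MDM2), parse_bel(WORKED), parse_bel(AKT1_HSF1)]
        chosen, result = best_match(query, candidates)
        assert chosen == query and result.total_score == pytest.approx(1.0)

    def test_empty_candidates_rejected(self):
        with pytest.raises(ValueError):
            best_match(parse_bel(AKT1_HSF1), [])

    def test_agrees_with_brute_force_argmax(self, rng):
        # exhaustive scoring over 50 random candidate sets; first-wins ties
        for _ in range(50):
            query = random_statement(rng)
            candidates = [random_statement(rng) for _ in range(rng.randint(1, 8))]
            chosen, result = best_match(query, candidates)
            scores = [compare_statements(query, c).total_score for c in candidates]
            best_score = max(scores)
            assert result.total_score == pytest.approx(best_score)
            assert chosen == candidates[scores.index(best_score)]


class TestAggregateAgreement:
    def test_engineered_corpus_reports_published_style_percentages(self):
        # 29 pairs built to 6/11/8 subject/relation/object matches
        pairs = [
            compare_statements(a, b) for a, b in make_agreement_corpus(29, 6, 11, 8)
        ]
        report = aggregate_agreement(pairs)
        assert report.n_pairs == 29
        assert report.subject_matches == 6
        assert report.relation_matches == 11
        assert report.object_matches == 8
        assert report.percent("subject") == 20.7
        assert report.percent("relation") == 37.9
        assert report.percent("object") == 27.6

    def test_empty_input_fractions_undefined(self):
        report = aggregate_agreement([])
        assert report.n_pairs == 0
        assert report.fraction("subject") is None
        assert report.percent("relation") is None

    def test_counts_match_brute_force_recount(self, rng):
        pairs = [
            compare_statements(random_statement(rng), random_statement(rng))
            for _ in range(60)
        ]
        report = aggregate_agreement(pairs)
        assert report.subject_matches == sum(1 for p in pairs if p.subject_match)
        assert report.relation_matches == sum(1 for p in pairs if p.relation_match)
        assert report.object_matches == sum(1 for p in pairs if p.object_match)
        assert report.subject_ns_matches == sum(1 for p in pairs if p.subject_ns_match)
        assert report.object_ns_matches == sum(1 for p in pairs if p.object_ns_match)

    def test_judge_counts_tallied(self):
        base = compare_statements(parse_bel(AKT1_HSF1), parse_bel(TP53_MDM2))
        from dataclasses import replace

        pairs = [replace(base, judge=j) for j in ("Good", "Good", "Bad", None)]
        report = aggregate_agreement(pairs)
        assert report.judge_counts == {"Good": 2, "Bad": 1}


def rec(bel: str, evidence: str) -> EvidenceRecord:
    return EvidenceRecord(parse_bel(bel), evidence, 0, "test")


class TestJudgeSimilarity:
    def test_scripted_category_returned(self):
        a, b = rec(AKT1_HSF1, "shared evidence"), rec(WORKED, "shared evidence")
        assert judge_similarity(a, b, ScriptedBackend(script=["Good"])) == "Good"

    def test_prompt_embeds_rubric_and_statements(self):
        a, b = rec(AKT1_HSF1, "shared evidence"), rec(WORKED, "shared evidence")
        backend = ScriptedBackend(script=["Medium"])
        judge_similarity(a, b, backend)
        prompt = backend.calls[0]
        for needle in ("Good", "Medium", "Bad", "same relationship",
                       "specificity", a.bel, b.bel, "shared evidence"):
            assert needle in prompt

    def test_out_of_vocabulary_label_rejected(self):
        a, b = rec(AKT1_HSF1, "e"), rec(TP53_MDM2, "e")
        with pytest.raises(JudgeError, match="Excellent"):
            judge_similarity(a, b, ScriptedBackend(script=["Excellent"]))


class TestLoadExternalBel:
    def entries(self):
        return [
            {"bel_statement": AKT1_HSF1, "evidence": "e1", "paragraph_index": 0,
             "source_id": "indra"},
            {"bel_statement": TP53_MDM2, "evidence": "e2", "paragraph_index": 1,
             "source_id": "indra"},
            {"bel_statement": WORKED, "evidence": "e3", "paragraph_index": 2,
             "source_id": "indra"},
        ]

    def test_well_formed_file_loads_all_records(self, tmp_path):
        path = tmp_path / "theirs.json"
        path.write_text(json.dumps(self.entries()))
        records, quarantined = load_external_bel(path)
        assert len(records) == 3 and quarantined == []
        assert records[0].bel == AKT1_HSF1

    def test_bad_bel_quarantined_per_record(self, tmp_path):
        entries = self.entries()
        entries[1]["bel_statement"] = "p(HGNC:TP53 increases"
        path = tmp_path / "theirs.json"
        path.write_text(json.dumps(entries))
        records, quarantined = load_external_bel(path)
        assert len(records) == 2 and len(quarantined) == 1
        assert "error" in quarantined[0]

    def test_pairing_uses_only_shared_evidence(self, tmp_path):
        ours = [rec(AKT1_HSF1, "shared A"), rec(TP53_MDM2, "only ours")]
        theirs = [rec(WORKED, "shared A"), rec(TP53_MDM2, "only theirs")]
        pairs = pair_by_evidence(ours, theirs)
        # set-intersection oracle on normalized evidence
        shared = {"shared a"}
        expected = [r for r in ours if r.evidence_sentence.lower() in shared]
        assert len(pairs) == len(expected) == 1
        assert pairs[0].a == ours[0].statement

    def test_pairing_with_judge_backend_labels_pairs(self):
        ours = [rec(AKT1_HSF1, "shared")]
        theirs = [rec(WORKED, "shared")]
        pairs = pair_by_evidence(ours, theirs, judge_backend=ScriptedBackend(script=["Medium"]))
        assert pairs[0].judge == "Medium"
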