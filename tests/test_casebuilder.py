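"""Matching-rate gate, de-identification, difficulty grading, review flow."""

import numpy as np
import pytest

from vcase.casebuilder import (
    DeidConfig,
    apply_difficulty,
    build_virtual_case,
    compute_matching_rate,
    deidentify,
    leak_scan,
    rank_and_gate,
    review_action,
)
from vcase.fixtures import (
    generate_question_library,
    generate_source_record,
    make_case_fixture,
)
from vcase.matching import Scene, StandardQuestion
from vcase.records import get_template


@pytest.fixture(scope="module")
def lib20():
    lib, lex = generate_question_library(20, seed=12)
    from vcase.fixtures import build_pipeline

    return lib, build_pipeline(lex)


class TestMatchingRate:
    def test_full_coverage_rate_one(self, lib20):
        lib, pipe = lib20
        rec = generate_source_record("inguinal_hernia", lib, 1.0, seed=0)
        assert compute_matching_rate(rec, lib, pipe) == 1.0

    def test_gate_at_ninety_percent(self, lib20):
        lib, pipe = lib20
        rec = generate_source_record("inguinal_hernia", lib, 0.9, seed=0)
        rate = compute_matching_rate(rec, lib, pipe)
        assert rate == pytest.approx(0.9)
        assert rate >= 0.90

    def test_below_gate(self, lib20):
        lib, pipe = lib20
        rec = generate_source_record("inguinal_hernia", lib, 0.85, seed=0)
        rate = compute_matching_rate(rec, lib, pipe)
        assert rate == pytest.approx(0.85)
        assert rate < 0.90

    def test_empty_narrative_rate_zero(self, lib20):
        lib, pipe = lib20
        rec = generate_source_record("inguinal_hernia", lib, 0.5, seed=0)
        rec = rec.model_copy(update={"narrative": {}})
        assert compute_matching_rate(rec, lib, pipe) == 0.0


class TestRankAndGate:
    def test_orders_and_flags(self, lib20):
        lib, pipe = lib20
        records = [
            generate_source_record("inguinal_hernia", lib, cov, seed=i)
            for i, cov in enumerate((0.85, 0.95, 0.90))
        ]
        ranked = rank_and_gate(records, lib, pipe, threshold=0.90)
        rates = [r for _rec, r, _g in ranked]
        assert rates == sorted(rates, reverse=True)
        assert [g for _rec, _r, g in ranked] == [True, True, False]

    def test_permutation_invariance(self, lib20):
        lib, pipe = lib20
        records = [
            generate_source_record("inguinal_hernia", lib, 0.8, seed=i)
            for i in range(4)
        ]
        a = rank_and_gate(records, lib, pipe)
        b = rank_and_gate(records[::-1], lib, pipe)
        assert [r.record_id for r, _x, _y in a] == [
            r.record_id for r, _x, _y in b
        ]

    def test_equal_rates_ordered_by_record_id(self, lib20):
        lib, pipe = lib20
        records = [
            generate_source_record("inguinal_hernia", lib, 1.0, seed=i)
            for i in (3, 1, 2)
        ]
        ranked = rank_and_gate(records, lib, pipe)
        ids = [r.record_id for r, _x, _y in ranked]
        assert ids == sorted(ids)


class TestDeidentify:
    def test_masks_everywhere_with_equal_length(self, lib20):
        lib, _pipe = lib20
        rec = generate_source_record("inguinal_hernia", lib, 1.0, seed=4)
        name = rec.structured["name"]
        clean = deidentify(rec, DeidConfig())
        assert clean.structured["name"] == "*" * len(name)
        blob = clean.model_dump_json()
        for value in rec.pii_manifest.values():
            assert value not in blob

    def test_value_embedded_mid_narrative_masked(self, lib20):
        lib, _pipe = lib20
        rec = generate_source_record("inguinal_hernia", lib, 1.0, seed=4)
        name = rec.structured["name"]
        assert name in rec.narrative["present_illness"]
        clean = deidentify(rec)
        assert name not in clean.narrative["present_illness"]
        assert "*" * len(name) in clean.narrative["present_illness"]

    def test_empty_pii_fields_unchanged(self, lib20):
        lib, _pipe = lib20
        rec = generate_source_record("inguinal_hernia", lib, 0.5, seed=4)
        rec = rec.model_copy(deep=True)
        for f in rec.pii_manifest:
            rec.structured[f] = ""
            rec.pii_manifest[f] = ""
        rec.narrative = {"chief_complaint": "stable content"}
        clean = deidentify(rec)
        assert clean.narrative == rec.narrative
        assert clean.structured["gender"] == rec.structured["gender"]

    def test_unmapped_custom_field_warns(self, lib20):
        lib, _pipe = lib20
        rec = generate_source_record("inguinal_hernia", lib, 0.5, seed=4)
        with pytest.warns(UserWarning):
            deidentify(rec, DeidConfig(custom_fields=("nonexistent_field",)))

    def test_fuzz_no_leaks_in_released_cases(self, lib20):
        lib, pipe = lib20
        template = get_template("inguinal_hernia")
        for seed in range(50):
            rec = generate_source_record("inguinal_hernia", lib, 1.0, seed=seed)
            pii = list(rec.pii_manifest.values())
            case = build_virtual_case(
                deidentify(rec), lib, template=template
            )
            released = review_action(case, "release")
            assert leak_scan(released, pii) == []


class TestApplyDifficulty:
    def test_level1_guided(self, hernia_fixture):
        p = apply_difficulty(hernia_fixture.case, 1, seed=0)
        assert p.visible_answers
        assert p.distractors == []
        assert p.free_entry_items == []

    def test_level2_distractors_seeded_and_incorrect(self, hernia_fixture):
        pool, _ = generate_question_library(8, seed=99)
        a = apply_difficulty(
            hernia_fixture.case, 2, seed=5, distractor_pool=list(pool)
        )
        b = apply_difficulty(
            hernia_fixture.case, 2, seed=5, distractor_pool=list(pool)
        )
        assert a.distractors == b.distractors
        assert len(a.distractors) >= 1
        assert all(not d.is_correct_item for d in a.distractors)
        # original items untouched
        assert a.base.questions == hernia_fixture.case.questions

    def test_level3_top_weighted_free_entry(self, hernia_fixture):
        p = apply_difficulty(hernia_fixture.case, 3, seed=0)
        assert p.free_entry_items
        weights = {
            q.question_id: q.score_weight for q in hernia_fixture.case.questions
        }
        free_w = [weights[i] for i in p.free_entry_items if i in weights]
        kept_w = [w for i, w in weights.items() if i not in p.free_entry_items]
        assert min(free_w) >= max(kept_w)

    def test_level4_all_scoring_items_free_entry(self, hernia_fixture):
        from vcase.casebuilder import scoring_item_ids

        p = apply_difficulty(hernia_fixture.case, 4, seed=0)
        assert sorted(p.free_entry_items) == sorted(
            scoring_item_ids(hernia_fixture.case)
        )
        assert not p.visible_answers

    def test_invalid_level_rejected(self, hernia_fixture):
        with pytest.raises(ValueError):
            apply_difficulty(hernia_fixture.case, 5, seed=0)

    def test_unreleased_case_rejected(self, lib20):
        lib, _pipe = lib20
        rec = generate_source_record("inguinal_hernia", lib, 1.0, seed=0)
        case = build_virtual_case(
            deidentify(rec), lib, template=get_template("inguinal_hernia")
        )
        with pytest.raises(ValueError):
            apply_difficulty(case, 1, seed=0)


class TestReviewActions:
    def _draft(self, lib20):
        lib, _pipe = lib20
        rec = generate_source_record("inguinal_hernia", lib, 1.0, seed=0)
        return build_virtual_case(
            deidentify(rec), lib, template=get_template("inguinal_hernia")
        ), lib

    def test_add_then_delete_is_identity(self, lib20):
        case, _lib = self._draft(lib20)
        extra = StandardQuestion(
            question_id="extra-1",
            canonical_tokens=["aaa", "bbb", "ccc", "ddd", "eee"],
            display_text="aaabbbcccdddeee",
            scene=Scene.CONSULTATION,
        )
        edited = review_action(case, "add_item", item=extra)
        assert len(edited.questions) == len(case.questions) + 1
        back = review_action(edited, "delete_item", item_id="extra-1")
        assert back == case

    def test_release_blocked_on_leaking_case(self, lib20):
        lib, _pipe = lib20
        rec = generate_source_record("inguinal_hernia", lib, 1.0, seed=0)
        # build from the raw (un-deidentified) record: PII still embedded
        case = build_virtual_case(
            rec, lib, template=get_template("inguinal_hernia")
        )
        case.overview += " seen for " + rec.structured["name"]
        with pytest.raises(ValueError, match="release blocked"):
            review_action(case, "release")

    def test_released_case_immutable(self, lib20):
        case, _lib = self._draft(lib20)
        released = review_action(case, "release")
        with pytest.raises(ValueError, match="cannot be edited"):
            review_action(released, "delete_item", item_id="q000")

    def test_state_machine_order(self, lib20):
        case, _lib = self._draft(lib20)
        mid = review_action(case, "submit_for_review")
        assert mid.review_status.value == "under_review"
        done = review_action(mid, "release")
        assert done.review_status.value == "released"
        with pytest.raises(ValueError):
            review_action(done, "release")
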