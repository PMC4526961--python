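"""Subscore arithmetic, NA exclusion, totals, and lattice properties."""

import itertools

import pytest
from hypothesis import given, settings, strategies as st

from dischargesat import (
    ITEMS,
    NOT_APPLICABLE,
    score_cohort,
    score_item,
    score_record,
    score_total,
)
from dischargesat.instrument import PatientProfile
from dischargesat.report import round_half_up

from conftest import make_complete_record


class TestScoreItem:
    def test_all_favorable_logistics_is_one(self, smap, favorable_record):
        assert score_item(favorable_record, "logistics", smap) == 1.0

    def test_continuity_graded_example(self, smap):
        rec = make_complete_record(smap, Q7="Satisfied", Q9="Yes", Q10="No")
        assert score_item(rec, "continuity", smap) == pytest.approx((0.75 + 1 + 0) / 3)

    def test_logistics_na_shrinks_denominator(self, smap):
        rec = make_complete_record(
            smap, Q11D="Not concerned", Q11E="Not concerned", Q3="No"
        )
        assert score_item(rec, "logistics", smap) == pytest.approx(4 / 5)

    def test_continuity_single_applicable_question(self, smap):
        rec = make_complete_record(
            smap,
            Q7="Not concerned",
            Q9="I don't have a primary care physician",
            Q10="Yes",
        )
        assert score_item(rec, "continuity", smap) == 1.0

    def test_na_answers_shrink_applicable_counts(self, smap):
        rec = make_complete_record(
            smap, Q11C="Not concerned", Q11D="Not concerned", Q11E="Not concerned"
        )
        assert score_item(rec, "logistics", smap) == pytest.approx(4 / 4)
        assert score_record(rec, smap).applicable_counts["logistics"] == 4

    def test_all_na_item_is_undefined(self):
        # the default instrument keeps one always-applicable question per
        # item, so UNDEFINED needs a synthetic mini-instrument to manifest
        from dischargesat import QuestionDef, ResponseRecord, ScoringMap

        mini = ScoringMap(
            [
                QuestionDef(
                    "QX",
                    "synthetic NA-only question",
                    "continuity",
                    ("Yes", "No", "Not concerned"),
                    {"Yes": 1.0, "No": 0.0, "Not concerned": NOT_APPLICABLE},
                )
            ]
        )
        rec = ResponseRecord("p", {"QX": "Not concerned"})
        assert score_item(rec, "continuity", mini) is None

    def test_unknown_item_errors(self, smap, favorable_record):
        with pytest.raises(KeyError):
            score_item(favorable_record, "nonexistent", smap)

    def test_incomplete_record_errors(self, smap, favorable_record):
        del favorable_record.answers["Q2"]
        with pytest.raises(ValueError):
            score_item(favorable_record, "logistics", smap)


class TestScoreTotal:
    def test_all_ones(self):
        assert score_total([1.0, 1.0, 1.0]) == 1.0

    def test_hand_computed_mean(self):
        total = score_total([6 / 7, (0.75 + 1 + 0) / 3, 0.75])
        assert total == pytest.approx((6 / 7 + 7 / 12 + 3 / 4) / 3)
        assert total == pytest.approx(0.7302, abs=5e-5)

    def test_undefined_subscore_makes_total_undefined(self):
        assert score_total([0.9, None, 1.0]) is None

    def test_wrong_arity_errors(self):
        with pytest.raises(ValueError):
            score_total([1.0, 1.0])


class TestScoreCohort:
    def test_extremes(self, smap):
        best = make_complete_record(smap, pid="best")
        worst_answers = {}
        for q in smap:
            if q.documentation_only:
                continue
            worst_answers[q.id] = min(
                (r for r in q.responses if isinstance(q.score_map.get(r), float)),
                key=lambda r: q.score_map[r],
            )
        from dischargesat import ResponseRecord

        worst = ResponseRecord("worst", worst_answers)
        sets = {s.patient_id: s for s in score_cohort([best, worst], scoring_map=smap)}
        assert sets["best"].total == 1.0
        assert sets["worst"].total == 0.0
        assert (sets["worst"].logistics, sets["worst"].continuity, sets["worst"].impressions) == (0, 0, 0)

    def test_order_invariance(self, smap):
        recs = [
            make_complete_record(smap, pid="a", Q3="No"),
            make_complete_record(smap, pid="b", Q7="Satisfied"),
            make_complete_record(smap, pid="c", Q11D="Not concerned"),
        ]
        fwd = {s.patient_id: s for s in score_cohort(recs, scoring_map=smap)}
        rev = {s.patient_id: s for s in score_cohort(recs[::-1], scoring_map=smap)}
        assert fwd == rev

    def test_profile_mismatch_errors(self, smap, favorable_record):
        other = PatientProfile("someone-else", "internet", "u", 40, "male", 1, 3.0, False, None)
        with pytest.raises(ValueError):
            score_cohort([favorable_record], [other], smap)


def _scored_response_sets(smap, item):
    """Per-question applicable (non-NA) responses for an item's questions."""
    out = []
    for qid in smap.item_members(item):
        q = smap[qid]
        out.append([(qid, r) for r in q.responses if isinstance(q.score_map.get(r), float)])
    return out


class TestAttainableValues:
    """Exhaustive enumeration of every no-NA response combination per item."""

    @pytest.mark.parametrize(
        "item, lattice_denominator", [("logistics", 7), ("impressions", 4)]
    )
    def test_binaryish_items_live_on_lattice(self, smap, item, lattice_denominator):
        values = set()
        for combo in itertools.product(*_scored_response_sets(smap, item)):
            rec = make_complete_record(smap, **dict(combo))
            v = score_item(rec, item, smap)
            # independent per-question summation oracle
            oracle = sum(smap[q].score_map[r] for q, r in combo) / len(combo)
            assert v == pytest.approx(oracle, abs=1e-12)
            values.add(round(v, 10))
        assert values == {round(k / lattice_denominator, 10) for k in range(lattice_denominator + 1)}

    def test_continuity_values_match_component_structure(self, smap):
        values = set()
        for combo in itertools.product(*_scored_response_sets(smap, "continuity")):
            rec = make_complete_record(smap, **dict(combo))
            v = score_item(rec, "continuity", smap)
            oracle = sum(smap[q].score_map[r] for q, r in combo) / len(combo)
            assert v == pytest.approx(oracle, abs=1e-12)
            values.add(round(v, 10))
        expected = {
            round((a + b) / 3, 10)
            for a in (0.0, 0.25, 0.75, 1.0)  # Q7 levels
            for b in (0, 1, 2)  # Q9 + Q10 favorable count
        }
        assert values == expected

    def test_printed_percentile_levels_are_attainable(self, smap):
        """Rounded attainable continuity values cover the published
        percentile levels 0.25, 0.33, 0.58, 0.67, 0.92, 1."""
        rounded = set()
        for combo in itertools.product(*_scored_response_sets(smap, "continuity")):
            rec = make_complete_record(smap, **dict(combo))
            rounded.add(round_half_up(score_item(rec, "continuity", smap), 2))
        assert {0.25, 0.33, 0.58, 0.67, 0.92, 1.0} <= rounded

    def test_all_values_in_unit_interval_even_with_na(self, smap):
        na_capable = {"Q7": "Not concerned", "Q11C": "Not concerned",
                      "Q11D": "Not concerned", "Q11E": "Not concerned",
                      "Q9": "I don't have a primary care physician"}
        for subset in itertools.chain.from_iterable(
            itertools.combinations(na_capable, k) for k in range(len(na_capable) + 1)
        ):
            rec = make_complete_record(smap, **{q: na_capable[q] for q in subset})
            s = score_record(rec, smap)
            for item in ITEMS:
                v = s.subscore(item)
                assert v is None or 0.0 <= v <= 1.0
            assert s.total is None or 0.0 <= s.total <= 1.0


@st.composite
def _complete_answers(draw):
    from dischargesat import build_default_scoring_map

    smap = build_default_scoring_map()
    answers = {}
    for qid in smap.scored_ids:
        q = smap[qid]
        answers[qid] = draw(st.sampled_from(q.responses))
    return answers


class TestMonotonicity:
    @settings(max_examples=60, derandomize=True)
    @given(_complete_answers(), st.data())
    def test_upgrading_one_answer_never_decreases_scores(self, smap, answers, data):
        from dischargesat import ResponseRecord

        qid = data.draw(st.sampled_from(sorted(answers)))
        q = smap[qid]
        current = q.score_map[answers[qid]]
        if current is NOT_APPLICABLE:
            return  # NA -> scored transitions change the denominator, not ordered
        higher = [
            r
            for r in q.responses
            if isinstance(q.score_map.get(r), float) and q.score_map[r] >= current
        ]
        upgraded = dict(answers, **{qid: data.draw(st.sampled_from(higher))})
        before = score_record(ResponseRecord("a", answers), smap)
        after = score_record(ResponseRecord("a", upgraded), smap)
        for item in ITEMS:
            b, a = before.subscore(item), after.subscore(item)
            if b is not None and a is not None:
                assert a >= b - 1e-12
        if before.total is not None and after.total is not None:
            assert after.total >= before.total - 1e-12
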