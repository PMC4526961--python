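import pytest

from dischargesat import (
    ResponseRecord,
    build_default_scoring_map,
    reference_cohort,
)


@pytest.fixture(scope="session")
def smap():
    return build_default_scoring_map()


@pytest.fixture(scope="session")
def reference():
    """Deterministic cohort matching the reference marginal counts."""
    return reference_cohort()


def make_complete_record(smap, pid="p1", **overrides):
    """A fully favorable complete record, with per-question overrides."""
    answers = {}
    for q in smap:
        if q.documentation_only:
            continue
        best = max(
            (r for r in q.responses if isinstance(q.score_map.get(r), float)),
            key=lambda r: q.score_map[r],
        )
        answers[q.id] = best
    answers.update(overrides)
    return ResponseRecord(patient_id=pid, answers=answers)


@pytest.fixture
def favorable_record(smap):
    return make_complete_record(smap)
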