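"""Satisfaction subscores and total score.

Each item subscore is the normalized sum of its question scores -- the
mean over *applicable* questions only, so a "Not concerned" answer drops
the question from both numerator and denominator.  The total score is the
arithmetic mean of the three subscores and is UNDEFINED (``None``) when
any subscore is UNDEFINED (i.e. when every question of an item was not
applicable).  All scores lie in ``[0, 1]``.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Iterable, Sequence

import pandas as pd

from .instrument import (
    ITEMS,
    MISSING,
    NOT_APPLICABLE,
    PatientProfile,
    ResponseRecord,
    ScoringMap,
    build_default_scoring_map,
)

__all__ = ["ScoreSet", "score_item", "score_total", "score_record", "score_cohort", "scores_to_frame"]

#: A subscore or total that cannot be computed (all questions not applicable).
UNDEFINED = None


@dataclass(frozen=True)
class ScoreSet:
    """The three item subscores and the total score of one patient.

    Any field may be ``None`` (UNDEFINED).  ``applicable_counts`` records
    how many questions entered each item's denominator.
    """

    patient_id: str
    logistics: float | None
    continuity: float | None
    impressions: float | None
    total: float | None
    applicable_counts: dict[str, int]

    def subscore(self, item: str) -> float | None:
        if item not in ITEMS:
            raise KeyError(f"unknown item {item!r}")
        return getattr(self, item)


def score_item(
    record: ResponseRecord, item: str, scoring_map: ScoringMap | None = None
) -> float | None:
    """Subscore of ``record`` on one item, or ``None`` if nothing applies.

    Exact rational arithmetic is used internally so lattice values such as
    7/12 come out bit-reproducible.
    """
    smap = scoring_map or build_default_scoring_map()
    members = smap.item_members(item)  # raises KeyError on unknown item
    total = Fraction(0)
    n_applicable = 0
    for qid in members:
        answer = record.answer(qid)
        if answer is MISSING:
            raise ValueError(
                f"record {record.patient_id!r}: {qid} missing; score only complete records"
            )
        score = smap[qid].score_for(answer)
        if score is NOT_APPLICABLE:
            continue
        total += Fraction(score).limit_denominator(10**6)
        n_applicable += 1
    if n_applicable == 0:
        return UNDEFINED
    return float(total / n_applicable)


def score_total(subscores: Sequence[float | None]) -> float | None:
    """Mean of the three subscores; UNDEFINED when any subscore is."""
    if len(subscores) != 3:
        raise ValueError(f"expected 3 subscores, got {len(subscores)}")
    if any(s is None for s in subscores):
        return UNDEFINED
    return float(sum(Fraction(s).limit_denominator(10**9) for s in subscores) / 3)


def _applicable_count(record: ResponseRecord, item: str, smap: ScoringMap) -> int:
    return sum(
        1
        for qid in smap.item_members(item)
        if smap[qid].score_for(record.answer(qid)) is not NOT_APPLICABLE
    )


def score_record(record: ResponseRecord, scoring_map: ScoringMap | None = None) -> ScoreSet:
    """Full :class:`ScoreSet` for one complete record."""
    smap = scoring_map or build_default_scoring_map()
    subs = {item: score_item(record, item, smap) for item in ITEMS}
    counts = {item: _applicable_count(record, item, smap) for item in ITEMS}
    return ScoreSet(
        patient_id=record.patient_id,
        logistics=subs["logistics"],
        continuity=subs["continuity"],
        impressions=subs["impressions"],
        total=score_total([subs[i] for i in ITEMS]),
        applicable_counts=counts,
    )


def score_cohort(
    records: Iterable[ResponseRecord],
    profiles: Iterable[PatientProfile] | None = None,
    scoring_map: ScoringMap | None = None,
) -> list[ScoreSet]:
    """Score every complete record; deterministic and order-independent.

    When ``profiles`` is given, every record's patient_id must be present
    among the profiles (mismatch raises ``ValueError``).
    """
    smap = scoring_map or build_default_scoring_map()
    records = list(records)
    if profiles is not None:
        known = {p.patient_id for p in profiles}
        unknown = sorted({r.patient_id for r in records} - known)
        if unknown:
            raise ValueError(f"records without a matching profile: {unknown[:10]}")
    return [score_record(rec, smap) for rec in records]


def scores_to_frame(
    score_sets: Iterable[ScoreSet],
    profiles: Iterable[PatientProfile] | None = None,
) -> pd.DataFrame:
    """Tidy frame of scores (one row per patient), with arm when profiles given."""
    rows = []
    arm_by_id = {p.patient_id: p.arm for p in profiles} if profiles is not None else {}
    for ss in score_sets:
        rows.append(
            {
                "patient_id": ss.patient_id,
                "arm": arm_by_id.get(ss.patient_id),
                "logistics": ss.logistics,
                "continuity": ss.continuity,
                "impressions": ss.impressions,
                "total": ss.total,
                "n_applicable_logistics": ss.applicable_counts["logistics"],
                "n_applicable_continuity": ss.applicable_counts["continuity"],
                "n_applicable_impressions": ss.applicable_counts["impressions"],
            }
        )
    frame = pd.DataFrame(
        rows,
        columns=[
            "patient_id",
            "arm",
            "logistics",
            "continuity",
            "impressions",
            "total",
            "n_applicable_logistics",
            "n_applicable_continuity",
            "n_applicable_impressions",
        ],
    )
    return frame
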