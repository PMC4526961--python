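"""Flow accounting, descriptive tables and the end-to-end pipeline.

Every percentage in every report is recomputed from its counts at access
time (half-up rounding, 1 decimal for ordinary percentages and 2 decimals
for the overall completion rate), so a stored percentage can never drift
from the underlying counts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .instrument import (
    ARMS,
    EDUCATION_REFUSED,
    MISSING,
    NOT_APPLICABLE,
    PatientProfile,
    ResponseRecord,
    ScoringMap,
    build_default_scoring_map,
    completeness_filter,
)
from .scoring import score_cohort, scores_to_frame
from .simulate import SimScenario, default_trial_scenario, simulate_cohort
from .stats import (
    compare_arms,
    compare_items_within,
    fisher_exact,
    mann_whitney,
)
from . import io as dio

__all__ = [
    "round_half_up",
    "FlowReport",
    "ProportionSummary",
    "REPORT_DEFINITIONS",
    "response_rate_report",
    "item_proportions",
    "characteristics_table",
    "reference_cohort",
    "PipelineConfig",
    "run_pipeline",
]

logger = logging.getLogger("dischargesat")


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Decimal half-up rounding (so 0.25 -> 0.3 at 1 digit)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(str(float(x))).quantize(q, rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# Flow accounting
# ---------------------------------------------------------------------------


@dataclass
class FlowReport:
    """Per-arm inclusion/response accounting.

    ``arms`` maps arm -> dict with ``included``, ``responders``,
    ``nonresponders``, ``complete``, ``incomplete`` counts; percentages are
    always derived from these counts.
    """

    arms: dict[str, dict[str, int]] = field(default_factory=dict)
    units: dict[str, dict[str, int]] = field(default_factory=dict)

    def arm_rate_pct(self, arm: str) -> float:
        d = self.arms[arm]
        return round_half_up(100.0 * d["complete"] / d["included"], 1)

    def unit_rate_pct(self, unit: str) -> float:
        d = self.units[unit]
        return round_half_up(100.0 * d["complete"] / d["included"], 1)

    @property
    def n_included(self) -> int:
        return sum(d["included"] for d in self.arms.values())

    @property
    def n_complete(self) -> int:
        return sum(d["complete"] for d in self.arms.values())

    @property
    def overall_rate_pct(self) -> float:
        return round_half_up(100.0 * self.n_complete / self.n_included, 2)

    def to_dict(self) -> dict:
        return {
            "arms": {
                arm: {**d, "response_rate_pct": self.arm_rate_pct(arm)}
                for arm, d in self.arms.items()
            },
            "units": {
                unit: {**d, "response_rate_pct": self.unit_rate_pct(unit)}
                for unit, d in self.units.items()
            },
            "n_included": self.n_included,
            "n_complete": self.n_complete,
            "overall_response_rate_pct": self.overall_rate_pct,
        }


def response_rate_report(
    profiles: Iterable[PatientProfile],
    records: Iterable[ResponseRecord] | None = None,
    scoring_map: ScoringMap | None = None,
) -> FlowReport:
    """Flow report over included patients.

    A patient counts as *complete* when they responded and (if records are
    given) their questionnaire passes the completeness rule; incomplete
    questionnaires count toward ``incomplete`` and are excluded from the
    response-rate numerator, matching the exclusion rule of the score
    analyses.
    """
    smap = scoring_map or build_default_scoring_map()
    profiles = list(profiles)
    complete_ids: set[str] | None = None
    if records is not None:
        complete, _ = completeness_filter(records, smap)
        complete_ids = {r.patient_id for r in complete}
    report = FlowReport()
    for arm in ARMS:
        arm_profiles = [p for p in profiles if p.arm == arm]
        if not arm_profiles:
            warnings.warn(f"arm {arm!r} has no included patients; omitted from flow")
            continue
        responders = [p for p in arm_profiles if p.responder]
        n_complete = (
            len(responders)
            if complete_ids is None
            else sum(1 for p in responders if p.patient_id in complete_ids)
        )
        report.arms[arm] = {
            "included": len(arm_profiles),
            "responders": len(responders),
            "nonresponders": len(arm_profiles) - len(responders),
            "complete": n_complete,
            "incomplete": len(responders) - n_complete,
        }
    for unit in sorted({p.unit for p in profiles}):
        unit_profiles = [p for p in profiles if p.unit == unit]
        responders = [p for p in unit_profiles if p.responder]
        n_complete = (
            len(responders)
            if complete_ids is None
            else sum(1 for p in responders if p.patient_id in complete_ids)
        )
        report.units[unit] = {
            "included": len(unit_profiles),
            "responders": len(responders),
            "complete": n_complete,
        }
    return report


# ---------------------------------------------------------------------------
# Question-level descriptive proportions
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ProportionSummary:
    """One reported proportion with its NA-excluded denominator."""

    question_id: str
    label: str
    numerator: int
    denominator: int  # respondents minus not-applicable
    excluded_not_applicable: int

    @property
    def undefined(self) -> bool:
        return self.denominator == 0

    @property
    def percentage(self) -> float:
        if self.undefined:
            return float("nan")
        return round_half_up(100.0 * self.numerator / self.denominator, 1)

    def to_dict(self) -> dict:
        return {
            "question_id": self.question_id,
            "label": self.label,
            "numerator": self.numerator,
            "denominator": self.denominator,
            "excluded_not_applicable": self.excluded_not_applicable,
            "percentage": None if self.undefined else self.percentage,
        }


#: The notable response category reported for each question: (question id,
#: label, responses counted in the numerator).
REPORT_DEFINITIONS: tuple[tuple[str, str, tuple[str, ...]], ...] = (
    ("Q2", "informed_of_discharge_modalities", ("Yes",)),
    ("Q3", "not_consulted_for_date_time", ("No",)),
    ("Q4", "date_time_compatible", ("Yes",)),
    ("Q5", "scheduled_time_respected", ("Yes",)),
    ("Q11C", "document_waiting_time_reasonable", ("Reasonable",)),
    ("Q11E", "no_administrative_difficulties", ("No",)),
    ("Q7", "no_explanations_given", ("No information given",)),
    ("Q7", "explanations_poorly_or_not_satisfactory", ("Poorly satisfied", "Not at all satisfied")),
    ("Q9", "pcp_not_informed", ("No",)),
    ("Q9", "pcp_informed_unknown", ("I don't know",)),
    ("Q10", "has_unit_phone_number", ("Yes",)),
    ("Q11A", "discharge_well_planned", ("Well planned",)),
    ("Q11B", "anxious_about_return_home", ("Anxious",)),
    ("Q11F", "information_insufficient", ("Insufficient",)),
    ("Q11G", "staff_availability_insufficient", ("Insufficient",)),
)


def item_proportions(
    records: Iterable[ResponseRecord],
    scoring_map: ScoringMap | None = None,
    definitions: Sequence[tuple[str, str, tuple[str, ...]]] = REPORT_DEFINITIONS,
) -> list[ProportionSummary]:
    """Per-question notable-category proportions over complete records.

    The denominator excludes not-applicable answers ("Not concerned",
    "I don't have a primary care physician"); a denominator of zero is
    flagged as undefined rather than raising.
    """
    smap = scoring_map or build_default_scoring_map()
    records = list(records)
    out = []
    for qid, label, numerator_codes in definitions:
        q = smap[qid]
        num = denom = excluded = 0
        for rec in records:
            ans = rec.answer(qid)
            if ans is MISSING:
                continue
            if q.score_map.get(ans) is NOT_APPLICABLE:
                excluded += 1
                continue
            denom += 1
            if ans in numerator_codes:
                num += 1
        out.append(ProportionSummary(qid, label, num, denom, excluded))
    return out


# ---------------------------------------------------------------------------
# Characteristics table
# ---------------------------------------------------------------------------


def _median_iqr(values: Sequence[float]) -> tuple[float, float, float] | None:
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        return None
    q1, med, q3 = np.percentile(arr, [25, 50, 75])
    return (float(med), float(q1), float(q3))


_EDU_ROWS = ("1", "2", "3", "4", EDUCATION_REFUSED)


def characteristics_table(profiles: Iterable[PatientProfile]) -> dict:
    """Arm x responder-status descriptive table with between-group tests.

    Counts and medians per arm and overall, split by responder status, with
    Fisher tests on categorical rows (response by arm, sex by responder
    status) and rank-sum tests on age, stay duration and ordinal education
    (education "do not wish to answer" rows are shown in the counts but
    excluded from the ordinal comparison).
    """
    profiles = list(profiles)
    groups = {"all": profiles}
    for arm in ARMS:
        arm_p = [p for p in profiles if p.arm == arm]
        if arm_p:
            groups[arm] = arm_p
    table: dict = {"groups": {}, "tests": {}}
    for gname, members in groups.items():
        by_status = {
            "total": members,
            "responders": [p for p in members if p.responder],
            "nonresponders": [p for p in members if not p.responder],
        }
        gtab = {}
        for status, rows in by_status.items():
            edu_counts = {lvl: 0 for lvl in _EDU_ROWS}
            for p in rows:
                edu_counts[str(p.education)] += 1
            gtab[status] = {
                "n": len(rows),
                "sex": {
                    "male": sum(p.sex == "male" for p in rows),
                    "female": sum(p.sex == "female" for p in rows),
                },
                "age_median_iqr": _median_iqr([p.age for p in rows]),
                "los_median_iqr": _median_iqr([p.length_of_stay for p in rows]),
                "education": {
                    lvl: {
                        "n": c,
                        "pct": round_half_up(100 * c / len(rows), 1) if rows else None,
                    }
                    for lvl, c in edu_counts.items()
                },
            }
        table["groups"][gname] = gtab

    def _count(members, pred):
        return sum(1 for p in members if pred(p))

    tests: dict = {}
    # response rates: telephone vs internet / vs noneligible
    for other in ("internet", "noneligible"):
        if other in groups and "telephone" in groups:
            tbl = [
                [
                    _count(groups[other], lambda p: p.responder),
                    _count(groups[other], lambda p: not p.responder),
                ],
                [
                    _count(groups["telephone"], lambda p: p.responder),
                    _count(groups["telephone"], lambda p: not p.responder),
                ],
            ]
            tests[f"response_{other}_vs_telephone"] = _result_dict(fisher_exact(tbl))
    resp = [p for p in profiles if p.responder]
    nonresp = [p for p in profiles if not p.responder]
    if resp and nonresp:
        sexes = {s for p in profiles for s in [p.sex]}
        if len(sexes) < 2:
            tests["sex_responders_vs_nonresponders"] = {"degenerate": True, "reason": "single sex category"}
        else:
            tbl = [
                [sum(p.sex == "male" for p in resp), sum(p.sex == "female" for p in resp)],
                [sum(p.sex == "male" for p in nonresp), sum(p.sex == "female" for p in nonresp)],
            ]
            tests["sex_responders_vs_nonresponders"] = _result_dict(fisher_exact(tbl))
        tests["age_responders_vs_nonresponders"] = _result_dict(
            mann_whitney([p.age for p in resp], [p.age for p in nonresp])
        )
        tests["los_responders_vs_nonresponders"] = _result_dict(
            mann_whitney(
                [p.length_of_stay for p in resp], [p.length_of_stay for p in nonresp]
            )
        )
        edu_r = [int(p.education) for p in resp if p.education != EDUCATION_REFUSED]
        edu_n = [int(p.education) for p in nonresp if p.education != EDUCATION_REFUSED]
        if edu_r and edu_n:
            tests["education_responders_vs_nonresponders"] = _result_dict(
                mann_whitney(edu_r, edu_n)
            )
    table["tests"] = tests
    return table


def _result_dict(res) -> dict:
    return {
        "statistic": res.statistic,
        "p_value": res.p_value,
        "method": res.method,
        "n_per_group": list(res.n_per_group),
        "degenerate": res.degenerate,
    }


# ---------------------------------------------------------------------------
# Deterministic reference fixture
# ---------------------------------------------------------------------------

# responder answer counts over the 755 complete questionnaires; values not
# reported for the reference cohort (Q11D split, Q9 no-PCP, Q1/Q6/Q8,
# Q7 highly/satisfied split) are synthetic fills, chosen once.
_FIXTURE_COUNTS: dict[str, tuple[tuple[str, int], ...]] = {
    "Q1": (
        ("Staff physician", 600),
        ("Yourself", 60),
        ("Your entourage", 15),
        ("Your primary care physician", 40),
        ("Other", 40),
    ),
    "Q2": (("Yes", 664), ("No", 91)),
    "Q3": (("Yes", 354), ("No", 401)),
    "Q4": (("Yes", 699), ("No", 56)),
    "Q5": (("Yes", 685), ("No", 70)),
    "Q7": (
        ("Highly satisfied", 262),
        ("Satisfied", 262),
        ("Poorly satisfied", 40),
        ("Not at all satisfied", 40),
        ("No information given", 115),
        ("Not concerned", 36),
    ),
    "Q8": (("Yes", 120), ("No", 635)),
    "Q9": (("Yes", 453), ("No", 177), ("I don't know", 125)),
    "Q10": (("Yes", 675), ("No", 80)),
    "Q11A": (("Well planned", 642), ("A sense of haste, upheaval", 113)),
    "Q11B": (("Relieved", 651), ("Anxious", 104)),
    "Q11C": (("Reasonable", 676), ("Too long", 61), ("Not concerned", 18)),
    "Q11D": (("Reasonable", 510), ("Too long", 90), ("Not concerned", 155)),
    "Q11E": (("No", 650), ("Yes", 70), ("Not concerned", 35)),
    "Q11F": (("Sufficient", 602), ("Insufficient", 153)),
    "Q11G": (("Sufficient", 683), ("Insufficient", 72)),
}

_FIXTURE_ARMS = (
    # arm, included, responders
    ("internet", 430, 168),
    ("telephone", 437, 381),
    ("noneligible", 274, 206),
)

_FIXTURE_UNITS = ("surgery", "gastroenterology", "hepatology", "internal_medicine", "infectious")


def reference_cohort() -> tuple[list[PatientProfile], list[ResponseRecord]]:
    """Deterministic cohort reproducing the reference marginal counts.

    1141 included patients (430/437/274 per arm, 168/381/206 responders)
    and 755 complete questionnaires whose per-question counts equal the
    published ones (e.g. Q11C Reasonable 676 / Too long 61 / Not concerned
    18).  Distinct from the stochastic simulator: answers are assigned in
    deterministic blocks per question, so joint distributions are
    artificial but every marginal count is exact.
    """
    profiles: list[PatientProfile] = []
    responder_ids: list[str] = []
    pid = 0
    for arm, included, responders in _FIXTURE_ARMS:
        for i in range(included):
            is_resp = i < responders
            patient_id = f"F{pid:06d}"
            pid += 1
            profiles.append(
                PatientProfile(
                    patient_id=patient_id,
                    arm=arm,
                    unit=_FIXTURE_UNITS[i % len(_FIXTURE_UNITS)],
                    age=30.0 + (i % 41),
                    sex="female" if i % 2 else "male",
                    education=1 + (i % 4),
                    length_of_stay=2.0 + (i % 12),
                    responder=is_resp,
                    completion_delay=7.0 if is_resp else None,
                )
            )
            if is_resp:
                responder_ids.append(patient_id)
    n = len(responder_ids)
    answers: list[dict] = [dict() for _ in range(n)]
    for qid, blocks in _FIXTURE_COUNTS.items():
        assert sum(c for _, c in blocks) == n, qid
        pos = 0
        for code, count in blocks:
            for j in range(pos, pos + count):
                answers[j][qid] = code
            pos += count
    # Q6 multiselect: 153 patients leave with a summary and/or PCP letter
    for j in range(n):
        if j < 100:
            answers[j]["Q6"] = frozenset(["Prescription(s)", "Discharge summary"])
        elif j < 153:
            answers[j]["Q6"] = frozenset(["Prescription(s)", "Letter for primary care physician"])
        elif j >= n - 10:
            answers[j]["Q6"] = frozenset(["None"])
        else:
            answers[j]["Q6"] = frozenset(["Prescription(s)"])
    records = [
        ResponseRecord(patient_id=rid, answers=ans)
        for rid, ans in zip(responder_ids, answers)
    ]
    return profiles, records


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------


@dataclass
class PipelineConfig:
    """Configuration of one pipeline run.

    Exactly one of ``input_csv`` (a responses CSV) or ``scenario`` (a
    :class:`SimScenario`, a scenario JSON path, or the strings
    ``"default"`` / ``"reference"``) must be given.
    """

    out_dir: str | Path
    input_csv: str | Path | None = None
    scenario: SimScenario | str | Path | None = None
    seed: int | None = None
    alpha: float = 0.05
    quantile_method: str = "linear"
    comparisons: tuple[tuple[str, str], ...] = (
        ("telephone", "internet"),
        ("telephone", "noneligible"),
    )


def _resolve_inputs(
    config: PipelineConfig, smap: ScoringMap
) -> tuple[list[PatientProfile], list[ResponseRecord], dict]:
    if (config.input_csv is None) == (config.scenario is None):
        raise ValueError("exactly one of input_csv or scenario must be provided")
    meta: dict = {}
    if config.input_csv is not None:
        pairs = dio.read_responses(config.input_csv, smap)
        profiles = [p for p, _ in pairs]
        records = [r for _, r in pairs if r is not None]
        meta["input"] = str(config.input_csv)
        return profiles, records, meta
    scen = config.scenario
    if scen == "reference":
        profiles, records = reference_cohort()
        meta["input"] = "reference_cohort"
        return profiles, records, meta
    if scen == "default":
        scen = default_trial_scenario()
    elif isinstance(scen, (str, Path)):
        scen = SimScenario.from_json(scen)
    if config.seed is not None:
        scen = scen.with_seed(config.seed)
    profiles, records = simulate_cohort(scen, smap)
    meta["input"] = "simulated"
    meta["scenario"] = scen.to_dict()
    return profiles, records, meta


def run_pipeline(config: PipelineConfig) -> dict[str, Path]:
    """simulate/load -> validate -> score -> compare, writing all artifacts.

    Deterministic stages are bit-identical across reruns with the same
    inputs.  Returns a mapping of artifact name to written path.
    """
    smap = build_default_scoring_map()
    profiles, records, meta = _resolve_inputs(config, smap)  # before any output
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    complete, incomplete = completeness_filter(records, smap)
    flow = response_rate_report(profiles, records, smap)
    paths["flow"] = out / "flow.json"
    paths["flow"].write_text(json.dumps(flow.to_dict(), indent=2), encoding="utf-8")

    pairs = [(p, None) for p in profiles if not p.responder]
    rec_by_id = {r.patient_id: r for r in records}
    pairs += [
        (p, rec_by_id[p.patient_id])
        for p in profiles
        if p.responder and p.patient_id in rec_by_id
    ]
    paths["responses"] = out / "responses.csv"
    dio.write_responses(paths["responses"], pairs, smap)

    score_sets = score_cohort(complete, profiles, smap)
    frame = scores_to_frame(score_sets, profiles)
    paths["scores"] = out / "scores.csv"
    frame.to_csv(paths["scores"], index=False)

    props = item_proportions(complete, smap)
    paths["proportions"] = out / "proportions.csv"
    pd.DataFrame([p.to_dict() for p in props]).to_csv(paths["proportions"], index=False)

    comparison = compare_arms(
        frame,
        comparisons=config.comparisons,
        alpha=config.alpha,
        quantile_method=config.quantile_method,
    )
    paths["comparisons"] = out / "comparisons.json"
    paths["comparisons"].write_text(
        json.dumps(comparison.to_dict(), indent=2), encoding="utf-8"
    )
    paths["percentiles"] = out / "percentiles.csv"
    comparison.percentile_frame().to_csv(paths["percentiles"], index=False)

    ordering = compare_items_within(frame)
    paths["item_ordering"] = out / "item_ordering.json"
    paths["item_ordering"].write_text(
        json.dumps(ordering.to_dict(), indent=2), encoding="utf-8"
    )

    chars = characteristics_table(profiles)
    paths["characteristics"] = out / "characteristics.json"
    paths["characteristics"].write_text(json.dumps(chars, indent=2), encoding="utf-8")

    # box-plot data export (quartiles/whiskers per arm), no plotting dependency
    box_rows = []
    for col in ("total", "logistics", "continuity", "impressions"):
        for arm in ["all"] + sorted(set(frame["arm"].dropna())):
            vals = frame[col].dropna() if arm == "all" else frame.loc[frame["arm"] == arm, col].dropna()
            if len(vals) == 0:
                continue
            p2, q1, med, q3, p97 = np.percentile(vals, [2.5, 25, 50, 75, 97.5])
            box_rows.append(
                {"score": col, "group": arm, "n": len(vals), "whisker_low": p2,
                 "q1": q1, "median": med, "q3": q3, "whisker_high": p97}
            )
    paths["boxplot_data"] = out / "boxplot_data.csv"
    pd.DataFrame(box_rows).to_csv(paths["boxplot_data"], index=False)

    config_dict = {
        k: (str(v) if isinstance(v, Path) else v)
        for k, v in dataclasses.asdict(config).items()
    }
    config_json = json.dumps(config_dict, sort_keys=True, default=str)
    run_meta = {
        "seed": config.seed,
        "config": config_dict,
        "config_sha256": hashlib.sha256(config_json.encode()).hexdigest(),
        "versions": {"dischargesat": _version(), "numpy": np.__version__, "pandas": pd.__version__},
        "n_included": len(profiles),
        "n_complete": len(complete),
        "n_incomplete": len(incomplete),
        **meta,
    }
    paths["run_log"] = out / "run.log"
    paths["run_log"].write_text(
        "\n".join(f"{k}: {json.dumps(v, sort_keys=True, default=str)}" for k, v in run_meta.items()) + "\n",
        encoding="utf-8",
    )
    logger.info("pipeline complete: %d artifacts in %s", len(paths), out)
    return paths


def _version() -> str:
    from . import __version__

    return __version__
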