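"""Synthetic trial cohorts.

Generates cohorts with the structure the analysis assumes: eligible
patients (home Internet access) randomized 1:1 to an Internet or telephone
arm stratified by recruiting unit, plus a noneligible arm (no home
Internet) enrolled at 1:4 of the eligible count; arm-specific, optionally
age-dependent response probabilities; per-question categorical response
distributions over the instrument vocabularies (including the
not-applicable codes of Q7/Q9/Q11C/Q11D/Q11E); and per-arm completion
delays.

The packaged default scenario (:func:`default_trial_scenario`) targets the
marginals reported for the reference cohort of 1141 included patients: arm
sizes 430/437/274, response rates 39.1%/87.2%/75.2%, and the published
favorable-response proportions (e.g. 87.9% informed of discharge
modalities, 85.0% judging the discharge well planned, 18/755 not concerned
by the document waiting time).

Questions are sampled independently given the arm; an optional per-patient
latent satisfaction propensity (a shared logit shift of every
favorable-response probability) can induce positive correlation between
questions to probe the robustness of the rank tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit, logit

from .instrument import (
    ARMS,
    EDUCATION_REFUSED,
    PatientProfile,
    Q6_OPTIONS,
    ResponseRecord,
    ScoringMap,
    build_default_scoring_map,
)

__all__ = [
    "SimScenario",
    "default_trial_scenario",
    "two_arm_null_scenario",
    "simulate_cohort",
    "inject_effect",
    "empirical_marginals",
    "FAVORABLE",
]

#: The highest-scoring ("favorable") response of each scored question, the
#: probability mass that effect shifts and the latent propensity act on.
FAVORABLE = {
    "Q2": "Yes",
    "Q3": "Yes",
    "Q4": "Yes",
    "Q5": "Yes",
    "Q7": "Highly satisfied",
    "Q9": "Yes",
    "Q10": "Yes",
    "Q11A": "Well planned",
    "Q11B": "Relieved",
    "Q11C": "Reasonable",
    "Q11D": "Reasonable",
    "Q11E": "No",
    "Q11F": "Sufficient",
    "Q11G": "Sufficient",
}

_NOT_APPLICABLE_CODES = {
    "Q7": "Not concerned",
    "Q9": "I don't have a primary care physician",
    "Q11C": "Not concerned",
    "Q11D": "Not concerned",
    "Q11E": "Not concerned",
}

_Z75 = 0.6744897501960817  # standard normal 75th percentile


@dataclass(frozen=True)
class SimScenario:
    """Full description of one simulation scenario.

    Quantitative models are parameterized by (median, q1, q3) triples and
    realised as log-normal distributions matching the median and
    interquartile range.  ``response_age_slope`` is a logit-scale slope per
    year of age; the per-arm intercept is calibrated on the drawn ages so
    the marginal response rate matches ``response_rate`` exactly in
    expectation.
    """

    arm_sizes: Mapping[str, int]
    unit_weights: Mapping[str, float]
    response_rate: Mapping[str, float]
    response_age_slope: float
    age_model: Mapping[str, tuple[float, float, float]]  # arm -> (median, q1, q3)
    sex_female: Mapping[str, float]
    education_probs: Mapping[str, Mapping[str, float]]  # arm -> level -> prob
    hospitalization_type_probs: Mapping[str, float]
    los_model: Mapping[str, tuple[float, float, float]]  # type -> (median, q1, q3)
    delay_model: Mapping[str, tuple[float, float, float]]  # arm -> (median, q1, q3)
    question_probs: Mapping[str, Mapping[str, float]]  # single-select questions
    q6_none_prob: float
    q6_option_probs: Mapping[str, float]  # given not-"None", independent checks
    effect: Mapping[str, float] = field(default_factory=dict)  # arm -> delta
    latent_sd: float = 0.0
    seed: int = 0

    # -- validation ---------------------------------------------------------
    def validate(self, scoring_map: ScoringMap | None = None) -> None:
        smap = scoring_map or build_default_scoring_map()
        for arm in self.arm_sizes:
            if arm not in ARMS:
                raise ValueError(f"unknown arm {arm!r}")
            if self.arm_sizes[arm] < 0:
                raise ValueError(f"{arm}: negative arm size")
        for arm, p in self.response_rate.items():
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"{arm}: response rate {p} outside [0, 1]")
        for mapping, label in [
            (self.unit_weights, "unit_weights"),
            (self.hospitalization_type_probs, "hospitalization_type_probs"),
        ]:
            if abs(sum(mapping.values()) - 1.0) > 1e-9 or min(mapping.values()) < 0:
                raise ValueError(f"{label} must be a probability vector summing to 1")
        for arm, probs in self.education_probs.items():
            if abs(sum(probs.values()) - 1.0) > 1e-9 or min(probs.values()) < 0:
                raise ValueError(f"{arm}: education probabilities must sum to 1")
        for qid, probs in self.question_probs.items():
            q = smap[qid]
            if q.multiselect:
                raise ValueError(f"{qid}: multiselect handled by q6_* fields")
            unknown = set(probs) - set(q.responses)
            if unknown:
                raise ValueError(f"{qid}: probabilities for unknown responses {sorted(unknown)}")
            if abs(sum(probs.values()) - 1.0) > 1e-9 or min(probs.values()) < -1e-12:
                raise ValueError(f"{qid}: probabilities must be nonnegative and sum to 1")
        for arm, delta in self.effect.items():
            _shifted_probs_all(self, arm, smap)  # raises if invalid
        if not (0.0 <= self.q6_none_prob <= 1.0):
            raise ValueError("q6_none_prob outside [0, 1]")
        for opt, p in self.q6_option_probs.items():
            if opt not in Q6_OPTIONS or opt == "None":
                raise ValueError(f"q6_option_probs: illegal option {opt!r}")
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"q6_option_probs[{opt!r}] outside [0, 1]")
        if self.latent_sd < 0:
            raise ValueError("latent_sd must be >= 0")

    # -- serialisation ------------------------------------------------------
    def to_dict(self) -> dict:
        def plain(m):
            return {k: (list(v) if isinstance(v, tuple) else v) for k, v in m.items()}

        return {
            "arm_sizes": dict(self.arm_sizes),
            "unit_weights": dict(self.unit_weights),
            "response_rate": dict(self.response_rate),
            "response_age_slope": self.response_age_slope,
            "age_model": plain(self.age_model),
            "sex_female": dict(self.sex_female),
            "education_probs": {a: dict(p) for a, p in self.education_probs.items()},
            "hospitalization_type_probs": dict(self.hospitalization_type_probs),
            "los_model": plain(self.los_model),
            "delay_model": plain(self.delay_model),
            "question_probs": {q: dict(p) for q, p in self.question_probs.items()},
            "q6_none_prob": self.q6_none_prob,
            "q6_option_probs": dict(self.q6_option_probs),
            "effect": dict(self.effect),
            "latent_sd": self.latent_sd,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimScenario":
        def triples(m):
            return {k: tuple(v) for k, v in m.items()}

        return cls(
            arm_sizes=dict(d["arm_sizes"]),
            unit_weights=dict(d["unit_weights"]),
            response_rate=dict(d["response_rate"]),
            response_age_slope=float(d["response_age_slope"]),
            age_model=triples(d["age_model"]),
            sex_female=dict(d["sex_female"]),
            education_probs={a: dict(p) for a, p in d["education_probs"].items()},
            hospitalization_type_probs=dict(d["hospitalization_type_probs"]),
            los_model=triples(d["los_model"]),
            delay_model=triples(d["delay_model"]),
            question_probs={q: dict(p) for q, p in d["question_probs"].items()},
            q6_none_prob=float(d["q6_none_prob"]),
            q6_option_probs=dict(d["q6_option_probs"]),
            effect=dict(d.get("effect", {})),
            latent_sd=float(d.get("latent_sd", 0.0)),
            seed=int(d.get("seed", 0)),
        )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2), encoding="utf-8")

    @classmethod
    def from_json(cls, path: str | Path) -> "SimScenario":
        return cls.from_dict(json.loads(Path(path).read_text(encoding="utf-8")))

    # -- derived scenarios ---------------------------------------------------
    def with_sizes(
        self, n_eligible: int, noneligible_ratio: float = 0.25
    ) -> "SimScenario":
        """Same distributions at different size: eligible split ~1:1, plus
        the noneligible arm at the given ratio of the eligible count."""
        n_int = n_eligible // 2
        sizes = {
            "internet": n_int,
            "telephone": n_eligible - n_int,
            "noneligible": int(round(noneligible_ratio * n_eligible)),
        }
        return replace(self, arm_sizes=sizes)

    def with_seed(self, seed: int) -> "SimScenario":
        return replace(self, seed=int(seed))


# ---------------------------------------------------------------------------
# Packaged scenarios
# ---------------------------------------------------------------------------


def default_trial_scenario(seed: int = 0) -> SimScenario:
    """Scenario whose marginal targets are the reference cohort's printed
    values (arm sizes, response rates, favorable-response proportions,
    not-applicable rates).  Quantities never reported (the Q11D response
    split, the no-primary-care-physician rate, the Q7 Highly/Satisfied
    split, documentation-question distributions, per-unit weights) are
    fixed once at plausible values and documented in the methods note.
    """
    n = 755.0  # responders the published proportions are expressed over

    def q(counts: Mapping[str, float]) -> dict[str, float]:
        total = sum(counts.values())
        probs = {k: v / n for k, v in counts.items()}
        if abs(total - n) > 1e-9:
            raise ValueError("question counts must sum to 755")
        return probs

    question_probs = {
        "Q1": {
            "Staff physician": 0.78,
            "Yourself": 0.06,
            "Your entourage": 0.02,
            "Your primary care physician": 0.06,
            "Other": 0.08,
        },
        "Q2": q({"Yes": 664, "No": 91}),
        "Q3": q({"Yes": 354, "No": 401}),
        "Q4": q({"Yes": 699, "No": 56}),
        "Q5": q({"Yes": 685, "No": 70}),
        "Q7": q(
            {
                "Highly satisfied": 262,
                "Satisfied": 262,
                "Poorly satisfied": 40,
                "Not at all satisfied": 40,
                "No information given": 115,
                "Not concerned": 36,
            }
        ),
        "Q8": {"Yes": 0.15, "No": 0.85},
        "Q9": q(
            {
                "Yes": 443,
                "No": 177,
                "I don't know": 125,
                "I don't have a primary care physician": 10,
            }
        ),
        "Q10": q({"Yes": 675, "No": 80}),
        "Q11A": q({"Well planned": 642, "A sense of haste, upheaval": 113}),
        "Q11B": q({"Relieved": 651, "Anxious": 104}),
        "Q11C": q({"Reasonable": 676, "Too long": 61, "Not concerned": 18}),
        "Q11D": q({"Reasonable": 510, "Too long": 90, "Not concerned": 155}),
        "Q11E": q({"Yes": 70, "No": 650, "Not concerned": 35}),
        "Q11F": q({"Sufficient": 602, "Insufficient": 153}),
        "Q11G": q({"Sufficient": 683, "Insufficient": 72}),
    }
    return SimScenario(
        arm_sizes={"internet": 430, "telephone": 437, "noneligible": 274},
        unit_weights={
            "surgery": 0.3558,
            "gastroenterology": 0.20,
            "hepatology": 0.17,
            "internal_medicine": 0.1401,
            "infectious": 0.1341,
        },
        response_rate={"internet": 0.391, "telephone": 0.872, "noneligible": 0.752},
        response_age_slope=0.02,  # responders skew older
        age_model={
            "internet": (51, 36, 63),
            "telephone": (52, 34, 64),
            "noneligible": (65, 52, 74),
        },
        sex_female={
            "internet": 226 / 430,
            "telephone": 209 / 437,
            "noneligible": 156 / 274,
        },
        education_probs={
            "internet": {"1": 48 / 430, "2": 138 / 430, "3": 61 / 430, "4": 182 / 430, EDUCATION_REFUSED: 1 / 430},
            "telephone": {"1": 47 / 437, "2": 139 / 437, "3": 68 / 437, "4": 182 / 437, EDUCATION_REFUSED: 1 / 437},
            "noneligible": {"1": 128 / 274, "2": 88 / 274, "3": 21 / 274, "4": 37 / 274, EDUCATION_REFUSED: 0.0},
        },
        hospitalization_type_probs={"standard": 0.8, "weekday": 0.2},
        los_model={"standard": (7, 4, 11), "weekday": (3, 2, 3)},
        delay_model={
            "internet": (6, 3, 16),
            "telephone": (7, 7, 9),
            "noneligible": (7, 7, 8),
        },
        question_probs=question_probs,
        q6_none_prob=0.05,
        q6_option_probs={
            "Prescription(s)": 0.92,
            "Discharge summary": 0.12,
            "Letter for primary care physician": 0.10,
            "Nursing discharge notes": 0.08,
            "Information booklet(s)": 0.10,
            "Appointment for a next hospitalization": 0.10,
            "Appointment for your next consultation": 0.45,
            "Appointment for your complementary test(s)": 0.15,
            "Other, specify": 0.05,
        },
        seed=seed,
    )


def two_arm_null_scenario(n_per_arm: int, seed: int = 0) -> SimScenario:
    """No-effect scenario: internet and telephone arms of equal size drawn
    from identical response distributions, everyone responding.  Used for
    type-I-error calibration of the downstream rank tests."""
    base = default_trial_scenario(seed)
    return replace(
        base,
        arm_sizes={"internet": n_per_arm, "telephone": n_per_arm, "noneligible": 0},
        response_rate={"internet": 1.0, "telephone": 1.0, "noneligible": 1.0},
        response_age_slope=0.0,
        effect={},
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Effect injection
# ---------------------------------------------------------------------------


def _shifted_probs(
    probs: Mapping[str, float], qid: str, delta: float
) -> dict[str, float]:
    """Shift the favorable-response probability by delta, renormalizing the
    other applicable responses; the not-applicable mass is left untouched."""
    fav = FAVORABLE[qid]
    na_code = _NOT_APPLICABLE_CODES.get(qid)
    p_fav = probs.get(fav, 0.0)
    p_na = probs.get(na_code, 0.0) if na_code else 0.0
    new_fav = p_fav + delta
    rest = 1.0 - p_fav - p_na
    new_rest = 1.0 - new_fav - p_na
    if not (-1e-12 <= new_fav <= 1.0 + 1e-12) or new_rest < -1e-12:
        raise ValueError(
            f"{qid}: shifting favorable probability {p_fav:.4f} by {delta:+.4f} "
            "leaves no valid distribution"
        )
    scale = 0.0 if rest <= 0 else new_rest / rest
    out = {}
    for resp, p in probs.items():
        if resp == fav:
            out[resp] = min(max(new_fav, 0.0), 1.0)
        elif na_code and resp == na_code:
            out[resp] = p
        else:
            out[resp] = p * scale
    return out


def _shifted_probs_all(
    scenario: SimScenario, arm: str, smap: ScoringMap
) -> dict[str, dict[str, float]]:
    delta = scenario.effect.get(arm, 0.0)
    out = {}
    for qid, probs in scenario.question_probs.items():
        if qid in FAVORABLE and delta != 0.0:
            out[qid] = _shifted_probs(probs, qid, delta)
        else:
            out[qid] = dict(probs)
    return out


def inject_effect(scenario: SimScenario, arm: str, delta: float) -> SimScenario:
    """Scenario with the named arm's favorable-response probabilities
    shifted by ``delta`` on the probability scale (validated up front)."""
    if arm not in ARMS:
        raise ValueError(f"unknown arm {arm!r}")
    new_delta = scenario.effect.get(arm, 0.0) + delta
    for qid in FAVORABLE:
        _shifted_probs(scenario.question_probs[qid], qid, new_delta)  # raises
    effects = {**scenario.effect, arm: new_delta}
    if new_delta == 0.0:
        effects.pop(arm)
    return replace(scenario, effect=effects)


# ---------------------------------------------------------------------------
# Sampling
# ---------------------------------------------------------------------------


def _lognormal_from_quartiles(
    rng: np.random.Generator,
    size: int,
    median: float,
    q1: float,
    q3: float,
    low: float | None = None,
    high: float | None = None,
) -> np.ndarray:
    """Log-normal draws matching a (median, q1, q3) target, optionally
    truncated to [low, high] by resampling."""
    mu = np.log(median)
    sigma = np.log(q3 / q1) / (2 * _Z75) if q3 > q1 else 0.0
    draws = np.exp(rng.normal(mu, sigma, size))
    if low is not None or high is not None:
        lo = low if low is not None else -np.inf
        hi = high if high is not None else np.inf
        bad = (draws < lo) | (draws > hi)
        while bad.any():
            draws[bad] = np.exp(rng.normal(mu, sigma, int(bad.sum())))
            bad = (draws < lo) | (draws > hi)
    return draws


def _calibrated_response_prob(
    ages: np.ndarray, target: float, slope: float
) -> np.ndarray:
    """Per-patient response probabilities sigmoid(b + slope*age) with the
    intercept b solved so the mean probability equals ``target``."""
    if target <= 0.0:
        return np.zeros_like(ages)
    if target >= 1.0:
        return np.ones_like(ages)
    if slope == 0.0:
        return np.full_like(ages, target)

    def gap(b: float) -> float:
        return float(expit(b + slope * ages).mean() - target)

    lo = logit(target) - abs(slope) * float(np.max(np.abs(ages))) - 1.0
    hi = logit(target) + abs(slope) * float(np.max(np.abs(ages))) + 1.0
    b = brentq(gap, lo, hi, xtol=1e-10)
    return expit(b + slope * ages)


def _sample_categorical(
    rng: np.random.Generator, responses: list[str], probs: np.ndarray
) -> list[str]:
    """Vectorized categorical sampling; ``probs`` is (n, k) or (k,)."""
    if probs.ndim == 1:
        idx = rng.choice(len(responses), size=None, p=probs)
        return [responses[idx]]
    cum = np.cumsum(probs, axis=1)
    cum[:, -1] = 1.0
    u = rng.random((probs.shape[0], 1))
    idx = (u > cum).sum(axis=1)
    return [responses[i] for i in idx]


def simulate_cohort(
    scenario: SimScenario, scoring_map: ScoringMap | None = None
) -> tuple[list[PatientProfile], list[ResponseRecord]]:
    """Draw one cohort; the scenario seed fully determines the output.

    Returns the profiles of every included patient and one complete
    :class:`ResponseRecord` per responder.
    """
    smap = scoring_map or build_default_scoring_map()
    scenario.validate(smap)
    rng = np.random.default_rng(scenario.seed)
    profiles: list[PatientProfile] = []
    responses: list[ResponseRecord] = []
    units = list(scenario.unit_weights)
    unit_p = np.asarray([scenario.unit_weights[u] for u in units], dtype=float)
    hosp_types = list(scenario.hospitalization_type_probs)
    hosp_p = np.asarray(
        [scenario.hospitalization_type_probs[t] for t in hosp_types], dtype=float
    )
    pid = 0
    for arm in ARMS:
        n_arm = int(scenario.arm_sizes.get(arm, 0))
        if n_arm == 0:
            continue
        unit_idx = rng.choice(len(units), size=n_arm, p=unit_p / unit_p.sum())
        med, q1, q3 = scenario.age_model[arm]
        ages = np.round(_lognormal_from_quartiles(rng, n_arm, med, q1, q3, 18, 100))
        sexes = np.where(rng.random(n_arm) < scenario.sex_female[arm], "female", "male")
        edu_levels = list(scenario.education_probs[arm])
        edu_p = np.asarray([scenario.education_probs[arm][k] for k in edu_levels])
        edu_idx = rng.choice(len(edu_levels), size=n_arm, p=edu_p / edu_p.sum())
        type_idx = rng.choice(len(hosp_types), size=n_arm, p=hosp_p)
        los = np.empty(n_arm)
        for t, tname in enumerate(hosp_types):
            mask = type_idx == t
            if mask.any():
                tm, tq1, tq3 = scenario.los_model[tname]
                los[mask] = np.round(
                    _lognormal_from_quartiles(rng, int(mask.sum()), tm, tq1, tq3, 2, 120)
                )
        p_resp = _calibrated_response_prob(
            ages, scenario.response_rate.get(arm, 1.0), scenario.response_age_slope
        )
        responders = rng.random(n_arm) < p_resp
        dm, dq1, dq3 = scenario.delay_model[arm]
        delays = np.round(_lognormal_from_quartiles(rng, n_arm, dm, dq1, dq3, 0.5, 60))
        arm_ids = [f"P{pid + i:06d}" for i in range(n_arm)]
        pid += n_arm
        for i in range(n_arm):
            profiles.append(
                PatientProfile(
                    patient_id=arm_ids[i],
                    arm=arm,
                    unit=units[unit_idx[i]],
                    age=float(ages[i]),
                    sex=str(sexes[i]),
                    education=(
                        EDUCATION_REFUSED
                        if edu_levels[edu_idx[i]] == EDUCATION_REFUSED
                        else int(edu_levels[edu_idx[i]])
                    ),
                    length_of_stay=float(los[i]),
                    hospitalization_type=hosp_types[type_idx[i]],
                    responder=bool(responders[i]),
                    completion_delay=float(delays[i]) if responders[i] else None,
                )
            )
        # -- answers for this arm's responders ------------------------------
        r_idx = np.flatnonzero(responders)
        n_resp = len(r_idx)
        if n_resp == 0:
            continue
        answers: list[dict] = [dict() for _ in range(n_resp)]
        probs_by_q = _shifted_probs_all(scenario, arm, smap)
        u_latent = (
            rng.normal(0.0, scenario.latent_sd, n_resp)
            if scenario.latent_sd > 0
            else None
        )
        for qid, probs in probs_by_q.items():
            vocab = [r for r in smap[qid].responses if probs.get(r, 0.0) > 0.0 or r in probs]
            base = np.asarray([probs.get(r, 0.0) for r in vocab], dtype=float)
            base = base / base.sum()
            if u_latent is not None and qid in FAVORABLE:
                mat = _latent_prob_matrix(vocab, base, qid, u_latent)
                drawn = _sample_categorical(rng, vocab, mat)
            else:
                cum = np.cumsum(base)
                cum[-1] = 1.0
                u = rng.random(n_resp)
                drawn = [vocab[i] for i in np.searchsorted(cum, u, side="right")]
            for j, resp in enumerate(drawn):
                answers[j][qid] = resp
        _sample_q6(rng, scenario, answers)
        for j, i in enumerate(r_idx):
            responses.append(ResponseRecord(patient_id=arm_ids[i], answers=answers[j]))
    return profiles, responses


def _latent_prob_matrix(
    vocab: list[str], base: np.ndarray, qid: str, u_latent: np.ndarray
) -> np.ndarray:
    """Per-patient probability rows with the favorable mass shifted on the
    logit scale by the latent propensity; NA mass held fixed."""
    fav_i = vocab.index(FAVORABLE[qid])
    na_code = _NOT_APPLICABLE_CODES.get(qid)
    na_i = vocab.index(na_code) if na_code in vocab else None
    p_fav = base[fav_i]
    p_na = base[na_i] if na_i is not None else 0.0
    applicable = 1.0 - p_na
    if p_fav <= 0 or p_fav >= applicable or applicable <= 0:
        return np.tile(base, (len(u_latent), 1))
    # shift the favorable share of the applicable mass on the logit scale;
    # the intercept is solved so the mean share stays at the target, which
    # keeps the marginal response frequencies unbiased by the latent mixing
    share = p_fav / applicable

    def gap(b: float) -> float:
        return float(expit(b + u_latent).mean() - share)

    span = float(np.max(np.abs(u_latent))) + 1.0
    b0 = brentq(gap, logit(share) - span, logit(share) + span, xtol=1e-10)
    new_share = expit(b0 + u_latent)
    mat = np.tile(base, (len(u_latent), 1))
    mat[:, fav_i] = new_share * applicable
    rest = applicable - p_fav
    scale = (applicable - mat[:, fav_i]) / rest
    for k in range(len(vocab)):
        if k != fav_i and k != na_i:
            mat[:, k] = base[k] * scale
    return mat


def _sample_q6(
    rng: np.random.Generator, scenario: SimScenario, answers: list[dict]
) -> None:
    n = len(answers)
    options = [o for o in Q6_OPTIONS if o != "None"]
    p = np.asarray([scenario.q6_option_probs.get(o, 0.0) for o in options])
    none_mask = rng.random(n) < scenario.q6_none_prob
    checks = rng.random((n, len(options))) < p
    empty = ~none_mask & ~checks.any(axis=1)
    while empty.any():  # "None" is exclusive; empty selections are redrawn
        checks[empty] = rng.random((int(empty.sum()), len(options))) < p
        empty = ~none_mask & ~checks.any(axis=1)
    for j in range(n):
        if none_mask[j]:
            answers[j]["Q6"] = frozenset(["None"])
        else:
            answers[j]["Q6"] = frozenset(
                opt for k, opt in enumerate(options) if checks[j, k]
            )


# ---------------------------------------------------------------------------
# Empirical summaries (parameter recovery)
# ---------------------------------------------------------------------------


def empirical_marginals(
    profiles: Iterable[PatientProfile],
    responses: Iterable[ResponseRecord],
) -> dict:
    """Observed per-arm response rates and per-question response
    frequencies over responders -- for checking parameter recovery."""
    profiles = list(profiles)
    responses = list(responses)
    rates = {}
    for arm in ARMS:
        arm_profiles = [p for p in profiles if p.arm == arm]
        if arm_profiles:
            rates[arm] = {
                "n": len(arm_profiles),
                "responders": sum(p.responder for p in arm_profiles),
            }
    freqs: dict[str, dict[str, int]] = {}
    n_resp = len(responses)
    for rec in responses:
        for qid, ans in rec.answers.items():
            if isinstance(ans, (set, frozenset)):
                continue
            freqs.setdefault(qid, {}).setdefault(str(ans), 0)
            freqs[qid][str(ans)] += 1
    return {
        "arm_rates": {
            arm: d["responders"] / d["n"] for arm, d in rates.items() if d["n"]
        },
        "arm_counts": rates,
        "question_freqs": {
            qid: {r: c / n_resp for r, c in counts.items()}
            for qid, counts in freqs.items()
        },
        "n_responders": n_resp,
    }
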