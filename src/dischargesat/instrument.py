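"""The hospital-discharge satisfaction instrument.

A 17-question questionnaire administered shortly after discharge from an
acute-care hospital stay of two or more days.  The questions are grouped in
three dimensions ("items"):

* **discharge logistics organization** -- how the practical side of leaving
  the hospital was handled (information, scheduling, waiting times,
  administrative formalities);
* **preplanned posthospital continuity-of-care organization** -- documents
  and information handed over for the follow-up of care at home;
* **patient's impressions** at the time of discharge.

Each scored question maps its coded responses to values in ``[0, 1]``.  Some
responses (e.g. ``"Not concerned"``) mark the question as not applicable to
that patient and remove it from both the numerator and the denominator of
its item subscore.  Three questions (Q1, Q6, Q8) only document the situation
and feed no score.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Union

__all__ = [
    "MISSING",
    "NOT_APPLICABLE",
    "ARMS",
    "EDUCATION_REFUSED",
    "ITEMS",
    "ITEM_SIZES",
    "QuestionDef",
    "ScoringMap",
    "ResponseRecord",
    "PatientProfile",
    "build_default_scoring_map",
    "validate_record",
    "completeness_filter",
    "tabulate_documentation",
]


class _Sentinel:
    """Named singleton used for MISSING / NOT_APPLICABLE markers."""

    __slots__ = ("_name",)

    def __init__(self, name: str) -> None:
        self._name = name

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return self._name

    def __deepcopy__(self, memo):
        return self

    def __copy__(self):
        return self


#: An answer that was not given (blank cell).  A scored question left
#: MISSING makes the whole record incomplete.
MISSING = _Sentinel("MISSING")

#: A legal answer meaning the question does not apply to this patient
#: ("Not concerned", "I don't have a primary care physician", ...).  The
#: question is dropped from its subscore's numerator and denominator.
NOT_APPLICABLE = _Sentinel("NOT_APPLICABLE")

Score = Union[float, _Sentinel]
Answer = Union[str, frozenset, _Sentinel]

ARMS = ("internet", "telephone", "noneligible")
EDUCATION_REFUSED = "REFUSED"
EDUCATION_LEVELS = (1, 2, 3, 4)

ITEMS = ("logistics", "continuity", "impressions")
ITEM_SIZES = {"logistics": 7, "continuity": 3, "impressions": 4}


@dataclass(frozen=True)
class QuestionDef:
    """Definition of a single question: vocabulary, item membership, scores.

    Parameters
    ----------
    id : str
        Question identifier (``"Q1"`` ... ``"Q11G"``).
    text : str
        Human-readable wording (abridged).
    item : str or None
        One of :data:`ITEMS` for scored questions, ``None`` for
        documentation-only questions.
    responses : tuple of str
        Ordered legal coded responses.
    score_map : mapping
        Partial mapping response -> score in ``[0, 1]`` or
        :data:`NOT_APPLICABLE`.  Empty for documentation-only questions.
    multiselect : bool
        ``True`` only for Q6 ("check all that apply").
    documentation_only : bool
        ``True`` for Q1, Q6, Q8.
    exclusive_responses : tuple of str
        Multiselect options that cannot be combined with any other option
        (Q6 ``"None"``).
    """

    id: str
    text: str
    item: str | None
    responses: tuple[str, ...]
    score_map: Mapping[str, Score] = field(default_factory=dict)
    multiselect: bool = False
    documentation_only: bool = False
    exclusive_responses: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.documentation_only:
            if self.item is not None:
                raise ValueError(
                    f"{self.id}: documentation-only questions carry no item"
                )
            if self.score_map:
                raise ValueError(f"{self.id}: documentation-only questions have no scores")
        else:
            if self.item not in ITEMS:
                raise ValueError(f"{self.id}: unknown item {self.item!r}")
            for resp in self.responses:
                score = self.score_map.get(resp)
                if score is NOT_APPLICABLE:
                    continue
                if score is None or not (0.0 <= float(score) <= 1.0):
                    raise ValueError(
                        f"{self.id}: response {resp!r} must map to [0,1] or NOT_APPLICABLE"
                    )

    def score_for(self, response: str) -> Score:
        """Score of a coded response (NOT_APPLICABLE for NA-type answers)."""
        if response not in self.responses:
            raise KeyError(f"{self.id}: {response!r} not in vocabulary")
        return self.score_map[response]


class ScoringMap:
    """The full instrument: an ordered collection of :class:`QuestionDef`.

    Provides item membership lookups and validates the structural
    invariants of the instrument (documentation questions score nothing,
    item sizes 7/3/4, vocabulary-closed score maps).
    """

    def __init__(self, questions: Iterable[QuestionDef]) -> None:
        self._questions: dict[str, QuestionDef] = {}
        for q in questions:
            if q.id in self._questions:
                raise ValueError(f"duplicate question id {q.id}")
            self._questions[q.id] = q
        self._items: dict[str, tuple[str, ...]] = {
            item: tuple(q.id for q in self._questions.values() if q.item == item)
            for item in ITEMS
        }

    # -- container protocol -------------------------------------------------
    def __getitem__(self, qid: str) -> QuestionDef:
        try:
            return self._questions[qid]
        except KeyError:
            raise KeyError(f"unknown question id {qid!r}") from None

    def __iter__(self) -> Iterator[QuestionDef]:
        return iter(self._questions.values())

    def __len__(self) -> int:
        return len(self._questions)

    def __contains__(self, qid: str) -> bool:
        return qid in self._questions

    # -- views ---------------------------------------------------------------
    @property
    def question_ids(self) -> tuple[str, ...]:
        return tuple(self._questions)

    @property
    def scored_ids(self) -> tuple[str, ...]:
        return tuple(q.id for q in self if not q.documentation_only)

    @property
    def documentation_ids(self) -> tuple[str, ...]:
        return tuple(q.id for q in self if q.documentation_only)

    def item_members(self, item: str) -> tuple[str, ...]:
        if item not in ITEMS:
            raise KeyError(f"unknown item {item!r}; expected one of {ITEMS}")
        return self._items[item]

    # -- audit export --------------------------------------------------------
    def to_dict(self) -> dict:
        """JSON-serialisable description of the instrument."""

        def enc(score: Score):
            return "NA" if score is NOT_APPLICABLE else score

        return {
            "questions": [
                {
                    "id": q.id,
                    "text": q.text,
                    "item": q.item,
                    "responses": list(q.responses),
                    "score_map": {r: enc(s) for r, s in q.score_map.items()},
                    "multiselect": q.multiselect,
                    "documentation_only": q.documentation_only,
                }
                for q in self
            ]
        }


# ---------------------------------------------------------------------------
# Default instrument
# ---------------------------------------------------------------------------

Q6_OPTIONS = (
    "Prescription(s)",
    "Discharge summary",
    "Letter for primary care physician",
    "Nursing discharge notes",
    "Information booklet(s)",
    "Appointment for a next hospitalization",
    "Appointment for your next consultation",
    "Appointment for your complementary test(s)",
    "Other, specify",
    "None",
)


def build_default_scoring_map() -> ScoringMap:
    """The 17-question instrument with its published score map.

    Binary yes/no questions score 1/0 with the printed polarity (Q11E asks
    about *difficulties*, so "Yes" scores 0); "Reasonable"/"Too long"
    questions score 1/0; "Not concerned" and "I don't have a primary care
    physician" are not-applicable; Q7 uses the graded map
    1 / 0.75 / 0.25 / 0 / 0.  Q1, Q6 and Q8 document the situation and are
    never scored.
    """
    NA = NOT_APPLICABLE
    yes_no = ("Yes", "No")
    questions = [
        QuestionDef(
            "Q1",
            "Who decided when you would be discharged?",
            None,
            (
                "Staff physician",
                "Yourself",
                "Your entourage",
                "Your primary care physician",
                "Other",
            ),
            documentation_only=True,
        ),
        QuestionDef(
            "Q2",
            "Were you informed of the modalities of your discharge?",
            "logistics",
            yes_no,
            {"Yes": 1.0, "No": 0.0},
        ),
        QuestionDef(
            "Q3",
            "Were you consulted for the choice of discharge date and time?",
            "logistics",
            yes_no,
            {"Yes": 1.0, "No": 0.0},
        ),
        QuestionDef(
            "Q4",
            "Were the discharge date and time compatible with your return home?",
            "logistics",
            yes_no,
            {"Yes": 1.0, "No": 0.0},
        ),
        QuestionDef(
            "Q5",
            "Was the scheduled discharge time respected?",
            "logistics",
            yes_no,
            {"Yes": 1.0, "No": 0.0},
        ),
        QuestionDef(
            "Q6",
            "What documents were you given concerning your subsequent care?",
            None,
            Q6_OPTIONS,
            multiselect=True,
            documentation_only=True,
            exclusive_responses=("None",),
        ),
        QuestionDef(
            "Q7",
            "What did you think of the information provided with the discharge documents?",
            "continuity",
            (
                "Highly satisfied",
                "Satisfied",
                "Poorly satisfied",
                "Not at all satisfied",
                "No information given",
                "Not concerned",
            ),
            {
                "Highly satisfied": 1.0,
                "Satisfied": 0.75,
                "Poorly satisfied": 0.25,
                "Not at all satisfied": 0.0,
                "No information given": 0.0,
                "Not concerned": NA,
            },
        ),
        QuestionDef(
            "Q8",
            "Did you meet with a social worker to discuss your return home?",
            None,
            yes_no,
            documentation_only=True,
        ),
        QuestionDef(
            "Q9",
            "Was your primary care physician informed of your hospitalization?",
            "continuity",
            ("Yes", "No", "I don't know", "I don't have a primary care physician"),
            {
                "Yes": 1.0,
                "No": 0.0,
                "I don't know": 0.0,
                "I don't have a primary care physician": NA,
            },
        ),
        QuestionDef(
            "Q10",
            "Did you have the phone number of the unit in which you were hospitalized?",
            "continuity",
            yes_no,
            {"Yes": 1.0, "No": 0.0},
        ),
        QuestionDef(
            "Q11A",
            "At discharge, what did you think about its organization?",
            "impressions",
            ("Well planned", "A sense of haste, upheaval"),
            {"Well planned": 1.0, "A sense of haste, upheaval": 0.0},
        ),
        QuestionDef(
            "Q11B",
            "At discharge, what did you think about returning home?",
            "impressions",
            ("Relieved", "Anxious"),
            {"Relieved": 1.0, "Anxious": 0.0},
        ),
        # Q11C: the reported denominators show a not-concerned fraction for
        # this question as well, so its vocabulary includes it.
        QuestionDef(
            "Q11C",
            "What did you think of the time needed to obtain your documents?",
            "logistics",
            ("Reasonable", "Too long", "Not concerned"),
            {"Reasonable": 1.0, "Too long": 0.0, "Not concerned": NA},
        ),
        QuestionDef(
            "Q11D",
            "What did you think of the time needed for your transportation to arrive?",
            "logistics",
            ("Reasonable", "Too long", "Not concerned"),
            {"Reasonable": 1.0, "Too long": 0.0, "Not concerned": NA},
        ),
        QuestionDef(
            "Q11E",
            "Did you have any difficulties with the administrative discharge formalities?",
            "logistics",
            ("Yes", "No", "Not concerned"),
            {"Yes": 0.0, "No": 1.0, "Not concerned": NA},
        ),
        QuestionDef(
            "Q11F",
            "At discharge, what did you think about the information provided?",
            "impressions",
            ("Sufficient", "Insufficient"),
            {"Sufficient": 1.0, "Insufficient": 0.0},
        ),
        QuestionDef(
            "Q11G",
            "What did you think about the team's availability and listening?",
            "impressions",
            ("Sufficient", "Insufficient"),
            {"Sufficient": 1.0, "Insufficient": 0.0},
        ),
    ]
    smap = ScoringMap(questions)
    for item, size in ITEM_SIZES.items():
        assert len(smap.item_members(item)) == size
    return smap


# ---------------------------------------------------------------------------
# Records
# ---------------------------------------------------------------------------


@dataclass
class ResponseRecord:
    """One responder's coded answers.

    ``answers`` maps question id to a coded response string, a frozenset of
    options (Q6 only), or :data:`MISSING`.  A question id absent from the
    mapping is treated as MISSING.
    """

    patient_id: str
    answers: dict[str, Answer] = field(default_factory=dict)

    def answer(self, qid: str) -> Answer:
        return self.answers.get(qid, MISSING)

    def is_complete(self, scoring_map: ScoringMap) -> bool:
        """Complete iff no *scored* question is missing.

        Not-applicable answers ("Not concerned", ...) count as answered;
        missing documentation-only questions do not make a record
        incomplete because they feed no score.
        """
        return all(self.answer(qid) is not MISSING for qid in scoring_map.scored_ids)


@dataclass
class PatientProfile:
    """Administrative and demographic description of one included patient."""

    patient_id: str
    arm: str
    unit: str
    age: float
    sex: str
    education: int | str
    length_of_stay: float
    responder: bool
    completion_delay: float | None = None
    hospitalization_type: str = "standard"

    def __post_init__(self) -> None:
        if self.arm not in ARMS:
            raise ValueError(f"unknown arm {self.arm!r}; expected one of {ARMS}")
        if self.sex not in ("male", "female"):
            raise ValueError(f"sex must be 'male' or 'female', got {self.sex!r}")
        if not (self.education in EDUCATION_LEVELS or self.education == EDUCATION_REFUSED):
            raise ValueError(f"education must be 1-4 or {EDUCATION_REFUSED!r}")
        if self.length_of_stay < 2:
            raise ValueError("length_of_stay must be >= 2 days (study population)")
        if self.responder and self.completion_delay is None:
            raise ValueError("responders must carry a completion_delay")
        if not self.responder and self.completion_delay is not None:
            raise ValueError("nonresponders cannot carry a completion_delay")


# ---------------------------------------------------------------------------
# Validation and filtering
# ---------------------------------------------------------------------------


def validate_record(record: ResponseRecord, scoring_map: ScoringMap) -> list[str]:
    """Return a list of human-readable vocabulary violations (empty if valid)."""
    problems: list[str] = []
    for qid, answer in record.answers.items():
        if qid not in scoring_map:
            problems.append(f"unknown question id {qid!r}")
            continue
        if answer is MISSING:
            continue
        q = scoring_map[qid]
        if q.multiselect:
            if isinstance(answer, str):
                answer = frozenset([answer])
            if not isinstance(answer, (set, frozenset)):
                problems.append(f"{qid}: multiselect answer must be a set of options")
                continue
            bad = sorted(set(answer) - set(q.responses))
            if bad:
                problems.append(f"{qid}: illegal option(s) {bad}")
            for excl in q.exclusive_responses:
                if excl in answer and len(answer) > 1:
                    problems.append(f"{qid}: {excl!r} is exclusive with other options")
            if len(answer) == 0:
                problems.append(f"{qid}: empty selection (use {q.exclusive_responses or 'an option'})")
        else:
            if not isinstance(answer, str):
                problems.append(f"{qid}: expected a single coded response")
            elif answer not in q.responses:
                problems.append(f"{qid}: illegal response {answer!r}")
    return problems


def completeness_filter(
    records: Iterable[ResponseRecord], scoring_map: ScoringMap
) -> tuple[list[ResponseRecord], list[ResponseRecord]]:
    """Partition records into (complete, excluded).

    Incomplete questionnaires are excluded from all score analyses; the
    excluded list is preserved for flow accounting.
    """
    complete: list[ResponseRecord] = []
    excluded: list[ResponseRecord] = []
    for rec in records:
        (complete if rec.is_complete(scoring_map) else excluded).append(rec)
    return complete, excluded


def tabulate_documentation(
    records: Iterable[ResponseRecord], scoring_map: ScoringMap | None = None
) -> dict[str, dict]:
    """Frequency tables for the documentation-only questions Q1, Q6, Q8.

    Q6 is multiselect: each option is counted over patients, so option
    counts need not sum to the number of respondents.  Returns, per
    question, ``{"n": answered, "counts": {...}, "proportions": {...}}``.
    """
    smap = scoring_map or build_default_scoring_map()
    records = list(records)
    tables: dict[str, dict] = {}
    for qid in smap.documentation_ids:
        q = smap[qid]
        counts = {resp: 0 for resp in q.responses}
        n = 0
        for rec in records:
            ans = rec.answer(qid)
            if ans is MISSING:
                continue
            n += 1
            if q.multiselect:
                for opt in ans if isinstance(ans, (set, frozenset)) else [ans]:
                    counts[opt] += 1
            else:
                counts[ans] += 1
        tables[qid] = {
            "n": n,
            "counts": counts,
            "proportions": {r: (c / n if n else float("nan")) for r, c in counts.items()},
        }
    return tables
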