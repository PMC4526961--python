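"""Reading and writing response tables and derived artifacts.

CSV schema (UTF-8, comma-separated, one row per included patient):

``patient_id, arm, unit, age, sex, education, length_of_stay,
hospitalization_type, responder, completion_delay, Q1, Q2, ..., Q11G``

* ``responder`` is ``1``/``0``; nonresponders leave ``completion_delay``
  and every question cell empty.
* ``education`` is ``1``-``4`` or ``REFUSED``.
* A blank question cell on a responder row means MISSING.
* Q6 (multiselect) joins the checked options with ``|``; ``None`` is
  exclusive.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path
from typing import Iterable, Sequence

from .instrument import (
    MISSING,
    PatientProfile,
    ResponseRecord,
    ScoringMap,
    build_default_scoring_map,
    validate_record,
)

__all__ = [
    "ResponseParseError",
    "ResponseValidationError",
    "read_responses",
    "write_responses",
    "write_instrument_json",
]

MULTISELECT_DELIMITER = "|"

_PROFILE_COLUMNS = [
    "patient_id",
    "arm",
    "unit",
    "age",
    "sex",
    "education",
    "length_of_stay",
    "hospitalization_type",
    "responder",
    "completion_delay",
]


class ResponseParseError(ValueError):
    """A row could not be parsed (malformed field, bad header)."""


class ResponseValidationError(ValueError):
    """Parsed rows contained responses outside the instrument vocabulary.

    ``problems`` is a list of ``(row_number, message)`` pairs; row numbers
    are 1-based file line numbers (header = line 1).
    """

    def __init__(self, problems: Sequence[tuple[int, str]]):
        self.problems = list(problems)
        lines = "; ".join(f"row {r}: {m}" for r, m in self.problems[:20])
        more = "" if len(self.problems) <= 20 else f" (+{len(self.problems) - 20} more)"
        super().__init__(f"invalid responses: {lines}{more}")


def _parse_profile(row: dict, rownum: int) -> PatientProfile:
    try:
        education: int | str = row["education"]
        if education != "REFUSED":
            education = int(education)
        delay = row["completion_delay"]
        return PatientProfile(
            patient_id=row["patient_id"],
            arm=row["arm"],
            unit=row["unit"],
            age=float(row["age"]),
            sex=row["sex"],
            education=education,
            length_of_stay=float(row["length_of_stay"]),
            hospitalization_type=row.get("hospitalization_type") or "standard",
            responder=row["responder"] == "1",
            completion_delay=float(delay) if delay not in ("", None) else None,
        )
    except (KeyError, ValueError) as exc:
        raise ResponseParseError(f"row {rownum}: cannot parse patient profile ({exc})") from exc


def read_responses(
    path: str | Path, scoring_map: ScoringMap | None = None
) -> list[tuple[PatientProfile, ResponseRecord | None]]:
    """Read a responses CSV.

    Returns one ``(profile, record)`` pair per row; ``record`` is ``None``
    for nonresponders.  All vocabulary violations are collected and raised
    together as :class:`ResponseValidationError` naming row and question.
    """
    smap = scoring_map or build_default_scoring_map()
    path = Path(path)
    pairs: list[tuple[PatientProfile, ResponseRecord | None]] = []
    problems: list[tuple[int, str]] = []
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise ResponseParseError(f"{path}: empty file")
        missing_cols = [c for c in _PROFILE_COLUMNS if c not in reader.fieldnames]
        if missing_cols:
            raise ResponseParseError(f"{path}: missing column(s) {missing_cols}")
        question_cols = [c for c in reader.fieldnames if c in smap]
        for rownum, row in enumerate(reader, start=2):
            profile = _parse_profile(row, rownum)
            if not profile.responder:
                pairs.append((profile, None))
                continue
            answers: dict = {}
            for qid in question_cols:
                cell = (row.get(qid) or "").strip()
                if cell == "":
                    answers[qid] = MISSING
                elif smap[qid].multiselect:
                    answers[qid] = frozenset(
                        part.strip() for part in cell.split(MULTISELECT_DELIMITER)
                    )
                else:
                    answers[qid] = cell
            record = ResponseRecord(patient_id=profile.patient_id, answers=answers)
            for msg in validate_record(record, smap):
                problems.append((rownum, msg))
            pairs.append((profile, record))
    if problems:
        raise ResponseValidationError(problems)
    return pairs


def write_responses(
    path: str | Path,
    pairs: Iterable[tuple[PatientProfile, ResponseRecord | None]],
    scoring_map: ScoringMap | None = None,
) -> None:
    """Write pairs to the responses CSV schema (inverse of :func:`read_responses`)."""
    smap = scoring_map or build_default_scoring_map()
    path = Path(path)
    qids = list(smap.question_ids)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(_PROFILE_COLUMNS + qids)
        for profile, record in pairs:
            delay = "" if profile.completion_delay is None else _fmt(profile.completion_delay)
            row = [
                profile.patient_id,
                profile.arm,
                profile.unit,
                _fmt(profile.age),
                profile.sex,
                str(profile.education),
                _fmt(profile.length_of_stay),
                profile.hospitalization_type,
                "1" if profile.responder else "0",
                delay,
            ]
            for qid in qids:
                ans = record.answer(qid) if record is not None else MISSING
                if ans is MISSING:
                    row.append("")
                elif isinstance(ans, (set, frozenset)):
                    # stable option order for round-trips
                    order = {r: i for i, r in enumerate(smap[qid].responses)}
                    row.append(
                        MULTISELECT_DELIMITER.join(sorted(ans, key=order.__getitem__))
                    )
                else:
                    row.append(ans)
            writer.writerow(row)


def _fmt(x: float) -> str:
    return str(int(x)) if float(x).is_integer() else repr(float(x))


def write_instrument_json(path: str | Path, scoring_map: ScoringMap | None = None) -> None:
    """Export the instrument definition as JSON for audit."""
    smap = scoring_map or build_default_scoring_map()
    Path(path).write_text(json.dumps(smap.to_dict(), indent=2), encoding="utf-8")
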