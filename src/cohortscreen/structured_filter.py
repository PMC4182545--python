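"""Stage 1 of the screen: candidate selection from structured data.

An intentionally broad set of ten ICD-9 codes (favouring sensitivity
over specificity) selects an initial cohort from the diagnosis table.
Three further structured criteria apply: a per-code sex restriction
(the adrenogenital-disorders code 255.2 qualifies female patients
only), a birth-date window (the study recruited children born during a
seven-year period), and an age criterion of 0–81 completed months at a
configured reference date.

Code matching is exact string equality on the dotted code by default:
the shipped code set lists ``752`` and several of its subcodes
separately, so each recorded code string is matched as assigned.  A
``code_prefix`` option enables family-prefix semantics for corpora
whose extracts roll subcodes up.
"""

from __future__ import annotations

import datetime
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import yaml

from .corpus import Corpus

#: The shipped initial-cohort code set: congenital anomalies of the
#: genital organs (752 family), adrenogenital disorders (255.2, female
#: patients only), and androgen insensitivity syndrome (259.5).
DSD_ICD9_CODES: tuple[str, ...] = (
    "752",
    "752.4",
    "752.40",
    "752.49",
    "752.61",
    "752.64",
    "752.69",
    "752.7",
    "255.2",
    "259.5",
)

HYPOSPADIAS_CODE = "752.61"

REVIEW_STATES = ("unscreened", "candidate", "initial_pass",
                 "uncertain", "not_eligible", "confirmed")


class ConfigurationError(ValueError):
    """The filter spec is not fully configured for a run."""


class DomainError(ValueError):
    """An argument violates an operation's domain (e.g. reference < birth)."""


@dataclass(frozen=True)
class CodeFilterSpec:
    """Configuration of the structured filter.

    ``birth_window`` and ``age_reference_date`` have no defaults: both
    change cohort membership and must be stated explicitly for a run.
    """

    codes: frozenset[str]
    sex_restricted_codes: Mapping[str, str]
    age_range_months: tuple[int, int]
    birth_window: tuple[datetime.date, datetime.date] | None = None
    age_reference_date: datetime.date | None = None
    code_prefix: bool = False

    def __post_init__(self) -> None:
        lo, hi = self.age_range_months
        if not (0 <= lo <= hi):
            raise ValueError(f"invalid age range {self.age_range_months}")
        for code, sex in self.sex_restricted_codes.items():
            if code not in self.codes:
                raise ValueError(f"sex-restricted code {code!r} not in code set")
            if sex not in ("F", "M"):
                raise ValueError(f"sex restriction must be F or M, got {sex!r}")
        if self.birth_window is not None and self.birth_window[0] > self.birth_window[1]:
            raise ValueError("birth_window start after end")

    @property
    def configured(self) -> bool:
        return self.birth_window is not None and self.age_reference_date is not None

    def configure(self, birth_window: tuple[datetime.date, datetime.date],
                  age_reference_date: datetime.date) -> "CodeFilterSpec":
        return replace(self, birth_window=birth_window,
                       age_reference_date=age_reference_date)

    # -- serialisation ----------------------------------------------------
    def to_dict(self) -> dict:
        d: dict = {
            "codes": sorted(self.codes),
            "sex_restricted": dict(sorted(self.sex_restricted_codes.items())),
            "age_months": {"min": self.age_range_months[0],
                           "max": self.age_range_months[1]},
            "code_prefix": self.code_prefix,
        }
        if self.birth_window is not None:
            d["birth_window"] = {"start": self.birth_window[0].isoformat(),
                                 "end": self.birth_window[1].isoformat()}
        if self.age_reference_date is not None:
            d["age_reference_date"] = self.age_reference_date.isoformat()
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "CodeFilterSpec":
        def _date(v):
            return v if isinstance(v, datetime.date) else datetime.date.fromisoformat(str(v))
        window = None
        if "birth_window" in d and d["birth_window"] is not None:
            window = (_date(d["birth_window"]["start"]), _date(d["birth_window"]["end"]))
        ref = d.get("age_reference_date")
        return cls(
            codes=frozenset(str(c) for c in d["codes"]),
            sex_restricted_codes=dict(d.get("sex_restricted", {})),
            age_range_months=(int(d["age_months"]["min"]), int(d["age_months"]["max"])),
            birth_window=window,
            age_reference_date=_date(ref) if ref is not None else None,
            code_prefix=bool(d.get("code_prefix", False)),
        )

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "CodeFilterSpec":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class CandidateCase:
    """A patient carried through the screen and review funnel."""

    patient_id: str
    qualifying_codes: set[str] = field(default_factory=set)
    keyword_positive: bool = False
    matched_patterns: set[str] = field(default_factory=set)
    review_state: str = "candidate"

    def __post_init__(self) -> None:
        if self.review_state not in REVIEW_STATES:
            raise ValueError(f"unknown review_state {self.review_state!r}")


def default_dsd_spec() -> CodeFilterSpec:
    """The shipped filter spec: ten codes, 255.2 female-only, age 0–81 months.

    ``birth_window`` and ``age_reference_date`` are left unset and must
    be supplied before :func:`filter_by_codes` will run.
    """
    return CodeFilterSpec(
        codes=frozenset(DSD_ICD9_CODES),
        sex_restricted_codes={"255.2": "F"},
        age_range_months=(0, 81),
    )


def age_in_months(birth_date: datetime.date, reference_date: datetime.date) -> int:
    """Whole completed calendar months between two dates.

    A month counts as completed only when the reference day-of-month has
    reached the birth day-of-month; for birth days with no counterpart
    in the reference month (29–31), the month completes on the first of
    the following month.  Hence a child born 2004-02-29 is 11 months old
    on 2005-02-28 and 12 months old on 2005-03-01.
    """
    if reference_date < birth_date:
        raise DomainError(
            f"reference date {reference_date} precedes birth date {birth_date}")
    months = ((reference_date.year - birth_date.year) * 12
              + (reference_date.month - birth_date.month))
    if reference_date.day < birth_date.day:
        months -= 1
    return months


def _code_qualifies(spec_code: str, assigned: set[str], *, prefix: bool) -> bool:
    if spec_code in assigned:
        return True
    if prefix:
        return any(a.startswith(spec_code + ".") for a in assigned)
    return False


def filter_by_codes(corpus: Corpus, spec: CodeFilterSpec) -> list[CandidateCase]:
    """Select the initial candidate cohort.

    A patient becomes a candidate when at least one assigned code is in
    the spec's code set and satisfies every restriction attached to that
    code, the birth date falls within the birth window, and the age at
    the reference date is within the configured range.  A code failing
    its sex restriction does not qualify the patient, but other assigned
    codes still may.  Patients are deduplicated: one candidate per
    patient, listing exactly the codes that qualified, sorted by
    patient_id.
    """
    if not spec.configured:
        raise ConfigurationError(
            "CodeFilterSpec needs birth_window and age_reference_date")
    assert spec.birth_window is not None and spec.age_reference_date is not None
    start, end = spec.birth_window
    lo, hi = spec.age_range_months

    by_patient = corpus.diagnoses_by_patient()
    candidates: list[CandidateCase] = []
    for patient in corpus.patients:
        if not (start <= patient.birth_date <= end):
            continue
        if patient.birth_date > spec.age_reference_date:
            continue
        age = age_in_months(patient.birth_date, spec.age_reference_date)
        if not (lo <= age <= hi):
            continue
        assigned = {d.icd9_code for d in by_patient.get(patient.patient_id, [])}
        if not assigned:
            continue
        qualifying = set()
        for code in spec.codes:
            required_sex = spec.sex_restricted_codes.get(code)
            if required_sex is not None and patient.sex != required_sex:
                continue
            if _code_qualifies(code, assigned, prefix=spec.code_prefix):
                qualifying.add(code)
        if qualifying:
            candidates.append(CandidateCase(
                patient_id=patient.patient_id,
                qualifying_codes=qualifying,
                review_state="candidate",
            ))
    candidates.sort(key=lambda c: c.patient_id)
    return candidates


def candidates_to_rows(candidates: Iterable[CandidateCase]) -> list[dict]:
    """Rows for candidates.csv: codes semicolon-joined and sorted."""
    return [
        {
            "patient_id": c.patient_id,
            "qualifying_codes": ";".join(sorted(c.qualifying_codes)),
            "review_state": c.review_state,
        }
        for c in candidates
    ]
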