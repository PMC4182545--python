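"""Two-stage manual chart review as an auditable state machine.

Eligibility for a rare-disease study cannot be decided by the screen
itself — it depends on details (genital exam descriptions, laboratory
values, co-occurring diagnoses) that only an expert reader can weigh.
The tool therefore never auto-decides; it records human decisions in an
append-only log and advances each candidate's review state.

Stage 1 (*initial*) removes clearly ineligible cases with a coded
reason (developmental delay, isolated distal hypospadias, cloacal
exstrophy, Turner syndrome, Klinefelter syndrome, or other).  Stage 2
(*final*) inspects the remaining pool in detail and classifies each
case as confirmed eligible, not eligible, or of uncertain eligibility.
"Uncertain" is a terminal outcome, not a pending queue.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from .corpus import read_table, write_table
from .structured_filter import CandidateCase

EXCLUSION_REASONS = frozenset({
    "developmental_delay",
    "isolated_distal_hypospadias",
    "cloacal_exstrophy",
    "turner_syndrome",
    "klinefelter_syndrome",
    "other",
})

INITIAL_DECISIONS = ("pass", "exclude")
FINAL_DECISIONS = ("confirmed", "not_eligible", "uncertain")


class SequencingError(ValueError):
    """A final decision was recorded before an initial pass."""


class ConflictError(ValueError):
    """A second decision for the same (patient, stage)."""


class ValidationError(ValueError):
    """A decision violates the decision-record invariants."""


@dataclass(frozen=True)
class ReviewDecision:
    patient_id: str
    stage: str  # "initial" | "final"
    decision: str
    reason: str | None = None
    reviewer: str = ""
    decided_at: str = ""  # ISO timestamp, opaque to the tool

    def __post_init__(self) -> None:
        if self.stage == "initial":
            if self.decision not in INITIAL_DECISIONS:
                raise ValidationError(
                    f"initial-stage decision must be one of {INITIAL_DECISIONS}, "
                    f"got {self.decision!r}")
            if self.decision == "exclude":
                if not self.reason:
                    raise ValidationError(
                        f"initial exclude for {self.patient_id!r} requires a reason")
                if self.reason not in EXCLUSION_REASONS:
                    raise ValidationError(
                        f"unknown exclusion reason {self.reason!r}")
        elif self.stage == "final":
            if self.decision not in FINAL_DECISIONS:
                raise ValidationError(
                    f"final-stage decision must be one of {FINAL_DECISIONS}, "
                    f"got {self.decision!r}")
        else:
            raise ValidationError(f"unknown stage {self.stage!r}")


class DecisionLog:
    """Append-only log of review decisions with sequencing enforcement."""

    def __init__(self, decisions: Iterable[ReviewDecision] = ()) -> None:
        self._entries: list[ReviewDecision] = []
        for d in decisions:
            self.record(d)

    @property
    def entries(self) -> tuple[ReviewDecision, ...]:
        return tuple(self._entries)

    def record(self, decision: ReviewDecision) -> "DecisionLog":
        key_seen = {(d.patient_id, d.stage) for d in self._entries}
        if (decision.patient_id, decision.stage) in key_seen:
            raise ConflictError(
                f"duplicate decision for patient {decision.patient_id!r} "
                f"at stage {decision.stage!r}")
        if decision.stage == "final":
            initial = self._initial_for(decision.patient_id)
            if initial is None:
                raise SequencingError(
                    f"final decision for {decision.patient_id!r} "
                    "without a prior initial decision")
            if initial.decision != "pass":
                raise SequencingError(
                    f"final decision for {decision.patient_id!r} "
                    "but the patient was excluded at initial review")
        self._entries.append(decision)
        return self

    def _initial_for(self, patient_id: str) -> ReviewDecision | None:
        for d in self._entries:
            if d.patient_id == patient_id and d.stage == "initial":
                return d
        return None

    def replay(self) -> "DecisionLog":
        """Rebuild the log entry by entry; tabulation is replay-invariant."""
        return DecisionLog(self._entries)

    # -- persistence ------------------------------------------------------
    def to_csv(self, path: str | Path) -> None:
        write_table(list(self._entries), path, "csv", record_type=ReviewDecision)

    @classmethod
    def from_csv(cls, path: str | Path) -> "DecisionLog":
        return cls(read_table(path, ReviewDecision, "csv"))


def record_decision(log: DecisionLog, decision: ReviewDecision) -> DecisionLog:
    """Append a decision to the log (validating sequencing and conflicts)."""
    return log.record(decision)


def apply_to_candidates(log: DecisionLog,
                        candidates: Sequence[CandidateCase]) -> list[CandidateCase]:
    """Advance candidate review states according to the log.

    Initial pass → ``initial_pass``; final decisions → ``confirmed`` /
    ``not_eligible`` / ``uncertain``.  A candidate excluded at the
    initial stage keeps its pre-review state (the exclusion lives in the
    log), since the terminal outcome states are reserved for the final
    pool.  Patients in the log but not among the candidates raise
    :class:`ValidationError`.
    """
    by_id = {c.patient_id: c for c in candidates}
    unknown = sorted({d.patient_id for d in log.entries} - set(by_id))
    if unknown:
        raise ValidationError(
            "decisions reference unknown patients: " + ", ".join(unknown))
    out = [CandidateCase(
        patient_id=c.patient_id, qualifying_codes=set(c.qualifying_codes),
        keyword_positive=c.keyword_positive,
        matched_patterns=set(c.matched_patterns),
        review_state=c.review_state) for c in candidates]
    by_id = {c.patient_id: c for c in out}
    for d in log.entries:
        cand = by_id[d.patient_id]
        if d.stage == "initial" and d.decision == "pass":
            cand.review_state = "initial_pass"
        elif d.stage == "final":
            cand.review_state = d.decision
    return out


def tabulate_outcomes(log: DecisionLog,
                      screened: Sequence[CandidateCase]) -> dict[str, int]:
    """The review-funnel counts for one corpus.

    Returns ``{icd_cases, keyword_positive, initial_review_pool,
    uncertain, not_eligible, confirmed}``.  ``initial_review_pool`` is
    the number of initial-stage passes; once every final decision is in,
    ``uncertain + not_eligible + confirmed == initial_review_pool``.
    """
    screened_ids = {c.patient_id for c in screened}
    unknown = sorted({d.patient_id for d in log.entries} - screened_ids)
    if unknown:
        raise ValidationError(
            "decision log references patients outside the screened set: "
            + ", ".join(unknown))
    counts = {
        "icd_cases": len(screened),
        "keyword_positive": sum(1 for c in screened if c.keyword_positive),
        "initial_review_pool": 0,
        "uncertain": 0,
        "not_eligible": 0,
        "confirmed": 0,
    }
    for d in log.entries:
        if d.stage == "initial" and d.decision == "pass":
            counts["initial_review_pool"] += 1
        elif d.stage == "final":
            counts[d.decision] += 1
    return counts
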