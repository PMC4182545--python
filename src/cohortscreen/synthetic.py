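"""Seeded synthetic EHR corpus with planted ground truth.

No public corpus exists for this screening problem — the source data
are private hospital records — so every stage of the pipeline is
exercised against generated corpora whose ground truth is known
exactly.  The generator emulates the statistical structure the screen
exploits, not clinical prose style:

* a small fraction of patients are *true cases* whose notes carry
  phenotype sentences built from the screening vocabulary
  ("penoscrotal hypospadias with chordee", "karyotype 46 XY", ...);
* ICD-9 coding is noisy: true cases receive a qualifying code only
  with probability ``coding_sensitivity``, while *non-cases* receive
  one at ``nonspecific_coding_rate`` — this drives the few-percent
  positive predictive value of the structured filter;
* coded non-cases usually carry benign keyword language ("no chordee
  was noted", "labia were normal in appearance"), so the keyword
  screen trims the code cohort only modestly, as a nonspecific
  vocabulary does on real charts;
* notes occasionally contain *trap tokens* — substrings such as the
  "xy" inside "oxygen" or "hydroxylase" that fire short patterns
  spuriously;
* a fraction of true cases are *known to the clinic only*: they carry
  no qualifying code (their records live elsewhere), so no EHR screen
  can find them, while a clinician-nomination arm can.

Each patient is generated from a pseudo-random stream keyed by
``(seed, patient index)``, so corpora are byte-identical under a fixed
seed and config.
"""

from __future__ import annotations

import datetime
import random
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Iterable

import yaml

from .corpus import (ClinicalDocument, Corpus, DiagnosisAssignment,
                     PatientRecord, write_corpus, write_table)
from .keyword_screen import default_dsd_dictionary, run_keyword_screen
from .review_workflow import EXCLUSION_REASONS, DecisionLog, ReviewDecision
from .structured_filter import CodeFilterSpec, default_dsd_spec, filter_by_codes

# Phenotype sentences planted in true cases' notes.  Every sentence
# contains at least one universal-tier keyword, so a planted case is
# detectable whichever pattern tier its qualifying codes select.
PHENOTYPE_SENTENCES: tuple[str, ...] = (
    "Exam notable for penoscrotal hypospadias with chordee present.",
    "Karyotype returned 46 XY with no mosaicism detected.",
    "Bilateral undescended testes palpated in the inguinal canals.",
    "Virilized external genitalia noted; karyotype pending.",
    "A urogenital sinus was noted on exam of the perineal area.",
    "Ambiguous genitalia with a small phallus and perineal opening.",
    "Severe hypospadias with a bifid scrotum noted at birth.",
    "Gonads not palpable; karyotype 46 XX on chromosomal analysis.",
)

# Benign sentences for coded NON-cases that nonetheless contain
# screening keywords — the mechanism that keeps the keyword screen from
# narrowing the code cohort much.
BENIGN_KEYWORD_SENTENCES: tuple[str, ...] = (
    "Circumcision performed; the penile shaft healed well.",
    "No chordee was noted on examination.",
    "Testes descended bilaterally; no undescended testis.",
    "Labia were normal in appearance.",
    "The phallus was of normal size for age.",
    "Normal male genitalia without hypospadias.",
    "Gonads palpable in the scrotum bilaterally.",
    "Perineal hygiene discussed with the family.",
)

# Filler sentences free of every dictionary pattern.
DISTRACTOR_SENTENCES: tuple[str, ...] = (
    "Patient seen in clinic for routine well child visit.",
    "Mild intermittent asthma, continue albuterol as needed.",
    "Immunizations are up to date per the state registry.",
    "Growth parameters tracking along the 50th percentile.",
    "Tympanic membranes clear bilaterally, no effusion.",
    "Appetite and sleep are appropriate for age.",
    "Follow up in twelve months or sooner if concerns arise.",
    "Cardiac exam with regular rate and rhythm, no murmur.",
    "Afebrile with normal vital signs throughout the stay.",
    "Diet advanced and tolerated without emesis.",
)

# Sentences that spuriously fire short patterns ("xy" in oxygen or
# hydroxylase, "xo" in toxoplasmosis, a clinically-negative "labia").
TRAP_SENTENCES: tuple[str, ...] = (
    "Supplemental oxygen was weaned prior to discharge.",
    "The 21-hydroxylase level was within normal limits.",
    "Labia were normal in appearance.",
    "Toxoplasmosis titers were negative.",
)

SECTIONS: tuple[str, ...] = (
    "progress note", "operative note", "consult note",
    "discharge summary", "radiology report",
)

# Sex-plausible qualifying-code pools (255.2 is female-restricted in
# the filter, so it is only ever assigned to female patients here).
MALE_QUALIFYING_CODES = ("752", "752.61", "752.64", "752.69", "752.7", "259.5")
FEMALE_QUALIFYING_CODES = ("752", "752.4", "752.40", "752.49", "752.7",
                           "255.2", "259.5")

NOISE_CODES = ("493.90", "382.9", "079.99", "786.2", "558.9")


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator parameters; defaults target the few-percent-PPV regime."""

    n_patients: int = 2000
    true_case_fraction: float = 0.01
    coding_sensitivity: float = 0.9
    nonspecific_coding_rate: float = 0.17
    keyword_doc_rate: float = 0.95
    trap_rate: float = 0.1
    clinic_only_fraction: float = 0.1
    noncase_keyword_rate: float = 0.85
    noncase_initial_pass_rate: float = 0.1
    notes_per_patient: tuple[int, int] = (1, 5)
    birth_window: tuple[datetime.date, datetime.date] = (
        datetime.date(2005, 4, 1), datetime.date(2011, 12, 31))
    age_reference_date: datetime.date = datetime.date(2011, 12, 31)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        for name in ("true_case_fraction", "coding_sensitivity",
                     "nonspecific_coding_rate", "keyword_doc_rate", "trap_rate",
                     "clinic_only_fraction", "noncase_keyword_rate",
                     "noncase_initial_pass_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be a probability, got {v}")
        lo, hi = self.notes_per_patient
        if not (0 <= lo <= hi):
            raise ValueError("invalid notes_per_patient range")
        if self.birth_window[0] > self.birth_window[1]:
            raise ValueError("birth_window start after end")

    def filter_spec(self) -> CodeFilterSpec:
        return default_dsd_spec().configure(self.birth_window,
                                            self.age_reference_date)

    @classmethod
    def from_yaml(cls, path) -> "SyntheticConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = dict(raw)
        if "notes_per_patient" in kwargs:
            kwargs["notes_per_patient"] = tuple(kwargs["notes_per_patient"])
        for key in ("birth_window",):
            if key in kwargs:
                kwargs[key] = tuple(
                    datetime.date.fromisoformat(str(v)) for v in kwargs[key])
        if "age_reference_date" in kwargs:
            kwargs["age_reference_date"] = datetime.date.fromisoformat(
                str(kwargs["age_reference_date"]))
        known = {f.name for f in fields(cls)}
        unknown = set(kwargs) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**kwargs)


@dataclass(frozen=True)
class GroundTruthRecord:
    patient_id: str
    is_true_case: bool
    has_qualifying_code: bool
    phrase_planted: bool
    known_to_clinic_only: bool


@dataclass
class SyntheticOutput:
    corpus: Corpus
    truth: dict[str, GroundTruthRecord]
    decisions: DecisionLog
    config: SyntheticConfig = field(repr=False, default=None)  # type: ignore[assignment]

    def true_case_ids(self) -> set[str]:
        return {pid for pid, r in self.truth.items() if r.is_true_case}


def _rng_for(seed: int, label: str) -> random.Random:
    # string seeding hashes via SHA-512: stable across runs and platforms
    return random.Random(f"{seed}:{label}")


def _random_date(rng: random.Random, start: datetime.date,
                 end: datetime.date) -> datetime.date:
    span = (end - start).days
    return start + datetime.timedelta(days=rng.randint(0, span))


def _build_note(rng: random.Random, config: SyntheticConfig,
                extra_sentences: list[str]) -> str:
    n_filler = rng.randint(2, 4)
    sentences = [rng.choice(DISTRACTOR_SENTENCES) for _ in range(n_filler)]
    if rng.random() < config.trap_rate:
        sentences.append(rng.choice(TRAP_SENTENCES))
    sentences.extend(extra_sentences)
    rng.shuffle(sentences)
    return " ".join(sentences)


def generate(config: SyntheticConfig) -> SyntheticOutput:
    """Emit a corpus, its ground truth, and a scripted decision log.

    The scripted decisions confirm exactly the planted true cases that
    reach the review pool (keyword-positive candidates), and dispose of
    the remaining pool members with exclusion reasons or final
    not-eligible / uncertain outcomes, mimicking a two-stage expert
    review against the known truth.
    """
    patients: list[PatientRecord] = []
    diagnoses: list[DiagnosisAssignment] = []
    documents: list[ClinicalDocument] = []
    truth: dict[str, GroundTruthRecord] = {}

    start, end = config.birth_window
    for i in range(config.n_patients):
        rng = _rng_for(config.seed, f"patient:{i}")
        pid = f"P{i:05d}"
        sex = "F" if rng.random() < 0.5 else "M"
        birth = _random_date(rng, start, end)
        patients.append(PatientRecord(pid, sex, birth))

        is_true = rng.random() < config.true_case_fraction
        clinic_only = is_true and rng.random() < config.clinic_only_fraction
        if clinic_only:
            has_code = False
        elif is_true:
            has_code = rng.random() < config.coding_sensitivity
        else:
            has_code = rng.random() < config.nonspecific_coding_rate
        phrase = (is_true and not clinic_only
                  and rng.random() < config.keyword_doc_rate)

        pool = FEMALE_QUALIFYING_CODES if sex == "F" else MALE_QUALIFYING_CODES
        if has_code:
            for code in rng.sample(pool, rng.randint(1, 2)):
                diagnoses.append(DiagnosisAssignment(
                    pid, code, _random_date(rng, birth, config.age_reference_date)))
        if rng.random() < 0.5:
            diagnoses.append(DiagnosisAssignment(
                pid, rng.choice(NOISE_CODES),
                _random_date(rng, birth, config.age_reference_date)))

        lo, hi = config.notes_per_patient
        n_notes = rng.randint(lo, hi)
        if phrase:
            n_notes = max(n_notes, 1)
        extra_by_note: dict[int, list[str]] = {}
        if phrase and n_notes:
            target = rng.randrange(n_notes)
            extra_by_note.setdefault(target, []).extend(
                rng.sample(PHENOTYPE_SENTENCES, rng.randint(1, 2)))
        if (not is_true and has_code
                and rng.random() < config.noncase_keyword_rate and n_notes):
            target = rng.randrange(n_notes)
            extra_by_note.setdefault(target, []).extend(
                rng.sample(BENIGN_KEYWORD_SENTENCES, rng.randint(1, 2)))
        for j in range(n_notes):
            documents.append(ClinicalDocument(
                doc_id=f"D{i:05d}-{j}",
                patient_id=pid,
                section=rng.choice(SECTIONS),
                doc_date=_random_date(rng, birth, config.age_reference_date),
                text=_build_note(rng, config, extra_by_note.get(j, [])),
            ))

        truth[pid] = GroundTruthRecord(
            patient_id=pid, is_true_case=is_true, has_qualifying_code=has_code,
            phrase_planted=phrase, known_to_clinic_only=clinic_only)

    corpus = Corpus(patients=patients, diagnoses=diagnoses, documents=documents)
    corpus.validate()
    corpus.sort()

    decisions = script_review_decisions(corpus, truth, config)
    return SyntheticOutput(corpus=corpus, truth=truth, decisions=decisions,
                           config=config)


def script_review_decisions(corpus: Corpus, truth: dict[str, GroundTruthRecord],
                            config: SyntheticConfig) -> DecisionLog:
    """Scripted two-stage review against the planted truth.

    Every keyword-positive candidate receives an initial decision; true
    cases pass and are finally confirmed, non-cases are mostly excluded
    at stage 1 with a coded reason, the rest classified not-eligible or
    uncertain at stage 2.
    """
    candidates = filter_by_codes(corpus, config.filter_spec())
    screened, _ = run_keyword_screen(corpus, candidates,
                                     default_dsd_dictionary())
    reasons = sorted(EXCLUSION_REASONS - {"other"})
    log = DecisionLog()
    finals: list[ReviewDecision] = []
    stamp = config.age_reference_date.isoformat() + "T00:00:00"
    for cand in screened:
        if not cand.keyword_positive:
            continue
        rng = _rng_for(config.seed, f"review:{cand.patient_id}")
        if truth[cand.patient_id].is_true_case:
            log.record(ReviewDecision(cand.patient_id, "initial", "pass",
                                      reviewer="scripted", decided_at=stamp))
            finals.append(ReviewDecision(cand.patient_id, "final", "confirmed",
                                         reviewer="scripted", decided_at=stamp))
        elif rng.random() < config.noncase_initial_pass_rate:
            log.record(ReviewDecision(cand.patient_id, "initial", "pass",
                                      reviewer="scripted", decided_at=stamp))
            outcome = "not_eligible" if rng.random() < 0.75 else "uncertain"
            finals.append(ReviewDecision(cand.patient_id, "final", outcome,
                                         reviewer="scripted", decided_at=stamp))
        else:
            log.record(ReviewDecision(cand.patient_id, "initial", "exclude",
                                      reason=rng.choice(reasons),
                                      reviewer="scripted", decided_at=stamp))
    for d in finals:
        log.record(d)
    return log


def simulate_traditional_arm(truth: dict[str, GroundTruthRecord],
                             recall: float, seed: int) -> set[str]:
    """Clinician-nomination comparator: each true case is independently
    known to the study team with probability ``recall`` — including the
    clinic-only cases the EHR screen cannot reach."""
    if not (0.0 <= recall <= 1.0):
        raise ValueError(f"recall must be a probability, got {recall}")
    rng = random.Random(f"{seed}:traditional")
    found = set()
    for pid in sorted(truth):
        if truth[pid].is_true_case and rng.random() < recall:
            found.add(pid)
    return found


def write_synthetic_outputs(output: SyntheticOutput, out_dir: str | Path,
                            traditional_recall: float = 0.3) -> dict[str, Path]:
    """Emit the corpus files plus ground_truth.csv, decisions.csv, a
    configured filter spec, and a sampled traditional-arm id list."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = write_corpus(output.corpus, out)
    paths["ground_truth"] = out / "ground_truth.csv"
    write_table([output.truth[k] for k in sorted(output.truth)],
                paths["ground_truth"], "csv", record_type=GroundTruthRecord)
    paths["decisions"] = out / "decisions.csv"
    output.decisions.to_csv(paths["decisions"])
    paths["filter_spec"] = out / "filter_spec.yaml"
    output.config.filter_spec().to_yaml(paths["filter_spec"])
    traditional = simulate_traditional_arm(output.truth, traditional_recall,
                                           output.config.seed)
    paths["traditional"] = out / "traditional_ids.txt"
    paths["traditional"].write_text(
        "".join(pid + "\n" for pid in sorted(traditional)), encoding="utf-8")
    return paths
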