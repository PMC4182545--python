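"""Corpus data model and I/O.

The screen consumes a three-table corpus: a patient demographics table
(CSV), a diagnosis-assignment table of ICD-9 codes (CSV), and a clinical
document collection with free narrative text (JSONL, one document per
line).  Note text is stored verbatim — no normalisation happens at load
time, so character offsets produced by the keyword matcher remain valid
against the source text.

All dates are ISO-8601 (``YYYY-MM-DD``).  Loading is canonicalising:
collections are sorted (patients by id, diagnoses by (patient, code,
date), documents by id) so that permuting input rows yields an equal
:class:`Corpus`.
"""

from __future__ import annotations

import csv
import dataclasses
import datetime
import json
import logging
import re
import types
import typing
from dataclasses import dataclass, field
from pathlib import Path

logger = logging.getLogger("cohortscreen")

ICD9_PATTERN = re.compile(r"^\d{3}(\.\d{1,2})?$")

SEX_VALUES = ("F", "M", "U")


class SchemaError(ValueError):
    """An input table is missing a required column."""


class IntegrityError(ValueError):
    """A row references a patient_id or doc_id that does not resolve."""


class ParseError(ValueError):
    """A field value (date, code) could not be parsed; carries row context."""


@dataclass(frozen=True, order=True)
class PatientRecord:
    """One patient: opaque id, administrative sex (F/M/U), birth date."""

    patient_id: str
    sex: str
    birth_date: datetime.date


@dataclass(frozen=True, order=True)
class DiagnosisAssignment:
    """One ICD-9 code assignment to a patient on a date."""

    patient_id: str
    icd9_code: str
    assigned_date: datetime.date


@dataclass(frozen=True, order=True)
class ClinicalDocument:
    """One free-text clinical document.

    ``section`` names the component of the medical record the document
    belongs to (e.g. "progress note", "operative note"); it is an
    uncontrolled free string because section taxonomies differ between
    hospitals.  ``text`` may be empty.
    """

    doc_id: str
    patient_id: str
    section: str
    doc_date: datetime.date
    text: str


@dataclass
class Corpus:
    """The three collections with referential integrity across them."""

    patients: list[PatientRecord] = field(default_factory=list)
    diagnoses: list[DiagnosisAssignment] = field(default_factory=list)
    documents: list[ClinicalDocument] = field(default_factory=list)

    def patient_index(self) -> dict[str, PatientRecord]:
        return {p.patient_id: p for p in self.patients}

    def diagnoses_by_patient(self) -> dict[str, list[DiagnosisAssignment]]:
        out: dict[str, list[DiagnosisAssignment]] = {}
        for d in self.diagnoses:
            out.setdefault(d.patient_id, []).append(d)
        return out

    def documents_by_patient(self) -> dict[str, list[ClinicalDocument]]:
        out: dict[str, list[ClinicalDocument]] = {}
        for doc in self.documents:
            out.setdefault(doc.patient_id, []).append(doc)
        return out

    def document_index(self) -> dict[str, ClinicalDocument]:
        return {d.doc_id: d for d in self.documents}

    def validate(self) -> None:
        """Enforce uniqueness and referential integrity invariants."""
        seen_p: set[str] = set()
        for p in self.patients:
            if p.patient_id in seen_p:
                raise IntegrityError(f"duplicate patient_id {p.patient_id!r}")
            seen_p.add(p.patient_id)
        seen_d: set[str] = set()
        for doc in self.documents:
            if doc.doc_id in seen_d:
                raise IntegrityError(f"duplicate doc_id {doc.doc_id!r}")
            seen_d.add(doc.doc_id)
        bad = sorted(
            {d.patient_id for d in self.diagnoses if d.patient_id not in seen_p}
            | {d.patient_id for d in self.documents if d.patient_id not in seen_p}
        )
        if bad:
            raise IntegrityError(
                "rows reference patient_ids absent from the patient table: "
                + ", ".join(repr(b) for b in bad)
            )
        for d in self.diagnoses:
            if not ICD9_PATTERN.match(d.icd9_code):
                raise ParseError(
                    f"{d.icd9_code!r} is not a valid ICD-9 code "
                    f"(patient {d.patient_id!r})"
                )

    def sort(self) -> None:
        """Canonical ordering: makes equality order-independent."""
        self.patients.sort()
        self.diagnoses.sort()
        self.documents.sort(key=lambda d: d.doc_id)


def _parse_date(value: str, *, row: int, column: str) -> datetime.date:
    try:
        return datetime.date.fromisoformat(value.strip())
    except ValueError as exc:
        raise ParseError(
            f"row {row}: cannot parse {column}={value!r} as an ISO date"
        ) from exc


def _require_columns(header: typing.Sequence[str], required: typing.Sequence[str],
                     path: Path) -> None:
    missing = [c for c in required if c not in header]
    if missing:
        raise SchemaError(f"{path}: missing column(s): {', '.join(missing)}")


def _coerce_sex(value: str, patient_id: str) -> str:
    v = value.strip().upper()
    if v in ("F", "M"):
        return v
    # real EHR extracts contain unknowns; only 255.2 is sex-restricted
    if v != "U":
        logger.warning("patient %s: sex %r mapped to U", patient_id, value)
    return "U"


def load_corpus(patients_path: str | Path, diagnoses_path: str | Path,
                documents_path: str | Path) -> Corpus:
    """Read the three corpus files and return a referentially-intact Corpus.

    Raises :class:`SchemaError` for missing columns, :class:`ParseError`
    for malformed dates/codes (with the offending row number), and
    :class:`IntegrityError` when a diagnosis or document references an
    unknown patient.
    """
    patients_path = Path(patients_path)
    diagnoses_path = Path(diagnoses_path)
    documents_path = Path(documents_path)

    patients: list[PatientRecord] = []
    with patients_path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        _require_columns(reader.fieldnames or [], ["patient_id", "sex", "birth_date"],
                         patients_path)
        for i, row in enumerate(reader, start=2):
            pid = row["patient_id"].strip()
            patients.append(PatientRecord(
                patient_id=pid,
                sex=_coerce_sex(row["sex"], pid),
                birth_date=_parse_date(row["birth_date"], row=i, column="birth_date"),
            ))

    diagnoses: list[DiagnosisAssignment] = []
    with diagnoses_path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        _require_columns(reader.fieldnames or [], ["patient_id", "icd9_code", "assigned_date"],
                         diagnoses_path)
        for i, row in enumerate(reader, start=2):
            code = row["icd9_code"].strip()
            if not ICD9_PATTERN.match(code):
                raise ParseError(f"row {i}: {code!r} is not a valid ICD-9 code")
            diagnoses.append(DiagnosisAssignment(
                patient_id=row["patient_id"].strip(),
                icd9_code=code,
                assigned_date=_parse_date(row["assigned_date"], row=i,
                                          column="assigned_date"),
            ))

    documents: list[ClinicalDocument] = []
    with documents_path.open(encoding="utf-8") as fh:
        for i, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                obj = json.loads(line)
            except json.JSONDecodeError as exc:
                raise ParseError(f"line {i}: invalid JSON") from exc
            missing = [k for k in ("doc_id", "patient_id", "section", "doc_date", "text")
                       if k not in obj]
            if missing:
                raise SchemaError(
                    f"{documents_path}: line {i}: missing key(s): {', '.join(missing)}")
            documents.append(ClinicalDocument(
                doc_id=str(obj["doc_id"]),
                patient_id=str(obj["patient_id"]),
                section=str(obj["section"]),
                doc_date=_parse_date(str(obj["doc_date"]), row=i, column="doc_date"),
                text=str(obj["text"]),
            ))

    corpus = Corpus(patients=patients, diagnoses=diagnoses, documents=documents)
    corpus.validate()
    corpus.sort()
    return corpus


def write_corpus(corpus: Corpus, out_dir: str | Path) -> dict[str, Path]:
    """Write the three corpus files into ``out_dir``; returns their paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "patients": out / "patients.csv",
        "diagnoses": out / "diagnoses.csv",
        "documents": out / "documents.jsonl",
    }
    write_table(corpus.patients, paths["patients"], "csv")
    write_table(corpus.diagnoses, paths["diagnoses"], "csv")
    write_table(corpus.documents, paths["documents"], "jsonl")
    return paths


# ---------------------------------------------------------------------------
# Generic dataclass table I/O (report writers)
# ---------------------------------------------------------------------------

def _encode_value(value: object, fmt: str) -> object:
    if isinstance(value, datetime.date):
        return value.isoformat()
    if isinstance(value, (set, frozenset)):
        items = sorted(str(v) for v in value)
        return ";".join(items) if fmt == "csv" else items
    if isinstance(value, bool):
        return ("true" if value else "false") if fmt == "csv" else value
    if value is None:
        return "" if fmt == "csv" else None
    if fmt == "jsonl" and isinstance(value, tuple):
        return list(value)
    return value


def _decode_value(raw: object, annotation: typing.Any) -> object:
    origin = typing.get_origin(annotation)
    if annotation is datetime.date:
        return datetime.date.fromisoformat(str(raw))
    if annotation is bool:
        if isinstance(raw, bool):
            return raw
        return str(raw).strip().lower() in ("true", "1", "yes")
    if annotation is int:
        return int(raw)  # type: ignore[arg-type]
    if annotation is float:
        return float(raw)  # type: ignore[arg-type]
    if origin in (set, frozenset):
        (item_t,) = typing.get_args(annotation) or (str,)
        if isinstance(raw, str):
            items = [s for s in raw.split(";") if s != ""]
        else:
            items = list(raw)  # type: ignore[arg-type]
        converted = {_decode_value(i, item_t) for i in items}
        return frozenset(converted) if origin is frozenset else converted
    if origin is typing.Union or origin is types.UnionType:  # Optional[...]
        args = [a for a in typing.get_args(annotation) if a is not type(None)]
        if raw is None or raw == "":
            return None
        return _decode_value(raw, args[0])
    return str(raw) if isinstance(raw, str) else raw


def write_table(records: typing.Sequence, path: str | Path,
                format: str = "csv", record_type: type | None = None) -> None:
    """Write a homogeneous collection of dataclass records to CSV or JSONL.

    The output round-trips through :func:`read_table`.  An empty
    collection yields a header-only CSV when ``record_type`` is given
    (or an empty file otherwise), and a zero-line JSONL.
    """
    if format not in ("csv", "jsonl"):
        raise ValueError(f"unknown format {format!r}")
    path = Path(path)
    kinds = {type(r) for r in records}
    if len(kinds) > 1:
        raise TypeError(f"mixed record kinds: {sorted(k.__name__ for k in kinds)}")
    if not records:
        if record_type is not None:
            write_empty_table(record_type, path, format)
        else:
            path.write_text("", encoding="utf-8")
        return
    cls = next(iter(kinds))
    if not dataclasses.is_dataclass(cls):
        raise TypeError(f"{cls.__name__} is not a dataclass record type")
    names = [f.name for f in dataclasses.fields(cls)]
    if format == "csv":
        with path.open("w", newline="", encoding="utf-8") as fh:
            writer = csv.DictWriter(fh, fieldnames=names)
            writer.writeheader()
            for r in records:
                writer.writerow({n: _encode_value(getattr(r, n), "csv") for n in names})
    else:
        with path.open("w", encoding="utf-8") as fh:
            for r in records:
                fh.write(json.dumps(
                    {n: _encode_value(getattr(r, n), "jsonl") for n in names},
                    ensure_ascii=False) + "\n")


def write_empty_table(record_type: type, path: str | Path, format: str = "csv") -> None:
    """Write a header-only CSV (or zero-line JSONL) for ``record_type``."""
    path = Path(path)
    if format == "csv":
        names = [f.name for f in dataclasses.fields(record_type)]
        with path.open("w", newline="", encoding="utf-8") as fh:
            csv.DictWriter(fh, fieldnames=names).writeheader()
    else:
        path.write_text("", encoding="utf-8")


def read_table(path: str | Path, record_type: type, format: str = "csv") -> list:
    """Read records written by :func:`write_table` back into dataclasses."""
    path = Path(path)
    hints = typing.get_type_hints(record_type)
    names = [f.name for f in dataclasses.fields(record_type)]
    out = []
    if format == "csv":
        with path.open(newline="", encoding="utf-8") as fh:
            for row in csv.DictReader(fh):
                out.append(record_type(**{
                    n: _decode_value(row[n], hints[n]) for n in names}))
    else:
        with path.open(encoding="utf-8") as fh:
            for line in fh:
                if not line.strip():
                    continue
                obj = json.loads(line)
                out.append(record_type(**{
                    n: _decode_value(obj.get(n), hints[n]) for n in names}))
    return out
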