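"""Traditional-vs-informatics ascertainment comparison.

Given the confirmed-eligible patient sets from two ascertainment
strategies — clinician nomination / informal registries ("traditional")
versus the two-stage EHR screen ("informatics") — this module computes
the evaluation quantities: the Venn overlap, the fold-increase of the
informatics arm over the traditional arm, the yield (positive
predictive value) of the structured filter, and per-code case counts.

Yield is kept unrounded internally and rendered to one decimal place;
fold-increase is kept as an exact ratio and additionally rendered in
the "N-fold" idiom (nearest integer).  An empty traditional arm makes
the fold undefined; it renders as "∞" with a warning rather than
erroring, because the tool must run where no traditional arm exists.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .structured_filter import CandidateCase

logger = logging.getLogger("cohortscreen")

NO_CODE = "no-code"


class ConsistencyError(ValueError):
    """Inputs contradict each other (e.g. more confirmed than ICD cases)."""


@dataclass
class ComparisonReport:
    n_traditional_confirmed: int
    n_informatics_confirmed: int
    n_overlap: int
    only_traditional: int
    only_informatics: int
    fold_increase: float | None  # None when no traditional arm
    yield_pct: float | None      # None when icd_case_count is 0
    per_code_counts: dict[str, tuple[int, int]] = field(default_factory=dict)

    @property
    def fold_label(self) -> str:
        if self.fold_increase is None:
            return "∞"
        return f"{round(self.fold_increase)}-fold"

    @property
    def yield_label(self) -> str:
        return "n/a" if self.yield_pct is None else f"{self.yield_pct:.1f}%"

    def to_dict(self) -> dict:
        return {
            "n_traditional_confirmed": self.n_traditional_confirmed,
            "n_informatics_confirmed": self.n_informatics_confirmed,
            "n_overlap": self.n_overlap,
            "only_traditional": self.only_traditional,
            "only_informatics": self.only_informatics,
            "fold_increase": self.fold_increase,
            "fold_label": self.fold_label,
            "yield_pct": self.yield_pct,
            "yield_label": self.yield_label,
            "per_code_counts": {k: list(v) for k, v in sorted(self.per_code_counts.items())},
        }

    def write_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(self.to_dict(), indent=2, ensure_ascii=False) + "\n",
            encoding="utf-8")


def compare_methods(traditional_ids: Iterable[str], informatics_ids: Iterable[str],
                    icd_case_count: int) -> ComparisonReport:
    """Exact set arithmetic between the two confirmed-eligible sets.

    ``icd_case_count`` is the size of the initial structured-filter
    cohort from which the informatics arm was confirmed; the yield is
    ``100 * |informatics| / icd_case_count``.
    """
    t = set(traditional_ids)
    i = set(informatics_ids)
    if icd_case_count < len(i):
        raise ConsistencyError(
            f"icd_case_count {icd_case_count} < informatics confirmed {len(i)}")
    overlap = len(t & i)
    fold: float | None
    if not t:
        logger.warning("traditional arm empty: fold-increase undefined (rendered ∞)")
        fold = None
    else:
        fold = len(i) / len(t)
    yield_pct = None if icd_case_count == 0 else 100.0 * len(i) / icd_case_count
    return ComparisonReport(
        n_traditional_confirmed=len(t),
        n_informatics_confirmed=len(i),
        n_overlap=overlap,
        only_traditional=len(t) - overlap,
        only_informatics=len(i) - overlap,
        fold_increase=fold,
        yield_pct=yield_pct,
    )


def per_code_breakdown(confirmed: Sequence[CandidateCase],
                       method_labels: Mapping[str, set[str] | frozenset[str]],
                       ) -> dict[str, tuple[int, int]]:
    """Per-ICD-9-code case counts by ascertainment method.

    ``method_labels`` maps patient_id to the subset of
    ``{"traditional", "informatics"}`` that found the patient.  A
    patient with several qualifying codes counts once under each; a
    case with no attributable code (e.g. one known to clinicians but
    never assigned a qualifying code) lands in the ``no-code`` row.
    """
    counts: dict[str, list[int]] = {}
    for case in confirmed:
        codes = sorted(case.qualifying_codes) or [NO_CODE]
        methods = method_labels.get(case.patient_id, set())
        for code in codes:
            row = counts.setdefault(code, [0, 0])
            if "traditional" in methods:
                row[0] += 1
            if "informatics" in methods:
                row[1] += 1
    return {code: (t, i) for code, (t, i) in sorted(counts.items())}


def write_comparison_csv(report: ComparisonReport, path: str | Path) -> None:
    lines = ["metric,value"]
    d = report.to_dict()
    for key in ("n_traditional_confirmed", "n_informatics_confirmed", "n_overlap",
                "only_traditional", "only_informatics", "fold_increase",
                "fold_label", "yield_pct", "yield_label"):
        value = d[key]
        lines.append(f"{key},{'' if value is None else value}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def write_venn_csv(report: ComparisonReport, path: str | Path) -> None:
    Path(path).write_text(
        "only_traditional,overlap,only_informatics\n"
        f"{report.only_traditional},{report.n_overlap},{report.only_informatics}\n",
        encoding="utf-8")


def write_per_code_csv(per_code: Mapping[str, tuple[int, int]], path: str | Path) -> None:
    lines = ["icd9_code,traditional,informatics"]
    for code, (t, i) in sorted(per_code.items()):
        lines.append(f"{code},{t},{i}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
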