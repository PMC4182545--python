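"""Stage 2 of the screen: free-text keyword matching.

Matching is deliberately naive — case-insensitive literal substring
search, the semantics of a SQL ``LIKE '%term%'`` query under a
case-insensitive collation.  A truncated literal such as ``karyotyp``
therefore matches "karyotype", "karyotyped", "karyotypes" and
"karyotyping" without any linguistic stemmer, and a short pattern such
as ``XY`` also fires inside unrelated words like "hydroxylase" — a
known false positive that manual review absorbs.

The shipped dictionary is tiered.  Patients whose only qualifying code
is the hypospadias code (752.61) are screened with the 14
universal-tier patterns only; all other candidates get the full set of
26.  The restriction exists because the extended tier contains
``hypospad`` itself, which would trivially match every chart in the
hypospadias-coded cohort.

Exclusion contexts are a proto-negation feature: a (pattern, context)
pair suppresses a match when the longer context phrase occurs in the
text overlapping the match position (e.g. suppressing ``labia`` inside
"labia were normal in appearance").  The default dictionary ships with
no exclusions.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

from .corpus import Corpus
from .structured_filter import CandidateCase, HYPOSPADIAS_CODE, DomainError

#: Universal-tier patterns: used for every candidate, including those
#: qualified only by the hypospadias code.
UNIVERSAL_KEYWORDS: tuple[str, ...] = (
    "46 XX",
    "46 XY",
    "46-XX",
    "46-XY",
    "XO",
    "XX",
    "XY",
    "ambig",
    "chordee",
    "karyotyp",
    "penoscrotal",
    "perineal",
    "severe hypospad",
    "undescended",
)

#: Extended-tier patterns: added for candidates qualified by any
#: non-hypospadias code.
EXTENDED_KEYWORDS: tuple[str, ...] = (
    "CAH",
    "congenital adrenal hyperplasia",
    "gonad",
    "hypospad",
    "labia",
    "mosaic",
    "penile",
    "penis",
    "phall",
    "prader",
    "urogenital sinus",
    "viriliz",
)

TIERS = ("universal", "extended")


@dataclass(frozen=True)
class KeywordPattern:
    pattern: str
    tier: str

    def __post_init__(self) -> None:
        if not self.pattern:
            raise ValueError("empty pattern")
        if self.tier not in TIERS:
            raise ValueError(f"unknown tier {self.tier!r}")


@dataclass(frozen=True)
class KeywordMatch:
    """A located substring hit: 0-based [start, end) offsets into the text."""

    doc_id: str
    pattern: str
    start: int
    end: int
    matched_text: str


@dataclass
class KeywordDictionary:
    patterns: list[KeywordPattern]
    exclusion_contexts: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.patterns:
            raise ValueError("dictionary must contain at least one pattern")
        seen: set[str] = set()
        for p in self.patterns:
            key = p.pattern.lower()
            if key in seen:
                raise ValueError(f"duplicate pattern (case-insensitive): {p.pattern!r}")
            seen.add(key)
        for pat, ctx in self.exclusion_contexts:
            if pat.lower() not in seen:
                raise ValueError(f"exclusion context for unknown pattern {pat!r}")
            if pat.lower() not in ctx.lower():
                raise ValueError(
                    f"exclusion context {ctx!r} does not contain its pattern {pat!r}")

    def tier_patterns(self, tier: str) -> list[str]:
        return [p.pattern for p in self.patterns if p.tier == tier]

    def all_patterns(self) -> list[str]:
        return [p.pattern for p in self.patterns]

    def with_exclusions(self, exclusions: Iterable[tuple[str, str]]) -> "KeywordDictionary":
        return replace(self, exclusion_contexts=list(exclusions))

    # -- serialisation ----------------------------------------------------
    def to_csv(self, path: str | Path) -> None:
        with Path(path).open("w", newline="", encoding="utf-8") as fh:
            w = csv.writer(fh)
            w.writerow(["pattern", "tier"])
            for p in self.patterns:
                w.writerow([p.pattern, p.tier])

    @classmethod
    def from_csv(cls, path: str | Path,
                 exclusions_path: str | Path | None = None) -> "KeywordDictionary":
        patterns = []
        with Path(path).open(newline="", encoding="utf-8") as fh:
            for row in csv.DictReader(fh):
                patterns.append(KeywordPattern(row["pattern"], row["tier"]))
        exclusions: list[tuple[str, str]] = []
        if exclusions_path is not None:
            with Path(exclusions_path).open(newline="", encoding="utf-8") as fh:
                for row in csv.DictReader(fh):
                    exclusions.append((row["pattern"], row["context"]))
        return cls(patterns=patterns, exclusion_contexts=exclusions)


def default_dsd_dictionary() -> KeywordDictionary:
    """The shipped 26-pattern dictionary (14 universal + 12 extended)."""
    return KeywordDictionary(
        patterns=[KeywordPattern(p, "universal") for p in UNIVERSAL_KEYWORDS]
        + [KeywordPattern(p, "extended") for p in EXTENDED_KEYWORDS],
    )


def select_patterns(dictionary: KeywordDictionary,
                    qualifying_codes: set[str] | frozenset[str]) -> list[str]:
    """Pick the pattern set for a candidate given its qualifying codes.

    Only candidates qualified *solely* by the hypospadias code get the
    restricted universal tier; any other code brings in the full set.
    """
    if not qualifying_codes:
        raise DomainError("qualifying_codes must be nonempty")
    if set(qualifying_codes) == {HYPOSPADIAS_CODE}:
        return dictionary.tier_patterns("universal")
    return dictionary.all_patterns()


def match_text(text: str, patterns: Sequence[str],
               doc_id: str = "") -> list[KeywordMatch]:
    """Every case-insensitive occurrence of every pattern in ``text``.

    Occurrences inside longer words and overlapping occurrences of
    distinct patterns are all reported.  Output is ordered by
    (start offset, pattern, end offset) and is deterministic.
    """
    lowered = text.lower()
    matches: list[KeywordMatch] = []
    for pattern in patterns:
        needle = pattern.lower()
        if not needle:
            continue
        pos = lowered.find(needle)
        while pos != -1:
            end = pos + len(needle)
            matches.append(KeywordMatch(
                doc_id=doc_id, pattern=pattern, start=pos, end=end,
                matched_text=text[pos:end]))
            pos = lowered.find(needle, pos + 1)
    matches.sort(key=lambda m: (m.start, m.pattern.lower(), m.end))
    return matches


def apply_exclusions(matches: Sequence[KeywordMatch], text: str,
                     dictionary: KeywordDictionary) -> list[KeywordMatch]:
    """Drop matches suppressed by an overlapping exclusion context.

    A match is removed when its pattern has an exclusion context that
    occurs (case-insensitively) in the text at a position overlapping
    the match span.  With no exclusion contexts this is the identity.
    """
    if not dictionary.exclusion_contexts:
        return list(matches)
    lowered = text.lower()
    # context occurrence spans per pattern (lowercased key)
    spans_by_pattern: dict[str, list[tuple[int, int]]] = {}
    for pat, ctx in dictionary.exclusion_contexts:
        needle = ctx.lower()
        spans = spans_by_pattern.setdefault(pat.lower(), [])
        pos = lowered.find(needle)
        while pos != -1:
            spans.append((pos, pos + len(needle)))
            pos = lowered.find(needle, pos + 1)
    kept = []
    for m in matches:
        suppressed = any(
            s < m.end and m.start < e
            for s, e in spans_by_pattern.get(m.pattern.lower(), ())
        )
        if not suppressed:
            kept.append(m)
    return kept


def patient_matches(corpus_docs, candidate: CandidateCase,
                    dictionary: KeywordDictionary) -> list[KeywordMatch]:
    """All surviving matches across one candidate's documents.

    ``corpus_docs`` is the candidate's document list (may be empty).
    Documents are scanned in doc_id order.
    """
    patterns = select_patterns(dictionary, candidate.qualifying_codes)
    out: list[KeywordMatch] = []
    for doc in sorted(corpus_docs, key=lambda d: d.doc_id):
        ms = match_text(doc.text, patterns, doc_id=doc.doc_id)
        out.extend(apply_exclusions(ms, doc.text, dictionary))
    return out


def run_keyword_screen(corpus: Corpus, candidates: Sequence[CandidateCase],
                       dictionary: KeywordDictionary,
                       ) -> tuple[list[CandidateCase], list[tuple[str, KeywordMatch]]]:
    """Screen every candidate; returns (screened candidates, match stream).

    The match stream pairs each surviving :class:`KeywordMatch` with its
    patient_id, in (patient_id, doc_id, start) order.  Candidates stay
    in the output whether or not any pattern fired; ``keyword_positive``
    and ``matched_patterns`` record the outcome.
    """
    docs_by_patient = corpus.documents_by_patient()
    screened: list[CandidateCase] = []
    stream: list[tuple[str, KeywordMatch]] = []
    for cand in sorted(candidates, key=lambda c: c.patient_id):
        docs = docs_by_patient.get(cand.patient_id, [])
        ms = patient_matches(docs, cand, dictionary)
        screened.append(CandidateCase(
            patient_id=cand.patient_id,
            qualifying_codes=set(cand.qualifying_codes),
            keyword_positive=bool(ms),
            matched_patterns={m.pattern for m in ms},
            review_state=cand.review_state,
        ))
        stream.extend((cand.patient_id, m) for m in ms)
    return screened, stream


def screen_candidates(corpus: Corpus, candidates: Sequence[CandidateCase],
                      dictionary: KeywordDictionary) -> list[CandidateCase]:
    """Flag candidates by keyword positivity (see :func:`run_keyword_screen`)."""
    screened, _ = run_keyword_screen(corpus, candidates, dictionary)
    return screened
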