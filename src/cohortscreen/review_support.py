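"""Chart-review display artifacts: snippets, highlighting, heat map.

The reviewer-facing outputs have three levels of drill-down, modelled
here as three static products:

* a patient × record-section *heat map* whose cells count documents
  containing at least one keyword hit;
* per-document *snippets* — short excerpts around each hit with a few
  words of context on either side (default 4, the midpoint of the
  3-to-5-word convention) so review stays brief but informative;
* the *full document* with every hit highlighted, rendered with
  configurable open/close markers (HTML ``<mark>`` or ANSI).

A "word" is a maximal run of non-whitespace characters; punctuation
stays attached.  Highlighting is lossless: stripping the markers
restores the source text exactly.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .corpus import Corpus
from .keyword_screen import KeywordMatch
from .structured_filter import DomainError

_WORD_RE = re.compile(r"\S+")

DEFAULT_CONTEXT_WORDS = 4


@dataclass
class Snippet:
    """An excerpt around one or more keyword hits.

    ``excerpt_start`` is the excerpt's offset in the source document, so
    snippets can be merged; ``match_spans`` are in excerpt coordinates.
    """

    doc_id: str
    patient_id: str
    excerpt: str
    excerpt_start: int
    match_spans: list[tuple[int, int]] = field(default_factory=list)
    context_words: int = DEFAULT_CONTEXT_WORDS

    @property
    def excerpt_end(self) -> int:
        return self.excerpt_start + len(self.excerpt)


@dataclass(frozen=True)
class HeatMapCell:
    patient_id: str
    section: str
    docs_with_hits: int


def make_snippet(text: str, match: KeywordMatch, context_words: int = DEFAULT_CONTEXT_WORDS,
                 patient_id: str = "") -> Snippet:
    """Excerpt ``context_words`` whitespace-delimited words around a match.

    The excerpt runs from the start of the word ``context_words`` words
    before the word containing the match to the end of the word
    ``context_words`` words after it, clipped at the text boundaries.
    With ``context_words`` 0 the excerpt is exactly the matched text.
    """
    if context_words < 0:
        raise DomainError("context_words must be >= 0")
    if not (0 <= match.start < match.end <= len(text)):
        raise DomainError(
            f"match span [{match.start},{match.end}) outside text of length {len(text)}")
    if context_words == 0:
        return Snippet(doc_id=match.doc_id, patient_id=patient_id,
                       excerpt=text[match.start:match.end], excerpt_start=match.start,
                       match_spans=[(0, match.end - match.start)],
                       context_words=0)
    words = [(m.start(), m.end()) for m in _WORD_RE.finditer(text)]
    # word containing the match start (or the next word if start is on whitespace)
    left_idx = 0
    for i, (ws, we) in enumerate(words):
        if we > match.start:
            left_idx = i
            break
    # word containing the last matched character (or the previous word)
    right_idx = len(words) - 1
    for i in range(len(words) - 1, -1, -1):
        if words[i][0] < match.end:
            right_idx = i
            break
    lo = words[max(0, left_idx - context_words)][0]
    hi = words[min(len(words) - 1, right_idx + context_words)][1]
    lo = min(lo, match.start)
    hi = max(hi, match.end)
    return Snippet(
        doc_id=match.doc_id, patient_id=patient_id,
        excerpt=text[lo:hi], excerpt_start=lo,
        match_spans=[(match.start - lo, match.end - lo)],
        context_words=context_words,
    )


def merge_snippets(snippets: Sequence[Snippet]) -> list[Snippet]:
    """Merge snippets with overlapping excerpt ranges within one document.

    Overlapping excerpts are stitched into a single excerpt carrying all
    match spans (re-based); disjoint snippets pass through.  Output is
    ordered by excerpt start.
    """
    if not snippets:
        return []
    doc_ids = {s.doc_id for s in snippets}
    if len(doc_ids) > 1:
        raise DomainError(f"snippets span multiple documents: {sorted(doc_ids)}")
    ordered = sorted(snippets, key=lambda s: (s.excerpt_start, s.excerpt_end))
    merged: list[Snippet] = []
    for s in ordered:
        if merged and s.excerpt_start <= merged[-1].excerpt_end:
            prev = merged[-1]
            overlap_end = max(prev.excerpt_end, s.excerpt_end)
            if s.excerpt_end > prev.excerpt_end:
                tail = s.excerpt[prev.excerpt_end - s.excerpt_start:]
                prev.excerpt = prev.excerpt + tail
            shift = s.excerpt_start - prev.excerpt_start
            prev.match_spans.extend(
                (a + shift, b + shift) for a, b in s.match_spans)
            prev.match_spans.sort()
            assert prev.excerpt_end == overlap_end
        else:
            merged.append(Snippet(
                doc_id=s.doc_id, patient_id=s.patient_id,
                excerpt=s.excerpt, excerpt_start=s.excerpt_start,
                match_spans=list(s.match_spans), context_words=s.context_words,
            ))
    return merged


def build_snippets(match_stream: Sequence[tuple[str, KeywordMatch]], corpus: Corpus,
                   context_words: int = DEFAULT_CONTEXT_WORDS) -> list[Snippet]:
    """Per-document merged snippets for a whole match stream.

    ``match_stream`` pairs patient_ids with matches (the output of the
    keyword screen).  Returns snippets ordered by (patient, doc,
    excerpt start).
    """
    docs = corpus.document_index()
    by_doc: dict[str, list[tuple[str, KeywordMatch]]] = {}
    for pid, m in match_stream:
        by_doc.setdefault(m.doc_id, []).append((pid, m))
    out: list[Snippet] = []
    for doc_id in sorted(by_doc):
        text = docs[doc_id].text
        raw = [make_snippet(text, m, context_words, patient_id=pid)
               for pid, m in by_doc[doc_id]]
        out.extend(merge_snippets(raw))
    out.sort(key=lambda s: (s.patient_id, s.doc_id, s.excerpt_start))
    return out


def build_heatmap(matches: Sequence[tuple[str, KeywordMatch]] | Sequence[KeywordMatch],
                  corpus: Corpus) -> list[HeatMapCell]:
    """Patient × section cells counting distinct documents with ≥1 hit.

    Accepts either bare matches or (patient_id, match) pairs; the
    document's owning patient and section come from the corpus either
    way.  Cells with zero hits are omitted.  Ordered by (patient,
    section).
    """
    docs = corpus.document_index()
    hit_docs: set[str] = set()
    for item in matches:
        m = item[1] if isinstance(item, tuple) else item
        if m.doc_id not in docs:
            raise DomainError(f"match references unknown doc_id {m.doc_id!r}")
        hit_docs.add(m.doc_id)
    counts: dict[tuple[str, str], int] = {}
    for doc_id in hit_docs:
        doc = docs[doc_id]
        key = (doc.patient_id, doc.section)
        counts[key] = counts.get(key, 0) + 1
    return [HeatMapCell(pid, section, n)
            for (pid, section), n in sorted(counts.items())]


def _merge_spans(spans: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of overlapping (not merely touching) intervals."""
    ordered = sorted(spans)
    merged: list[list[int]] = []
    for s, e in ordered:
        if merged and s < merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def render_highlighted(text: str, matches: Sequence[KeywordMatch],
                       marker_open: str = "<mark>",
                       marker_close: str = "</mark>") -> str:
    """The full text with each (overlap-merged) match span wrapped in markers.

    Stripping the markers restores the source text exactly.
    """
    for m in matches:
        if not (0 <= m.start < m.end <= len(text)):
            raise DomainError(f"match span [{m.start},{m.end}) outside text")
    spans = _merge_spans((m.start, m.end) for m in matches)
    parts: list[str] = []
    pos = 0
    for s, e in spans:
        parts.append(text[pos:s])
        parts.append(marker_open)
        parts.append(text[s:e])
        parts.append(marker_close)
        pos = e
    parts.append(text[pos:])
    return "".join(parts)


def strip_markers(rendered: str, marker_open: str = "<mark>",
                  marker_close: str = "</mark>") -> str:
    return rendered.replace(marker_open, "").replace(marker_close, "")
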