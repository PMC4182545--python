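import random
import string

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cohortscreen import (CandidateCase, DomainError, KeywordDictionary,
                          KeywordPattern, apply_exclusions,
                          default_dsd_dictionary, match_text,
                          run_keyword_screen, screen_candidates,
                          select_patterns)
from cohortscreen.keyword_screen import (EXTENDED_KEYWORDS,
                                         UNIVERSAL_KEYWORDS)


def brute_force_matches(text: str, patterns) -> set[tuple[str, int, int]]:
    """Exhaustive (offset, pattern) oracle: test every position."""
    found = set()
    low = text.lower()
    for p in patterns:
        pl = p.lower()
        for i in range(len(text) - len(pl) + 1):
            if low[i:i + len(pl)] == pl:
                found.add((p, i, i + len(pl)))
    return found


class TestDefaultDictionary:
    def test_twenty_six_patterns_split_14_universal_12_extended(self):
        d = default_dsd_dictionary()
        assert len(d.patterns) == 26
        assert len(d.tier_patterns("universal")) == 14
        assert len(d.tier_patterns("extended")) == 12

    def test_tier_assignment_examples(self):
        d = default_dsd_dictionary()
        tiers = {p.pattern: p.tier for p in d.patterns}
        assert tiers["severe hypospad"] == "universal"
        assert tiers["gonad"] == "extended"
        assert tiers["hypospad"] == "extended"
        assert tiers["karyotyp"] == "universal"

    def test_csv_round_trip(self, tmp_path):
        d = default_dsd_dictionary()
        d.to_csv(tmp_path / "kw.csv")
        assert KeywordDictionary.from_csv(tmp_path / "kw.csv") == d

    def test_shipped_data_file_matches_defaults(self):
        from importlib.resources import files
        shipped = files("cohortscreen") / "data" / "keywords.csv"
        with shipped.open() as fh:  # type: ignore[attr-defined]
            import csv
            rows = [(r["pattern"], r["tier"]) for r in csv.DictReader(fh)]
        assert rows == [(p.pattern, p.tier)
                        for p in default_dsd_dictionary().patterns]

    def test_duplicate_patterns_rejected_case_insensitively(self):
        with pytest.raises(ValueError, match="duplicate"):
            KeywordDictionary(patterns=[KeywordPattern("XY", "universal"),
                                        KeywordPattern("xy", "extended")])


class TestSelectPatterns:
    def test_pure_hypospadias_candidates_get_universal_tier_only(self):
        d = default_dsd_dictionary()
        assert len(select_patterns(d, {"752.61"})) == 14
        assert "hypospad" not in select_patterns(d, {"752.61"})

    @pytest.mark.parametrize("codes", [{"752.7"}, {"752.61", "259.5"}, {"255.2"}])
    def test_any_other_code_brings_full_set(self, codes):
        assert len(select_patterns(default_dsd_dictionary(), codes)) == 26

    def test_empty_code_set_is_domain_error(self):
        with pytest.raises(DomainError):
            select_patterns(default_dsd_dictionary(), set())


class TestMatchText:
    def test_truncated_literal_matches_inflections(self):
        for word in ("karyotype", "karyotyped", "karyotypes", "karyotyping"):
            (m,) = match_text(f"{word} was sent", ["karyotyp"])
            assert (m.start, m.end, m.matched_text) == (0, 8, "karyotyp")

    def test_xy_fires_inside_hydroxylase(self):
        (m,) = match_text("21-hydroxylase deficiency", ["XY"])
        assert m.pattern == "XY"
        assert m.matched_text == "xy"
        assert m.start == "21-hydroxylase".index("xy") + 0

    def test_gonad_fires_on_each_inflection(self):
        ms = match_text("gonads appeared gonadal", ["gonad"])
        assert [(m.start, m.end) for m in ms] == [(0, 5), (16, 21)]

    def test_empty_text_yields_nothing(self):
        assert match_text("", default_dsd_dictionary().all_patterns()) == []

    def test_overlapping_distinct_patterns_all_recorded(self):
        ms = match_text("severe hypospadias", ["severe hypospad", "hypospad"])
        assert {(m.pattern, m.start) for m in ms} == {
            ("severe hypospad", 0), ("hypospad", 7)}

    def test_output_order_is_start_then_pattern(self):
        ms = match_text("46 XY karyotype", ["karyotyp", "XY", "46 XY"])
        assert [(m.start, m.pattern) for m in ms] == [
            (0, "46 XY"), (3, "XY"), (6, "karyotyp")]

    def test_case_insensitivity_positionally_identical(self):
        text = "Severe Hypospadias with 46 xy MOSAIC pattern"
        pats = default_dsd_dictionary().all_patterns()
        a = [(m.pattern, m.start, m.end) for m in match_text(text, pats)]
        b = [(m.pattern, m.start, m.end) for m in match_text(text.upper(), pats)]
        assert a == b

    def test_matches_brute_force_on_random_2kb_text(self):
        rng = random.Random(3)
        words = ["xy", "karyotype", "oxygen", "note", "exam", "labia",
                 "gonadal", "46", "XX", "hypospadias", "the", "a"]
        text = " ".join(rng.choice(words) for _ in range(400))
        assert len(text) >= 2000
        pats = default_dsd_dictionary().all_patterns()
        got = {(m.pattern, m.start, m.end) for m in match_text(text, pats)}
        assert got == brute_force_matches(text, pats)

    @settings(max_examples=200, derandomize=True, deadline=None)
    @given(st.text(alphabet=string.ascii_letters + " -46", min_size=0,
                   max_size=120))
    def test_matcher_equals_brute_force_property(self, text):
        pats = default_dsd_dictionary().all_patterns()
        got = {(m.pattern, m.start, m.end) for m in match_text(text, pats)}
        assert got == brute_force_matches(text, pats)

    def test_match_invariants_hold(self):
        text = "46-XY mosaic karyotype with severe hypospadias"
        for m in match_text(text, default_dsd_dictionary().all_patterns()):
            assert 0 <= m.start < m.end <= len(text)
            assert m.matched_text.lower() == m.pattern.lower()
            assert m.end - m.start == len(m.pattern)


class TestApplyExclusions:
    def test_overlapping_context_suppresses_match(self):
        d = default_dsd_dictionary().with_exclusions(
            [("labia", "labia were normal")])
        text = "labia were normal in appearance"
        ms = match_text(text, d.all_patterns())
        assert any(m.pattern == "labia" for m in ms)
        assert not any(m.pattern == "labia"
                       for m in apply_exclusions(ms, text, d))

    def test_empty_exclusions_is_identity(self):
        d = default_dsd_dictionary()
        text = "labia were normal in appearance"
        ms = match_text(text, d.all_patterns())
        assert apply_exclusions(ms, text, d) == ms

    def test_non_overlapping_context_elsewhere_keeps_match(self):
        # context occurs in sentence 1; the match in sentence 2 survives
        d = default_dsd_dictionary().with_exclusions(
            [("labia", "labia were normal")])
        text = "The labia were normal today. Fusion of the labia noted."
        kept = apply_exclusions(match_text(text, ["labia"]), text, d)
        assert [m.start for m in kept] == [text.index("labia", 30)]

    def test_adding_exclusion_never_increases_matches(self):
        d0 = default_dsd_dictionary()
        d1 = d0.with_exclusions([("gonad", "gonads were normal")])
        text = "gonads were normal; gonadal streak seen"
        ms = match_text(text, d0.all_patterns())
        assert len(apply_exclusions(ms, text, d1)) <= len(
            apply_exclusions(ms, text, d0))


class TestScreenCandidates:
    def test_pure_hypospadias_candidate_not_flagged_by_extended_vocab(self, tiny_corpus):
        # p2's note says "Severe hypospadias ... chordee" -> universal hits
        cands = [CandidateCase("p2", {"752.61"})]
        (s,) = screen_candidates(tiny_corpus, cands, default_dsd_dictionary())
        assert s.keyword_positive
        assert s.matched_patterns >= {"severe hypospad", "chordee"}
        assert "hypospad" not in s.matched_patterns  # extended tier not selected

    def test_candidate_without_documents_is_negative(self, tiny_corpus):
        cands = [CandidateCase("p1", {"255.2"})]
        tiny_corpus.documents = [d for d in tiny_corpus.documents
                                 if d.patient_id != "p1"]
        (s,) = screen_candidates(tiny_corpus, cands, default_dsd_dictionary())
        assert not s.keyword_positive and s.matched_patterns == set()

    def test_candidates_stay_in_output_flagged_either_way(self, tiny_corpus):
        cands = [CandidateCase("p1", {"255.2"}), CandidateCase("p3", {"752.7"})]
        screened = screen_candidates(tiny_corpus, cands, default_dsd_dictionary())
        flags = {s.patient_id: s.keyword_positive for s in screened}
        assert flags == {"p1": True, "p3": False}

    def test_keyword_positive_count_bounded_by_candidates(self, tiny_corpus):
        cands = [CandidateCase(p, {"752.7"}) for p in ("p1", "p2", "p3")]
        screened, stream = run_keyword_screen(tiny_corpus, cands,
                                              default_dsd_dictionary())
        assert sum(s.keyword_positive for s in screened) <= len(cands)
        positive = {s.patient_id for s in screened if s.keyword_positive}
        assert positive == {pid for pid, _ in stream}

    def test_repeated_runs_are_identical(self, tiny_corpus):
        cands = [CandidateCase(p, {"752.7"}) for p in ("p1", "p2", "p3")]
        r1 = run_keyword_screen(tiny_corpus, cands, default_dsd_dictionary())
        r2 = run_keyword_screen(tiny_corpus, cands, default_dsd_dictionary())
        assert r1 == r2


def test_universal_and_extended_vocabularies_are_disjoint():
    assert not set(UNIVERSAL_KEYWORDS) & set(EXTENDED_KEYWORDS)
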