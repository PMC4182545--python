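# Methods

## The screening model

The package treats rare-disease case ascertainment as a monotone funnel
over a three-table corpus (patients, ICD-9 diagnosis assignments,
free-text documents):

```
code-positive candidates ≥ keyword-positive ≥ initial-review pool ≥ confirmed
```

Stage 1 is purely structured: a patient is a candidate when at least one
assigned code is in the configured code set and passes every per-code
restriction, the birth date lies in the configured window, and the age at
the reference date is within the configured range. Stage 2 is free-text:
literal, case-insensitive substring matching of a keyword dictionary over
all of the candidate's documents. Neither stage decides eligibility; both
exist to shrink and organise the set a human expert must read. The final
two review stages are human decisions recorded in an append-only log.

Assumptions worth stating explicitly:

* **Substring semantics are the contract, not an approximation.** The
  matcher is the semantics of `SELECT ... WHERE text LIKE '%term%'` under a
  case-insensitive collation. No word boundaries, no whitespace
  normalisation, no regex, no negation. "46 XX" and "46-XX" are separate
  dictionary entries precisely because matching is literal. Short patterns
  (`XY`, `XO`) fire inside unrelated words (*hydroxylase*, *oxygen*,
  *toxoplasmosis*); this is accepted because manual review absorbs false
  positives and the cost of a missed case is high.
* **The dictionary is nonspecific by design.** The terms name phenotypic
  and genetic-testing vocabulary, not diagnoses, so the keyword stage trims
  the code cohort only modestly; its main value is highlighting for fast
  review.
* **Documents are stored verbatim.** No normalisation at load time, so all
  match offsets index directly into the source text, and highlighting is
  lossless (marker-strip round trip is tested).

## Tunable parameters

| parameter | default | meaning / rationale |
|---|---|---|
| code set | 10 ICD-9 codes | broad congenital-genital / adrenogenital / AIS set, sensitivity over specificity |
| sex restrictions | `255.2 → F` | the adrenogenital code qualifies female patients only |
| `age_range_months` | (0, 81) | eligibility window in completed calendar months at the reference date |
| `birth_window`, `age_reference_date` | **no default** | both change cohort membership; silent defaults would alter cohorts invisibly, so they are required configuration |
| `code_prefix` | off | exact dotted-code equality by default; the shipped set lists `752` and subcodes separately, so each recorded code is matched as assigned. Prefix mode serves extracts that roll subcodes up |
| dictionary | 26 patterns (14 universal + 12 extended) | tier selection: a candidate qualified solely by 752.61 gets the universal tier; any other code selects all 26. Multi-code patients get the full set — the wider net is harmless given manual review |
| exclusion contexts | empty | overlap-based proto-negation: a match is dropped when a configured longer phrase containing its pattern overlaps it (e.g. suppressing `labia` inside "labia were normal in appearance"). Off by default to match plain LIKE semantics |
| `context_words` | 4 (range 0–10) | snippet context per side; midpoint of the 3-to-5-word display convention |

**Age in months.** `age_in_months` counts whole completed calendar months:
`(Y2−Y1)·12 + (M2−M1)`, minus one when the reference day-of-month has not
yet reached the birth day-of-month. A birth day with no counterpart in the
reference month (29–31) completes its month on the 1st of the following
month, so a child born 2004-02-29 turns 12 months on 2005-03-01. The unit
tests check this against an independent month-anniversary walk.

**Ordering and determinism.** Every output ordering is fully specified
(matches by start offset then pattern; candidates, truth, snippets, heat-map
cells by id); repeated runs are byte-identical, which the CLI tests assert.

## The review workflow

Decisions are append-only `(patient, stage, decision, reason, reviewer,
timestamp)` records. Invariants enforced at record time: one decision per
(patient, stage); a final decision requires a prior initial *pass*; an
initial *exclude* requires a reason from the shipped vocabulary
(developmental delay, isolated distal hypospadias, cloacal exstrophy,
Turner syndrome, Klinefelter syndrome, other). "Uncertain" is a terminal
outcome. The tabulation reports the funnel counts and satisfies
`uncertain + not_eligible + confirmed = initial_review_pool` once all final
decisions are in. The tool never auto-decides eligibility; the synthetic
module ships a *scripted* decision file derived from planted truth solely
to make the workflow testable.

## The comparison engine

Exact set arithmetic between confirmed-eligible sets. Yield is
`100 · confirmed / code-positive` and is rounded only at rendering (one
decimal place); fold-increase is kept as an exact ratio and rendered in
the nearest-integer "N-fold" idiom. An empty traditional arm renders the
fold as "∞" with a warning instead of erroring, because the tool must run
at sites with no traditional arm. Per-code tables count a multi-code
patient once under each qualifying code; a confirmed case with no
attributable code (e.g. known to clinicians but never coded) lands in a
`no-code` row.

## The synthetic corpus

The generator emulates the statistical structure the screen exploits, with
template-based notes (ground truth must be exact and generation offline;
no attempt at realistic clinical prose, hospital section taxonomies, or
protected health information). Each patient is drawn from a pseudo-random
stream keyed by `(seed, patient index)`, so corpora are reproducible even
under partial or parallel generation.

Default regime (chosen once to land in the operating range the screen is
designed for, and verified by a seeded multi-seed test):

* `n_patients = 2000`, `true_case_fraction = 0.01` — a rare condition at
  tertiary-referral prevalence;
* `coding_sensitivity = 0.9` — true cases usually, not always, receive a
  qualifying code;
* `nonspecific_coding_rate = 0.17` — non-cases receive qualifying codes
  often enough that the structured filter's PPV lands in the few-percent
  range (observed ≈ 4–6% over seeds);
* `noncase_keyword_rate = 0.85` — coded non-cases usually carry benign
  keyword language ("no chordee was noted", "labia were normal in
  appearance"), so the keyword stage trims only ~5–25% of the code cohort;
* `trap_rate = 0.1` — notes occasionally contain trap tokens (*oxygen*,
  *hydroxylase*, *toxoplasmosis*) that fire short patterns spuriously;
* `keyword_doc_rate = 0.95` — a planted case's phenotype is documented in
  its notes with high but imperfect probability;
* `clinic_only_fraction = 0.1` — a tenth of true cases are known to the
  clinical team but have no qualifying code in this EHR; they are
  unreachable by any EHR screen and reachable by the traditional arm;
* birth window 2005-04-01 … 2011-12-31 with the age reference at the window
  end — an 81-month recruitment span, so every generated patient satisfies
  the age criterion by construction and planted coded cases cannot be lost
  to the age gate;
* every phenotype template sentence contains at least one universal-tier
  keyword (tested), so a planted case is detectable whichever tier its
  codes select — this is what makes the end-to-end recovery of coded,
  phrase-bearing cases exactly 100% rather than approximately so.

The traditional comparator samples each true case independently with a
configurable recall (CLI default 0.3), including clinic-only cases. Under
the defaults this reproduces the observed direction of the Venn asymmetry:
many informatics-only cases, few traditional-only ones.

What passing tests on this corpus do **not** show: robustness to real
clinical language (abbreviations, OCR noise, templated negation, copy-paste
duplication), to section taxonomies that differ across hospitals, or to
coding practices correlated with phenotype severity. The generator's
independence assumptions (coding, phrasing, and traps independent given
case status) are simplifications.

## Numerical / edge-case choices

* Sex values outside {F, M} load as U with a logged warning, not an error;
  only one code's restriction depends on sex.
* A code failing its sex restriction does not qualify a patient, but other
  assigned codes still can.
* Overlapping matches from distinct patterns are all recorded; overlap
  merging happens only at rendering/snippet time (touching-but-not-
  overlapping highlight regions stay separate).
* Snippet "words" are maximal non-whitespace runs; excerpts are clipped at
  text boundaries and always contain the matched text verbatim.
* Diagnosis dates are not constrained: a qualifying code counts whenever
  assigned. Whether source systems restricted assignment dates is unknown,
  so the filter imposes nothing.
* Problem sizes in the test suite and acceptance script (corpora of
  150–2000 patients, 1000-text matcher/oracle comparisons, 5-seed
  Monte-Carlo bands) were chosen as the smallest sizes at which the checked
  regimes are stable.

## Known limitations

* No NLP: no stemmer, lemmatiser, negation detector, or relevance ranking —
  the naive matcher is the method, and its false positives are part of the
  measured behaviour.
* The exclusion-context semantics (overlap-based suppression) are this
  package's own definition of a feature that production search engines
  implement in richer ways; it defaults off.
* ICD-10 is out of scope; codes are matched as ICD-9 strings.
* The review workflow records decisions but offers no adjudication or
  inter-rater machinery.
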