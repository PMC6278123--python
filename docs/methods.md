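# Methods

## Scope and design

`cohortval` validates two longitudinal HIV biomarkers — CD4+ T-cell
counts and viral loads — held in a clinical-cohort database against the
same tests captured by a laboratory-surveillance registry.  The unit of
analysis is the adult patient starting combined antiretroviral therapy
(cART) between 2003-01-01 and 2013-12-31, administratively censored on
2014-07-31.  The pipeline is: record linkage → closest-date test
matching → eligibility/censoring/derivation → agreement statistics.
All stages operate on plain delimited-text tables (patients: code,
identity triple, site, cART start, follow-up end; results: code,
analyte, collection date, value, detection limit).

## Record linkage

The only fields both registries share are the patient's full name, the
mother's full name and the date of birth.  Names are normalized
(upper-cased, diacritics stripped via Unicode decomposition, whitespace
collapsed); birth dates are compared by exact calendar equality.  A pair
is auto-matched iff all three normalized fields agree and the triple is
unambiguous on both sides.  Everything else is routed to a review queue
for a human: pairs agreeing on exactly 2 of 3 fields (the rule that
catches a single typo'd field, including day/month-swapped birth dates),
ambiguous full-triple ties, and records with unparseable birth dates.
The queue is restricted to pairs in which at least one member is not
already auto-matched — a queue exists to resolve non-matches, not to
second-guess resolved ones.  The pipeline never adjudicates the queue;
it only emits it.

No probabilistic (Fellegi–Sunter) weights and no phonetic encodings are
used: the method under validation is exact matching plus manual review,
and the implementation deliberately stays within it.

## Closest-date test matching

Same-analyte results for a linked patient are paired one-to-one within
a symmetric window of 30 days, inclusive (|Δ| ≤ 30).  Candidate pairs
are taken greedily in ascending |Δ|, ties broken by earlier cohort date
then earlier surveillance date.  Greedy closest-date pairing alone is
not maximum-cardinality: in alternating chains a result's nearest
partner can "steal" the only admissible partner of another (e.g. cohort
days {0, 5} vs. surveillance days {−28, 1}: pairing 0↔1 strands 5,
whereas 0↔−28 and 5↔1 pairs everything).  A deterministic
augmenting-path pass therefore follows the greedy pass, rescuing any
result that can still be paired.  The final matching is maximum
cardinality (verified against exhaustive enumeration on small
instances), keeps the greedy closest-date pairs wherever they block
nothing, and involves no cost-minimizing assignment solver.  Same-day
duplicates within one source are deduplicated to the earliest-entered
record before matching and logged.

## Eligibility, censoring, derivation

Exclusions are applied in order, each patient counted once under the
first reason that applies: (1) no linkage code with the surveillance
register; (2) no cohort lab data during clinical follow-up; (3) lab data
but none on/after the cART start date.  Percentages are reported to one
decimal; the default convention is round-half-up, with truncation
available as an option because published flowcharts are frequently
truncated (1.153% printed as 1.1%) while tables round — both conventions
are supported rather than guessing intent.

Censoring: the cohort series is truncated at the administrative date
(and the patient's follow-up end); the surveillance series is further
truncated at the date of the last cohort test of the same analyte, so
the secondary source can never contribute observation time the cohort
did not have.  When the cohort holds no test of an analyte, the
surveillance series for that analyte is emptied — the strictest reading
of "no recorded date" — which also guarantees that surveillance-side
missingness for derived measures is a superset of cohort-side
missingness, the pattern real validations report.  Censoring is
idempotent and commutes with eligibility.

Derived per patient and per source:

- **Nadir CD4 before cART** — minimum over tests strictly before the
  cART start date (same-day tests count as on-treatment; a
  `pre_cart_inclusive` switch flips this convention), categorized as
  <200, [200, 350), ≥350 cells/mm³; no pre-cART test → NDA ("no data
  available"), which propagates and is never imputed.
- **Peak viral load before cART** — maximum over *detectable* pre-cART
  results (value ≥ the assay limit in force at the collection date),
  reported as copies/ml and log₁₀ copies/ml.  Below-limit results count
  qualitatively ("below") but are excluded from the quantitative
  maximum; if only below-limit results exist the quantitative peak is
  NDA while detectability is "below".  Log base 10 is the virology
  standard.
- **First ten post-cART measures** — tests on/after cART start in date
  order, CD4 quantitative, viral load as above/below flags.
- **Person-years** — (censoring bound − cART start) in days / 365.25.

The assay lower limit of detection is a year-indexed schedule (default
400 copies/ml from 2003, 80 from 2008, 40 from 2013, spanning the
40–400 range assays covered over the era); the limit in force is the
entry with the largest year not exceeding the collection year.

## Agreement battery

- **Testing rate**: ⌊100·n/py⌋ per 100 person-years.  Flooring is the
  only convention consistent with all published totals this design is
  benchmarked against (80 302/32 397 → 247; 79 997 → 246; 94 083 → 290;
  84 810 → 261).
- **Proportion CIs**: percentile bootstrap, B = 1000, mandatory seed.
  Resampling n patient-level binary outcomes with replacement makes the
  bootstrap count Binomial(n, p̂); the implementation draws it that way
  directly (distributionally identical, much faster).  Point estimates
  are 100·k/n rounded half-up to one decimal.
- **Pearson r**: product-moment formula on pairwise-complete pairs,
  two-sided p from t = r·√((n−2)/(1−r²)).  Identical (or exactly
  negated) series short-circuit to r = ±1 so the zero-discordance null
  is exact.  Zero variance raises an error naming the offending series.
- **Bland–Altman**: differences d = x − y; mean, SD (ddof 1), t-based
  95% CI of the mean difference, limits of agreement d̄ ± 1.96·s_d, and
  a two-sided one-sample t-test of zero mean difference.  Both the CI of
  the mean and the LoA are always reported side by side, because
  published agreement tables frequently print one unlabelled interval.
  With zero-variance differences the t statistics are undefined and the
  p-value is NaN (the "not calculated, SD is zero" convention).
- **Cohen's kappa**: unweighted, κ = (p_o − p_e)/(1 − p_e) with p_e from
  marginal products; p_o is computed from integer cell counts so a
  perfect diagonal yields exactly 1.  The p-value uses the asymptotic
  z-test with the Fleiss null SE; confidence intervals use the
  non-null Fleiss–Cohen–Everitt SE.  Both SEs are cross-checked against
  an independent implementation in the test suite.  Degenerate tables
  (one category in both margins, chance agreement 1) are reported as
  κ = 1 with a `degenerate` flag when perfectly diagonal — observed
  agreement is perfect and the invariant "κ = 1 iff perfect diagonal"
  is preserved — and inference is returned as NaN.  Kappa is unweighted
  even though the CD4 categories are ordinal, matching the cutoff
  literature the bands come from.
- **Interpretation bands**: kappa bins are upper-closed
  ((0.80, 1.00] "almost perfect", 0.80 itself "substantial"); |r| bins
  are lower-closed ([0.90, 1.00] "very high").  The published cutoff
  lists overlap at their boundaries; these conventions resolve every
  printed example consistently.

Site stratification is carried through every statistic (13 sites by
default), with a "Total" row that aggregates the site rows; categorized
proportions are reported both over all eligible patients (NDA as a
category) and restricted to patients non-NDA in *both* sources, so the
two sources share a denominator in the restricted panel.

## The synthetic-data generator

No registry publishes a generative model for biomarker trajectories, so
the simulator's latent process is an explicit stand-in, chosen for
qualitative realism and fully exposed as configuration:

- Latent testing: per analyte, a Poisson process at 2.5 tests per
  person-year from one year before cART start to the end of follow-up
  (follow-up exponential, mean 5 years, capped at the administrative
  date) — producing overall testing rates in the 200–300 per 100 py
  range typical of treated cohorts.
- CD4: lognormal patient baseline (median ≈ 220 cells/mm³, log-SD 0.6)
  with exponential post-treatment recovery (0.20/year on the log scale)
  and log-normal within-patient dispersion — rising means after cART.
- Viral load: log₁₀-normal before treatment (mean 4.3, SD 0.9); after
  treatment each successive test is detectable with probability
  0.30·0.92^(k−1) for count index k — detectability falling with time on
  treatment; detectable post-treatment values are drawn above the
  era's assay limit, suppressed results carry value 0.
- Observation: each latent test enters each source independently
  (missingness 10% cohort, 15% surveillance); the surveillance copy gets
  integer date jitter in ±3 days, value noise (SD 10 cells/mm³ for CD4,
  0.05 log₁₀ for VL), and each surveillance identity string suffers one
  random character edit with probability 5%.  Typos are injected only on
  the surveillance side — one dirty source suffices to exercise the
  review queue.  The surveillance detection limit is copied from the
  latent test rather than recomputed from the jittered date, so a jitter
  across a year boundary cannot retroactively change the assay.

Randomness comes from one master seed with per-patient sub-streams
(`SeedSequence([seed, patient_index])`), so runs are byte-reproducible
and a patient's data do not change when the cohort grows.

What the generator does **not** emulate: calendar-time trends in
missingness (real surveillance gaps concentrate in early years), site
heterogeneity in testing intensity, assay-level reporting quirks,
within-patient testing bursts around clinical events, or mortality and
loss to follow-up as informative censoring.  Passing tests therefore
demonstrate that the pipeline recovers known truth under independent,
stationary discordance — not that any real pair of registries agrees.

One behaviour of the defaults is worth flagging: peak-viral-load
detectability is heavily skewed (nearly every pre-treatment peak is
detectable), so its kappa is fragile — a handful of noise-flipped
borderline results can pull κ far below the raw agreement.  That is a
property of kappa under skewed margins, not a defect of either source.

## Numerical choices and degenerate inputs

- Dates are ISO-8601; all intervals are days / 365.25.
- The 30-day matching window is inclusive.
- Zero follow-up time is allowed but flagged; negative intervals raise.
- Empty pre-cART series produce NDA, never zeros.
- Bootstrap cells inside the pipeline consume one seeded generator in
  fixed table order, so whole report tables are byte-reproducible.
- Configuration errors name the offending field; structural input
  errors (duplicate codes, mixed analytes) raise before any computation.

## Problem sizes

The test suite exercises cohorts of 60–500 patients for unit and
property tests and 2,000 patients for the end-to-end zero-discordance
null; kappa parameter recovery uses 200 replicates of 250 paired
categories.  The acceptance script runs the published-count arithmetic
(instant) plus the 2,000-patient null pipeline.  These sizes were chosen
so the full battery runs comfortably on a laptop while keeping every
statistical check at ≥3-SE resolution.
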