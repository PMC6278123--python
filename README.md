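# cohortval

Validation of clinical-cohort laboratory biomarkers against a
laboratory-surveillance registry.

## The problem

Longitudinal HIV cohorts built from medical-record abstraction hold two
biomarkers that drive almost every downstream analysis: the CD4+ T-cell
count (cells/mm³) and the HIV viral load (RNA copies/ml, analysed as
log₁₀ and as detectable vs. below the assay limit).  The same tests are
usually also captured, independently, by a national laboratory
surveillance system.  Before either database is trusted for
epidemiological work, the two must be shown to agree — which requires
linking patients across registries that share only free-text identity
fields, pairing tests that were recorded under slightly different dates,
deriving the per-patient summary measures under common censoring rules,
and then quantifying agreement.

`cohortval` implements that full validation design as a reusable,
tested pipeline for biostatisticians and epidemiologists:

1. **Record linkage** — normalized exact matching on the identity triple
   (patient name, mother's name, birth date); anything short of full
   agreement goes to a review queue rather than being guessed.
2. **Test matching** — one-to-one closest-date pairing of same-analyte
   results within a 30-day window.
3. **Derivation** — eligibility flowchart, administrative and per-analyte
   censoring, person-years, pre-treatment nadir CD4 (categorized at
   200 and 350 cells/mm³), pre-treatment peak viral load (quantitative
   and detectable/below-limit), and the first ten post-treatment
   measures.
4. **Agreement battery** — testing rates per 100 person-years
   (⌊100·n/py⌋), bootstrap percentile CIs for proportions (B = 1000),
   Pearson correlation with t-based inference, Bland–Altman analysis
   (mean difference d̄, limits of agreement d̄ ± 1.96·s_d, test of zero
   mean difference), and Cohen's kappa κ = (p_o − p_e)/(1 − p_e) with
   asymptotic standard errors and the conventional interpretation bands
   (Viera & Garrett for κ, Mukaka for |r|).

Because real registry data are confidential, the package ships a
**paired-registry simulator** with known ground truth: one latent test
process per patient, observed by both sources with independent
missingness, date jitter, value noise and identity typos.  Every stage
of the pipeline is validated against that truth.

## Worked example

```python
from cohortval import (testing_rate, proportion_ci, pearson,
                       bland_altman, cohen_kappa, interpret_kappa)

testing_rate(n_tests=80302, person_years=32397.0).rate_per_100py
# 247  -> 247 CD4 tests per 100 person-years of follow-up

ci = proportion_ci(k=3878, n=8007, B=1000, seed=1)
(ci.p_hat, ci.ci_low, ci.ci_high)
# (48.4, 47.4, 49.5) -> 48.4% of patients had a nadir CD4 < 200 cells/mm3,
#                       with a 1000-sample bootstrap percentile 95% CI
```

Running the full pipeline on synthetic registries
(`python examples/06_full_pipeline.py`) prints, among other tables:

```
      measure  n_pairs        r  mean_diff  diff_p_value
    cd4_nadir      447 0.980911  -0.666667      0.667320
vl_log10_peak      436 0.854803   0.017688      0.392166
```

i.e. with the default discordance levels (5% identity typos, ±3-day date
jitter, mild value noise, 10/15% per-source missingness) the nadir CD4
derived independently from the two sources correlates at r = 0.98 and
differs on average by −0.7 cells/mm³ — statistically indistinguishable
from zero (p = 0.67), the signature of two interchangeable databases.
The remaining `examples/` scripts walk through each stage in isolation.

A command-line interface mirrors the stages:

```bash
cohortval simulate --out reg --seed 5
cohortval link --cohort reg/cohort_patients.csv \
               --surveillance reg/surveillance_patients.csv --out linked
cohortval all --config pipeline.yml --out report --seed 5
```

## Layout

- `src/cohortval/` — library (`simulate`, `linkage`, `matching`,
  `derivation`, `agreement`, `pipeline`, `cli`)
- `examples/` — one narrative script per capability
- `docs/methods.md` — models, assumptions, numerical choices, limitations
- `tests/` — unit, property and acceptance suites
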