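"""Run the whole validation pipeline on synthetic registries.

simulate -> link -> match -> derive -> validate, producing the full
report: testing rates, categorized proportions with bootstrap CIs,
first-ten post-treatment series, correlation/Bland-Altman and kappa
panels, each per site plus an overall row.
"""

from cohortval import PipelineConfig, SimConfig, run_pipeline

cfg = PipelineConfig(
    sim=SimConfig(n_patients=600, seed=11),
    seed=11,
    bootstrap_samples=500,
)
res = run_pipeline(cfg)

print(res.eligibility.to_frame().to_string(index=False))

rates = res.tables["rates"]
total = rates.loc[rates["site"] == "Total"].iloc[0]
print(f"\noverall CD4 testing rate: cohort {total['cd4_cohort_n']} tests "
      f"({total['cd4_cohort_rate']}/100py) vs surveillance "
      f"{total['cd4_surveillance_n']} ({total['cd4_surveillance_rate']}/100py)")

kap = res.tables["kappa"]
print("\nkappa per measure (overall):")
print(kap.loc[kap["site"] == "Total"].to_string(index=False))

cba = res.tables["correlation_ba"]
print("\ncorrelation / Bland-Altman (overall):")
print(cba.loc[cba["site"] == "Total",
              ["measure", "n_pairs", "r", "mean_diff", "diff_p_value"]]
      .to_string(index=False))

# With the default discordance levels (5% typos, ±3-day jitter, mild
# value noise, 10/15% missingness) the quantitative measures agree almost
# perfectly: r near 1 and mean differences statistically indistinguishable
# from zero.  The CD4 category kappa stays "almost perfect", while the
# viral-load detectability kappa is much lower than its raw agreement:
# nearly every peak is detectable, so chance agreement is high and the
# handful of noise-flipped borderline results dominate the chance
# correction — a known fragility of kappa under skewed margins.
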