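"""Link the two registries on the normalized identity triple.

A pair is auto-matched only when full name, mother's name and birth date
all agree after normalization (upper case, diacritics stripped, collapsed
whitespace).  Near-misses — one typo'd field, ambiguous ties — go to a
review queue instead of being guessed.
"""

from cohortval import SimConfig, generate, link, linkage_recovery

reg = generate(SimConfig(n_patients=200, seed=42, typo_rate=0.05))
res = link(reg.cohort_patients, reg.surveillance_patients)

print(f"auto-matched pairs:   {len(res.matched)}")
print(f"unmatched cohort:     {len(res.unmatched_cohort)}")
print(f"review-queue pairs:   {len(res.review_queue)}")
print(res.review_queue.head(5).to_string(index=False))

sens, fmr = linkage_recovery(res, reg.truth)
print(f"\nsensitivity {sens:.3f}, false-match rate {fmr:.3f}")
# With a 5% per-string typo rate both names must survive untouched, so
# sensitivity sits near (1 - 0.05)^2 ~ 0.90; exact matching on globally
# unique triples cannot cross-link people, hence a zero false-match rate.
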