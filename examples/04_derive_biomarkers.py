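"""Derive the per-patient summary biomarkers under the censoring rules.

For one patient: the nadir (lowest) CD4 count strictly before cART start
with its clinical category, and the peak (highest) viral load before
cART with its detectability at the era's assay limit.
"""

import pandas as pd

from cohortval import (categorize_cd4, first_n_post_cart, nadir_cd4_pre_cart,
                       peak_vl_pre_cart, person_years)

cart_start = pd.Timestamp("2008-06-15")

cd4 = pd.DataFrame({
    "collection_date": pd.to_datetime(
        ["2008-01-10", "2008-04-02", "2008-07-01", "2009-01-20", "2009-08-05"]),
    "value": [310.0, 180.0, 255.0, 340.0, 490.0],
})
vl = pd.DataFrame({
    "collection_date": pd.to_datetime(
        ["2008-02-01", "2008-05-01", "2008-09-01", "2009-06-01"]),
    "value": [48000.0, 125000.0, 0.0, 0.0],
    "lod": [400.0, 400.0, 80.0, 80.0],
})

nadir = nadir_cd4_pre_cart(cd4, cart_start)
peak = peak_vl_pre_cart(vl, cart_start)
py = person_years(cart_start, "2014-07-31")

print(f"nadir CD4 before cART: {nadir:.0f} cells/mm3 "
      f"({categorize_cd4(nadir)})")
print(f"peak VL before cART:   {peak.copies:.0f} copies/ml "
      f"(log10 {peak.log10:.2f}, {peak.detectability})")
print(f"person-years to administrative censoring: {py:.2f}")
print("\nfirst post-cART CD4 counts:")
print(first_n_post_cart(cd4, cart_start)["value"].tolist())

# Only the two pre-treatment CD4 tests compete for the nadir (180 < 310,
# category <200, advanced immunosuppression); the suppressed post-cART
# viral loads (value 0, below the 80 copies/ml limit) never touch the
# pre-cART peak.
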