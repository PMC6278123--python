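"""Derivation contracts: eligibility flowchart, censoring, person-years,
nadir/peak rules with detection limits, categorization boundaries and
the first-ten post-treatment series."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from cohortval import (DataError, apply_eligibility, categorize_cd4, censor,
                       dichotomize_vl, first_n_post_cart, nadir_cd4_pre_cart,
                       peak_vl_pre_cart, person_years)
from cohortval.derivation import EligibilityReport, percent

CART = pd.Timestamp("2008-06-15")


def series(dates, values, lod=None):
    df = pd.DataFrame({"collection_date": pd.to_datetime(dates),
                       "value": [float(v) for v in values]})
    if lod is not None:
        df["lod"] = float(lod) if np.isscalar(lod) else [float(x) for x in lod]
    return df


class TestPercentConventions:
    def test_half_up_matches_published_rounding(self):
        assert percent(2153, 8007) == 26.9
        assert percent(136, 8674) == 1.6

    def test_truncation_matches_flowchart_style(self):
        assert percent(100, 8674, "truncate") == 1.1
        assert percent(431, 8674, "truncate") == 4.9
        # same ratios under half-up differ at the boundary
        assert percent(431, 8674, "half_up") == 5.0


class TestEligibility:
    def _patients(self):
        return pd.DataFrame({
            "code": ["C1", "C2", "C3", "C4"],
            "site": ["I"] * 4,
            "cart_start": pd.to_datetime(["2008-01-01"] * 4),
            "followup_end": pd.to_datetime(["2012-01-01"] * 4),
        })

    def test_exclusion_reasons_in_order_first_wins(self):
        patients = self._patients()
        matched = {"C2": "S2", "C3": "S3", "C4": "S4"}  # C1 unlinked
        results = pd.DataFrame({
            # C2 linked but no labs at all; C3 labs only before cART;
            # C4 fully eligible
            "code": ["C3", "C4", "C4"],
            "analyte": ["CD4", "CD4", "VL"],
            "collection_date": pd.to_datetime(["2007-06-01", "2008-02-01", "2008-03-01"]),
            "value": [150.0, 200.0, 1000.0],
        })
        eligible, rep = apply_eligibility(patients, matched, results, "2014-07-31")
        assert eligible == ["C4"]
        assert (rep.excluded_no_link, rep.excluded_no_labs_followup,
                rep.excluded_no_labs_post_cart) == (1, 1, 1)
        assert rep.n_eligible + 3 == rep.n_enrolled

    def test_all_linked_with_labs_zero_exclusions(self):
        patients = self._patients()
        matched = {c: c.replace("C", "S") for c in patients["code"]}
        results = pd.DataFrame({
            "code": ["C1", "C2", "C3", "C4"],
            "analyte": ["CD4"] * 4,
            "collection_date": pd.to_datetime(["2009-01-01"] * 4),
            "value": [300.0] * 4,
        })
        eligible, rep = apply_eligibility(patients, matched, results, "2014-07-31")
        assert len(eligible) == 4 and rep.n_eligible == 4

    def test_counts_equal_bruteforce_per_patient_oracle(self, small_registries):
        reg = small_registries
        from cohortval import link
        res = link(reg.cohort_patients, reg.surveillance_patients)
        eligible, rep = apply_eligibility(
            reg.cohort_patients, res.matched, reg.cohort_results, "2014-07-31")
        # oracle: classify each patient independently
        admin = pd.Timestamp("2014-07-31")
        n = {"link": 0, "labs": 0, "post": 0, "ok": 0}
        for p in reg.cohort_patients.itertuples(index=False):
            if p.code not in res.matched:
                n["link"] += 1
                continue
            labs = reg.cohort_results.loc[reg.cohort_results["code"] == p.code]
            labs = labs.loc[pd.to_datetime(labs["collection_date"])
                            <= min(admin, p.followup_end)]
            if labs.empty:
                n["labs"] += 1
            elif not (pd.to_datetime(labs["collection_date"]) >= p.cart_start).any():
                n["post"] += 1
            else:
                n["ok"] += 1
        assert (rep.excluded_no_link, rep.excluded_no_labs_followup,
                rep.excluded_no_labs_post_cart, rep.n_eligible) == \
            (n["link"], n["labs"], n["post"], n["ok"])

    def test_report_partition_enforced(self):
        with pytest.raises(DataError):
            EligibilityReport(n_enrolled=10, n_eligible=5, excluded_no_link=1,
                              excluded_no_labs_followup=1, excluded_no_labs_post_cart=1)


class TestCensor:
    def test_tests_after_bound_removed(self):
        s = series(["2013-01-01", "2014-06-01", "2014-09-01"], [1, 2, 3])
        out = censor(s, "2014-07-31")
        assert list(out["value"]) == [1.0, 2.0]

    def test_surveillance_bound_is_last_cohort_date(self):
        s = series(["2013-01-01", "2013-06-01"], [1, 2])
        out = censor(s, "2014-07-31", last_cohort_test_date="2013-03-01")
        assert list(out["value"]) == [1.0]

    def test_idempotent_and_no_op_below_bounds(self):
        s = series(["2010-01-01", "2011-01-01"], [1, 2])
        once = censor(s, "2014-07-31")
        pd.testing.assert_frame_equal(once, censor(once, "2014-07-31"))
        pd.testing.assert_frame_equal(once, s)

    @given(st.lists(st.integers(0, 4000), min_size=0, max_size=30),
           st.integers(0, 4000))
    @settings(max_examples=100, derandomize=True, deadline=None)
    def test_matches_filter_comprehension_oracle(self, offsets, bound_offset):
        base = pd.Timestamp("2004-01-01")
        s = series([base + pd.Timedelta(days=d) for d in offsets],
                   list(range(len(offsets))))
        bound = base + pd.Timedelta(days=bound_offset)
        out = censor(s, bound)
        expected = [v for d, v in zip(s["collection_date"], s["value"]) if d <= bound]
        assert list(out["value"]) == expected


class TestPersonYears:
    def test_one_year(self):
        assert person_years("2003-01-01", "2004-01-01") == pytest.approx(
            1.0, abs=1 / 365.25)

    def test_zero_interval_is_zero(self):
        assert person_years("2003-01-01", "2003-01-01") == 0.0

    def test_negative_interval_rejected(self):
        with pytest.raises(DataError):
            person_years("2004-01-01", "2003-01-01")

    def test_cohort_sum_equals_per_patient_oracle(self, small_registries):
        pat = small_registries.cohort_patients
        admin = pd.Timestamp("2014-07-31")
        total = sum(person_years(p.cart_start, min(admin, p.followup_end))
                    for p in pat.itertuples(index=False))
        oracle = ((pat["followup_end"].clip(upper=admin) - pat["cart_start"])
                  .dt.days / 365.25).sum()
        assert total == pytest.approx(oracle, rel=1e-12)


class TestNadirPeak:
    def test_nadir_is_minimum_before_cart(self):
        s = series(["2008-01-01", "2008-03-01", "2008-05-01"], [310, 180, 420])
        assert nadir_cd4_pre_cart(s, CART) == 180.0
        assert categorize_cd4(180.0) == "<200"

    def test_same_day_test_counts_post_cart_by_default(self):
        s = series([CART], [100])
        assert nadir_cd4_pre_cart(s, CART) is None
        assert nadir_cd4_pre_cart(s, CART, inclusive=True) == 100.0

    def test_no_pre_cart_tests_is_nda(self):
        s = series(["2009-01-01"], [300])
        assert nadir_cd4_pre_cart(s, CART) is None
        peak = peak_vl_pre_cart(series(["2009-01-01"], [1000], lod=400), CART)
        assert peak.copies is None and peak.detectability is None

    def test_peak_vl_below_limit_rules(self):
        # detectable max wins; below-limit results only set detectability
        s = series(["2008-01-01", "2008-02-01", "2008-03-01"],
                   [0, 50000, 200], lod=400)
        peak = peak_vl_pre_cart(s, CART)
        assert peak.copies == 50000.0
        assert peak.log10 == pytest.approx(np.log10(50000.0))
        assert peak.detectability == "above"
        only_below = series(["2008-01-01", "2008-02-01"], [0, 200], lod=400)
        peak = peak_vl_pre_cart(only_below, CART)
        assert peak.copies is None and peak.log10 is None
        assert peak.detectability == "below"

    @given(st.lists(st.integers(1, 1500), min_size=1, max_size=20))
    @settings(max_examples=100, derandomize=True, deadline=None)
    def test_nadir_peak_match_min_max_oracle(self, values):
        dates = [pd.Timestamp("2008-01-01") + pd.Timedelta(days=i) for i in range(len(values))]
        cd4 = series(dates, values)
        assert nadir_cd4_pre_cart(cd4, CART) == min(values)
        vl = series(dates, values, lod=40)
        peak = peak_vl_pre_cart(vl, CART)
        detectable = [v for v in values if v >= 40]
        assert peak.copies == (max(detectable) if detectable else None)


class TestCategorization:
    @pytest.mark.parametrize("v,cat", [
        (0, "<200"), (199, "<200"), (199.9, "<200"),
        (200, "200-349"), (349, "200-349"), (349.9, "200-349"),
        (350, ">=350"), (1500, ">=350"),
    ])
    def test_half_open_middle_bin(self, v, cat):
        assert categorize_cd4(v) == cat

    def test_boundary_sweep_matches_interval_oracle(self):
        for v in np.arange(0, 600, 0.5):
            expected = "<200" if v < 200 else ("200-349" if v < 350 else ">=350")
            assert categorize_cd4(float(v)) == expected

    def test_negative_cd4_rejected(self):
        with pytest.raises(DataError):
            categorize_cd4(-1.0)

    def test_vl_dichotomy_at_assay_limit(self):
        assert dichotomize_vl(500.0, 400.0) == "above"
        assert dichotomize_vl(399.0, 400.0) == "below"
        assert dichotomize_vl(40.0, 40.0) == "above"


class TestFirstN:
    def test_short_series_returned_whole(self):
        s = series(["2009-01-01", "2009-06-01", "2010-01-01"], [1, 2, 3])
        out = first_n_post_cart(s, CART, n=10)
        assert list(out["value"]) == [1.0, 2.0, 3.0]

    def test_empty_series_gives_empty_list(self):
        s = series([], [])
        assert len(first_n_post_cart(s, CART)) == 0

    def test_ordering_and_truncation_match_sort_oracle(self, rng):
        offsets = rng.integers(-400, 2000, size=30)
        dates = [CART + pd.Timedelta(days=int(d)) for d in offsets]
        s = series(dates, range(30))
        out = first_n_post_cart(s, CART, n=10)
        post = sorted((d, v) for d, v in zip(dates, map(float, range(30))) if d >= CART)
        assert list(out["value"]) == [v for _, v in post[:10]]
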