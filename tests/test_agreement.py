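"""Agreement-statistic contracts, each checked against an independent
oracle: hand formulas for Pearson/Bland-Altman/kappa, statsmodels for the
kappa standard errors, the Wald formula for large-n bootstrap CIs, and
the published interpretation cutoffs."""

import math

import numpy as np
import pytest
from scipy import stats

from cohortval import (DataError, InputError, bland_altman, cohen_kappa,
                       interpret_kappa, interpret_r, pearson, proportion_ci)
from cohortval import testing_rate as floored_testing_rate


class TestTestingRate:
    @pytest.mark.parametrize("n,py,rate", [
        (80302, 32397, 247), (79997, 32397, 246),
        (94083, 32397, 290), (84810, 32397, 261),
        (0, 100, 0),
    ])
    def test_floored_rate(self, n, py, rate):
        assert floored_testing_rate(n, py).rate_per_100py == rate

    def test_nonpositive_person_years_rejected(self):
        with pytest.raises(InputError):
            floored_testing_rate(10, 0.0)


class TestProportionCI:
    def test_point_estimates_round_half_up(self):
        assert proportion_ci(3878, 8007, seed=0).p_hat == 48.4
        assert proportion_ci(2923, 5753, seed=0).p_hat == 50.8
        assert proportion_ci(975, 8007, seed=0).p_hat == 12.2

    def test_degenerate_zero_count(self):
        ci = proportion_ci(0, 100, seed=1)
        assert (ci.p_hat, ci.ci_low, ci.ci_high) == (0.0, 0.0, 0.0)

    def test_out_of_range_count_rejected(self):
        with pytest.raises(InputError):
            proportion_ci(11, 10)

    @pytest.mark.parametrize("k,n", [(3878, 8007), (500, 1000), (2153, 8007)])
    def test_large_n_close_to_wald_oracle(self, k, n):
        ci = proportion_ci(k, n, B=1000, seed=5)
        p = k / n
        half = 1.96 * math.sqrt(p * (1 - p) / n) * 100
        assert ci.ci_low == pytest.approx(p * 100 - half, abs=0.2)
        assert ci.ci_high == pytest.approx(p * 100 + half, abs=0.2)

    def test_ci_width_shrinks_with_sample_size(self):
        wide = proportion_ci(300, 1000, seed=9)
        narrow = proportion_ci(1200, 4000, seed=9)
        assert (narrow.ci_high - narrow.ci_low) < (wide.ci_high - wide.ci_low)

    def test_bounds_bracket_point_estimate(self):
        for seed in range(5):
            ci = proportion_ci(137, 911, seed=seed)
            assert ci.ci_low <= ci.p_hat <= ci.ci_high


class TestPearson:
    def test_perfect_lines(self, rng):
        x = rng.normal(size=20)
        r, p = pearson(x, x)
        assert r == 1.0 and p == 0.0
        r, _ = pearson(x, -x)
        assert r == -1.0

    def test_five_point_covariance_oracle(self):
        x = np.array([1.0, 2.0, 4.0, 7.0, 11.0])
        y = np.array([2.0, 1.0, 5.0, 8.0, 9.0])
        n = 5
        sxy = (x * y).sum() - x.sum() * y.sum() / n
        sxx = (x * x).sum() - x.sum() ** 2 / n
        syy = (y * y).sum() - y.sum() ** 2 / n
        r_oracle = sxy / math.sqrt(sxx * syy)
        t = r_oracle * math.sqrt((n - 2) / (1 - r_oracle**2))
        p_oracle = 2 * stats.t.sf(abs(t), n - 2)
        r, p = pearson(x, y)
        assert r == pytest.approx(r_oracle, abs=1e-12)
        assert p == pytest.approx(p_oracle, abs=1e-12)

    def test_matches_scipy_cross_check(self, rng):
        x = rng.normal(size=40)
        y = 0.6 * x + rng.normal(size=40)
        r, p = pearson(x, y)
        r2, p2 = stats.pearsonr(x, y)
        assert r == pytest.approx(r2, abs=1e-12)
        assert p == pytest.approx(p2, rel=1e-9)

    def test_linear_transform_invariance(self, rng):
        x = rng.normal(size=25)
        y = rng.normal(size=25)
        r0, _ = pearson(x, y)
        r1, _ = pearson(3.5 * x + 2.0, y)
        assert r1 == pytest.approx(r0, abs=1e-12)
        r2, _ = pearson(-2.0 * x, y)
        assert r2 == pytest.approx(-r0, abs=1e-12)

    def test_nda_pairs_dropped(self):
        x = np.array([1.0, 2.0, np.nan, 4.0, 5.0])
        y = np.array([1.1, 2.2, 3.0, np.nan, 5.2])
        r, _ = pearson(x, y)
        r_ref, _ = pearson(np.array([1.0, 2.0, 5.0]), np.array([1.1, 2.2, 5.2]))
        assert r == pytest.approx(r_ref)

    def test_zero_variance_names_offending_series(self):
        with pytest.raises(DataError, match="y"):
            pearson([1.0, 2.0, 3.0], [5.0, 5.0, 5.0])


class TestBlandAltman:
    def test_identical_series(self, rng):
        x = rng.normal(size=10)
        ba = bland_altman(x, x)
        assert ba.mean_diff == 0.0 and ba.sd_diff == 0.0
        assert math.isnan(ba.p_value)  # zero-variance differences: no test

    def test_constant_offset_collapses_loa(self, rng):
        # quarter-unit grid keeps x - 3.0 exactly representable
        x = rng.integers(-40, 40, size=12) / 4.0
        ba = bland_altman(x, x - 3.0)
        assert ba.mean_diff == pytest.approx(3.0)
        assert ba.sd_diff == 0.0
        assert ba.loa_low == ba.loa_high == pytest.approx(3.0)

    def test_six_pair_hand_oracle(self):
        x = np.array([210.0, 180.0, 455.0, 322.0, 97.0, 510.0])
        y = np.array([205.0, 190.0, 450.0, 310.0, 105.0, 500.0])
        d = x - y
        mean = d.mean()
        sd = math.sqrt(((d - mean) ** 2).sum() / 5)
        t = mean / (sd / math.sqrt(6))
        p = 2 * stats.t.sf(abs(t), 5)
        tc = stats.t.ppf(0.975, 5)
        ba = bland_altman(x, y)
        assert ba.mean_diff == pytest.approx(mean, abs=1e-10)
        assert ba.sd_diff == pytest.approx(sd, abs=1e-10)
        assert ba.ci_mean_low == pytest.approx(mean - tc * sd / math.sqrt(6), abs=1e-10)
        assert ba.loa_high == pytest.approx(mean + 1.96 * sd, abs=1e-10)
        assert ba.p_value == pytest.approx(p, abs=1e-10)

    def test_loa_bracket_mean_and_ci_narrower(self, rng):
        x = rng.normal(size=30)
        y = x + rng.normal(scale=0.5, size=30)
        ba = bland_altman(x, y)
        assert ba.loa_low <= ba.mean_diff <= ba.loa_high
        assert (ba.ci_mean_high - ba.ci_mean_low) < (ba.loa_high - ba.loa_low)

    def test_single_pair_rejected(self):
        with pytest.raises(InputError):
            bland_altman([1.0], [2.0])


class TestKappa:
    def test_perfect_agreement(self):
        res = cohen_kappa(list("AABBC"), list("AABBC"))
        assert res.kappa == 1.0
        assert res.band == "almost perfect"

    def test_2x2_counts_formula_oracle(self):
        # table [[20, 5], [10, 65]]
        a = ["pos"] * 25 + ["neg"] * 75
        b = ["pos"] * 20 + ["neg"] * 5 + ["pos"] * 10 + ["neg"] * 65
        n = 100
        po = (20 + 65) / n
        pe = (25 / n) * (30 / n) + (75 / n) * (70 / n)
        oracle = (po - pe) / (1 - pe)
        res = cohen_kappa(a, b, categories=["pos", "neg"])
        assert res.kappa == pytest.approx(oracle, abs=1e-12)
        assert res.table.loc["pos", "pos"] == 20 and res.table.loc["neg", "neg"] == 65

    def test_independent_sequences_near_zero(self, rng):
        n = 4000
        a = rng.integers(0, 3, n)
        b = rng.integers(0, 3, n)
        res = cohen_kappa(a, b, categories=[0, 1, 2])
        assert abs(res.kappa) < 3 * res.se0

    def test_standard_errors_match_statsmodels(self, rng):
        from statsmodels.stats.inter_rater import cohens_kappa as sm_kappa
        for _ in range(5):
            a = rng.integers(0, 3, 150)
            b = np.where(rng.random(150) < 0.6, a, rng.integers(0, 3, 150))
            res = cohen_kappa(a, b, categories=[0, 1, 2])
            sm = sm_kappa(res.table.values)
            assert res.kappa == pytest.approx(sm.kappa, abs=1e-12)
            assert res.se == pytest.approx(math.sqrt(sm.var_kappa), abs=1e-12)
            assert res.se0 == pytest.approx(math.sqrt(sm.var_kappa0), abs=1e-12)
            assert res.p_value == pytest.approx(sm.pvalue_two_sided, rel=1e-9)

    def test_degenerate_single_category_perfect_diagonal(self):
        res = cohen_kappa(["x"] * 8, ["x"] * 8)
        assert res.degenerate and res.kappa == 1.0
        assert math.isnan(res.p_value)

    def test_confidence_interval_covers_generator_concordance(self, rng):
        # b copies a with probability c, else redraws from the marginal:
        # analytic kappa equals c; 95% CIs should cover c ~95% of the time
        c = 0.8
        q = np.array([0.5, 0.3, 0.2])
        hits = 0
        B = 200
        for _ in range(B):
            a = rng.choice(3, size=300, p=q)
            redraw = rng.choice(3, size=300, p=q)
            b = np.where(rng.random(300) < c, a, redraw)
            res = cohen_kappa(a, b, categories=[0, 1, 2])
            lo, hi = res.confint()
            hits += lo <= c <= hi
        assert hits / B >= 0.90


class TestInterpretationBands:
    @pytest.mark.parametrize("k,band", [
        (0.932, "almost perfect"), (0.996, "almost perfect"),
        (0.80, "substantial"), (0.805, "almost perfect"),
        (0.5, "moderate"), (0.15, "slight"),
        (0.0, "less than chance"), (-0.4, "less than chance"),
    ])
    def test_kappa_bands(self, k, band):
        assert interpret_kappa(k) == band

    @pytest.mark.parametrize("r,band", [
        (0.971, "very high"), (0.90, "very high"), (0.85, "high"),
        (0.70, "high"), (0.6, "moderate"), (0.4, "low"),
        (-0.95, "very high"), (0.1, "negligible"),
    ])
    def test_r_bands_use_magnitude(self, r, band):
        assert interpret_r(r) == band

    def test_out_of_range_rejected(self):
        with pytest.raises(InputError):
            interpret_kappa(1.2)
        with pytest.raises(InputError):
            interpret_r(-1.5)
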