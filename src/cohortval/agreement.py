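"""Agreement and testing-rate statistics.

Implements the validation battery applied to the paired derived
measures: person-year testing rates, bootstrap percentile confidence
intervals for proportions, the Pearson product-moment correlation with
its t-based test, Bland-Altman paired-difference analysis (mean
difference, its t-based CI, 1.96-SD limits of agreement, and the test of
zero mean difference), and Cohen's unweighted kappa with asymptotic
standard errors.  Interpretation bands follow the conventional
epidemiological cutoffs: Viera & Garrett for kappa (0.81-1.00 "almost
perfect") and Mukaka's rule of thumb for |r| (0.90-1.00 "very high").
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .derivation import percent
from .errors import DataError, InputError

__all__ = [
    "RateResult", "ProportionCI", "BlandAltman", "KappaResult",
    "testing_rate", "proportion_ci", "pearson", "bland_altman",
    "cohen_kappa", "interpret_kappa", "interpret_r",
]


# ---------------------------------------------------------------- rates

@dataclass(frozen=True)
class RateResult:
    """Testing rate per 100 person-years, floored to an integer."""

    n_tests: int
    person_years: float
    rate_per_100py: int


def testing_rate(n_tests: int, person_years: float) -> RateResult:
    """floor(100 * n_tests / person_years)."""
    if person_years <= 0:
        raise InputError("person_years must be positive")
    if n_tests < 0:
        raise InputError("n_tests must be >= 0")
    return RateResult(n_tests, person_years,
                      math.floor(100.0 * n_tests / person_years))


# ---------------------------------------------------- bootstrap proportion

@dataclass(frozen=True)
class ProportionCI:
    """Proportion (percent, 1 decimal) with a percentile bootstrap CI."""

    k: int
    n: int
    p_hat: float
    ci_low: float
    ci_high: float
    B: int = 1000
    method: str = "percentile bootstrap"


def proportion_ci(k: int, n: int, B: int = 1000,
                  seed: int | None = None,
                  rng: np.random.Generator | None = None) -> ProportionCI:
    """Percentile bootstrap CI for a binomial proportion.

    Resampling the n patient-level binary outcomes with replacement makes
    each bootstrap count Binomial(n, k/n); the resample is drawn that way
    directly.  Bounds are the 2.5th/97.5th percentiles of the B resampled
    proportions; the point estimate is 100*k/n rounded half-up to one
    decimal.
    """
    if n <= 0:
        raise InputError("n must be positive")
    if not 0 <= k <= n:
        raise InputError(f"k={k} outside [0, n={n}]")
    if rng is None:
        rng = np.random.default_rng(seed)
    boots = rng.binomial(n, k / n, size=B) / n * 100.0
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return ProportionCI(
        k=k, n=n, p_hat=percent(k, n),
        ci_low=round(float(lo), 1), ci_high=round(float(hi), 1), B=B,
    )


# ------------------------------------------------------------- pearson

def _complete_pairs(x, y, name_x="x", name_y="y"):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise InputError("series lengths differ")
    keep = ~(np.isnan(x) | np.isnan(y))
    return x[keep], y[keep]


def pearson(x, y, name_x: str = "x", name_y: str = "y") -> tuple[float, float]:
    """Product-moment correlation with a two-sided t-based p-value.

    NaN pairs are dropped (pairwise-complete).  Requires at least three
    complete pairs and nonzero variance in both series.
    """
    x, y = _complete_pairs(x, y)
    n = len(x)
    if n < 3:
        raise InputError(f"need at least 3 complete pairs, got {n}")
    sx, sy = x.std(ddof=1), y.std(ddof=1)
    if sx == 0:
        raise DataError(f"series {name_x!r} has zero variance")
    if sy == 0:
        raise DataError(f"series {name_y!r} has zero variance")
    # identical (or exactly negated) series are perfectly correlated by
    # definition; bypass the formula's last-ulp rounding
    if np.array_equal(x, y):
        return 1.0, 0.0
    if np.array_equal(x, -y):
        return -1.0, 0.0
    r = float(np.cov(x, y, ddof=1)[0, 1] / (sx * sy))
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        return r, 0.0
    t = r * math.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * stats.t.sf(abs(t), df=n - 2)
    return r, float(p)


# --------------------------------------------------------- Bland-Altman

@dataclass(frozen=True)
class BlandAltman:
    """Paired-difference agreement summary for d = x − y.

    ``ci_mean_low``/``ci_mean_high`` is the t-based 95% CI of the mean
    difference; ``loa_low``/``loa_high`` are the 1.96-SD limits of
    agreement; ``p_value`` tests mean difference = 0 (two-sided, one
    sample t).  With zero-variance differences the t statistics are
    undefined and the p-value is NaN.
    """

    n_pairs: int
    mean_diff: float
    sd_diff: float
    ci_mean_low: float
    ci_mean_high: float
    loa_low: float
    loa_high: float
    p_value: float


def bland_altman(x, y) -> BlandAltman:
    """Bland-Altman analysis of paired measurements (differences x − y)."""
    x, y = _complete_pairs(x, y)
    n = len(x)
    if n < 2:
        raise InputError(f"need at least 2 complete pairs, got {n}")
    d = x - y
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    if sd == 0.0:
        return BlandAltman(n, mean, 0.0, mean, mean, mean, mean, float("nan"))
    tcrit = stats.t.ppf(0.975, df=n - 1)
    se = sd / math.sqrt(n)
    _, p = stats.ttest_1samp(d, 0.0)
    return BlandAltman(
        n_pairs=n, mean_diff=mean, sd_diff=sd,
        ci_mean_low=mean - tcrit * se, ci_mean_high=mean + tcrit * se,
        loa_low=mean - 1.96 * sd, loa_high=mean + 1.96 * sd,
        p_value=float(p),
    )


# --------------------------------------------------------------- kappa

@dataclass
class KappaResult:
    """Cohen's unweighted kappa with asymptotic inference.

    ``p_value`` is from the z-test of kappa = 0 using the Fleiss null
    standard error; ``se`` is the non-null (Fleiss-Cohen-Everitt)
    standard error used for confidence intervals.  ``degenerate`` marks
    tables where chance agreement is 1 (a single category on both
    margins): a perfectly diagonal such table is reported as kappa = 1
    (perfect observed agreement) with undefined inference.
    """

    kappa: float
    p_value: float
    n_pairs: int
    table: pd.DataFrame
    band: str
    se: float = float("nan")
    se0: float = float("nan")
    degenerate: bool = False

    def confint(self, level: float = 0.95) -> tuple[float, float]:
        z = stats.norm.ppf(0.5 + level / 2.0)
        return self.kappa - z * self.se, self.kappa + z * self.se


def cohen_kappa(cat_a, cat_b, categories=None) -> KappaResult:
    """Cohen's kappa between two equal-length category sequences.

    kappa = (p_o − p_e) / (1 − p_e) with chance agreement p_e from the
    marginal products.  Missing-pair handling is the caller's job (NDA
    pairs are excluded before the call).
    """
    a = pd.Series(list(cat_a))
    b = pd.Series(list(cat_b))
    if len(a) != len(b):
        raise InputError("category sequences differ in length")
    if len(a) == 0:
        raise InputError("empty category sequences")
    if categories is None:
        categories = sorted(set(a) | set(b))
    table = pd.crosstab(a, b).reindex(index=categories, columns=categories,
                                      fill_value=0).fillna(0).astype(int)
    n = int(table.values.sum())
    p = table.values / n
    # integer-count trace keeps a perfect diagonal at exactly po = 1.0
    po = float(np.trace(table.values)) / n
    row = p.sum(axis=1)
    col = p.sum(axis=0)
    pe = float(row @ col)

    if pe == 1.0:
        # single category on both margins: chance agreement saturates
        kappa = 1.0 if po == 1.0 else float("nan")
        band = interpret_kappa(kappa) if not math.isnan(kappa) else "undefined"
        return KappaResult(kappa, float("nan"), n, table, band, degenerate=True)

    kappa = (po - pe) / (1.0 - pe)

    # Fleiss null SE (for the test of kappa = 0)
    var0 = (pe + pe * pe - float(np.sum(row * col * (row + col)))) / (n * (1 - pe) ** 2)
    se0 = math.sqrt(max(var0, 0.0))
    if se0 > 0:
        z = kappa / se0
        p_value = float(2.0 * stats.norm.sf(abs(z)))
    else:
        p_value = float("nan")

    # Fleiss-Cohen-Everitt non-null SE (for confidence intervals)
    diag = np.diag(p)
    term1 = float(np.sum(diag * (1.0 - (row + col) * (1.0 - kappa)) ** 2))
    off = p.copy()
    np.fill_diagonal(off, 0.0)
    # off-diagonal cell (i, j) weighs (p_.i + p_j.)^2
    term2 = float((1.0 - kappa) ** 2
                  * np.sum(off * (col[:, None] + row[None, :]) ** 2))
    term3 = (kappa - pe * (1.0 - kappa)) ** 2
    var = (term1 + term2 - term3) / (n * (1.0 - pe) ** 2)
    se = math.sqrt(max(var, 0.0))

    return KappaResult(kappa, p_value, n, table, interpret_kappa(kappa),
                       se=se, se0=se0)


# ------------------------------------------------- interpretation bands

#: Upper-closed kappa bands (Viera & Garrett): 0.80 -> "substantial",
#: anything above 0.80 -> "almost perfect".
_KAPPA_BANDS = [
    (0.0, "less than chance"),
    (0.20, "slight"),
    (0.40, "fair"),
    (0.60, "moderate"),
    (0.80, "substantial"),
    (1.0, "almost perfect"),
]

#: Lower-closed |r| bands (Mukaka): 0.90 itself -> "very high".
_R_BANDS = [
    (0.90, "very high"),
    (0.70, "high"),
    (0.50, "moderate"),
    (0.30, "low"),
    (0.0, "negligible"),
]


def interpret_kappa(k: float) -> str:
    """Agreement band for a kappa coefficient (upper-closed bins)."""
    if not -1.0 <= k <= 1.0:
        raise InputError(f"kappa {k} outside [-1, 1]")
    for upper, label in _KAPPA_BANDS[:-1]:
        if k <= upper:
            return label
    return _KAPPA_BANDS[-1][1]


def interpret_r(r: float) -> str:
    """Correlation-size band for |r| (lower-closed bins)."""
    if not -1.0 <= r <= 1.0:
        raise InputError(f"r {r} outside [-1, 1]")
    a = abs(r)
    for lower, label in _R_BANDS:
        if a >= lower:
            return label
    return "negligible"
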