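"""Eligibility, censoring and per-patient biomarker derivation.

The unit of analysis is the patient on combined antiretroviral therapy
(cART).  From each source's censored lab series this module derives the
pre-cART summary biomarkers — the nadir (lowest) CD4+ T-cell count and
the peak (highest) viral load, quantitative and categorized — and the
first ten post-cART measures.  "Before cART" means strictly before the
cART start date by default (same-day labs count as on-treatment; the
``pre_cart_inclusive`` switch flips this).

Censoring follows the study design: the cohort series is truncated at
the administrative censoring date, and the surveillance series is
additionally truncated at the date of the last cohort test of the same
analyte, so the surveillance source can never contribute observation
time the cohort did not have.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .errors import DataError, InputError

__all__ = [
    "EligibilityReport",
    "PeakVL",
    "DAYS_PER_YEAR",
    "apply_eligibility",
    "censor",
    "person_years",
    "nadir_cd4_pre_cart",
    "peak_vl_pre_cart",
    "categorize_cd4",
    "dichotomize_vl",
    "first_n_post_cart",
]

DAYS_PER_YEAR = 365.25

CD4_CATEGORIES = ["<200", "200-349", ">=350"]
VL_CATEGORIES = ["below", "above"]

NDA = "NDA"  # no data available


def percent(k: int, n: int, convention: str = "half_up") -> float:
    """k/n as a percentage to one decimal, under the given convention.

    ``half_up`` rounds 0.05 upward (2153/8007 -> 26.9); ``truncate``
    drops digits beyond the first decimal (100/8674 -> 1.1).
    """
    if n <= 0:
        raise InputError("percentage denominator must be positive")
    x = Decimal(100 * k) / Decimal(n)
    if convention == "half_up":
        return float(x.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))
    if convention == "truncate":
        return float(int(x * 10) / Decimal(10))
    raise InputError(f"unknown percentage convention {convention!r}")


@dataclass
class EligibilityReport:
    """Counts and percentages of the enrollment flowchart.

    Exclusions are applied in order — (1) no linkage code with the
    surveillance register, (2) no lab data during clinical follow-up,
    (3) no lab data after cART initiation — and each patient is counted
    once under the first reason that applies.
    """

    n_enrolled: int
    n_eligible: int
    excluded_no_link: int
    excluded_no_labs_followup: int
    excluded_no_labs_post_cart: int
    percent_convention: str = "half_up"

    def __post_init__(self):
        total = (self.n_eligible + self.excluded_no_link
                 + self.excluded_no_labs_followup + self.excluded_no_labs_post_cart)
        if total != self.n_enrolled:
            raise DataError(
                f"eligibility counts do not partition enrollment: {total} != {self.n_enrolled}"
            )

    def percentages(self) -> dict:
        conv = self.percent_convention
        return {
            "eligible": percent(self.n_eligible, self.n_enrolled, conv),
            "no_link": percent(self.excluded_no_link, self.n_enrolled, conv),
            "no_labs_followup": percent(self.excluded_no_labs_followup, self.n_enrolled, conv),
            "no_labs_post_cart": percent(self.excluded_no_labs_post_cart, self.n_enrolled, conv),
        }

    def to_frame(self) -> pd.DataFrame:
        pct = self.percentages()
        return pd.DataFrame({
            "group": ["enrolled", "eligible", "excluded_no_link",
                      "excluded_no_labs_followup", "excluded_no_labs_post_cart"],
            "n": [self.n_enrolled, self.n_eligible, self.excluded_no_link,
                  self.excluded_no_labs_followup, self.excluded_no_labs_post_cart],
            "percent": [100.0, pct["eligible"], pct["no_link"],
                        pct["no_labs_followup"], pct["no_labs_post_cart"]],
        })


def apply_eligibility(patients: pd.DataFrame, matched: dict,
                      cohort_results: pd.DataFrame,
                      admin_censor_date, percent_convention: str = "half_up",
                      ) -> tuple[list, EligibilityReport]:
    """Classify every enrolled patient as eligible or excluded.

    ``matched`` is the linkage map (cohort code -> surveillance code).
    Lab availability is judged on the cohort series censored at the
    administrative date and the patient's follow-up end.
    """
    admin = pd.Timestamp(admin_censor_date)
    res = cohort_results.copy()
    res["collection_date"] = pd.to_datetime(res["collection_date"])
    by_code = dict(tuple(res.groupby("code", sort=False)))

    eligible, n_no_link, n_no_labs, n_no_post = [], 0, 0, 0
    for row in patients.itertuples(index=False):
        if row.code not in matched:
            n_no_link += 1
            continue
        bound = min(admin, pd.Timestamp(row.followup_end))
        series = by_code.get(row.code)
        if series is not None:
            series = series.loc[series["collection_date"] <= bound]
        if series is None or series.empty:
            n_no_labs += 1
            continue
        if not (series["collection_date"] >= pd.Timestamp(row.cart_start)).any():
            n_no_post += 1
            continue
        eligible.append(row.code)

    report = EligibilityReport(
        n_enrolled=len(patients), n_eligible=len(eligible),
        excluded_no_link=n_no_link, excluded_no_labs_followup=n_no_labs,
        excluded_no_labs_post_cart=n_no_post,
        percent_convention=percent_convention,
    )
    return eligible, report


def censor(series: pd.DataFrame, admin_date, last_cohort_test_date=None) -> pd.DataFrame:
    """Truncate a result series at its censoring bound.

    The bound is the administrative date, lowered to the last cohort test
    date of the same analyte when one is given (surveillance censoring).
    Tests dated strictly after the bound are removed; the operation is
    idempotent.
    """
    bound = pd.Timestamp(admin_date)
    if last_cohort_test_date is not None:
        bound = min(bound, pd.Timestamp(last_cohort_test_date))
    dates = pd.to_datetime(series["collection_date"])
    return series.loc[dates <= bound]


def person_years(cart_start, censor_bound) -> float:
    """Follow-up time from cART start to the censoring bound, in years.

    Computed as calendar days / 365.25.  A zero interval is returned as
    0.0 (the caller flags such patients); a negative interval is an error.
    """
    days = (pd.Timestamp(censor_bound) - pd.Timestamp(cart_start)).days
    if days < 0:
        raise DataError(
            f"censoring bound {censor_bound} precedes cART start {cart_start}"
        )
    return days / DAYS_PER_YEAR


def _pre_cart(series: pd.DataFrame, cart_date, inclusive: bool) -> pd.DataFrame:
    dates = pd.to_datetime(series["collection_date"])
    cart = pd.Timestamp(cart_date)
    mask = dates <= cart if inclusive else dates < cart
    return series.loc[mask]


def nadir_cd4_pre_cart(series: pd.DataFrame, cart_date,
                       inclusive: bool = False) -> float | None:
    """Lowest CD4 count before cART, or None when no pre-cART test exists."""
    pre = _pre_cart(series, cart_date, inclusive)
    if pre.empty:
        return None
    values = pre["value"].astype(float)
    if (values < 0).any():
        raise DataError("negative CD4 count in series")
    return float(values.min())


@dataclass(frozen=True)
class PeakVL:
    """Peak pre-cART viral load: quantitative and dichotomized.

    ``copies``/``log10`` are None when no detectable pre-cART result
    exists; ``detectability`` is 'above' if the peak is detectable,
    'below' if only below-limit results exist, None when no pre-cART
    test exists at all (NDA).
    """

    copies: float | None
    log10: float | None
    detectability: str | None


def peak_vl_pre_cart(series: pd.DataFrame, cart_date,
                     inclusive: bool = False) -> PeakVL:
    """Highest viral load before cART under the detection-limit rules.

    Below-limit results count qualitatively ('below') but are excluded
    from the quantitative maximum; if no detectable result exists the
    quantitative peak is NDA while detectability is still 'below'.
    """
    pre = _pre_cart(series, cart_date, inclusive)
    if pre.empty:
        return PeakVL(None, None, None)
    values = pre["value"].astype(float)
    lods = pre["lod"].astype(float)
    detectable = values >= lods
    if (values[detectable] <= 0).any():
        raise DataError("nonpositive viral load flagged detectable")
    if detectable.any():
        copies = float(values[detectable].max())
        return PeakVL(copies, float(np.log10(copies)), "above")
    return PeakVL(None, None, "below")


def categorize_cd4(v: float) -> str:
    """CD4 count category: <200, 200-349 (half-open [200, 350)), >=350."""
    if v < 0:
        raise DataError(f"negative CD4 count {v}")
    if v < 200:
        return "<200"
    if v < 350:
        return "200-349"
    return ">=350"


def dichotomize_vl(value: float, lod: float) -> str:
    """'above' iff the result is detectable at its assay's lower limit."""
    if value < 0:
        raise DataError(f"negative viral load {value}")
    return "above" if value >= lod else "below"


def first_n_post_cart(series: pd.DataFrame, cart_date, n: int = 10,
                      inclusive: bool = False) -> pd.DataFrame:
    """First ``n`` tests on/after the cART start date, in date order.

    ``inclusive`` mirrors the pre-cART convention: when same-day tests
    count as pre-cART, the post-cART series starts strictly after the
    start date.  Fewer than ``n`` rows are returned when the series is
    short.
    """
    dates = pd.to_datetime(series["collection_date"])
    cart = pd.Timestamp(cart_date)
    mask = dates > cart if inclusive else dates >= cart
    post = series.loc[mask].copy()
    post["collection_date"] = pd.to_datetime(post["collection_date"])
    post = post.sort_values("collection_date", kind="stable")
    return post.head(n).reset_index(drop=True)
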