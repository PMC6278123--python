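"""Paired-registry simulator with known ground truth.

Emulates one latent laboratory-testing process per patient (CD4+ T-cell
counts and HIV viral loads from a pre-treatment period through follow-up)
observed by two imperfect sources: a clinical cohort database and a
laboratory surveillance database.  Each source misses tests independently;
the surveillance copy additionally carries collection-date jitter, value
perturbation and identity-string typos.  The ground truth (true
cohort-to-surveillance links and the full latent series) is returned so
linkage, matching and derivation can be validated against it.

The latent biomarker model is a stand-in (no registry publishes one): CD4
is lognormal around a patient baseline with exponential post-treatment
recovery; viral load is log10-normal before treatment, and after treatment
start each successive test is detectable with geometrically decaying
probability.  This reproduces the qualitative pattern real treated cohorts
show — rising CD4 means and falling per-count detectability — without
claiming its parameters.
"""

from __future__ import annotations

import datetime as dt
import string
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .config import ANALYTES, SimConfig
from .errors import InputError
from . import names as name_pools

__all__ = ["LinkTruth", "SyntheticRegistries", "generate", "inject_typo", "lod_for_date"]

_TYPO_ALPHABET = string.ascii_uppercase + " "

_ROMAN = (
    (1000, "M"), (900, "CM"), (500, "D"), (400, "CD"), (100, "C"),
    (90, "XC"), (50, "L"), (40, "XL"), (10, "X"), (9, "IX"),
    (5, "V"), (4, "IV"), (1, "I"),
)


def _roman(n: int) -> str:
    out = []
    for val, sym in _ROMAN:
        while n >= val:
            out.append(sym)
            n -= val
    return "".join(out)


def site_labels(n_sites: int) -> list[str]:
    """Roman-numeral site labels (I, II, ..., XIII, ...)."""
    return [_roman(i + 1) for i in range(n_sites)]


def inject_typo(s: str, rng: np.random.Generator) -> str:
    """Apply exactly one random character edit (substitute/delete/insert).

    The result always differs from ``s`` and is non-empty.
    """
    if not s:
        raise InputError("cannot inject a typo into an empty string")
    ops = ["substitute", "insert"] if len(s) == 1 else ["substitute", "delete", "insert"]
    op = ops[int(rng.integers(len(ops)))]
    if op == "substitute":
        i = int(rng.integers(len(s)))
        choices = [c for c in _TYPO_ALPHABET if c != s[i]]
        return s[:i] + choices[int(rng.integers(len(choices)))] + s[i + 1 :]
    if op == "delete":
        i = int(rng.integers(len(s)))
        return s[:i] + s[i + 1 :]
    # insertions use letters only: an inserted space could collapse away
    # under whitespace normalization and no longer count as an edit
    i = int(rng.integers(len(s) + 1))
    letters = string.ascii_uppercase
    return s[:i] + letters[int(rng.integers(len(letters)))] + s[i:]


def lod_for_date(schedule: dict, date: dt.date) -> float:
    """Assay lower limit of detection in force at ``date``.

    The schedule maps year -> limit (copies/ml); the entry with the
    largest year not exceeding the test year applies.  Dates before the
    earliest scheduled year use the earliest entry.
    """
    years = sorted(schedule)
    applicable = years[0]
    for y in years:
        if y <= date.year:
            applicable = y
    return float(schedule[applicable])


@dataclass
class LinkTruth:
    """Ground truth of the simulated pair of registries.

    ``code_map`` is the bijection cohort code -> surveillance code over
    all generated patients.  ``latent_tests`` holds one row per latent
    test with its per-source observation flags and the (possibly
    perturbed) surveillance copy.
    """

    code_map: dict
    latent_tests: pd.DataFrame


@dataclass
class SyntheticRegistries:
    """The two simulated databases plus ground truth."""

    cohort_patients: pd.DataFrame
    cohort_results: pd.DataFrame
    surveillance_patients: pd.DataFrame
    surveillance_results: pd.DataFrame
    truth: LinkTruth

    def write(self, out_dir: str | Path) -> None:
        """Write all tables as comma-separated text with a header row."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        date_cols = {
            "cohort_patients": ["birth_date", "cart_start", "followup_end"],
            "surveillance_patients": ["birth_date", "cart_start", "followup_end"],
            "cohort_results": ["collection_date"],
            "surveillance_results": ["collection_date"],
        }
        for name, cols in date_cols.items():
            df = getattr(self, name).copy()
            for c in cols:
                df[c] = pd.to_datetime(df[c]).dt.strftime("%Y-%m-%d")
            df.to_csv(out / f"{name}.csv", index=False)
        links = pd.DataFrame(
            sorted(self.truth.code_map.items()), columns=["cohort_code", "surveillance_code"]
        )
        links.to_csv(out / "truth_links.csv", index=False)
        latent = self.truth.latent_tests.copy()
        for c in ("date", "surv_date"):
            latent[c] = pd.to_datetime(latent[c]).dt.strftime("%Y-%m-%d")
        latent.to_csv(out / "truth_latent.csv", index=False)


def _patient_rng(seed: int, index: int) -> np.random.Generator:
    # Sub-stream per patient index: stable under changes of n_patients.
    return np.random.default_rng(np.random.SeedSequence([seed, index]))


def _make_identity(rng: np.random.Generator) -> tuple[str, str]:
    given = name_pools.GIVEN_NAMES[int(rng.integers(len(name_pools.GIVEN_NAMES)))]
    family = name_pools.SURNAMES[int(rng.integers(len(name_pools.SURNAMES)))]
    parts = [given]
    conn = name_pools.SURNAME_CONNECTORS[int(rng.integers(len(name_pools.SURNAME_CONNECTORS)))]
    if conn:
        parts.append(conn)
    parts.append(family)
    if rng.random() < 0.5:
        parts.append(name_pools.SURNAMES[int(rng.integers(len(name_pools.SURNAMES)))])
    full_name = " ".join(parts)

    m_given = name_pools.FEMALE_GIVEN_NAMES[
        int(rng.integers(len(name_pools.FEMALE_GIVEN_NAMES)))
    ]
    # mother usually shares the family surname
    m_family = family if rng.random() < 0.7 else name_pools.SURNAMES[
        int(rng.integers(len(name_pools.SURNAMES)))
    ]
    m_conn = name_pools.SURNAME_CONNECTORS[
        int(rng.integers(len(name_pools.SURNAME_CONNECTORS)))
    ]
    mother = " ".join(p for p in (m_given, m_conn, m_family) if p)
    return full_name, mother


def _latent_series(cfg: SimConfig, rng: np.random.Generator, cart_start: dt.date,
                   followup_end: dt.date, cd4_baseline: float):
    """Draw the latent CD4 and VL test series for one patient.

    Returns a list of dicts (analyte, date, value, lod, detectable is
    implicit: VL value >= lod).  Undetectable viral loads carry value 0.
    """
    window_start = cart_start - dt.timedelta(days=cfg.pre_cart_days)
    window_days = (followup_end - window_start).days
    window_years = window_days / 365.25
    rows = []
    for analyte in ANALYTES:
        n = int(rng.poisson(cfg.tests_per_py * window_years))
        if n == 0:
            continue
        offsets = np.sort(rng.integers(0, window_days + 1, size=n))
        dates = [window_start + dt.timedelta(days=int(o)) for o in offsets]
        if analyte == "CD4":
            eps = rng.normal(0.0, cfg.cd4_within_sd, size=n)
            for date, e in zip(dates, eps):
                years_post = max(0.0, (date - cart_start).days / 365.25)
                val = cd4_baseline * np.exp(cfg.cd4_recovery_rate * years_post + e)
                rows.append({
                    "analyte": "CD4",
                    "date": date,
                    "value": float(np.clip(round(val), 1, 5000)),
                    "lod": np.nan,
                })
        else:
            post_index = 0
            for date in dates:
                lod = lod_for_date(cfg.lod_schedule, date)
                if date < cart_start:
                    log10v = rng.normal(cfg.vl_pre_log_mean, cfg.vl_pre_log_sd)
                    copies = max(1.0, float(round(10.0 ** log10v)))
                else:
                    post_index += 1
                    p_det = cfg.vl_post_detect_p0 * cfg.vl_post_detect_decay ** (post_index - 1)
                    if rng.random() < p_det:
                        log10v = rng.normal(cfg.vl_post_log_mean, cfg.vl_post_log_sd)
                        copies = max(lod, float(round(10.0 ** log10v)))
                    else:
                        copies = 0.0  # suppressed below the assay limit
                rows.append({"analyte": "VL", "date": date, "value": copies, "lod": lod})
    return rows


def generate(config: SimConfig) -> SyntheticRegistries:
    """Generate the paired cohort/surveillance registries and ground truth.

    Deterministic: identical configs (including seed) yield byte-identical
    tables.  Each latent test is copied into each source independently
    with that source's missingness; the surveillance copy carries date
    jitter, value noise and identity typos per the config.
    """
    cfg = config
    sites = site_labels(cfg.n_sites)
    enroll_days = (cfg.enrollment_end - cfg.enrollment_start).days

    cohort_patients, surv_patients = [], []
    latent_rows = []
    code_map: dict[str, str] = {}

    for i in range(cfg.n_patients):
        rng = _patient_rng(cfg.seed, i)
        c_code = f"C{i + 1:06d}"
        s_code = f"S{i + 1:06d}"
        code_map[c_code] = s_code

        site = sites[int(rng.integers(cfg.n_sites))]
        cart_start = cfg.enrollment_start + dt.timedelta(days=int(rng.integers(enroll_days + 1)))
        fu_days = max(cfg.min_followup_days,
                      int(round(rng.exponential(cfg.mean_followup_years * 365.25))))
        followup_end = min(cfg.admin_censor_date, cart_start + dt.timedelta(days=fu_days))
        age_years = 18.0 + rng.uniform(0.0, 47.0)
        birth_date = cart_start - dt.timedelta(days=int(round(age_years * 365.25)))
        full_name, mother_name = _make_identity(rng)

        cohort_patients.append({
            "code": c_code, "full_name": full_name, "mother_name": mother_name,
            "birth_date": birth_date, "site": site,
            "cart_start": cart_start, "followup_end": followup_end,
        })

        s_name = inject_typo(full_name, rng) if rng.random() < cfg.typo_rate else full_name
        s_mother = inject_typo(mother_name, rng) if rng.random() < cfg.typo_rate else mother_name
        surv_patients.append({
            "code": s_code, "full_name": s_name, "mother_name": s_mother,
            "birth_date": birth_date, "site": site,
            "cart_start": cart_start, "followup_end": followup_end,
        })

        cd4_baseline = float(np.exp(rng.normal(cfg.cd4_baseline_log_mean,
                                               cfg.cd4_baseline_log_sd)))
        series = _latent_series(cfg, rng, cart_start, followup_end, cd4_baseline)
        for row in series:
            in_cohort = bool(rng.random() >= cfg.missing_prob_cohort)
            in_surv = bool(rng.random() >= cfg.missing_prob_surveillance)
            jitter = int(rng.integers(-cfg.date_jitter_days, cfg.date_jitter_days + 1)) \
                if cfg.date_jitter_days > 0 else 0
            surv_date = row["date"] + dt.timedelta(days=jitter)
            value = row["value"]
            if row["analyte"] == "CD4":
                noise = rng.normal(0.0, cfg.value_noise_sd["CD4"]) \
                    if cfg.value_noise_sd["CD4"] > 0 else 0.0
                surv_value = float(np.clip(round(value + noise), 1, 5000))
            else:
                if value > 0 and cfg.value_noise_sd["VL"] > 0:
                    log10v = np.log10(value) + rng.normal(0.0, cfg.value_noise_sd["VL"])
                    surv_value = max(1.0, float(round(10.0 ** log10v)))
                else:
                    surv_value = value
            latent_rows.append({
                "cohort_code": c_code, "surveillance_code": s_code, "site": site,
                "analyte": row["analyte"], "date": row["date"], "value": value,
                "lod": row["lod"], "in_cohort": in_cohort, "in_surveillance": in_surv,
                "surv_date": surv_date, "surv_value": surv_value,
            })

    latent = pd.DataFrame(latent_rows, columns=[
        "cohort_code", "surveillance_code", "site", "analyte", "date", "value",
        "lod", "in_cohort", "in_surveillance", "surv_date", "surv_value",
    ])
    for c in ("date", "surv_date"):
        latent[c] = pd.to_datetime(latent[c])

    cohort_results = (
        latent.loc[latent["in_cohort"],
                   ["cohort_code", "analyte", "date", "value", "lod"]]
        .rename(columns={"cohort_code": "code", "date": "collection_date"})
        .reset_index(drop=True)
    )
    surveillance_results = (
        latent.loc[latent["in_surveillance"],
                   ["surveillance_code", "analyte", "surv_date", "surv_value", "lod"]]
        .rename(columns={"surveillance_code": "code", "surv_date": "collection_date",
                         "surv_value": "value"})
        .reset_index(drop=True)
    )

    cohort_patients_df = pd.DataFrame(cohort_patients)
    surv_patients_df = pd.DataFrame(surv_patients)
    for df in (cohort_patients_df, surv_patients_df):
        for c in ("birth_date", "cart_start", "followup_end"):
            df[c] = pd.to_datetime(df[c])
    # surveillance registries arrive in no particular order
    shuffle_rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 2**30]))
    perm = shuffle_rng.permutation(len(surv_patients_df))
    surv_patients_df = surv_patients_df.iloc[perm].reset_index(drop=True)

    return SyntheticRegistries(
        cohort_patients=cohort_patients_df,
        cohort_results=cohort_results,
        surveillance_patients=surv_patients_df,
        surveillance_results=surveillance_results,
        truth=LinkTruth(code_map=code_map, latent_tests=latent),
    )
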