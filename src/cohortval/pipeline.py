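"""End-to-end orchestration: simulate/load -> link -> match -> derive -> validate.

Produces the full validation report as tidy tables, one row per cohort
site plus a "Total" row wherever a statistic is site-stratified:

* ``rates`` — patients, person-years, test counts and testing rates per
  100 person-years per source and analyte;
* ``proportions`` — categorized pre-cART nadir CD4 and peak viral-load
  detectability per source, with bootstrap percentile CIs, both over the
  full eligible cohort (NDA as its own category) and restricted to
  patients with data in both sources;
* ``first10`` — descriptive statistics of the first ten post-cART CD4
  counts and the per-count proportion of detectable viral loads;
* ``correlation_ba`` — Pearson correlation and Bland-Altman analysis of
  the quantitative nadir CD4 and log10 peak viral load between sources;
* ``kappa`` — Cohen's kappa for the categorized measures.

Every run is reproducible from the configuration and its seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import derivation as dv
from .agreement import (bland_altman, cohen_kappa, interpret_r, pearson,
                        proportion_ci, testing_rate)
from .config import ANALYTES, PipelineConfig
from .derivation import EligibilityReport, apply_eligibility
from .errors import CohortValError, DataError, InputError
from .linkage import LinkResult, link
from .matching import match_tests
from .simulate import SyntheticRegistries, generate

logger = logging.getLogger("cohortval")

TOTAL = "Total"


@dataclass
class PipelineResult:
    link_result: LinkResult
    eligibility: EligibilityReport
    eligible: list
    derived: pd.DataFrame
    counts: pd.DataFrame
    first10: pd.DataFrame
    matched_audit: pd.DataFrame
    tables: dict = field(default_factory=dict)
    registries: SyntheticRegistries | None = None

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.link_result.write(out)
        self.eligibility.to_frame().to_csv(out / "eligibility.csv", index=False)
        self.derived.to_csv(out / "derived_measures.csv", index=False)
        self.counts.to_csv(out / "test_counts.csv", index=False)
        self.first10.to_csv(out / "first10.csv", index=False)
        self.matched_audit.to_csv(out / "matched_tests.csv", index=False)
        for name, table in self.tables.items():
            table.to_csv(out / f"table_{name}.csv", index=False)


def _load_inputs(config: PipelineConfig):
    if config.sim is not None:
        reg = generate(config.sim)
        return (reg.cohort_patients, reg.cohort_results,
                reg.surveillance_patients, reg.surveillance_results, reg)
    read = lambda p: pd.read_csv(p)
    cp = read(config.cohort_patients)
    cr = read(config.cohort_results)
    sp = read(config.surveillance_patients)
    sr = read(config.surveillance_results)
    for df, cols in ((cp, ("birth_date", "cart_start", "followup_end")),
                     (sp, ("birth_date", "cart_start", "followup_end")),
                     (cr, ("collection_date",)), (sr, ("collection_date",))):
        for c in cols:
            if c in df.columns:
                df[c] = pd.to_datetime(df[c])
    return cp, cr, sp, sr, None


def _series_by_code_analyte(results: pd.DataFrame) -> dict:
    res = results.copy()
    res["collection_date"] = pd.to_datetime(res["collection_date"])
    res = res.sort_values(["code", "analyte", "collection_date"], kind="stable")
    return {key: grp for key, grp in res.groupby(["code", "analyte"], sort=False)}


def derive_cohort(patients: pd.DataFrame, matched: dict, eligible: list,
                  cohort_results: pd.DataFrame, surveillance_results: pd.DataFrame,
                  config: PipelineConfig):
    """Per-patient censoring, matching audit and derived measures.

    Returns (derived, counts, first10, matched_audit) tidy frames; one
    derived row per eligible patient per source.
    """
    admin = pd.Timestamp(config.admin_censor_date)
    inclusive = config.pre_cart_inclusive
    coh = _series_by_code_analyte(cohort_results)
    srv = _series_by_code_analyte(surveillance_results)
    pinfo = patients.set_index("code")

    derived_rows, count_rows, first10_rows, audit_rows = [], [], [], []
    n_dedup = 0
    for code in eligible:
        row = pinfo.loc[code]
        s_code = matched[code]
        cart = pd.Timestamp(row["cart_start"])
        bound = min(admin, pd.Timestamp(row["followup_end"]))
        py = dv.person_years(cart, bound)
        if py <= 0:
            logger.warning("patient %s has zero follow-up time; flagged", code)

        per_source = {}
        for analyte in ANALYTES:
            c_series = coh.get((code, analyte))
            c_series = dv.censor(c_series, bound) if c_series is not None else None
            last_c = c_series["collection_date"].max() if c_series is not None \
                and not c_series.empty else None
            s_series = srv.get((s_code, analyte))
            if s_series is not None:
                s_series = dv.censor(s_series, bound, last_c) if last_c is not None \
                    else s_series.iloc[0:0]
            per_source[("cohort", analyte)] = c_series
            per_source[("surveillance", analyte)] = s_series

            for source in ("cohort", "surveillance"):
                s = per_source[(source, analyte)]
                count_rows.append({
                    "code": code, "site": row["site"], "source": source,
                    "analyte": analyte, "n_tests": 0 if s is None else len(s),
                    "person_years": py,
                })

            if c_series is not None and s_series is not None \
                    and len(c_series) and len(s_series):
                m = match_tests(c_series, s_series, config.window_days)
                n_dedup += m.n_dedup_a + m.n_dedup_b
                for pr in m.pairs.itertuples(index=False):
                    audit_rows.append({
                        "code": code, "analyte": analyte,
                        "cohort_date": pr.a_date, "surveillance_date": pr.b_date,
                        "delta_days": pr.delta_days,
                        "cohort_value": pr.a_value, "surveillance_value": pr.b_value,
                    })

        for source in ("cohort", "surveillance"):
            cd4 = per_source[(source, "CD4")]
            vl = per_source[(source, "VL")]
            nadir = dv.nadir_cd4_pre_cart(cd4, cart, inclusive) \
                if cd4 is not None and len(cd4) else None
            peak = dv.peak_vl_pre_cart(vl, cart, inclusive) \
                if vl is not None and len(vl) else dv.PeakVL(None, None, None)
            derived_rows.append({
                "code": code, "site": row["site"], "source": source,
                "person_years": py,
                "nadir_cd4": np.nan if nadir is None else nadir,
                "cd4_category": dv.NDA if nadir is None else dv.categorize_cd4(nadir),
                "peak_vl_copies": np.nan if peak.copies is None else peak.copies,
                "peak_vl_log10": np.nan if peak.log10 is None else peak.log10,
                "vl_detectability": dv.NDA if peak.detectability is None
                else peak.detectability,
            })
            if cd4 is not None and len(cd4):
                first = dv.first_n_post_cart(cd4, cart, 10, inclusive)
                for seq, r in enumerate(first.itertuples(index=False), start=1):
                    first10_rows.append({
                        "code": code, "site": row["site"], "source": source,
                        "analyte": "CD4", "seq": seq, "value": float(r.value),
                        "flag": "",
                    })
            if vl is not None and len(vl):
                first = dv.first_n_post_cart(vl, cart, 10, inclusive)
                for seq, r in enumerate(first.itertuples(index=False), start=1):
                    first10_rows.append({
                        "code": code, "site": row["site"], "source": source,
                        "analyte": "VL", "seq": seq, "value": float(r.value),
                        "flag": dv.dichotomize_vl(float(r.value), float(r.lod)),
                    })

    if n_dedup:
        logger.warning("deduplicated %d same-day duplicate tests before matching",
                       n_dedup)
    derived = pd.DataFrame(derived_rows)
    counts = pd.DataFrame(count_rows)
    first10 = pd.DataFrame(first10_rows, columns=[
        "code", "site", "source", "analyte", "seq", "value", "flag"])
    audit = pd.DataFrame(audit_rows, columns=[
        "code", "analyte", "cohort_date", "surveillance_date", "delta_days",
        "cohort_value", "surveillance_value"])
    return derived, counts, first10, audit


# ------------------------------------------------------------ validation


def rates_table(counts: pd.DataFrame) -> pd.DataFrame:
    """Patients, person-years and per-source testing rates by site."""
    rows = []
    sites = sorted(counts["site"].unique()) + [TOTAL]
    for site in sites:
        sub = counts if site == TOTAL else counts.loc[counts["site"] == site]
        per_patient = sub.drop_duplicates("code")
        py = float(per_patient["person_years"].sum())
        row = {"site": site, "n_patients": per_patient["code"].nunique(),
               "person_years": round(py, 2)}
        for source in ("cohort", "surveillance"):
            for analyte in ANALYTES:
                n = int(sub.loc[(sub["source"] == source)
                                & (sub["analyte"] == analyte), "n_tests"].sum())
                key = f"{analyte.lower()}_{source}"
                row[f"{key}_n"] = n
                row[f"{key}_rate"] = testing_rate(n, py).rate_per_100py if py > 0 else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def _proportion_rows(values: pd.Series, categories: list, site, panel, measure,
                     source, B, rng):
    n = len(values)
    rows = []
    for cat in categories:
        k = int((values == cat).sum())
        ci = proportion_ci(k, n, B=B, rng=rng)
        rows.append({
            "site": site, "panel": panel, "measure": measure, "source": source,
            "category": cat, "k": k, "n": n, "percent": ci.p_hat,
            "ci_low": ci.ci_low, "ci_high": ci.ci_high,
        })
    return rows


def proportions_table(derived: pd.DataFrame, B: int, seed: int) -> pd.DataFrame:
    """Categorized nadir CD4 / peak VL proportions with bootstrap CIs.

    The ``full`` panel spans all eligible patients with NDA as its own
    category; the ``excl_nda`` panel is restricted to patients with data
    in both sources for the measure (so both sources share a
    denominator).  Bootstrap draws come from one seeded generator
    consumed in fixed table order, so the table is reproducible.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 11]))
    wide = derived.pivot(index="code", columns="source",
                         values=["cd4_category", "vl_detectability"])
    sites = derived.drop_duplicates("code").set_index("code")["site"]
    wide["site"] = sites

    specs = [("cd4", "cd4_category", dv.CD4_CATEGORIES),
             ("vl", "vl_detectability", dv.VL_CATEGORIES)]
    rows = []
    site_list = sorted(derived["site"].unique()) + [TOTAL]
    for site in site_list:
        sub = wide if site == TOTAL else wide.loc[wide["site"] == site]
        for measure, col, cats in specs:
            both = sub.loc[(sub[(col, "cohort")] != dv.NDA)
                           & (sub[(col, "surveillance")] != dv.NDA)]
            for source in ("cohort", "surveillance"):
                rows += _proportion_rows(sub[(col, source)], cats + [dv.NDA],
                                         site, "full", measure, source, B, rng)
                rows += _proportion_rows(both[(col, source)], cats,
                                         site, "excl_nda", measure, source, B, rng)
    return pd.DataFrame(rows)


def first10_table(first10: pd.DataFrame) -> pd.DataFrame:
    """Per-count descriptive statistics of the first ten post-cART measures."""
    rows = []
    for source in ("cohort", "surveillance"):
        for seq in range(1, 11):
            cd4 = first10.loc[(first10["source"] == source)
                              & (first10["analyte"] == "CD4")
                              & (first10["seq"] == seq), "value"]
            vl = first10.loc[(first10["source"] == source)
                             & (first10["analyte"] == "VL")
                             & (first10["seq"] == seq), "flag"]
            row = {"source": source, "seq": seq, "cd4_n": len(cd4)}
            if len(cd4):
                row.update(cd4_mean=round(float(cd4.mean()), 1),
                           cd4_sd=round(float(cd4.std(ddof=1)), 1) if len(cd4) > 1 else np.nan,
                           cd4_median=float(cd4.median()),
                           cd4_q1=float(cd4.quantile(0.25)),
                           cd4_q3=float(cd4.quantile(0.75)))
            row["vl_n"] = len(vl)
            row["vl_pct_above"] = dv.percent(int((vl == "above").sum()), len(vl)) \
                if len(vl) else np.nan
            rows.append(row)
    return pd.DataFrame(rows)


def _agreement_rows(sub: pd.DataFrame, site):
    rows = []
    for measure, col in (("cd4_nadir", "nadir_cd4"), ("vl_log10_peak", "peak_vl_log10")):
        x = sub[(col, "cohort")].astype(float)
        y = sub[(col, "surveillance")].astype(float)
        keep = ~(x.isna() | y.isna())
        x, y = x[keep].values, y[keep].values
        row = {"site": site, "measure": measure, "n_pairs": len(x)}
        try:
            r, p = pearson(x, y)
            row.update(r=r, r_p_value=p, r_band=interpret_r(r))
        except (InputError, DataError) as exc:
            row.update(r=np.nan, r_p_value=np.nan, r_band="", note=str(exc))
        try:
            ba = bland_altman(x, y)
            row.update(mean_diff=ba.mean_diff, sd_diff=ba.sd_diff,
                       ci_mean_low=ba.ci_mean_low, ci_mean_high=ba.ci_mean_high,
                       loa_low=ba.loa_low, loa_high=ba.loa_high,
                       diff_p_value=ba.p_value)
        except (InputError, DataError) as exc:
            row.setdefault("note", str(exc))
        rows.append(row)
    return rows


def correlation_ba_table(derived: pd.DataFrame) -> pd.DataFrame:
    """Pearson + Bland-Altman per site and overall, pairwise-complete."""
    wide = derived.pivot(index="code", columns="source",
                         values=["nadir_cd4", "peak_vl_log10"])
    wide["site"] = derived.drop_duplicates("code").set_index("code")["site"]
    rows = []
    for site in sorted(derived["site"].unique()) + [TOTAL]:
        sub = wide if site == TOTAL else wide.loc[wide["site"] == site]
        rows += _agreement_rows(sub, site)
    return pd.DataFrame(rows)


def kappa_table(derived: pd.DataFrame) -> pd.DataFrame:
    """Cohen's kappa for the categorized measures per site and overall."""
    wide = derived.pivot(index="code", columns="source",
                         values=["cd4_category", "vl_detectability"])
    wide["site"] = derived.drop_duplicates("code").set_index("code")["site"]
    specs = [("cd4", "cd4_category", dv.CD4_CATEGORIES),
             ("vl", "vl_detectability", dv.VL_CATEGORIES)]
    rows = []
    for site in sorted(derived["site"].unique()) + [TOTAL]:
        sub = wide if site == TOTAL else wide.loc[wide["site"] == site]
        for measure, col, cats in specs:
            a = sub[(col, "cohort")]
            b = sub[(col, "surveillance")]
            keep = (a != dv.NDA) & (b != dv.NDA)
            row = {"site": site, "measure": measure, "n_pairs": int(keep.sum())}
            if keep.sum() == 0:
                row.update(kappa=np.nan, p_value=np.nan, band="", degenerate=True)
            else:
                res = cohen_kappa(a[keep], b[keep], categories=cats)
                row.update(kappa=res.kappa, p_value=res.p_value, band=res.band,
                           degenerate=res.degenerate)
            rows.append(row)
    return pd.DataFrame(rows)


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run simulate/load -> link -> match -> derive -> validate."""
    stage = "load"
    try:
        cp, cr, sp, sr, registries = _load_inputs(config)
        logger.info("load: %d cohort patients, %d cohort results, "
                    "%d surveillance patients, %d surveillance results",
                    len(cp), len(cr), len(sp), len(sr))

        stage = "link"
        link_result = link(cp, sp)
        logger.info("link: %d matched, %d/%d unmatched, %d review-queue pairs",
                    len(link_result.matched), len(link_result.unmatched_cohort),
                    len(link_result.unmatched_surveillance),
                    len(link_result.review_queue))

        stage = "eligibility"
        eligible, report = apply_eligibility(
            cp, link_result.matched, cr, config.admin_censor_date,
            config.percent_convention)
        logger.info("eligibility: %d of %d eligible (excluded %d/%d/%d)",
                    report.n_eligible, report.n_enrolled, report.excluded_no_link,
                    report.excluded_no_labs_followup, report.excluded_no_labs_post_cart)

        stage = "derive"
        derived, counts, first10, audit = derive_cohort(
            cp, link_result.matched, eligible, cr, sr, config)
        logger.info("derive: %d derived rows, %d matched test pairs",
                    len(derived), len(audit))

        stage = "validate"
        tables = {
            "rates": rates_table(counts),
            "proportions": proportions_table(derived, config.bootstrap_samples,
                                             config.seed),
            "first10": first10_table(first10),
            "correlation_ba": correlation_ba_table(derived),
            "kappa": kappa_table(derived),
        }
        logger.info("validate: %d tables", len(tables))
    except CohortValError:
        logger.error("pipeline stage %r failed", stage)
        raise

    result = PipelineResult(
        link_result=link_result, eligibility=report, eligible=eligible,
        derived=derived, counts=counts, first10=first10, matched_audit=audit,
        tables=tables, registries=registries,
    )
    if config.out_dir:
        result.write(config.out_dir)
        if registries is not None:
            registries.write(Path(config.out_dir) / "registries")
    return result
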