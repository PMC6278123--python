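"""Deterministic record linkage on the identity triple.

Two registries are linked by normalized exact matching on the three
fields both hold: the patient's full name, the mother's full name, and
the date of birth.  A pair is auto-matched only when all three normalized
fields are equal and the triple is unambiguous on both sides (100%
compatibility).  Everything short of that — exactly two of three fields
agreeing, ambiguous ties, unparseable birth dates — lands in a review
queue for manual adjudication; this module never adjudicates.
"""

from __future__ import annotations

import unicodedata
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .errors import InputError
from .simulate import LinkTruth

__all__ = [
    "Identity",
    "LinkResult",
    "normalize_name",
    "normalize_identity",
    "link",
    "linkage_recovery",
]

IDENTITY_FIELDS = ("full_name", "mother_name", "birth_date")


@dataclass(frozen=True)
class Identity:
    full_name: str
    mother_name: str
    birth_date: object  # datetime.date / pd.Timestamp / ISO string


def normalize_name(raw: str) -> str:
    """Upper-case, strip diacritics, collapse internal whitespace, trim."""
    s = unicodedata.normalize("NFKD", str(raw))
    s = "".join(ch for ch in s if not unicodedata.combining(ch))
    return " ".join(s.upper().split())


def normalize_identity(raw: Identity) -> Identity:
    """Normalized identity; idempotent; the birth date is left unchanged."""
    return Identity(
        full_name=normalize_name(raw.full_name),
        mother_name=normalize_name(raw.mother_name),
        birth_date=raw.birth_date,
    )


@dataclass
class LinkResult:
    """Outcome of the exact-match linkage.

    ``matched`` maps cohort code -> surveillance code, one-to-one.
    ``review_queue`` holds candidate pairs for manual review: pairs that
    agree on exactly 2 of the 3 normalized fields, full-triple ties that
    could not be auto-matched unambiguously, and records whose birth
    date failed to parse (queued with an empty counterpart).
    """

    matched: dict = field(default_factory=dict)
    unmatched_cohort: list = field(default_factory=list)
    unmatched_surveillance: list = field(default_factory=list)
    review_queue: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["cohort_code", "surveillance_code", "n_fields_agree", "reason"]
        )
    )

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(
            sorted(self.matched.items()), columns=["cohort_code", "surveillance_code"]
        ).to_csv(out / "matched.csv", index=False)
        pd.DataFrame({"code": sorted(self.unmatched_cohort)}).to_csv(
            out / "unmatched_cohort.csv", index=False
        )
        pd.DataFrame({"code": sorted(self.unmatched_surveillance)}).to_csv(
            out / "unmatched_surveillance.csv", index=False
        )
        self.review_queue.to_csv(out / "review_queue.csv", index=False)


def _normalized_frame(patients: pd.DataFrame, which: str):
    """Returns (normalized valid-records frame, bad-birth-date codes)."""
    required = ("code",) + IDENTITY_FIELDS
    missing = [c for c in required if c not in patients.columns]
    if missing:
        raise InputError(f"{which} patient table lacks columns {missing}")
    if patients["code"].duplicated().any():
        dupes = patients.loc[patients["code"].duplicated(), "code"].tolist()
        raise InputError(f"duplicate codes in {which} patient table: {dupes[:5]}")
    df = patients.loc[:, list(required)].copy()
    df["full_name"] = df["full_name"].map(normalize_name)
    df["mother_name"] = df["mother_name"].map(normalize_name)
    parsed = pd.to_datetime(df["birth_date"], errors="coerce")
    bad = df.loc[parsed.isna(), "code"].tolist()
    df["birth_date"] = parsed
    return df.loc[parsed.notna()].reset_index(drop=True), bad


def link(cohort_patients: pd.DataFrame, surveillance_patients: pd.DataFrame) -> LinkResult:
    """Link the two patient tables by normalized exact identity match.

    A cohort/surveillance pair is auto-matched iff all three normalized
    fields are equal and no other record on either side shares that
    triple; tied candidates all go to the review queue instead.  Pairs
    agreeing on exactly two of the three fields (with at least one side
    unmatched) are also queued.
    """
    coh, bad_coh = _normalized_frame(cohort_patients, "cohort")
    srv, bad_srv = _normalized_frame(surveillance_patients, "surveillance")

    key = list(IDENTITY_FIELDS)
    coh_groups = coh.groupby(key, sort=False)["code"].agg(list)
    srv_groups = srv.groupby(key, sort=False)["code"].agg(list)

    matched: dict = {}
    queue_rows: list[dict] = []
    common = coh_groups.index.intersection(srv_groups.index)
    for triple in common:
        c_codes, s_codes = coh_groups[triple], srv_groups[triple]
        if len(c_codes) == 1 and len(s_codes) == 1:
            matched[c_codes[0]] = s_codes[0]
        else:
            # ambiguous tie: nothing auto-matched, every cross-pair reviewed
            for c in c_codes:
                for s in s_codes:
                    queue_rows.append({
                        "cohort_code": c, "surveillance_code": s,
                        "n_fields_agree": 3, "reason": "ambiguous_tie",
                    })

    matched_surv = set(matched.values())
    unmatched_cohort = [c for c in cohort_patients["code"] if c not in matched]
    unmatched_surv = [
        s for s in surveillance_patients["code"] if s not in matched_surv
    ]

    # pairs agreeing on exactly 2 of 3 fields: a pair agreeing on a given
    # field pair appears in exactly one of the three two-field joins
    # (three agreements would make it a full match)
    two_field_pairs: set[tuple[str, str]] = set()
    for dropped in IDENTITY_FIELDS:
        on = [f for f in IDENTITY_FIELDS if f != dropped]
        merged = coh.merge(srv, on=on, suffixes=("_c", "_s"))
        merged = merged.loc[merged[f"{dropped}_c"] != merged[f"{dropped}_s"]]
        two_field_pairs.update(
            zip(merged["code_c"], merged["code_s"])
        )
    for c, s in sorted(two_field_pairs):
        if matched.get(c) == s:
            continue
        if c in matched and s in matched_surv:
            continue  # both already resolved elsewhere
        queue_rows.append({
            "cohort_code": c, "surveillance_code": s,
            "n_fields_agree": 2, "reason": "partial_match",
        })

    for c in bad_coh:
        queue_rows.append({"cohort_code": c, "surveillance_code": "",
                           "n_fields_agree": 0, "reason": "unparseable_birth_date"})
    for s in bad_srv:
        queue_rows.append({"cohort_code": "", "surveillance_code": s,
                           "n_fields_agree": 0, "reason": "unparseable_birth_date"})

    queue = pd.DataFrame(
        queue_rows, columns=["cohort_code", "surveillance_code", "n_fields_agree", "reason"]
    ).sort_values(["reason", "cohort_code", "surveillance_code"]).reset_index(drop=True)

    return LinkResult(
        matched=matched,
        unmatched_cohort=unmatched_cohort,
        unmatched_surveillance=unmatched_surv,
        review_queue=queue,
    )


def linkage_recovery(result: LinkResult, truth: LinkTruth) -> tuple[float, float]:
    """(sensitivity, false-match rate) of the auto-matcher against truth.

    Sensitivity is the fraction of true links auto-matched; the false
    match rate is the fraction of auto-matches that are not true links.
    """
    true_pairs = set(truth.code_map.items())
    auto_pairs = set(result.matched.items())
    sensitivity = len(auto_pairs & true_pairs) / len(true_pairs) if true_pairs else 1.0
    fmr = len(auto_pairs - true_pairs) / len(auto_pairs) if auto_pairs else 0.0
    return sensitivity, fmr
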