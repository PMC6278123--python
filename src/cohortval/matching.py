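"""Closest-date one-to-one pairing of lab results across two sources.

For one patient and one analyte, each cohort result is paired with the
closest-dated surveillance result of the same analyte within a symmetric
window (default 30 days, inclusive).  Pairing is greedy over all
within-window cross-pairs in ascending order of absolute date gap; ties
break on the earlier cohort date, then the earlier surveillance date.
Plain closest-date greed can strand pairable results in alternating
chains (a result's nearest partner "steals" the only partner of
another), so a deterministic augmenting-path pass then rescues any
result that can still be paired, making the final matching maximum
cardinality while keeping the greedy closest-date pairs wherever they do
not block anyone.  Each result is used at most once; leftovers are
returned unmatched.  Same-day duplicate tests within one source are
first deduplicated to the earliest-entered record.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InputError

__all__ = ["MatchResult", "match_tests"]


@dataclass
class MatchResult:
    """One-to-one pairing of two dated result series.

    ``pairs`` has one row per matched pair: the positional indices into
    the (deduplicated) input frames, both dates and values, and
    ``delta_days`` = surveillance date − cohort date.  ``unmatched_a`` /
    ``unmatched_b`` are the leftover positional indices; ``n_dedup_*``
    count same-day duplicates dropped before matching.
    """

    pairs: pd.DataFrame
    unmatched_a: list
    unmatched_b: list
    n_dedup_a: int = 0
    n_dedup_b: int = 0


def _prepare(series: pd.DataFrame, which: str) -> tuple[pd.DataFrame, int]:
    if "collection_date" not in series.columns:
        raise InputError(f"series {which} lacks a collection_date column")
    if "analyte" in series.columns and series["analyte"].nunique() > 1:
        raise InputError(
            f"series {which} mixes analytes {sorted(series['analyte'].unique())}; "
            "match one analyte at a time"
        )
    df = series.reset_index(drop=True).copy()
    df["collection_date"] = pd.to_datetime(df["collection_date"])
    # stable dedup: keep the earliest-entered record per calendar day
    keep = ~df["collection_date"].duplicated(keep="first")
    return df.loc[keep].copy(), int((~keep).sum())


def match_tests(series_a: pd.DataFrame, series_b: pd.DataFrame,
                window_days: int = 30) -> MatchResult:
    """Pair results of one analyte for one patient across two sources.

    Parameters
    ----------
    series_a, series_b :
        Result tables (cohort and surveillance, respectively) with a
        ``collection_date`` column and optionally ``value``/``analyte``.
    window_days :
        Maximum absolute date gap for a pair, inclusive.
    """
    if window_days <= 0:
        raise InputError("window_days must be positive")
    a, ndup_a = _prepare(series_a, "a")
    b, ndup_b = _prepare(series_b, "b")

    cols = ["a_index", "b_index", "a_date", "b_date", "delta_days"]
    has_values = "value" in a.columns and "value" in b.columns
    if has_values:
        cols += ["a_value", "b_value"]

    if len(a) == 0 or len(b) == 0:
        return MatchResult(pd.DataFrame(columns=cols), list(a.index), list(b.index),
                           ndup_a, ndup_b)

    a_days = a["collection_date"].values.astype("datetime64[D]").astype(int)
    b_days = b["collection_date"].values.astype("datetime64[D]").astype(int)
    delta = b_days[None, :] - a_days[:, None]  # surveillance − cohort
    ai, bi = np.nonzero(np.abs(delta) <= window_days)
    order = np.lexsort((b_days[bi], a_days[ai], np.abs(delta[ai, bi])))

    match_of_b: dict[int, int] = {}  # b position -> a position
    matched_a: set[int] = set()
    for k in order:
        i, j = int(ai[k]), int(bi[k])
        if i in matched_a or j in match_of_b:
            continue
        matched_a.add(i)
        match_of_b[j] = i

    # adjacency per cohort result, neighbours in closest-date order
    adj: dict[int, list[int]] = {i: [] for i in range(len(a))}
    for k in order:
        adj[int(ai[k])].append(int(bi[k]))

    def _augment(i: int, visited: set[int]) -> bool:
        for j in adj[i]:
            if j in visited:
                continue
            visited.add(j)
            if j not in match_of_b or _augment(match_of_b[j], visited):
                match_of_b[j] = i
                return True
        return False

    # rescue results stranded by greedy blocking chains (max cardinality)
    for i in range(len(a)):
        if i not in matched_a and _augment(i, set()):
            matched_a.add(i)

    rows = []
    for j, i in sorted(match_of_b.items()):
        row = {
            "a_index": int(a.index[i]), "b_index": int(b.index[j]),
            "a_date": a["collection_date"].iloc[i], "b_date": b["collection_date"].iloc[j],
            "delta_days": int(delta[i, j]),
        }
        if has_values:
            row["a_value"] = a["value"].iloc[i]
            row["b_value"] = b["value"].iloc[j]
        rows.append(row)
    used_a = np.zeros(len(a), dtype=bool)
    used_b = np.zeros(len(b), dtype=bool)
    for j, i in match_of_b.items():
        used_a[i] = used_b[j] = True

    pairs = pd.DataFrame(rows, columns=cols)
    if len(pairs):
        pairs = pairs.sort_values("a_date").reset_index(drop=True)
    unmatched_a = [int(a.index[i]) for i in range(len(a)) if not used_a[i]]
    unmatched_b = [int(b.index[j]) for j in range(len(b)) if not used_b[j]]
    return MatchResult(pairs, unmatched_a, unmatched_b, ndup_a, ndup_b)
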