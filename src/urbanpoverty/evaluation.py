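"""Selecting the preferred poverty measure across cities.

Seven candidate measures label every household poor/rich: three absolute
(``pline``, ``sds``, ``slum``) and four relative wealth-percentile cut-offs
(``w30`` … ``w60``).  Three criteria drive the choice:

1. feasibility — the unweighted poorest-group sample size per city
   (summarised across cities as median / IQR / min / max);
2. discriminatory power — the median rich−poor gap in the welfare outcomes;
3. comparability — the observed agreement (share of households given the
   same label) between each relative and each absolute measure, adequate
   when the median across cities is at least 0.60.

:func:`select_preferred_measure` freezes this into a deterministic rule:
keep measures with a median poorest-group count of at least ``min_n``; among
the surviving *relative* measures keep those whose median agreement with
every absolute measure reaches the threshold; if several remain take the one
with the largest mean absolute median gap across outcomes, breaking ties
toward the smaller cut-off.  The full decision record is always returned;
an empty survivor set yields an explicit no-selection result, never a silent
default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import EmptyDomainError

__all__ = [
    "MEASURES",
    "RELATIVE_MEASURES",
    "ABSOLUTE_MEASURES",
    "poorest_group_sizes",
    "observed_agreement",
    "agreement_by_city",
    "median_gap",
    "select_preferred_measure",
    "SelectionResult",
]

#: measure id -> kind, in catalog order
MEASURES = {
    "pline": "absolute",
    "sds": "absolute",
    "slum": "absolute",
    "w30": "relative",
    "w40": "relative",
    "w50": "relative",
    "w60": "relative",
}
RELATIVE_MEASURES = tuple(m for m, k in MEASURES.items() if k == "relative")
ABSOLUTE_MEASURES = tuple(m for m, k in MEASURES.items() if k == "absolute")

_CUTOFF = {"w30": 30, "w40": 40, "w50": 50, "w60": 60}


def poorest_group_sizes(labels_by_city: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Across-city summary of the unweighted poorest-group size per measure.

    ``labels_by_city`` maps city id to a DataFrame with one float/bool column
    per measure (1 = poor, NaN = unclassified).  Returns one row per measure
    with count and share (%) summaries (unweighted median/P25/P75/min/max,
    each city counting once).
    """
    rows = []
    measures = None
    per_city = {}
    for city, df in labels_by_city.items():
        measures = measures or [c for c in df.columns if c in MEASURES]
        for m in measures:
            col = pd.to_numeric(df[m], errors="coerce")
            n_poor = int((col == 1.0).sum())
            n_tot = int(col.notna().sum())
            per_city.setdefault(m, []).append((n_poor, 100.0 * n_poor / n_tot if n_tot else np.nan))
    for m, vals in per_city.items():
        counts = np.array([v[0] for v in vals], float)
        shares = np.array([v[1] for v in vals], float)
        rows.append({
            "measure": m,
            "count_median": float(np.median(counts)),
            "count_p25": float(np.percentile(counts, 25)),
            "count_p75": float(np.percentile(counts, 75)),
            "count_min": float(counts.min()),
            "count_max": float(counts.max()),
            "share_median": float(np.nanmedian(shares)),
            "share_p25": float(np.nanpercentile(shares, 25)),
            "share_p75": float(np.nanpercentile(shares, 75)),
            "share_min": float(np.nanmin(shares)),
            "share_max": float(np.nanmax(shares)),
            "n_cities": len(vals),
        })
    return pd.DataFrame(rows).set_index("measure")


def observed_agreement(labels_a, labels_b, weights=None) -> float:
    """Share of households given the same poor/rich label by two measures.

    Unweighted by default; pass weights for the weighted variant.  Households
    missing either label are excluded; an empty overlap is an error.
    """
    a = pd.to_numeric(pd.Series(labels_a).reset_index(drop=True), errors="coerce")
    b = pd.to_numeric(pd.Series(labels_b).reset_index(drop=True), errors="coerce")
    if len(a) != len(b):
        raise ValueError("label vectors must have equal length")
    ok = a.notna() & b.notna()
    if not ok.any():
        raise EmptyDomainError("no households classified by both measures")
    same = (a[ok].astype(bool) == b[ok].astype(bool)).to_numpy(float)
    if weights is None:
        return float(same.mean())
    w = np.asarray(weights, dtype=float)[ok.to_numpy()]
    return float(np.sum(w * same) / np.sum(w))


def agreement_by_city(labels_by_city: dict[str, pd.DataFrame], weighted: bool = False,
                      weights_by_city: dict | None = None) -> pd.DataFrame:
    """Observed agreement of every relative × absolute measure pair, per city,
    plus the across-city median per pair (long format)."""
    rows = []
    for city, df in labels_by_city.items():
        w = weights_by_city[city] if (weighted and weights_by_city) else None
        for rel in RELATIVE_MEASURES:
            for ab in ABSOLUTE_MEASURES:
                if rel not in df.columns or ab not in df.columns:
                    continue
                rows.append({
                    "city_id": city, "relative": rel, "absolute": ab,
                    "agreement": observed_agreement(df[rel], df[ab], w),
                })
    return pd.DataFrame(rows)


def agreement_medians(agreements: pd.DataFrame) -> pd.DataFrame:
    """Median across cities of the per-city agreement, per measure pair."""
    return (agreements.groupby(["relative", "absolute"])["agreement"]
            .median().rename("median_agreement").reset_index())


def median_gap(group_prevalences: pd.DataFrame) -> pd.DataFrame:
    """Across-city medians of poor/rich outcome prevalences and their gap.

    Input is long format with columns ``city_id, measure, outcome,
    prev_poor, prev_rich``.  Gap = median(rich) − median(poor): negative when
    the poor fare worse on a deprivation outcome.
    """
    med = (group_prevalences.groupby(["measure", "outcome"])[["prev_poor", "prev_rich"]]
           .median().reset_index())
    med = med.rename(columns={"prev_poor": "median_poor", "prev_rich": "median_rich"})
    med["gap"] = med["median_rich"] - med["median_poor"]
    return med


@dataclass
class SelectionResult:
    """Outcome of the three-criterion selection, with the full audit trail."""

    selected: str | None
    decision_record: pd.DataFrame
    reason: str
    parameters: dict = field(default_factory=dict)


def select_preferred_measure(
    size_summary: pd.DataFrame,
    gaps: pd.DataFrame,
    agreement_median_table: pd.DataFrame,
    min_n: float = 100.0,
    agreement_threshold: float = 0.60,
) -> SelectionResult:
    """Deterministic three-step selection among the relative measures.

    ``agreement_median_table`` is the output of :func:`agreement_medians`
    (or :func:`agreement_by_city` — medians are then computed here).
    """
    if "median_agreement" not in agreement_median_table.columns:
        agreement_median_table = agreement_medians(agreement_median_table)

    record = []
    for m in MEASURES:
        if m not in size_summary.index:
            continue
        row = {"measure": m, "kind": MEASURES[m],
               "median_poorest_count": size_summary.loc[m, "count_median"]}
        row["size_ok"] = row["median_poorest_count"] >= min_n
        if MEASURES[m] == "relative":
            ag = agreement_median_table[agreement_median_table["relative"] == m]
            row["min_median_agreement"] = float(ag["median_agreement"].min()) if len(ag) else np.nan
            row["agreement_ok"] = bool(len(ag)) and bool((ag["median_agreement"] >= agreement_threshold).all())
        else:
            row["min_median_agreement"] = np.nan
            row["agreement_ok"] = np.nan
        g = gaps[gaps["measure"] == m]
        row["mean_abs_median_gap"] = float(g["gap"].abs().mean()) if len(g) else np.nan
        record.append(row)
    record = pd.DataFrame(record).set_index("measure")

    params = {"min_n": min_n, "agreement_threshold": agreement_threshold}
    candidates = record[(record["kind"] == "relative") & record["size_ok"]]
    if candidates.empty:
        return SelectionResult(None, record, "no relative measure meets the sample-size floor", params)
    passing = candidates[candidates["agreement_ok"] == True]  # noqa: E712
    if passing.empty:
        return SelectionResult(
            None, record,
            "no relative measure has median agreement >= threshold with every absolute measure",
            params,
        )
    best_gap = passing["mean_abs_median_gap"].max()
    tied = passing[np.isclose(passing["mean_abs_median_gap"], best_gap) |
                   passing["mean_abs_median_gap"].isna()]
    if passing["mean_abs_median_gap"].isna().all():
        tied = passing
    winner = min(tied.index, key=lambda m: _CUTOFF.get(m, 999))
    reason = ("single measure passed all criteria" if len(passing) == 1
              else "largest mean absolute median gap (ties broken toward the smaller cut-off)")
    return SelectionResult(winner, record, reason, params)
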