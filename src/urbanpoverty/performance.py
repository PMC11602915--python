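"""Per-city poor/rich gaps, the quadrant performance classification, and
correlations of prevalence/inequality with city-level human development.

Performance rule (all percentages / percentage points):

- prevalence bands: low < 5, intermediate 5–15 (edges inclusive), high > 15
- inequality bands: low when the rich−poor gap is within ±5 pp (inclusive),
  high otherwise
- class: (low, low) → good; (intermediate, low) or (low, high) →
  intermediate; (intermediate or high, high) → worse; (high, low) → worse
  (the rule's text leaves this cell open; a high burden is never "good",
  and the decision record flags whenever the extension fires).

Correlations are Pearson r with 95% Fisher-z confidence intervals,
tanh(atanh(r) ± 1.96/sqrt(n−3)), one r per outcome × statistic
(prev_poor / prev_rich / gap) × index (HDI and its three sub-indices).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import EmptyDomainError
from .outcomes import OUTCOME_NAMES
from .survey import weighted_prevalence

__all__ = [
    "PerformanceRule",
    "group_prevalences",
    "classify_performance",
    "performance_table",
    "context_correlations",
    "export_tidy_outputs",
]


@dataclass(frozen=True)
class PerformanceRule:
    low_prev_max: float = 5.0       # prev < 5 is low
    high_prev_min: float = 15.0     # prev > 15 is high; [5, 15] intermediate
    low_gap_abs: float = 5.0        # |gap| <= 5 pp is low inequality

    def prevalence_band(self, prev_pct: float) -> str:
        if not 0.0 <= prev_pct <= 100.0:
            raise ValueError(f"prevalence {prev_pct} outside [0, 100]")
        if prev_pct < self.low_prev_max:
            return "low"
        if prev_pct <= self.high_prev_min:
            return "intermediate"
        return "high"

    def inequality_band(self, gap_pp: float) -> str:
        if not -100.0 <= gap_pp <= 100.0:
            raise ValueError(f"gap {gap_pp} outside [-100, 100]")
        return "low" if abs(gap_pp) <= self.low_gap_abs else "high"


def classify_performance(prev_pct: float, gap_pp: float,
                         rule: PerformanceRule | None = None) -> str:
    """Quadrant class for one city × outcome: good / intermediate / worse."""
    rule = rule or PerformanceRule()
    p = rule.prevalence_band(prev_pct)
    g = rule.inequality_band(gap_pp)
    if p == "low" and g == "low":
        return "good"
    if (p == "intermediate" and g == "low") or (p == "low" and g == "high"):
        return "intermediate"
    return "worse"


def group_prevalences(households: pd.DataFrame, poor, outcome_df: pd.DataFrame,
                      city_id: str | None = None) -> pd.DataFrame:
    """Weighted prevalence of each outcome among poor, rich and overall.

    ``poor`` is a 1/0/NaN or boolean vector aligned with ``households``.
    Returns long format with gap = rich − poor (proportions; ×100 for pp).
    An empty group leaves that prevalence missing with a diagnostic column.
    """
    w = households["weight"].to_numpy(float)
    p = pd.to_numeric(pd.Series(np.asarray(poor), index=households.index), errors="coerce")
    poor_mask = (p == 1.0).to_numpy()
    rich_mask = (p == 0.0).to_numpy()
    rows = []
    for out in outcome_df.columns:
        x = outcome_df[out]
        row = {"city_id": city_id or str(households["city_id"].iloc[0]) if "city_id" in households.columns else city_id,
               "outcome": out,
               "n_poor": int(poor_mask.sum()), "n_rich": int(rich_mask.sum())}
        for name, mask in (("prev_poor", poor_mask), ("prev_rich", rich_mask), ("prev_overall", None)):
            try:
                val, n_eff = weighted_prevalence(x, w, mask)
            except EmptyDomainError:
                val, n_eff = np.nan, 0
            row[name] = val
            row[f"{name}_n"] = n_eff
        row["gap"] = row["prev_rich"] - row["prev_poor"]
        rows.append(row)
    return pd.DataFrame(rows)


def performance_table(city_summaries: pd.DataFrame,
                      rule: PerformanceRule | None = None,
                      prevalence_basis: str = "overall") -> pd.DataFrame:
    """City × outcome matrix of performance classes, plus per-city counts.

    ``prevalence_basis`` selects which prevalence feeds the quadrant rule:
    the overall city prevalence (default) or the poor-group prevalence.
    """
    rule = rule or PerformanceRule()
    col = {"overall": "prev_overall", "poor": "prev_poor"}[prevalence_basis]
    df = city_summaries.copy()

    def _cls(r):
        if pd.isna(r[col]) or pd.isna(r["gap"]):
            return "missing"
        return classify_performance(100.0 * r[col], 100.0 * r["gap"], rule)

    df["performance"] = df.apply(_cls, axis=1)
    wide = df.pivot(index="city_id", columns="outcome", values="performance")
    wide = wide.reindex(columns=[o for o in OUTCOME_NAMES if o in wide.columns])
    outcome_cols = list(wide.columns)
    for cls in ("good", "intermediate", "worse"):
        wide[f"n_{cls}"] = (wide[outcome_cols] == cls).sum(axis=1)
    return wide.sort_index()


def _fisher_ci(r: float, n: int, level: float = 0.95) -> tuple[float, float]:
    if n <= 3 or abs(r) >= 1.0:
        return (np.nan, np.nan)
    z = math.atanh(r)
    half = 1.959963984540054 * (1.0 / math.sqrt(n - 3))
    return (math.tanh(z - half), math.tanh(z + half))


def context_correlations(city_summaries: pd.DataFrame, contexts: pd.DataFrame) -> pd.DataFrame:
    """Pearson r (with Fisher 95% CI and n) of each outcome statistic against
    each human-development index across cities.

    Degenerate variance in either variable flags the cell undefined
    (r = NaN) rather than raising.
    """
    indices = ["hdi", "health_index", "education_index", "income_index"]
    merged = city_summaries.merge(contexts[["city_id"] + indices], on="city_id", how="inner")
    rows = []
    for outcome, sub in merged.groupby("outcome"):
        for stat in ("prev_poor", "prev_rich", "gap"):
            for idx in indices:
                pair = sub[[stat, idx]].dropna()
                n = len(pair)
                x, y = pair[stat].to_numpy(float), pair[idx].to_numpy(float)
                if n < 4 or x.max() == x.min() or y.max() == y.min():
                    r, lo, hi = np.nan, np.nan, np.nan
                    flag = "undefined" if (n >= 4) else "insufficient_n"
                else:
                    r = float(np.corrcoef(x, y)[0, 1])
                    lo, hi = _fisher_ci(r, n)
                    flag = ""
                rows.append({"outcome": outcome, "statistic": stat, "index": idx,
                             "r": r, "ci_low": lo, "ci_high": hi, "n": n, "flag": flag})
    return pd.DataFrame(rows)


def export_tidy_outputs(city_summaries: pd.DataFrame, correlations: pd.DataFrame,
                        performance: pd.DataFrame, outdir, plots: bool = False,
                        rule: PerformanceRule | None = None) -> dict:
    """Write tidy CSVs for the standard visualisations; deterministic bytes.

    equiplot.csv — city × group × outcome prevalence;
    boxplot.csv — per-group prevalence distributions (long);
    quadrant.csv — overall prevalence vs gap with the performance class;
    correlations.csv — r + CI per outcome × statistic × index.
    """
    from pathlib import Path

    rule = rule or PerformanceRule()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    long = city_summaries.melt(
        id_vars=["city_id", "outcome"], value_vars=["prev_poor", "prev_rich"],
        var_name="group", value_name="prevalence")
    long["group"] = long["group"].str.replace("prev_", "", regex=False)
    long = long.sort_values(["outcome", "city_id", "group"], kind="stable")
    equiplot = outdir / "equiplot.csv"
    long.to_csv(equiplot, index=False)

    box = long.copy()
    boxplot = outdir / "boxplot.csv"
    box.to_csv(boxplot, index=False)

    quad = city_summaries[["city_id", "outcome", "prev_overall", "gap"]].copy()
    quad["prevalence_pct"] = 100.0 * quad["prev_overall"]
    quad["gap_pp"] = 100.0 * quad["gap"]
    quad["performance"] = [
        "missing" if (pd.isna(p) or pd.isna(g)) else classify_performance(p, g, rule)
        for p, g in zip(quad["prevalence_pct"], quad["gap_pp"])
    ]
    quadrant = outdir / "quadrant.csv"
    quad.sort_values(["outcome", "city_id"], kind="stable").to_csv(quadrant, index=False)

    corr = outdir / "correlations.csv"
    correlations.to_csv(corr, index=False)

    perf = outdir / "performance_table.csv"
    performance.to_csv(perf)

    files = {"equiplot": equiplot, "boxplot": boxplot, "quadrant": quadrant,
             "correlations": corr, "performance_table": perf}

    if plots:
        files.update(_render_plots(long, quad, correlations, outdir))
    return files


def _render_plots(long: pd.DataFrame, quad: pd.DataFrame, correlations: pd.DataFrame, outdir):
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    files = {}
    fig, ax = plt.subplots(figsize=(7, 4))
    for i, (outcome, sub) in enumerate(quad.groupby("outcome")):
        ax.scatter(sub["gap_pp"], sub["prevalence_pct"], s=12, label=outcome)
    ax.axhline(5, ls=":", lw=0.8, c="grey")
    ax.axhline(15, ls=":", lw=0.8, c="grey")
    ax.axvline(-5, ls=":", lw=0.8, c="grey")
    ax.axvline(5, ls=":", lw=0.8, c="grey")
    ax.set_xlabel("rich − poor gap (pp)")
    ax.set_ylabel("overall prevalence (%)")
    ax.legend(fontsize=6)
    path = outdir / "quadrant.png"
    fig.savefig(path, dpi=120)
    plt.close(fig)
    files["quadrant_plot"] = path
    return files
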