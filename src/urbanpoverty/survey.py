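"""Core data model and survey-weighted estimation primitives.

A survey for one city is a :class:`SurveyDataset`: a household table (one row
per household, with sampling weight, design ids, asset/housing/WASH
variables) plus a person roster linked by ``household_id``.  City-level macro
covariates live in :class:`CityContext`.

The two estimation primitives every downstream stage uses are
:func:`weighted_prevalence` (a ratio estimator Σwx/Σw over a subset, with
listwise exclusion of missing indicator values) and
:func:`weighted_quantile_rank` (midpoint cumulative-weight ranks in [0, 1],
used for wealth-percentile cut-offs).  Point estimates only: design-based
variance estimation is deliberately out of scope, but the unweighted
effective n is always reported alongside a prevalence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .dictionary import VariableDictionary, default_dictionary
from .errors import DegenerateDataError, EmptyDomainError, MappingError, RecodeError

logger = logging.getLogger(__name__)

__all__ = [
    "CityContext",
    "SurveyDataset",
    "ColumnMapping",
    "read_survey",
    "write_survey",
    "weighted_prevalence",
    "weighted_quantile_rank",
    "weighted_mean",
    "HOUSEHOLD_COLUMNS",
    "PERSON_COLUMNS",
]

#: canonical household columns (assets are ``asset_<name>`` on top of these)
HOUSEHOLD_COLUMNS = [
    "household_id",
    "city_id",
    "cluster_id",
    "stratum_id",
    "weight",
    "n_members",
    "persons_per_room",
    "electricity",
    "water_source",
    "time_to_water",
    "sanitation_type",
    "sanitation_shared",
    "cooking_fuel",
    "floor_material",
    "wall_material",
    "roof_material",
]

PERSON_COLUMNS = ["person_id", "household_id", "age_years", "edu_years", "in_school"]

#: columns that must be present after mapping for any analysis to run
MANDATORY_HOUSEHOLD = ["household_id", "weight", "n_members"]
MANDATORY_PERSON = ["person_id", "household_id", "age_years"]


@dataclass(frozen=True)
class CityContext:
    """Macro covariates for one city.

    ``gdp_per_capita`` is in currency units per person-year; consumption
    shares are percentages of GDP; the human-development indices are each in
    [0, 1] and ``hdi`` is the mean of the three sub-indices.
    """

    city_id: str
    gdp_per_capita: float
    gini: float
    hh_consumption_share: float
    total_consumption_share: float
    hdi: float
    health_index: float
    education_index: float
    income_index: float

    def __post_init__(self):
        if not 0.0 <= self.gini < 1.0:
            raise ValueError(f"gini must be in [0, 1): got {self.gini}")
        for name in ("hdi", "health_index", "education_index", "income_index"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]: got {v}")
        for name in ("hh_consumption_share", "total_consumption_share"):
            v = getattr(self, name)
            if not 0.0 < v <= 100.0:
                raise ValueError(f"{name} must be in (0, 100]: got {v}")

    def to_dict(self) -> dict:
        return {
            "city_id": self.city_id,
            "gdp_per_capita": self.gdp_per_capita,
            "gini": self.gini,
            "hh_consumption_share": self.hh_consumption_share,
            "total_consumption_share": self.total_consumption_share,
            "hdi": self.hdi,
            "health_index": self.health_index,
            "education_index": self.education_index,
            "income_index": self.income_index,
        }


@dataclass
class SurveyDataset:
    """One city's survey: household table + person roster."""

    city_id: str
    households: pd.DataFrame
    persons: pd.DataFrame

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        hh = self.households
        if hh.empty:
            raise ValueError("household table is empty")
        if hh["household_id"].duplicated().any():
            dup = hh.loc[hh["household_id"].duplicated(), "household_id"].iloc[0]
            raise ValueError(f"duplicate household_id {dup!r}")
        w = hh["weight"].to_numpy(float)
        if not np.all(w > 0):
            raise ValueError("sampling weights must be strictly positive")
        if (hh["n_members"].to_numpy(float) < 1).any():
            raise ValueError("household sizes must be >= 1")
        known = set(hh["household_id"])
        orphan = ~self.persons["household_id"].isin(known)
        if orphan.any():
            bad = self.persons.loc[orphan, "household_id"].iloc[0]
            raise ValueError(f"person roster references unknown household_id {bad!r}")

    @property
    def n_households(self) -> int:
        return len(self.households)

    def roster_sizes(self) -> pd.Series:
        """Roster size per household (0 for households with no roster rows)."""
        counts = self.persons.groupby("household_id").size()
        return counts.reindex(self.households["household_id"], fill_value=0)


# ---------------------------------------------------------------------------
# column mapping / IO
# ---------------------------------------------------------------------------


@dataclass
class ColumnMapping:
    """Maps canonical variable names to source columns, with optional recodes.

    ``household`` / ``person`` map canonical name -> source column name.
    ``recodes`` maps canonical name -> {source value -> canonical code}, applied
    after renaming.  An identity mapping is the default for canonical files.
    """

    household: dict = field(default_factory=dict)
    person: dict = field(default_factory=dict)
    recodes: dict = field(default_factory=dict)

    @classmethod
    def identity(cls) -> "ColumnMapping":
        return cls()

    @classmethod
    def from_yaml(cls, path) -> "ColumnMapping":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(
            household=raw.get("household", {}) or {},
            person=raw.get("person", {}) or {},
            recodes=raw.get("recodes", {}) or {},
        )


_CATEGORICAL_CHECKS = {
    "water_source": "water_codes",
    "sanitation_type": "sanitation_codes",
    "floor_material": "floor_codes",
    "wall_material": "wall_codes",
    "roof_material": "roof_codes",
    "cooking_fuel": "fuel_codes",
}


def _apply_mapping(df: pd.DataFrame, colmap: dict, recodes: dict, mandatory: list[str], which: str) -> pd.DataFrame:
    rename = {src: canon for canon, src in colmap.items()}
    out = df.rename(columns=rename)
    missing = [c for c in mandatory if c not in out.columns]
    if missing:
        raise MappingError(f"{which} table is missing mandatory column(s): {', '.join(missing)}")
    for canon, table in recodes.items():
        if canon not in out.columns:
            continue
        col = out[canon]
        recoded = col.map(lambda v: table.get(v, v))
        out[canon] = recoded
    return out


def read_survey(
    household_path,
    person_path,
    mapping: ColumnMapping | None = None,
    dictionary: VariableDictionary | None = None,
    city_id: str | None = None,
) -> SurveyDataset:
    """Read and validate one city's household + person CSV tables.

    Raises :class:`MappingError` when a mandatory column is absent after
    mapping, :class:`RecodeError` (with the offending row id) when a
    categorical code is not in the variable dictionary, and ``ValueError``
    for referential-integrity violations.
    """
    mapping = mapping or ColumnMapping.identity()
    dictionary = dictionary or default_dictionary()

    hh = pd.read_csv(household_path)
    pp = pd.read_csv(person_path)
    hh = _apply_mapping(hh, mapping.household, mapping.recodes, MANDATORY_HOUSEHOLD, "household")
    pp = _apply_mapping(pp, mapping.person, mapping.recodes, MANDATORY_PERSON, "person")

    for col, codes_attr in _CATEGORICAL_CHECKS.items():
        if col not in hh.columns:
            continue
        codes = getattr(dictionary, codes_attr)
        vals = hh[col].dropna()
        bad = ~vals.isin(codes)
        if bad.any():
            idx = vals.index[bad][0]
            raise RecodeError(
                f"{col}={vals.loc[idx]!r} (household {hh.loc[idx, 'household_id']!r}) "
                f"is not a recognised code"
            )

    if city_id is None:
        city_id = str(hh["city_id"].iloc[0]) if "city_id" in hh.columns else "city"
    return SurveyDataset(city_id=city_id, households=hh, persons=pp)


def write_survey(dataset: SurveyDataset, household_path, person_path) -> None:
    dataset.households.to_csv(household_path, index=False)
    dataset.persons.to_csv(person_path, index=False)


# ---------------------------------------------------------------------------
# weighted estimation primitives
# ---------------------------------------------------------------------------


def _as_float_array(x) -> np.ndarray:
    if isinstance(x, pd.Series):
        return x.astype("float64").to_numpy(na_value=np.nan) if x.dtype == "boolean" else x.to_numpy(dtype=float, na_value=np.nan)
    return np.asarray(x, dtype=float)


def weighted_prevalence(indicator, weights, subset=None) -> tuple[float, int]:
    """Survey-weighted prevalence Σ(w·x)/Σ(w) over a subset of households.

    Missing indicator values are excluded from numerator and denominator
    (listwise per indicator).  Returns ``(proportion, effective_n)`` where
    ``effective_n`` is the unweighted count of contributing households.

    Raises :class:`EmptyDomainError` if no household with a nonmissing
    indicator falls in the subset — an empty domain is an error, never 0.
    """
    x = _as_float_array(indicator)
    w = np.asarray(weights, dtype=float)
    if x.shape != w.shape:
        raise ValueError("indicator and weights must have equal length")
    mask = ~np.isnan(x)
    if subset is not None:
        mask &= np.asarray(subset, dtype=bool)
    n = int(mask.sum())
    if n == 0:
        raise EmptyDomainError("no households with a nonmissing indicator in the requested subset")
    wm = w[mask]
    return float(np.sum(wm * x[mask]) / np.sum(wm)), n


def weighted_mean(values, weights, subset=None) -> float:
    """Weighted mean of a real-valued column (same missing-data policy)."""
    return weighted_prevalence(values, weights, subset)[0]


def weighted_quantile_rank(scores, weights) -> np.ndarray:
    """Midpoint cumulative-weight rank of each score, in (0, 1).

    rank(h) = (weight strictly below h + half the weight tied at h) / total.
    Invariant to rescaling the weights; monotone nondecreasing in score.
    Missing scores get NaN ranks (and are excluded from the weight totals).
    """
    s = _as_float_array(scores)
    w = np.asarray(weights, dtype=float)
    if s.shape != w.shape:
        raise ValueError("scores and weights must have equal length")
    ok = ~np.isnan(s)
    if not ok.any():
        raise DegenerateDataError("all scores are missing")
    if not ok.all():
        logger.info("weighted_quantile_rank: excluding %d households with missing score", int((~ok).sum()))
    ranks = np.full(s.shape, np.nan)
    sv, wv = s[ok], w[ok]
    order = np.argsort(sv, kind="stable")
    ss, ws = sv[order], wv[order]
    total = ws.sum()
    cum = np.cumsum(ws)
    # group boundaries of tied score values in sorted order
    grp_start = np.concatenate(([True], ss[1:] != ss[:-1]))
    grp_id = np.cumsum(grp_start) - 1
    below = np.concatenate(([0.0], cum[:-1]))[grp_start]  # weight strictly below each group
    grp_w = np.add.reduceat(ws, np.flatnonzero(grp_start))
    grp_rank = (below + 0.5 * grp_w) / total
    r_sorted = grp_rank[grp_id]
    out = np.empty_like(r_sorted)
    out[order] = r_sorted
    ranks[ok] = out
    return ranks
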