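"""Absolute poverty classifiers: poverty line via predicted income,
socioeconomic deprivation status (SDS), and the UN-Habitat slum definition.

Predicted income
----------------
City mean income per capita is derived from GDP per capita with a household
consumption-expenditure correction, and the within-city income distribution
is taken lognormal with the dispersion implied by the city's Gini index:

    sigma = sqrt(2) * Phi^-1((G + 1) / 2),   G = 2*Phi(sigma/sqrt(2)) - 1

A household at weighted wealth rank r is assigned the income at lognormal
quantile r, ``exp(mu + sigma * Phi^-1(r))`` with
``mu = ln(mean) - sigma^2/2``.  A household is below the line when its
predicted income, divided by household size (configurable) and by 365.25,
falls strictly below US$1.9/day.

SDS
---
Eight deprivations with MPI-style nested weights: two education indicators
at 1/4 each (school-age child out of school; no member aged 10+ with 6+
years of schooling) and six living-standards indicators at 1/12 each
(no electricity, unimproved water, inadequate sanitation, non-durable
housing, unclean cooking fuel, asset poverty).  Deprived when the weighted
score reaches the threshold (default 1/3).

Slum
----
A household is a slum household when it lacks any of: durable housing
(floor, wall and roof all durable), sufficient living space (at most 3
persons per room), safe water access (improved source within the time
threshold), adequate sanitation (improved and not shared).  Security of
tenure is not measured in these surveys and is excluded.  Households with a
missing criterion input are excluded (missing flag), never defaulted to
deprived.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm
from sklearn.base import BaseEstimator

from .dictionary import VariableDictionary, default_dictionary
from .errors import ConfigurationError
from .outcomes import (
    low_education,
    no_electricity,
    no_improved_sanitation,
    no_improved_water,
    out_of_school,
)
from .survey import CityContext

logger = logging.getLogger(__name__)

__all__ = [
    "sigma_from_gini",
    "gini_from_sigma",
    "IncomeModel",
    "build_income_model",
    "predicted_income_at_rank",
    "PovertyLineClassifier",
    "classify_below_poverty_line",
    "DeprivationIndex",
    "sds_table",
    "SlumClassifier",
    "slum_table",
    "DAYS_PER_YEAR",
]

DAYS_PER_YEAR = 365.25


def sigma_from_gini(gini: float) -> float:
    """Lognormal sigma implied by a Gini index: sqrt(2)*Phi^-1((G+1)/2)."""
    if not 0.0 <= gini < 1.0:
        raise ConfigurationError(f"gini must be in [0, 1): got {gini}")
    return float(math.sqrt(2.0) * norm.ppf((gini + 1.0) / 2.0))


def gini_from_sigma(sigma: float) -> float:
    """Gini index of a lognormal with scale sigma: 2*Phi(sigma/sqrt(2)) - 1."""
    if sigma < 0:
        raise ConfigurationError("sigma must be nonnegative")
    return float(2.0 * norm.cdf(sigma / math.sqrt(2.0)) - 1.0)


@dataclass(frozen=True)
class IncomeModel:
    """Lognormal city income distribution: mean per-capita income and sigma.

    ``mu`` satisfies mean = exp(mu + sigma^2/2).
    """

    mean_income_per_capita: float
    sigma: float

    def __post_init__(self):
        if self.mean_income_per_capita <= 0:
            raise ConfigurationError("mean_income_per_capita must be positive")
        if self.sigma < 0:
            raise ConfigurationError("sigma must be nonnegative")

    @property
    def mu(self) -> float:
        return math.log(self.mean_income_per_capita) - 0.5 * self.sigma**2


def build_income_model(context: CityContext, correction: str = "share_ratio") -> IncomeModel:
    """Income model from city context.

    ``share_ratio`` (default): mean = GDP pc × household-consumption share /
    total-consumption share.  ``hh_share_of_gdp``: mean = GDP pc ×
    household-consumption share / 100.
    """
    if context.hh_consumption_share <= 0 or context.total_consumption_share <= 0:
        raise ConfigurationError("consumption shares must be positive")
    if correction == "share_ratio":
        mean = context.gdp_per_capita * context.hh_consumption_share / context.total_consumption_share
    elif correction == "hh_share_of_gdp":
        mean = context.gdp_per_capita * context.hh_consumption_share / 100.0
    else:
        raise ConfigurationError(f"unknown correction mode {correction!r}")
    return IncomeModel(mean_income_per_capita=mean, sigma=sigma_from_gini(context.gini))


def predicted_income_at_rank(model: IncomeModel, rank, eps: float | None = None) -> np.ndarray:
    """Income at lognormal quantile ``rank``; strictly increasing in rank.

    Ranks at (or clamped beyond) 0/1 are clipped to [eps, 1-eps]; by default
    eps = 1/(2n) for an array of n ranks.
    """
    r = np.asarray(rank, dtype=float)
    scalar = r.ndim == 0
    r = np.atleast_1d(r)
    if eps is None:
        eps = 1.0 / (2.0 * max(r.size, 1))
    clipped = (r <= 0) | (r >= 1)
    if clipped.any():
        logger.info("predicted_income_at_rank: clamping %d boundary ranks to [%g, %g]",
                    int(clipped.sum()), eps, 1 - eps)
    r = np.clip(r, eps, 1.0 - eps)
    out = np.exp(model.mu + model.sigma * norm.ppf(r))
    return float(out[0]) if scalar else out


class PovertyLineClassifier(BaseEstimator):
    """Below-poverty-line classification from wealth ranks.

    ``division='household'`` (default) treats the model prediction as a
    household income and divides by household size before the daily
    conversion; ``'percapita'`` treats it as already per capita.
    Poor ⟺ daily amount strictly below the line.
    """

    def __init__(self, line_per_day: float = 1.9, division: str = "household",
                 correction: str = "share_ratio"):
        self.line_per_day = line_per_day
        self.division = division
        self.correction = correction

    def fit(self, context: CityContext, y=None):
        if self.division not in ("household", "percapita"):
            raise ConfigurationError(f"unknown division mode {self.division!r}")
        self.income_model_ = build_income_model(context, self.correction)
        return self

    def predict(self, ranks, n_members=None) -> np.ndarray:
        income = predicted_income_at_rank(self.income_model_, ranks)
        income = np.atleast_1d(np.asarray(income, dtype=float))
        if self.division == "household":
            if n_members is None:
                raise ValueError("n_members required under household division mode")
            income = income / np.asarray(n_members, dtype=float)
        daily = income / DAYS_PER_YEAR
        # strict <, robust to float round-trip: a daily amount within machine
        # tolerance of the line counts as exactly at the line (not poor)
        return daily < self.line_per_day * (1.0 - 1e-12)


def classify_below_poverty_line(
    ranks,
    n_members,
    context: CityContext,
    line_per_day: float = 1.9,
    division: str = "household",
    correction: str = "share_ratio",
) -> np.ndarray:
    clf = PovertyLineClassifier(line_per_day, division, correction).fit(context)
    return clf.predict(ranks, n_members)


# ---------------------------------------------------------------------------
# SDS
# ---------------------------------------------------------------------------

SDS_EDUCATION = ("edu_child_out_of_school", "edu_no_qualified_member")
SDS_LIVING = ("ls_no_electricity", "ls_no_improved_water", "ls_no_improved_sanitation",
              "ls_poor_housing", "ls_unclean_fuel", "ls_asset_poor")

#: MPI-style "small" assets; asset-poor = owns at most one of these and no car
SDS_SMALL_ASSETS = ("radio", "tv", "fridge", "phone", "computer", "bicycle", "motorcycle")


class DeprivationIndex(BaseEstimator):
    """Socioeconomic deprivation status: 8 indicators, nested equal weights.

    A stateless transformer in the sklearn sense (fit is a no-op); ``score``
    returns the full indicator table with the weighted deprivation score and
    the deprived flag.
    """

    def __init__(self, threshold: float = 1.0 / 3.0,
                 education_weight: float = 0.25, living_weight: float = 1.0 / 12.0,
                 school_age: tuple[int, int] = (6, 14)):
        self.threshold = threshold
        self.education_weight = education_weight
        self.living_weight = living_weight
        self.school_age = school_age

    def fit(self, X=None, y=None):
        total = 2 * self.education_weight + 6 * self.living_weight
        if not math.isclose(total, 1.0, rel_tol=1e-9):
            raise ConfigurationError("SDS weights must sum to 1 (2×education + 6×living)")
        return self

    def score(self, households: pd.DataFrame, persons: pd.DataFrame,
              dictionary: VariableDictionary | None = None) -> pd.DataFrame:
        d = dictionary or default_dictionary()
        self.fit()
        ind = pd.DataFrame(index=households.index)
        ind["edu_child_out_of_school"] = out_of_school(households, persons, self.school_age)
        ind["edu_no_qualified_member"] = low_education(households, persons, mode="household")
        ind["ls_no_electricity"] = no_electricity(households)
        ind["ls_no_improved_water"] = no_improved_water(households, d)
        ind["ls_no_improved_sanitation"] = no_improved_sanitation(households, d)

        durable = _durable_housing(households, d)
        ind["ls_poor_housing"] = 1.0 - durable

        fuel = households["cooking_fuel"] if "cooking_fuel" in households.columns else pd.Series(np.nan, index=households.index)
        ind["ls_unclean_fuel"] = fuel.map(lambda c: float(c not in d.fuel_clean) if pd.notna(c) else np.nan)

        ind["ls_asset_poor"] = _asset_poor(households)

        weights = np.array([self.education_weight] * 2 + [self.living_weight] * 6)
        cols = list(SDS_EDUCATION) + list(SDS_LIVING)
        M = ind[cols].to_numpy(dtype=float)
        score = M @ weights
        out = ind.copy()
        out["sds_score"] = score
        out["sds_deprived"] = np.where(np.isnan(score), np.nan, (score >= self.threshold).astype(float))
        return out


def _asset_poor(households: pd.DataFrame) -> pd.Series:
    small = [f"asset_{a}" for a in SDS_SMALL_ASSETS if f"asset_{a}" in households.columns]
    if not small:
        return pd.Series(np.nan, index=households.index)
    owned = households[small].astype(float).sum(axis=1)
    car = households["asset_car"].astype(float) if "asset_car" in households.columns else 0.0
    return ((owned <= 1) & (car < 0.5)).astype(float)


def _durable_housing(households: pd.DataFrame, d: VariableDictionary) -> pd.Series:
    """1.0 when floor, wall and roof are all durable; NaN if any is missing."""
    parts = []
    for col, good in [("floor_material", d.floor_durable), ("wall_material", d.wall_durable),
                      ("roof_material", d.roof_durable)]:
        s = households[col] if col in households.columns else pd.Series(np.nan, index=households.index)
        parts.append(s.map(lambda c: float(c in good) if pd.notna(c) else np.nan))
    M = pd.concat(parts, axis=1)
    return M.prod(axis=1, skipna=False)


def sds_table(households: pd.DataFrame, persons: pd.DataFrame,
              dictionary: VariableDictionary | None = None, **kwargs) -> pd.DataFrame:
    """Functional wrapper over :class:`DeprivationIndex`."""
    return DeprivationIndex(**kwargs).score(households, persons, dictionary)


# ---------------------------------------------------------------------------
# UN-Habitat slum
# ---------------------------------------------------------------------------


class SlumClassifier(BaseEstimator):
    """Four-criterion slum household classification (tenure excluded)."""

    def __init__(self, max_persons_per_room: float = 3.0, time_threshold_min: float = 30.0):
        self.max_persons_per_room = max_persons_per_room
        self.time_threshold_min = time_threshold_min

    def fit(self, X=None, y=None):
        return self

    def criteria(self, households: pd.DataFrame,
                 dictionary: VariableDictionary | None = None) -> pd.DataFrame:
        d = dictionary or default_dictionary()
        out = pd.DataFrame(index=households.index)
        out["durable_housing"] = _durable_housing(households, d)
        if "persons_per_room" in households.columns:
            ppr = pd.to_numeric(households["persons_per_room"], errors="coerce")
        else:
            ppr = pd.Series(np.nan, index=households.index)
        out["sufficient_space"] = np.where(np.isnan(ppr), np.nan,
                                           (ppr <= self.max_persons_per_room).astype(float))
        water_dep = no_improved_water(households, d, self.time_threshold_min)
        out["safe_water"] = 1.0 - water_dep
        san_dep = no_improved_sanitation(households, d)
        out["adequate_sanitation"] = 1.0 - san_dep
        return out

    def predict(self, households: pd.DataFrame,
                dictionary: VariableDictionary | None = None) -> pd.Series:
        """1.0 slum / 0.0 not / NaN when any criterion input is missing."""
        c = self.criteria(households, dictionary)
        met_all = c.prod(axis=1, skipna=False)  # NaN propagates -> excluded
        n_missing = int(met_all.isna().sum())
        if n_missing:
            logger.info("slum: %d households excluded for missing criterion inputs", n_missing)
        return (1.0 - met_all).rename("slum")


def slum_table(households: pd.DataFrame, dictionary: VariableDictionary | None = None,
               **kwargs) -> pd.DataFrame:
    clf = SlumClassifier(**kwargs)
    out = clf.criteria(households, dictionary)
    out["slum"] = clf.predict(households, dictionary)
    return out
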