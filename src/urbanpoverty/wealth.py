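"""Wealth index: weighted first-principal-component asset score and the
relative poverty classifications derived from its percentile distribution.

The score follows the DHS wealth-index tradition: binary asset/housing/WASH
indicators are standardised and combined with the loadings of the first
principal component of their (household-weight weighted) correlation matrix,
with the sign oriented so that a higher score means a richer household.

Relative poverty cut-offs (poorest 30/40/50/60% of the within-city weighted
wealth distribution) use midpoint cumulative-weight ranks, so classifications
are deterministic, order-independent, and nested across cut-offs.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .dictionary import VariableDictionary, default_dictionary
from .errors import DegenerateDataError
from .survey import SurveyDataset, weighted_quantile_rank

logger = logging.getLogger(__name__)

__all__ = [
    "WealthSpec",
    "WealthIndex",
    "RelativePovertyClassifier",
    "indicator_matrix",
    "compute_wealth_score",
    "validate_against_provided",
    "classify_relative_poor",
    "DEFAULT_CUTOFFS",
]

DEFAULT_CUTOFFS = (30, 40, 50, 60)

#: derived binary indicators available beyond raw ``asset_*`` columns
_DERIVED = ("electricity", "water_improved", "sanitation_improved", "fuel_clean",
            "floor_durable", "wall_durable", "roof_durable")


@dataclass
class WealthSpec:
    """Which indicators enter the PCA.  ``variables`` mixes ``asset_*`` column
    names and derived indicator names; empty means "all available"."""

    variables: tuple[str, ...] = ()
    standardize: bool = True

    def resolve(self, households: pd.DataFrame) -> tuple[str, ...]:
        if self.variables:
            return self.variables
        assets = tuple(c for c in households.columns if c.startswith("asset_"))
        derived = tuple(v for v in _DERIVED if _derivable(v, households))
        return assets + derived


def _derivable(name: str, hh: pd.DataFrame) -> bool:
    needs = {
        "electricity": ["electricity"],
        "water_improved": ["water_source"],
        "sanitation_improved": ["sanitation_type"],
        "fuel_clean": ["cooking_fuel"],
        "floor_durable": ["floor_material"],
        "wall_durable": ["wall_material"],
        "roof_durable": ["roof_material"],
    }[name]
    return all(c in hh.columns for c in needs)


def indicator_matrix(
    households: pd.DataFrame,
    variables: tuple[str, ...],
    dictionary: VariableDictionary | None = None,
) -> pd.DataFrame:
    """Build the 0/1 indicator matrix for the wealth PCA.

    Missing values are imputed to the (unweighted) within-table mode of the
    variable, with a log line recording how many cells were filled.
    """
    d = dictionary or default_dictionary()
    cols = {}
    for v in variables:
        if v.startswith("asset_") or v == "electricity":
            col = pd.to_numeric(households[v], errors="coerce")
        elif v == "water_improved":
            col = households["water_source"].map(lambda c: float(c in d.water_improved) if pd.notna(c) else np.nan)
        elif v == "sanitation_improved":
            col = households["sanitation_type"].map(
                lambda c: float(c in d.sanitation_improved) if pd.notna(c) else np.nan
            )
        elif v == "fuel_clean":
            col = households["cooking_fuel"].map(lambda c: float(c in d.fuel_clean) if pd.notna(c) else np.nan)
        elif v == "floor_durable":
            col = households["floor_material"].map(lambda c: float(c in d.floor_durable) if pd.notna(c) else np.nan)
        elif v == "wall_durable":
            col = households["wall_material"].map(lambda c: float(c in d.wall_durable) if pd.notna(c) else np.nan)
        elif v == "roof_durable":
            col = households["roof_material"].map(lambda c: float(c in d.roof_durable) if pd.notna(c) else np.nan)
        elif v in households.columns:
            col = pd.to_numeric(households[v], errors="coerce")
        else:
            raise KeyError(f"unknown wealth indicator {v!r}")
        cols[v] = np.asarray(col, dtype=float)
    X = pd.DataFrame(cols, index=households.index)
    n_missing = int(X.isna().to_numpy().sum())
    if n_missing:
        logger.info("indicator_matrix: imputing %d missing cells to variable mode", n_missing)
        for c in X.columns:
            if X[c].isna().any():
                mode = X[c].mode(dropna=True)
                X[c] = X[c].fillna(mode.iloc[0] if len(mode) else 0.0)
    return X


class WealthIndex(TransformerMixin, BaseEstimator):
    """First principal component of standardised welfare indicators.

    Fit computes weighted means/SDs and the leading eigenvector of the
    weighted correlation matrix; transform projects households onto it.
    Zero-variance indicators are dropped with a warning; fewer than two
    usable indicators is an error.

    Attributes
    ----------
    variables_ : list of retained indicator names
    loadings_ : ndarray, first-component loadings (unit norm)
    mean_, scale_ : weighted standardisation parameters
    explained_variance_ratio_ : float, share of total variance on component 1
    """

    def __init__(self, standardize: bool = True):
        self.standardize = standardize

    def fit(self, X: pd.DataFrame, y=None, sample_weight=None):
        X = pd.DataFrame(X)
        n, p = X.shape
        w = np.ones(n) if sample_weight is None else np.asarray(sample_weight, dtype=float)
        w = w / w.sum()
        M = X.to_numpy(dtype=float)
        mean = w @ M
        var = w @ (M - mean) ** 2
        keep = var > 1e-12
        if not keep.all():
            dropped = list(X.columns[~keep])
            warnings.warn(f"dropping zero-variance indicators: {dropped}", stacklevel=2)
        if keep.sum() < 2:
            raise DegenerateDataError("need at least 2 indicators with variance for a wealth index")
        M = M[:, keep]
        mean, var = mean[keep], var[keep]
        scale = np.sqrt(var) if self.standardize else np.ones(keep.sum())
        Z = (M - mean) / scale
        C = (Z * w[:, None]).T @ Z  # weighted covariance of standardised vars = correlation
        evals, evecs = np.linalg.eigh(C)
        v = evecs[:, -1]
        # orient: higher score should mean more assets owned
        if (M @ np.ones(M.shape[1])).std() > 0:
            score = Z @ v
            if np.corrcoef(score, M.sum(axis=1))[0, 1] < 0:
                v = -v
        self.variables_ = list(X.columns[keep])
        self.mean_, self.scale_, self.loadings_ = mean, scale, v
        self.explained_variance_ratio_ = float(evals[-1] / evals.sum())
        return self

    def transform(self, X: pd.DataFrame) -> np.ndarray:
        check_is_fitted(self, "loadings_")
        X = pd.DataFrame(X)[self.variables_]
        Z = (X.to_numpy(dtype=float) - self.mean_) / self.scale_
        return Z @ self.loadings_


class RelativePovertyClassifier(BaseEstimator):
    """Classify households as poor by position in the weighted wealth
    distribution: poor ⟺ midpoint-rank(score) ≤ percent_poor/100.

    Fit stores the reference score/weight distribution; predict ranks query
    scores against it (in-sample calls reproduce the exact tie handling of
    :func:`weighted_quantile_rank`).
    """

    def __init__(self, percent_poor: float = 40.0):
        self.percent_poor = percent_poor

    def fit(self, X, y=None, sample_weight=None):
        if not 0 < self.percent_poor < 100:
            raise ValueError("percent_poor must be in (0, 100)")
        s = np.asarray(X, dtype=float).ravel()
        w = np.ones_like(s) if sample_weight is None else np.asarray(sample_weight, dtype=float)
        ok = ~np.isnan(s)
        if not ok.any():
            raise DegenerateDataError("all scores missing")
        order = np.argsort(s[ok], kind="stable")
        self.ref_scores_ = s[ok][order]
        self.ref_weights_ = w[ok][order]
        self.total_weight_ = float(self.ref_weights_.sum())
        self.ref_cum_ = np.cumsum(self.ref_weights_)
        return self

    def rank(self, X) -> np.ndarray:
        """Midpoint cumulative-weight rank of each query score against the
        fitted reference distribution."""
        check_is_fitted(self, "ref_scores_")
        q = np.asarray(X, dtype=float).ravel()
        lo = np.searchsorted(self.ref_scores_, q, side="left")
        hi = np.searchsorted(self.ref_scores_, q, side="right")
        below = np.where(lo > 0, self.ref_cum_[lo - 1], 0.0)
        tied = np.where(hi > lo, np.where(hi > 0, self.ref_cum_[np.maximum(hi - 1, 0)], 0.0) - below, 0.0)
        r = (below + 0.5 * tied) / self.total_weight_
        r[np.isnan(q)] = np.nan
        return r

    def predict(self, X) -> np.ndarray:
        """Boolean poor flag; NaN scores give False-excluded (returned as
        pandas nullable boolean would — here plain bool with NaN rank → False)."""
        r = self.rank(X)
        return r <= self.percent_poor / 100.0


# ---------------------------------------------------------------------------
# functional wrappers
# ---------------------------------------------------------------------------


def compute_wealth_score(
    dataset: SurveyDataset,
    spec: WealthSpec | None = None,
    dictionary: VariableDictionary | None = None,
) -> pd.Series:
    """Weighted first-PC wealth score for every household in a city."""
    spec = spec or WealthSpec()
    variables = spec.resolve(dataset.households)
    X = indicator_matrix(dataset.households, variables, dictionary)
    model = WealthIndex(standardize=spec.standardize)
    score = model.fit(X, sample_weight=dataset.households["weight"].to_numpy()).transform(X)
    return pd.Series(score, index=dataset.households.index, name="wealth_score")


def validate_against_provided(score_computed, score_provided) -> float:
    """Pearson correlation between a re-computed and a survey-provided wealth
    score, on their overlap.  Degenerate variance raises; the caller decides
    (per the configurable pipeline policy) which score to use."""
    a = np.asarray(score_computed, dtype=float)
    b = np.asarray(score_provided, dtype=float)
    ok = ~(np.isnan(a) | np.isnan(b))
    if ok.sum() < 3:
        raise DegenerateDataError("need >= 3 overlapping households to validate")
    a, b = a[ok], b[ok]
    if a.std() == 0 or b.std() == 0:
        raise DegenerateDataError("undefined correlation: zero variance")
    return float(np.corrcoef(a, b)[0, 1])


def classify_relative_poor(scores, weights, percent_poor: float) -> np.ndarray:
    """poor ⟺ weighted midpoint rank ≤ percent_poor/100 (in-sample)."""
    ranks = weighted_quantile_rank(scores, weights)
    return ranks <= percent_poor / 100.0
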