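"""Household-level welfare outcome indicators.

Five deprivation outcomes, each a deterministic pure function of the
household row and (for the education pair) its person roster:

- ``out_of_school``: any school-age child (default ages 6–14) not attending.
  Households with no school-age children count as not deprived, so they stay
  in prevalence denominators.
- ``low_education``: under the default ``household`` mode, no member aged 10+
  has completed at least 6 years of schooling; the alternative
  ``any_member`` mode flags a household where any member older than 10 has
  under 6 years.  Households with no members in the reference age range are
  missing on this outcome.
- ``no_electricity``, ``no_improved_water``, ``no_improved_sanitation``:
  JMP-ladder classifications via the variable dictionary.  An improved water
  source still counts as deprived when the round-trip collection time is 30
  minutes or longer (threshold inclusive); a missing time on an improved
  source is treated as under threshold and logged.  Sanitation is deprived
  when unimproved, absent, or improved but shared; a missing shared flag on
  an improved facility makes the outcome missing.

Missing outcomes are represented as NaN in float columns (1.0 deprived /
0.0 not / NaN unknown) so they drop out of weighted prevalences.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .dictionary import VariableDictionary, default_dictionary

logger = logging.getLogger(__name__)

__all__ = [
    "OUTCOME_NAMES",
    "out_of_school",
    "low_education",
    "no_electricity",
    "no_improved_water",
    "no_improved_sanitation",
    "outcome_table",
]

OUTCOME_NAMES = (
    "out_of_school",
    "low_education",
    "no_electricity",
    "no_improved_water",
    "no_improved_sanitation",
)


def _numeric_col(households: pd.DataFrame, name: str) -> pd.Series:
    if name not in households.columns:
        return pd.Series(np.nan, index=households.index)
    return pd.to_numeric(households[name], errors="coerce").astype(float)


def out_of_school(
    households: pd.DataFrame,
    persons: pd.DataFrame,
    school_age: tuple[int, int] = (6, 14),
) -> pd.Series:
    """1.0 if any school-age roster member is out of school, else 0.0."""
    lo, hi = school_age
    kids = persons[(persons["age_years"] >= lo) & (persons["age_years"] <= hi)]
    any_out = kids.groupby("household_id")["in_school"].apply(lambda s: float((~s.astype(bool)).any()))
    out = any_out.reindex(households["household_id"], fill_value=0.0)
    out.index = households.index
    return out.rename("out_of_school")


def low_education(
    households: pd.DataFrame,
    persons: pd.DataFrame,
    mode: str = "household",
    min_years: int = 6,
) -> pd.Series:
    """Household education deprivation; NaN when no member is in the
    reference age range (10+ for ``household`` mode, >10 for ``any_member``)."""
    if mode == "household":
        ref = persons[persons["age_years"] >= 10]
        flag = ref.groupby("household_id")["edu_years"].apply(lambda s: float(not (s >= min_years).any()))
    elif mode == "any_member":
        ref = persons[persons["age_years"] > 10]
        flag = ref.groupby("household_id")["edu_years"].apply(lambda s: float((s < min_years).any()))
    else:
        raise ValueError(f"unknown low_education mode {mode!r}")
    out = flag.reindex(households["household_id"])
    out.index = households.index
    return out.rename("low_education")


def no_electricity(households: pd.DataFrame) -> pd.Series:
    """1.0 when the household lacks electricity; missing stays missing."""
    elec = _numeric_col(households, "electricity")
    return (1.0 - elec).rename("no_electricity")


def no_improved_water(
    households: pd.DataFrame,
    dictionary: VariableDictionary | None = None,
    time_threshold_min: float = 30.0,
) -> pd.Series:
    """Unimproved source, or improved but >= 30 minutes round trip."""
    d = dictionary or default_dictionary()
    src = households["water_source"]
    improved = src.map(lambda c: c in d.water_improved if pd.notna(c) else np.nan)
    time = _numeric_col(households, "time_to_water")
    missing_time = improved.eq(True) & time.isna()
    if missing_time.any():
        logger.info("no_improved_water: %d improved-source households missing collection "
                    "time, treated as under threshold", int(missing_time.sum()))
    far = time >= time_threshold_min  # NaN compares False: missing time => near
    out = pd.Series(np.nan, index=households.index, name="no_improved_water")
    out[improved.eq(False)] = 1.0
    out[improved.eq(True)] = far[improved.eq(True)].astype(float)
    return out


def no_improved_sanitation(
    households: pd.DataFrame,
    dictionary: VariableDictionary | None = None,
) -> pd.Series:
    """Unimproved facility, no facility, or improved-but-shared.

    Missing shared flag on an improved facility -> missing outcome (logged).
    """
    d = dictionary or default_dictionary()
    san = households["sanitation_type"]
    if "sanitation_shared" in households.columns:
        shared = households["sanitation_shared"].map(lambda v: bool(v) if pd.notna(v) else np.nan)
    else:
        shared = pd.Series(np.nan, index=households.index)
    out = pd.Series(np.nan, index=households.index, name="no_improved_sanitation")
    is_none = san.isin(d.sanitation_none)
    is_unimp = san.isin(d.sanitation_unimproved)
    is_imp = san.isin(d.sanitation_improved)
    out[is_none | is_unimp] = 1.0
    known_shared = is_imp & shared.notna()
    out[known_shared] = shared[known_shared].astype(float)
    n_unknown = int((is_imp & shared.isna()).sum())
    if n_unknown:
        logger.info("no_improved_sanitation: %d improved facilities with missing shared flag "
                    "left missing", n_unknown)
    return out


def outcome_table(
    households: pd.DataFrame,
    persons: pd.DataFrame,
    dictionary: VariableDictionary | None = None,
    school_age: tuple[int, int] = (6, 14),
    low_education_mode: str = "household",
    time_threshold_min: float = 30.0,
) -> pd.DataFrame:
    """All five outcomes for one city's households (1.0/0.0/NaN columns)."""
    return pd.DataFrame({
        "out_of_school": out_of_school(households, persons, school_age),
        "low_education": low_education(households, persons, low_education_mode),
        "no_electricity": no_electricity(households),
        "no_improved_water": no_improved_water(households, dictionary, time_threshold_min),
        "no_improved_sanitation": no_improved_sanitation(households, dictionary),
    })
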