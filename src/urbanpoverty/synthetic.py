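"""Synthetic multi-city household survey generator.

Emulates the latent structure the analysis assumes in DHS/MICS-style urban
surveys: each household carries a latent socioeconomic position (SES) drawn
around a city-level mean; binary asset ownership and housing/WASH quality are
Bernoulli with logit linear in that latent SES; the person roster carries
education and school-attendance gradients in the same latent factor; and the
city-level context (GDP per capita, Gini, HDI sub-indices) is generated so
that richer cities (higher mean latent SES) have higher GDP and HDI and
somewhat lower Gini.

The hidden latent SES is emitted only in the diagnostics column
``latent_ses_diag``, which is excluded from analysis inputs; it exists so
tests can measure parameter recovery.

Everything is driven by a single integer seed through
``numpy.random.default_rng([seed, city_index, stream])``, so any city can be
regenerated independently and the whole scenario is bit-for-bit reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import norm

from .errors import ConfigurationError
from .survey import CityContext, SurveyDataset, write_survey

__all__ = ["ScenarioConfig", "generate_city", "generate_context", "generate_scenario", "write_scenario"]


def _default_asset_loadings() -> dict:
    # (intercept, loading) on the logit scale; intercepts give realistic
    # urban SSA ownership levels at the city average, loadings give the
    # SES gradient the wealth index is meant to pick up.
    return {
        "radio": (0.4, 1.1),
        "tv": (0.0, 1.5),
        "fridge": (-0.8, 1.6),
        "phone": (1.2, 1.2),
        "computer": (-2.2, 1.6),
        "bicycle": (-0.4, 0.8),
        "motorcycle": (-1.0, 1.0),
        "car": (-2.6, 1.5),
    }


def _default_roster_dist() -> dict:
    # household sizes 1..15, mode around 4, thin upper tail
    sizes = np.arange(1, 16)
    p = np.exp(-0.5 * ((sizes - 4.0) / 2.6) ** 2)
    p[sizes > 8] *= 0.5
    p /= p.sum()
    return {int(s): float(q) for s, q in zip(sizes, p)}


@dataclass
class ScenarioConfig:
    """Study-condition parameters for a generated multi-city scenario.

    Defaults emulate the cross-country urban setting the pipeline targets:
    38 cities of 500–2,000 households, strong positive SES loadings on
    assets and services, Gini between 0.35 and 0.65, GDP per capita between
    800 and 8,000 currency units/year.
    """

    n_cities: int = 38
    households_per_city: tuple[int, int] = (500, 2000)
    latent_ses_sd: float = 1.2
    city_ses_spread: float = 0.6
    asset_loadings: dict = field(default_factory=_default_asset_loadings)
    roster_size_dist: dict = field(default_factory=_default_roster_dist)
    education_gradient: float = 2.0
    school_attendance_gradient: float = 1.0
    gini_range: tuple[float, float] = (0.35, 0.65)
    gdp_pc_range: tuple[float, float] = (800.0, 8000.0)
    hdi_noise_sd: float = 0.02
    school_age: tuple[int, int] = (6, 14)
    cluster_size: int = 20
    seed: int = 0

    def validate(self) -> None:
        if self.n_cities < 1:
            raise ConfigurationError("n_cities must be >= 1")
        lo, hi = self.households_per_city
        if not (1 <= lo <= hi):
            raise ConfigurationError("households_per_city must satisfy 1 <= min <= max")
        if self.latent_ses_sd <= 0:
            raise ConfigurationError("latent_ses_sd must be positive")
        if self.city_ses_spread < 0:
            raise ConfigurationError("city_ses_spread must be nonnegative")
        g0, g1 = self.gini_range
        if not (0.0 <= g0 <= g1 < 1.0):
            raise ConfigurationError("gini_range must be inside [0, 1) with min <= max")
        p0, p1 = self.gdp_pc_range
        if not (0.0 < p0 <= p1):
            raise ConfigurationError("gdp_pc_range must be positive with min <= max")
        if self.hdi_noise_sd < 0:
            raise ConfigurationError("hdi_noise_sd must be nonnegative")
        probs = np.array([self.roster_size_dist.get(s, 0.0) for s in range(1, 16)], float)
        if (probs < 0).any() or not np.isclose(probs.sum(), 1.0):
            raise ConfigurationError("roster_size_dist must be a distribution over sizes 1..15")
        for var, spec in self.asset_loadings.items():
            if len(spec) != 2:
                raise ConfigurationError(f"asset_loadings[{var!r}] must be (intercept, loading)")

    def roster_probs(self) -> np.ndarray:
        return np.array([self.roster_size_dist.get(s, 0.0) for s in range(1, 16)], float)

    def to_jsonable(self) -> dict:
        d = asdict(self)
        d["households_per_city"] = list(self.households_per_city)
        d["asset_loadings"] = {k: list(v) for k, v in self.asset_loadings.items()}
        d["roster_size_dist"] = {str(k): v for k, v in self.roster_size_dist.items()}
        return d


def _rng(config: ScenarioConfig, city_index: int, stream: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, city_index, stream])


def _pick(rng, codes: list[str], n: int) -> np.ndarray:
    return rng.choice(np.array(codes, dtype=object), size=n)


def _city_mean_ses(config: ScenarioConfig, city_index: int) -> float:
    return float(config.city_ses_spread * _rng(config, city_index, 0).standard_normal())


def generate_city(config: ScenarioConfig, city_index: int) -> SurveyDataset:
    """Generate one city's household table and person roster."""
    config.validate()
    if not 0 <= city_index < config.n_cities:
        raise ConfigurationError(f"city_index {city_index} outside [0, n_cities)")
    from .dictionary import default_dictionary

    d = default_dictionary()
    rng = _rng(config, city_index, 1)
    city_id = f"city{city_index:02d}"
    lo, hi = config.households_per_city
    n = int(rng.integers(lo, hi + 1))

    m = _city_mean_ses(config, city_index)
    z = m + config.latent_ses_sd * rng.standard_normal(n)

    hh = pd.DataFrame({
        "household_id": [f"{city_id}h{i:05d}" for i in range(n)],
        "city_id": city_id,
    })
    hh["cluster_id"] = [f"{city_id}c{i // config.cluster_size:03d}" for i in range(n)]
    hh["stratum_id"] = f"{city_id}s0"
    w = rng.uniform(0.5, 2.0, n)
    hh["weight"] = w / w.mean()

    sizes = rng.choice(np.arange(1, 16), size=n, p=config.roster_probs())
    hh["n_members"] = sizes
    rooms = 1 + rng.poisson(np.clip(1.0 + 0.6 * z, 0.1, None))
    hh["persons_per_room"] = sizes / rooms

    hh["electricity"] = rng.random(n) < expit(0.0 + 1.4 * z)

    improved_w = rng.random(n) < expit(0.8 + 1.2 * z)
    on_prem = improved_w & (rng.random(n) < expit(-0.5 + 1.0 * z))
    src = np.where(
        on_prem,
        _pick(rng, sorted(d.water_on_premises), n),
        np.where(
            improved_w,
            _pick(rng, sorted(d.water_improved - d.water_on_premises), n),
            _pick(rng, sorted(d.water_unimproved), n),
        ),
    )
    hh["water_source"] = src
    minutes = np.exp(rng.normal(3.0 - 0.35 * z, 0.6)).round(0)
    minutes[np.isin(src, sorted(d.water_on_premises))] = 0.0
    hh["time_to_water"] = np.clip(minutes, 0, 240)

    improved_s = rng.random(n) < expit(0.5 + 1.2 * z)
    none_s = (~improved_s) & (rng.random(n) < 0.25)
    san = np.where(
        none_s,
        "no_facility",
        np.where(
            improved_s,
            _pick(rng, sorted(d.sanitation_improved), n),
            _pick(rng, sorted(d.sanitation_unimproved), n),
        ),
    )
    hh["sanitation_type"] = san
    shared = rng.random(n) < expit(-0.2 - 0.8 * z)
    shared[san == "no_facility"] = False
    hh["sanitation_shared"] = shared

    fuel_clean = rng.random(n) < expit(-1.0 + 1.3 * z)
    hh["cooking_fuel"] = np.where(
        fuel_clean, _pick(rng, sorted(d.fuel_clean), n), _pick(rng, sorted(d.fuel_unclean), n)
    )

    for part, durable, non_durable in [
        ("floor_material", d.floor_durable, d.floor_non_durable),
        ("wall_material", d.wall_durable, d.wall_non_durable),
        ("roof_material", d.roof_durable, d.roof_non_durable),
    ]:
        is_durable = rng.random(n) < expit(0.7 + 1.2 * z)
        hh[part] = np.where(
            is_durable, _pick(rng, sorted(durable), n), _pick(rng, sorted(non_durable), n)
        )

    for var, (a0, lam) in config.asset_loadings.items():
        hh[f"asset_{var}"] = rng.random(n) < expit(a0 + lam * z)

    # survey-provided wealth score: latent SES plus measurement noise
    hh["survey_wealth_score"] = z + 0.15 * rng.standard_normal(n)
    hh["latent_ses_diag"] = z

    persons = _generate_roster(config, rng, hh, z)
    return SurveyDataset(city_id=city_id, households=hh, persons=persons)


def _generate_roster(config: ScenarioConfig, rng, hh: pd.DataFrame, z: np.ndarray) -> pd.DataFrame:
    sizes = hh["n_members"].to_numpy()
    total = int(sizes.sum())
    hh_idx = np.repeat(np.arange(len(hh)), sizes)
    zi = z[hh_idx]
    # first member of every household is an adult head; others mixed ages
    is_head = np.concatenate([[True] + [False] * (s - 1) for s in sizes])
    ages = rng.integers(0, 71, total)
    ages[is_head] = rng.integers(18, 71, int(is_head.sum()))

    potential = np.clip(ages - 6, 0, 14).astype(float)
    frac = expit(0.3 + 0.5 * config.education_gradient * zi + 0.8 * rng.standard_normal(total))
    edu = np.floor(potential * frac).astype(int)

    s_lo, s_hi = config.school_age
    school_age = (ages >= s_lo) & (ages <= s_hi)
    attend_p = expit(1.0 + config.school_attendance_gradient * zi)
    in_school = school_age & (rng.random(total) < attend_p)

    member_no = np.concatenate([np.arange(s) for s in sizes])
    hh_ids = hh["household_id"].to_numpy()[hh_idx]
    return pd.DataFrame({
        "person_id": [f"{h}p{j}" for h, j in zip(hh_ids, member_no)],
        "household_id": hh_ids,
        "age_years": ages,
        "edu_years": edu,
        "in_school": in_school,
    })


def generate_context(config: ScenarioConfig, dataset: SurveyDataset, city_index: int | None = None) -> CityContext:
    """Generate macro covariates consistent with the city's mean latent SES."""
    config.validate()
    if dataset.households.empty:
        raise ConfigurationError("dataset is empty")
    if city_index is None:
        city_index = int(dataset.city_id.removeprefix("city"))
    rng = _rng(config, city_index, 2)

    m_hat = float(dataset.households["latent_ses_diag"].mean())
    spread = config.city_ses_spread if config.city_ses_spread > 0 else 1.0
    u = float(norm.cdf(m_hat / spread))

    g0, g1 = config.gini_range
    gini = g1 - (g1 - g0) * float(np.clip(u + 0.25 * rng.standard_normal(), 0.0, 1.0))
    p0, p1 = config.gdp_pc_range
    gdp = p0 + (p1 - p0) * float(np.clip(u + 0.15 * rng.standard_normal(), 0.0, 1.0))

    hh_share = float(rng.uniform(55.0, 75.0))
    total_share = min(100.0, hh_share + float(rng.uniform(8.0, 18.0)))

    noise = config.hdi_noise_sd * rng.standard_normal(3)
    base = 0.30 + 0.40 * u
    health, education, income = (float(np.clip(base + e, 0.0, 1.0)) for e in noise)
    hdi = (health + education + income) / 3.0

    return CityContext(
        city_id=dataset.city_id,
        gdp_per_capita=gdp,
        gini=gini,
        hh_consumption_share=hh_share,
        total_consumption_share=total_share,
        hdi=hdi,
        health_index=health,
        education_index=education,
        income_index=income,
    )


def generate_scenario(config: ScenarioConfig) -> list[tuple[SurveyDataset, CityContext]]:
    """Generate all cities of a scenario, reproducibly under the config seed."""
    config.validate()
    out = []
    for i in range(config.n_cities):
        ds = generate_city(config, i)
        out.append((ds, generate_context(config, ds, i)))
    return out


def write_scenario(config: ScenarioConfig, outdir) -> Path:
    """Write one household/person CSV pair per city, a context table, and a manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    contexts = []
    for ds, ctx in generate_scenario(config):
        write_survey(ds, outdir / f"households_{ds.city_id}.csv", outdir / f"persons_{ds.city_id}.csv")
        contexts.append(ctx.to_dict())
    pd.DataFrame(contexts).to_csv(outdir / "contexts.csv", index=False)
    manifest = {"config": config.to_jsonable(), "n_cities": config.n_cities}
    (outdir / "scenario_manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return outdir
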