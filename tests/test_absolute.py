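"""Income model, SDS deprivation score, and slum classification."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.integrate import quad
from scipy.optimize import brentq
from scipy.stats import norm

from urbanpoverty import (
    CityContext,
    IncomeModel,
    ScenarioConfig,
    build_income_model,
    classify_below_poverty_line,
    generate_city,
    gini_from_sigma,
    predicted_income_at_rank,
    sds_table,
    sigma_from_gini,
    slum_table,
    weighted_quantile_rank,
)
from urbanpoverty.absolute import DAYS_PER_YEAR, DeprivationIndex
from urbanpoverty.errors import ConfigurationError


def _context(gini=0.4, gdp=1000.0, hh_share=60.0, total_share=80.0):
    return CityContext(city_id="c", gdp_per_capita=gdp, gini=gini,
                       hh_consumption_share=hh_share, total_consumption_share=total_share,
                       hdi=0.5, health_index=0.5, education_index=0.5, income_index=0.5)


class TestSigmaGini:
    def test_perfect_equality(self):
        assert sigma_from_gini(0.0) == 0.0

    def test_matches_root_finding_oracle_at_half(self):
        sigma_oracle = brentq(lambda s: 2 * norm.cdf(s / np.sqrt(2)) - 1 - 0.5, 1e-9, 10)
        assert sigma_from_gini(0.5) == pytest.approx(sigma_oracle, abs=1e-9)

    @pytest.mark.parametrize("gini", np.arange(0.1, 0.95, 0.1))
    def test_round_trip_identity(self, gini):
        assert gini_from_sigma(sigma_from_gini(gini)) == pytest.approx(gini, abs=1e-9)

    def test_domain_error(self):
        with pytest.raises(ConfigurationError):
            sigma_from_gini(1.0)
        with pytest.raises(ConfigurationError):
            sigma_from_gini(-0.1)


class TestIncomeModel:
    def test_mean_mu_identity(self):
        m = IncomeModel(mean_income_per_capita=1234.5, sigma=0.9)
        assert np.exp(m.mu + m.sigma**2 / 2) == pytest.approx(1234.5, rel=1e-9)

    def test_sigma_zero_flat_profile(self):
        m = IncomeModel(mean_income_per_capita=500.0, sigma=0.0)
        incomes = predicted_income_at_rank(m, np.array([0.01, 0.3, 0.5, 0.9]))
        assert incomes == pytest.approx([500.0] * 4)

    def test_median_identity(self):
        m = IncomeModel(mean_income_per_capita=800.0, sigma=1.1)
        assert predicted_income_at_rank(m, 0.5) == pytest.approx(
            800.0 * np.exp(-1.1**2 / 2), rel=1e-9)

    def test_strictly_increasing_in_rank(self):
        m = IncomeModel(mean_income_per_capita=1000.0, sigma=0.8)
        inc = predicted_income_at_rank(m, np.linspace(0.01, 0.99, 50))
        assert (np.diff(inc) > 0).all()

    def test_quadrature_mean_recovers_model_mean(self):
        m = IncomeModel(mean_income_per_capita=1500.0, sigma=0.7)
        val, _ = quad(lambda r: predicted_income_at_rank(m, r, eps=1e-12), 0, 1, limit=200)
        assert val == pytest.approx(1500.0, rel=1e-6)

    def test_build_model_share_ratio_and_alternative(self):
        assert build_income_model(_context()).mean_income_per_capita == pytest.approx(750.0)
        alt = build_income_model(_context(), correction="hh_share_of_gdp")
        assert alt.mean_income_per_capita == pytest.approx(600.0)

    def test_empirical_gini_of_samples_matches_input(self):
        gini = 0.45
        m = IncomeModel(1000.0, sigma_from_gini(gini))
        rng = np.random.default_rng(12)
        x = np.sort(np.exp(m.mu + m.sigma * rng.standard_normal(100_000)))
        n = len(x)
        emp = (2 * np.arange(1, n + 1) - n - 1).dot(x) / (n * x.sum())
        assert emp == pytest.approx(gini, abs=0.01)


class TestPovertyLine:
    def test_zero_poor_when_incomes_dominate_line(self):
        ctx = _context(gini=0.2, gdp=1e7)
        poor = classify_below_poverty_line(np.linspace(0.01, 0.99, 100), np.full(100, 5.0), ctx)
        assert not poor.any()

    def test_boundary_exact_line_is_not_poor(self):
        # per-member daily income exactly 1.9 => annual 693.975 × members
        m = IncomeModel(mean_income_per_capita=1.9 * DAYS_PER_YEAR * 4, sigma=0.0)
        from urbanpoverty.absolute import PovertyLineClassifier
        clf = PovertyLineClassifier()
        clf.income_model_ = m
        assert not clf.predict(np.array([0.5]), np.array([4.0]))[0]
        # one cent less is poor
        clf.income_model_ = IncomeModel(1.9 * DAYS_PER_YEAR * 4 - 0.01, 0.0)
        assert clf.predict(np.array([0.5]), np.array([4.0]))[0]

    def test_monotone_in_rank(self):
        ctx = _context(gini=0.5, gdp=3000)
        ranks = np.linspace(0.01, 0.99, 200)
        poor = classify_below_poverty_line(ranks, np.full(200, 4.0), ctx)
        # once not poor, never poor again at higher rank
        assert (np.diff(poor.astype(int)) <= 0).all()

    def test_headcount_matches_closed_form_on_synthetic_city(self):
        """Weighted poor share equals the lognormal CDF below the line."""
        cfg = ScenarioConfig(n_cities=1, households_per_city=(2000, 2000), seed=21)
        ds = generate_city(cfg, 0)
        w = ds.households["weight"].to_numpy()
        ranks = weighted_quantile_rank(ds.households["latent_ses_diag"], w)
        gini = 0.6
        sigma = sigma_from_gini(gini)
        # tune the mean so the analytic headcount below 1.9/day is 25%
        z = 1.9 * DAYS_PER_YEAR
        mu = np.log(z) - sigma * norm.ppf(0.25)
        mean = np.exp(mu + sigma**2 / 2)
        m = IncomeModel(mean, sigma)
        from urbanpoverty.absolute import PovertyLineClassifier
        clf = PovertyLineClassifier(division="percapita")
        clf.income_model_ = m
        poor = clf.predict(ranks)
        share = w[poor].sum() / w.sum()
        analytic = norm.cdf((np.log(z) - mu) / sigma)
        assert analytic == pytest.approx(0.25, abs=1e-12)
        assert share == pytest.approx(analytic, abs=0.02)


class TestSDS:
    def _household(self, **over):
        base = dict(household_id="h1", weight=1.0, n_members=4, persons_per_room=2.0,
                    electricity=True, water_source="piped_dwelling", time_to_water=0.0,
                    sanitation_type="flush_to_sewer", sanitation_shared=False,
                    cooking_fuel="lpg", floor_material="cement", wall_material="bricks",
                    roof_material="tiles", asset_radio=True, asset_tv=True, asset_fridge=True,
                    asset_phone=True, asset_computer=True, asset_bicycle=True,
                    asset_motorcycle=True, asset_car=True)
        base.update(over)
        return pd.DataFrame([base])

    def _roster(self, rows):
        return pd.DataFrame(rows, columns=["person_id", "household_id", "age_years",
                                           "edu_years", "in_school"])

    def test_deprived_on_none_scores_zero(self):
        hh = self._household()
        pp = self._roster([("p1", "h1", 30, 10, False), ("p2", "h1", 8, 2, True)])
        out = sds_table(hh, pp)
        assert out["sds_score"].iloc[0] == 0.0
        assert out["sds_deprived"].iloc[0] == 0.0

    def test_deprived_on_all_eight_scores_one(self):
        hh = self._household(electricity=False, water_source="surface_water",
                             sanitation_type="bucket", cooking_fuel="wood",
                             floor_material="earth_sand", wall_material="mud",
                             roof_material="thatch_palm",
                             **{f"asset_{a}": False for a in
                                ("radio", "tv", "fridge", "phone", "computer",
                                 "bicycle", "motorcycle", "car")})
        pp = self._roster([("p1", "h1", 30, 2, False), ("p2", "h1", 9, 0, False)])
        out = sds_table(hh, pp)
        assert out["sds_score"].iloc[0] == pytest.approx(1.0)
        assert out["sds_deprived"].iloc[0] == 1.0

    def test_education_only_weighted_half_and_deprived(self):
        hh = self._household()
        # child out of school + no member 10+ with 6 years
        pp = self._roster([("p1", "h1", 30, 3, False), ("p2", "h1", 9, 0, False)])
        out = sds_table(hh, pp)
        assert out["sds_score"].iloc[0] == pytest.approx(0.5)
        assert out["sds_deprived"].iloc[0] == 1.0  # 0.5 >= 1/3

    def test_score_is_hand_computed_weighted_sum(self):
        # deprived on: one education (1/4) + electricity and fuel (2/12)
        hh = self._household(electricity=False, cooking_fuel="charcoal")
        pp = self._roster([("p1", "h1", 30, 3, False)])  # no qualified member, no kids
        out = sds_table(hh, pp)
        assert out["sds_score"].iloc[0] == pytest.approx(0.25 + 2 / 12)
        assert out["sds_deprived"].iloc[0] == 1.0

    def test_score_bounded_on_generated_city(self, one_city):
        ds, _ = one_city
        out = sds_table(ds.households, ds.persons)
        s = out["sds_score"].dropna()
        assert ((s >= 0) & (s <= 1)).all()

    def test_bad_weights_rejected(self):
        with pytest.raises(ConfigurationError):
            DeprivationIndex(education_weight=0.3).fit()


class TestSlum:
    def _household(self, durable=True, space=True, water=True, sanitation=True):
        return pd.DataFrame([dict(
            household_id="h1", weight=1.0, n_members=4,
            persons_per_room=2.0 if space else 4.0,
            floor_material="cement" if durable else "earth_sand",
            wall_material="bricks", roof_material="tiles",
            water_source="piped_dwelling" if water else "surface_water",
            time_to_water=0.0,
            sanitation_type="flush_to_sewer" if sanitation else "bucket",
            sanitation_shared=False)])

    def test_all_met_is_not_slum(self):
        out = slum_table(self._household())
        assert out["slum"].iloc[0] == 0.0

    def test_shared_sanitation_alone_makes_slum(self):
        hh = self._household()
        hh["sanitation_shared"] = True
        out = slum_table(hh)
        assert out["adequate_sanitation"].iloc[0] == 0.0
        assert out["slum"].iloc[0] == 1.0

    def test_full_truth_table_any_failure_is_slum(self):
        for combo in itertools.product([True, False], repeat=4):
            out = slum_table(self._household(*combo))
            expected = 0.0 if all(combo) else 1.0
            assert out["slum"].iloc[0] == expected, combo

    def test_missing_input_excludes_household(self):
        hh = self._household()
        hh["persons_per_room"] = np.nan
        out = slum_table(hh)
        assert np.isnan(out["slum"].iloc[0])
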