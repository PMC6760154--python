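"""Growth estimation, flux-to-mass conversion, and feed prediction."""

import math

import numpy as np
import pytest

from mmc.mmc_controller import (
    GLUCOSE,
    NITRATE,
    NutrientSpec,
    ODSeries,
    estimate_growth_rate,
    feasible_growth,
    flux_to_feed_mass,
    predict_feed_autotrophic,
    predict_feeds_heterotrophic,
    run_schedule,
)
from mmc.fba_engine import minimize_uptake_at_growth
from mmc.uptake_kinetics import UptakeCapModel

from oracles import integrate_feed_mass

AA16_N_DEMAND = 0.16 * 11.1


@pytest.fixture
def series24():
    """OD doubling-ish over 24 h windows; od_to_gdw = 0.4."""
    return ODSeries(np.array([0.0, 24.0, 48.0]), np.array([1.0, 1.3893, 1.93]), 0.4)


class TestEstimateGrowthRate:
    def test_doubling_in_24h(self):
        s = ODSeries(np.array([0.0, 24.0]), np.array([1.0, 2.0]))
        est = estimate_growth_rate(s, 0.0, 24.0)
        assert est.mu == pytest.approx(math.log(2) / 24)
        assert not est.negative

    def test_flat_od_zero_growth(self):
        s = ODSeries(np.array([0.0, 12.0]), np.array([1.5, 1.5]))
        assert estimate_growth_rate(s, 0.0, 12.0).mu == 0.0

    def test_reference_growth_rate(self, series24):
        """OD 1.0 -> 1.3893 over 24 h gives the reference 0.0137 1/h."""
        est = estimate_growth_rate(series24, 0.0, 24.0)
        assert est.mu == pytest.approx(0.0137, abs=5e-6)

    def test_shrinking_culture_flagged(self):
        s = ODSeries(np.array([0.0, 24.0]), np.array([2.0, 1.5]))
        est = estimate_growth_rate(s, 0.0, 24.0)
        assert est.mu < 0 and est.negative

    def test_missing_time_point(self, series24):
        with pytest.raises(KeyError):
            estimate_growth_rate(series24, 0.0, 30.0)

    def test_invalid_series(self):
        with pytest.raises(ValueError):
            ODSeries(np.array([0.0, 0.0]), np.array([1.0, 1.0]))
        with pytest.raises(ValueError):
            ODSeries(np.array([0.0, 1.0]), np.array([1.0, -0.1]))


class TestFluxToFeedMass:
    def test_matches_numerical_integration_on_grid(self):
        """Closed form vs quadrature of flux*MW*X0*e^{mu t}, including mu -> 0."""
        for mu in [0.0, 1e-12, 1e-6, 0.0014, 0.0137, 0.05, 0.2]:
            for dt in [1.0, 12.0, 24.0, 48.0]:
                for X0 in [0.05, 0.5, 2.0]:
                    got = flux_to_feed_mass(0.5, NITRATE, X0, mu, dt)
                    want = integrate_feed_mass(0.5, 62.0, X0, mu, dt)
                    assert got == pytest.approx(want, rel=1e-6)

    def test_zero_growth_is_plain_product(self):
        assert flux_to_feed_mass(1.0, NITRATE, 0.1, 0.0, 24.0) == pytest.approx(148.8)

    def test_reference_point(self):
        got = flux_to_feed_mass(0.5, NITRATE, 0.1, 0.0137, 24.0)
        assert got == pytest.approx(88.1, abs=0.05)

    def test_zero_flux_zero_mass(self):
        for mu in (-0.01, 0.0, 0.1):
            assert flux_to_feed_mass(0.0, GLUCOSE, 1.0, mu, 24.0) == 0.0

    def test_constant_biomass_mode(self):
        got = flux_to_feed_mass(1.0, NITRATE, 0.1, 0.1, 24.0, biomass_model="constant")
        assert got == pytest.approx(1.0 * 62.0 * 0.1 * 24.0)


class TestPredictFeedAutotrophic:
    def test_composed_against_oracles(self, aa16_variant, series24):
        pred = predict_feed_autotrophic(aa16_variant, series24, 0.0, 24.0, 24.0)
        mu = math.log(1.3893) / 24.0
        assert pred.mu == pytest.approx(mu)
        assert pred.uptake_flux == pytest.approx(AA16_N_DEMAND * mu)
        want = integrate_feed_mass(AA16_N_DEMAND * mu, 62.0, 1.3893 * 0.4, mu, 24.0)
        assert pred.feed_mass_conc == pytest.approx(want, rel=1e-6)

    def test_scale_is_linear(self, aa16_variant, series24):
        full = predict_feed_autotrophic(aa16_variant, series24, 0.0, 24.0, 24.0, scale=1.0)
        scaled = predict_feed_autotrophic(aa16_variant, series24, 0.0, 24.0, 24.0, scale=0.8)
        assert scaled.feed_mass_conc == pytest.approx(0.8 * full.feed_mass_conc)

    def test_homogeneous_in_biomass(self, aa16_variant, series24):
        base = predict_feed_autotrophic(aa16_variant, series24, 0.0, 24.0, 24.0)
        doubled = ODSeries(series24.times, 2 * series24.od750, series24.od_to_gdw)
        pred2 = predict_feed_autotrophic(aa16_variant, doubled, 0.0, 24.0, 24.0)
        assert pred2.feed_mass_conc == pytest.approx(2 * base.feed_mass_conc)

    def test_negative_growth_feeds_nothing(self, aa16_variant):
        s = ODSeries(np.array([0.0, 24.0]), np.array([2.0, 1.5]), 0.4)
        pred = predict_feed_autotrophic(aa16_variant, s, 0.0, 24.0, 24.0)
        assert pred.feed_mass_conc == 0.0
        assert "negative_mu_floored" in pred.flags

    def test_infeasible_mu_capped_to_model_capacity(self, aa16_variant):
        aa16_variant.network.set_bounds("EX_no3", ub=1.776 * 0.01)  # caps mu at 0.01
        s = ODSeries(np.array([0.0, 24.0]), np.array([1.0, 2.0]), 0.4)  # mu ~ 0.029
        pred = predict_feed_autotrophic(aa16_variant, s, 0.0, 24.0, 24.0)
        assert "mu_capped_to_feasible" in pred.flags
        assert pred.mu == pytest.approx(0.01)

    def test_feed_mass_nondecreasing_in_mu(self, aa16_variant):
        masses = []
        for od_now in [1.0, 1.2, 1.5, 2.0, 3.0]:
            s = ODSeries(np.array([0.0, 24.0]), np.array([1.0, od_now]), 0.4)
            # hold X0 fixed by scaling back to the same final OD
            pred = predict_feed_autotrophic(aa16_variant, s, 0.0, 24.0, 24.0)
            masses.append(pred.feed_mass_conc / (od_now * 0.4))
        assert all(b >= a - 1e-12 for a, b in zip(masses, masses[1:]))


class TestPredictFeedsHeterotrophic:
    def test_consistent_with_single_nutrient_route(self, toy_het, series24):
        preds = predict_feeds_heterotrophic(toy_het, series24, 0.0, 24.0, 24.0)
        by_name = {p.nutrient: p for p in preds}
        mu = by_name["glucose"].mu
        glc_alone = minimize_uptake_at_growth(toy_het, "glucose", mu)
        assert by_name["glucose"].uptake_flux == pytest.approx(
            glc_alone.objective_value, abs=1e-8
        )
        want = integrate_feed_mass(
            glc_alone.objective_value, 180.16, 1.3893 * 0.4, mu, 24.0
        )
        assert by_name["glucose"].feed_mass_conc == pytest.approx(want, rel=1e-6)

    def test_huge_cap_changes_nothing(self, toy_het, series24):
        plain = predict_feeds_heterotrophic(toy_het, series24, 0.0, 24.0, 24.0)
        cap = UptakeCapModel([1e6, 0.0], 1, 1.0)
        capped = predict_feeds_heterotrophic(toy_het, series24, 0.0, 24.0, 24.0, cap=cap)
        for a, b in zip(plain, capped):
            assert b.feed_mass_conc == pytest.approx(a.feed_mass_conc, abs=1e-9)

    def test_binding_cap_lowers_both_feeds(self, toy_het, series24):
        plain = {p.nutrient: p for p in predict_feeds_heterotrophic(toy_het, series24, 0.0, 24.0, 24.0)}
        mu_est = plain["glucose"].mu
        c_demand = toy_het.composition.carbon_demand
        g = 0.5 * c_demand * mu_est / 6.0  # supports only half the estimated growth
        cap = UptakeCapModel([g, 0.0], 1, 1.0)
        capped = {
            p.nutrient: p
            for p in predict_feeds_heterotrophic(toy_het, series24, 0.0, 24.0, 24.0, cap=cap)
        }
        assert capped["glucose"].mu == pytest.approx(0.5 * mu_est)
        assert capped["glucose"].feed_mass_conc < plain["glucose"].feed_mass_conc
        assert capped["nitrate"].feed_mass_conc < plain["nitrate"].feed_mass_conc
        # nitrate flux tracks the capped feasible growth
        assert capped["nitrate"].uptake_flux == pytest.approx(
            toy_het.composition.nitrogen_demand * 0.5 * mu_est, abs=1e-8
        )

    def test_requires_heterotrophic_variant(self, aa16_variant, series24):
        with pytest.raises(ValueError, match="heterotrophic"):
            predict_feeds_heterotrophic(aa16_variant, series24, 0.0, 24.0, 24.0)


class TestFeasibleGrowth:
    def test_below_capacity_passthrough(self, aa16_variant):
        assert feasible_growth(aa16_variant, 0.01) == pytest.approx(0.01)

    def test_above_capacity_clamped(self, aa16_variant):
        aa16_variant.network.set_bounds("EX_no3", ub=1.776)
        assert feasible_growth(aa16_variant, 5.0) == pytest.approx(1.0)

    def test_zero_capacity(self, aa16_variant):
        aa16_variant.network.set_bounds("EX_photon", ub=0.0)
        aa16_variant.network.set_bounds("EX_glc", ub=0.0)
        assert feasible_growth(aa16_variant, 0.1) == pytest.approx(0.0, abs=1e-9)


class TestRunSchedule:
    def test_single_feed_time_equals_direct_prediction(self, aa16_variant, series24):
        schedule = run_schedule(aa16_variant, series24, [24.0], dt_next=24.0)
        direct = predict_feed_autotrophic(aa16_variant, series24, 0.0, 24.0, 24.0)
        assert len(schedule.predictions) == 1
        assert schedule.predictions[0].feed_mass_conc == pytest.approx(direct.feed_mass_conc)

    def test_uses_latest_two_observations(self, aa16_variant, series24):
        schedule = run_schedule(aa16_variant, series24, [24.0, 48.0])
        assert schedule.predictions[1].interval[0] == 48.0
        mu2 = math.log(1.93 / 1.3893) / 24.0
        assert schedule.predictions[1].mu == pytest.approx(mu2)

    def test_total_matches_sum_of_parts(self, aa16_variant, series24):
        schedule = run_schedule(aa16_variant, series24, [24.0, 48.0])
        assert schedule.total("nitrate") == pytest.approx(
            sum(p.feed_mass_conc for p in schedule.predictions)
        )

    def test_failed_point_flagged_not_fatal(self, aa16_variant, series24):
        schedule = run_schedule(aa16_variant, series24, [12.0, 24.0])
        # t=12 has only one earlier observation -> failure recorded, t=24 fine
        assert len(schedule.failures) == 1
        assert schedule.failures[0][0] == 12.0
        assert len(schedule.predictions) == 1

    def test_csv_round_trip(self, aa16_variant, series24, tmp_path):
        schedule = run_schedule(aa16_variant, series24, [24.0, 48.0])
        path = tmp_path / "schedule.csv"
        schedule.to_csv(path)
        import pandas as pd

        df = pd.read_csv(path)
        assert list(df["time_h"]) == [24.0, 48.0]
        assert df["feed_mg_L"].sum() == pytest.approx(schedule.total())


class TestNutrientSpec:
    def test_default_molecular_weights(self):
        assert NITRATE.molecular_weight == 62.00
        assert GLUCOSE.molecular_weight == 180.16

    def test_positive_weight_required(self):
        with pytest.raises(ValueError):
            NutrientSpec("x", 0.0, "EX_x")
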