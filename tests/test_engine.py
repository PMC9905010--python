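import numpy as np
import pytest
from sklearn.base import clone

from trendimpact import (
    Driver,
    ImpactMatrix,
    SimulationConfig,
    TrendImpactForecaster,
    compute_impact_matrix,
    percentiles_by_year,
    run_scenarios,
    run_tia,
    simulate_event_matrix,
    simulate_event_rep,
)

from oracle import exact_cdf, exact_mean, total_impact_distribution


def make_driver(event_id, p, impact, horizon, direction=None):
    """Constant or per-year profile driver over the given horizon."""
    horizon = tuple(horizon)
    p = np.broadcast_to(np.asarray(p, float), (len(horizon),))
    impact = np.broadcast_to(np.asarray(impact, float), (len(horizon),))
    if direction is None:
        direction = "negative" if impact.sum() < 0 else "positive"
    return Driver(
        event_id=event_id,
        name=event_id,
        direction=direction,
        yearly_probability=dict(zip(horizon, p.tolist())),
        yearly_impact=dict(zip(horizon, impact.tolist())),
    )


H3 = (2021, 2022, 2023)


class TestSingleRepetition:
    def test_zero_probability_never_fires(self):
        d = make_driver("e", 0.0, -2.0, H3)
        cfg = SimulationConfig(n_reps=1, horizon=H3)
        np.testing.assert_array_equal(
            simulate_event_rep(d, cfg, [0.1, 0.5, 0.9]), [0.0, 0.0, 0.0]
        )

    def test_certain_event_fires_in_first_year_and_persists(self):
        d = make_driver("e", 1.0, -2.0, H3)
        cfg = SimulationConfig(n_reps=1, horizon=H3)
        np.testing.assert_array_equal(
            simulate_event_rep(d, cfg, [0.3, 0.3, 0.3]), [-2.0, -2.0, -2.0]
        )

    def test_onset_year_impact_is_the_one_that_persists(self):
        d = make_driver("e", [0.0, 1.0, 0.0], [5.0, 2.0, 9.0], H3)
        cfg = SimulationConfig(n_reps=1, horizon=H3)
        np.testing.assert_array_equal(
            simulate_event_rep(d, cfg, [0.5, 0.5, 0.5]), [0.0, 2.0, 2.0]
        )

    def test_literal_rule_inverts_comparison(self):
        d = make_driver("e", 1.0, 1.0, H3)
        cfg = SimulationConfig(n_reps=1, horizon=H3, occurrence_rule="literal")
        np.testing.assert_array_equal(
            simulate_event_rep(d, cfg, [0.99, 0.99, 0.99]), [0.0, 0.0, 0.0]
        )
        d0 = make_driver("e", 0.0, 1.0, H3)
        np.testing.assert_array_equal(
            simulate_event_rep(d0, cfg, [0.01, 0.5, 0.5]), [1.0, 1.0, 1.0]
        )

    def test_per_year_profile_accumulates_after_onset(self):
        d = make_driver("e", 1.0, [1.0, 2.0, 3.0], H3)
        cfg = SimulationConfig(n_reps=1, horizon=H3, impact_profile="per_year")
        np.testing.assert_array_equal(
            simulate_event_rep(d, cfg, [0.0, 0.9, 0.9]), [1.0, 3.0, 6.0]
        )

    def test_multiple_occurrence_mode_restacks_impacts(self):
        d = make_driver("e", 1.0, 1.0, H3)
        cfg = SimulationConfig(n_reps=1, horizon=H3, single_occurrence=False)
        np.testing.assert_array_equal(
            simulate_event_rep(d, cfg, [0.0, 0.0, 0.0]), [1.0, 2.0, 3.0]
        )

    def test_missing_horizon_year_rejected(self):
        d = make_driver("e", 0.5, 1.0, (2021, 2022))
        cfg = SimulationConfig(n_reps=1, horizon=H3)
        with pytest.raises(ValueError, match="horizon year"):
            simulate_event_rep(d, cfg, [0.5, 0.5, 0.5])


class TestVectorisedAgreement:
    @pytest.mark.parametrize("profile", ["onset", "per_year"])
    @pytest.mark.parametrize("single", [True, False])
    def test_matrix_rows_equal_walked_repetitions(self, profile, single):
        """The vectorised simulation must match the literal walk draw for draw."""
        d = make_driver("e", [0.3, 0.7, 0.5], [1.0, 2.0, 3.0], H3)
        cfg = SimulationConfig(
            n_reps=500, horizon=H3, seed=4,
            impact_profile=profile, single_occurrence=single,
        )
        rng = np.random.default_rng(99)
        matrix = simulate_event_matrix(d, cfg, rng=rng)
        u = np.random.default_rng(99).uniform(size=(cfg.n_reps, 3))
        walked = np.array([simulate_event_rep(d, cfg, u[i]) for i in range(cfg.n_reps)])
        np.testing.assert_array_equal(matrix, walked)


class TestDistributionalProperties:
    def test_mean_trajectory_closed_form(self):
        """E[impact_t] = I * (1 - (1-p)^t) for constant p and impact."""
        p, impact = 0.5, 1.0
        horizon = (2021, 2022)
        d = make_driver("e", p, impact, horizon)
        cfg = SimulationConfig(n_reps=20_000, seed=2, horizon=horizon)
        traj = simulate_event_matrix(d, cfg)
        for t, expected in enumerate([0.5, 0.75]):
            q = 1 - (1 - p) ** (t + 1)
            se = impact * np.sqrt(q * (1 - q) / cfg.n_reps)
            assert abs(traj[:, t].mean() - expected) < 3 * se

    def test_final_year_exceedance_frequency(self):
        """P(event occurred by the last year) = 1 - prod_t (1 - p_t)."""
        p = np.array([0.2, 0.4, 0.6])
        d = make_driver("e", p, 1.0, H3)
        cfg = SimulationConfig(n_reps=10_000, seed=5, horizon=H3)
        traj = simulate_event_matrix(d, cfg)
        expected = 1 - np.prod(1 - p)
        freq = (traj[:, -1] != 0).mean()
        se = np.sqrt(expected * (1 - expected) / cfg.n_reps)
        assert abs(freq - expected) < 3 * se

    def test_single_occurrence_trajectory_values_binary(self):
        d = make_driver("e", 0.4, -1.5, H3)
        cfg = SimulationConfig(n_reps=5_000, seed=6, horizon=H3)
        traj = simulate_event_matrix(d, cfg)
        assert set(np.unique(traj)) <= {0.0, -1.5}

    @pytest.mark.parametrize("p_values", [(0.5, 0.5, 0.5), (1.0, 0.5, 0.0), (0.5, 1.0, 0.5)])
    def test_enumeration_oracle_matches_engine(self, p_values):
        """Exact enumerated distribution vs Monte-Carlo, via the CDF at every atom."""
        events = [
            (np.array(p_values), np.array([-1.0, -2.0, -0.5])),
            (np.array([0.5, 0.5, 1.0]), np.array([1.0, 0.5, 2.0])),
        ]
        drivers = [
            make_driver(f"ev{i}", p, imp, H3) for i, (p, imp) in enumerate(events)
        ]
        cfg = SimulationConfig(n_reps=20_000, seed=8, horizon=H3)
        matrix = compute_impact_matrix(drivers, cfg)
        dist = total_impact_distribution(events)
        for t in range(3):
            atoms = np.unique([traj[t] for _, traj in dist])
            for x in atoms:
                exact = exact_cdf(dist, t, x)
                empirical = (matrix.values[:, t] <= x + 1e-12).mean()
                se = np.sqrt(max(exact * (1 - exact), 1e-12) / cfg.n_reps)
                assert abs(empirical - exact) < 3 * se + 1e-9

    def test_mc_percentiles_bracket_exact_quantiles(self):
        """Engine percentiles agree with the enumerated distribution's quantiles."""
        events = [(np.array([0.5, 0.5, 0.5]), np.array([-2.0, -2.0, -2.0]))]
        d = make_driver("e", 0.5, -2.0, H3)
        cfg = SimulationConfig(n_reps=20_000, seed=9, horizon=H3)
        matrix = compute_impact_matrix([d], cfg)
        dist = total_impact_distribution(events)
        # final year: P(-2) = 1 - 0.5^3 = 0.875, P(0) = 0.125
        lo, med, hi = percentiles_by_year(matrix, (2.5, 50.0, 97.5))[:, -1]
        assert lo == -2.0
        assert med == -2.0
        assert hi == 0.0
        np.testing.assert_allclose(
            exact_mean(dist)[-1], matrix.values[:, -1].mean(), atol=0.02
        )


class TestPercentiles:
    def test_degenerate_column(self):
        m = ImpactMatrix(values=np.full((50, 2), 3.5), horizon=(2021, 2022))
        np.testing.assert_array_equal(
            percentiles_by_year(m, (2.5, 50, 97.5)), np.full((3, 2), 3.5)
        )

    def test_odd_length_median(self):
        m = ImpactMatrix(values=np.array([[1.0], [2.0], [3.0], [4.0], [5.0]]),
                         horizon=(2021,))
        assert percentiles_by_year(m, (50,))[0, 0] == 3.0

    def test_uniform_tail_quantile(self):
        rng = np.random.default_rng(12)
        m = ImpactMatrix(values=rng.uniform(size=(10_000, 1)), horizon=(2021,))
        assert percentiles_by_year(m, (97.5,))[0, 0] == pytest.approx(0.975, abs=0.01)

    def test_level_bounds(self):
        m = ImpactMatrix(values=np.zeros((5, 1)), horizon=(2021,))
        with pytest.raises(ValueError, match="levels"):
            percentiles_by_year(m, (101,))


class TestRunTIA:
    def test_empty_drivers_identity(self, linear_model):
        cfg = SimulationConfig(n_reps=500, seed=1)
        res = run_tia(linear_model, [], cfg)
        np.testing.assert_array_equal(res.forecast, res.baseline)
        np.testing.assert_array_equal(res.forecast_lo, res.forecast_hi)

    def test_certain_unit_driver_shifts_baseline_exactly(self, linear_model):
        cfg = SimulationConfig(n_reps=500, seed=1)
        d = make_driver("e", 1.0, 1.0, cfg.horizon)
        res = run_tia(linear_model, [d], cfg)
        np.testing.assert_allclose(res.forecast, res.baseline + 1.0, atol=1e-12)
        np.testing.assert_allclose(res.forecast_lo, res.forecast_hi, atol=1e-12)

    def test_symmetric_drivers_cancel_in_median(self, linear_model):
        cfg = SimulationConfig(n_reps=20_000, seed=3)
        pos = make_driver("plus", 0.6, 0.5, cfg.horizon)
        neg = make_driver("minus", 0.6, -0.5, cfg.horizon)
        res = run_tia(linear_model, [pos, neg], cfg)
        assert np.all(np.abs(res.impact_median) < 0.05)

    def test_band_ordering_invariant(self, linear_model, fixture_drivers):
        cfg = SimulationConfig(n_reps=2_000, seed=17)
        res = run_tia(linear_model, fixture_drivers, cfg)
        assert np.all(res.impact_lo <= res.impact_median + 1e-12)
        assert np.all(res.impact_median <= res.impact_hi + 1e-12)
        assert np.all(res.forecast_lo <= res.forecast)
        assert np.all(res.forecast <= res.forecast_hi)

    def test_seed_determinism(self, linear_model, fixture_drivers):
        cfg = SimulationConfig(n_reps=1_000, seed=42)
        a = run_tia(linear_model, fixture_drivers, cfg)
        b = run_tia(linear_model, fixture_drivers, cfg)
        np.testing.assert_array_equal(a.forecast, b.forecast)
        np.testing.assert_array_equal(a.impact_lo, b.impact_lo)
        np.testing.assert_array_equal(a.impact_hi, b.impact_hi)

    def test_crn_monotonicity_adding_negative_driver(self, linear_model):
        """Under common random numbers an all-negative driver can only lower impacts."""
        cfg = SimulationConfig(n_reps=2_000, seed=21)
        base_set = [make_driver("a", 0.5, 1.0, cfg.horizon),
                    make_driver("b", 0.4, -0.5, cfg.horizon)]
        extra = make_driver("c", 0.6, -0.8, cfg.horizon)
        m1 = compute_impact_matrix(base_set, cfg)
        m2 = compute_impact_matrix(base_set + [extra], cfg)
        assert np.all(m2.values <= m1.values + 1e-12)


class TestScenarios:
    def test_all_negative_panel_positive_scenario_is_baseline(self, linear_model):
        cfg = SimulationConfig(n_reps=500, seed=2)
        drivers = [make_driver("n1", 0.5, -1.0, cfg.horizon)]
        res = run_scenarios(linear_model, drivers, cfg)
        np.testing.assert_array_equal(res["positive"].forecast, res["positive"].baseline)

    def test_single_positive_driver_combined_equals_positive(self, linear_model):
        cfg = SimulationConfig(n_reps=500, seed=2)
        drivers = [make_driver("p1", 0.5, 1.0, cfg.horizon)]
        res = run_scenarios(linear_model, drivers, cfg)
        np.testing.assert_array_equal(
            res["combined"].forecast, res["positive"].forecast
        )

    def test_fixture_scenario_ordering_at_2031(self, linear_model, fixture_drivers):
        cfg = SimulationConfig(n_reps=2_000, seed=13)
        res = run_scenarios(linear_model, fixture_drivers, cfg)
        end = -1
        assert (
            res["negative"].forecast[end]
            < res["combined"].forecast[end]
            < res["combined"].baseline[end]
            < res["positive"].forecast[end]
        )


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs, match",
        [
            ({"n_reps": 0}, "n_reps"),
            ({"horizon": ()}, "non-empty"),
            ({"horizon": (2022, 2021)}, "increasing"),
            ({"occurrence_rule": "inverted"}, "occurrence_rule"),
            ({"impact_profile": "ramp"}, "impact_profile"),
        ],
    )
    def test_invalid_config_rejected(self, kwargs, match):
        with pytest.raises(ValueError, match=match):
            SimulationConfig(**kwargs)

    def test_impact_matrix_shape_checked(self):
        with pytest.raises(ValueError, match="shape"):
            ImpactMatrix(values=np.zeros((10, 3)), horizon=(2021, 2022))


class TestForecasterEstimator:
    def test_sklearn_params_roundtrip(self):
        est = TrendImpactForecaster(n_reps=100, seed=5)
        cloned = clone(est)
        assert cloned.get_params()["n_reps"] == 100
        cloned.set_params(seed=9)
        assert cloned.get_params()["seed"] == 9

    def test_fit_predict_horizon_and_history(self, table1):
        drivers = [make_driver("p", 1.0, 1.0, range(2021, 2032))]
        est = TrendImpactForecaster(drivers=drivers, n_reps=200, seed=1)
        est.fit(table1.years, table1.prevalences)
        assert round(est.baseline_.r_squared_, 2) == 0.80
        pred = est.predict([2031])
        assert pred[0] == pytest.approx(est.baseline_.predict([2031])[0] + 1.0)
        # historical years fall outside the horizon: baseline only
        hist = est.predict([2010])
        assert hist[0] == pytest.approx(est.baseline_.predict([2010])[0])

    def test_unfitted_predict_raises(self):
        from sklearn.exceptions import NotFittedError

        with pytest.raises(NotFittedError):
            TrendImpactForecaster().predict([2031])
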