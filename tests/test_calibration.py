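"""Beta-regression calibration: fit, predict, invert, serialization."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import expit, logit

from ednabycatch.calibration import (
    CalibrationModel,
    CalibrationSample,
    beta_loglik,
    fit_beta_glm,
    invert,
    model_from_text,
    model_to_text,
    predict_fraction,
    shrink_to_open_interval,
)
from ednabycatch.synthetic import GeneratorConfig, generate_calibration_design
from tests.conftest import make_model


class TestFitBetaGLM:
    def test_parameter_recovery_on_simulated_design(self, november_samples):
        model = fit_beta_glm(november_samples)
        assert model.converged
        se = model.se()
        assert abs(model.alpha - (-0.4)) < min(3 * se[0], 0.05)
        assert abs(model.beta_slope - 1.0) < min(3 * se[1], 0.05)

    def test_matches_independent_beta_regression(self, november_samples):
        """Cross-check the hand-written MLE against statsmodels' beta model."""
        sm = pytest.importorskip("statsmodels.api")
        from statsmodels.othermod.betareg import BetaModel

        w = np.array([s.true_weight_fraction for s in november_samples])
        o = np.array([s.edna_fraction for s in november_samples])
        X = sm.add_constant(logit(w))
        res = BetaModel(o, X).fit(disp=0)
        ours = fit_beta_glm(november_samples)
        assert ours.alpha == pytest.approx(res.params[0], abs=1e-4)
        assert ours.beta_slope == pytest.approx(res.params[1], abs=1e-4)
        assert ours.loglik == pytest.approx(res.llf, abs=1e-4)

    def test_noise_free_identity_data(self):
        rng = np.random.default_rng(3)
        w = np.linspace(0.05, 0.95, 11)
        samples = [
            CalibrationSample(f"s{i}", "March", "ship", float(wi), float(np.clip(wi + rng.normal(0, 1e-4), 1e-6, 1 - 1e-6)))
            for i, wi in enumerate(w)
        ]
        model = fit_beta_glm(samples)
        assert model.alpha == pytest.approx(0.0, abs=0.01)
        assert model.beta_slope == pytest.approx(1.0, abs=0.01)
        assert model.phi > 1e4  # near-noise-free data pushes precision very high

    def test_optimizer_beats_grid_search(self):
        """Likelihood oracle: brute-force grid never beats the optimizer."""
        for seed in range(5):
            config = GeneratorConfig(
                seed=seed, ratios=(0.2, 0.5, 0.8), n_replicates_per_ratio=5,
                alpha=-0.3, beta=1.2, phi=40.0,
            )
            samples = generate_calibration_design(config)
            model = fit_beta_glm(samples)
            w = np.array([s.true_weight_fraction for s in samples])
            o = np.array([s.edna_fraction for s in samples])
            grid_best = -np.inf
            for a in np.linspace(model.alpha - 0.5, model.alpha + 0.5, 20):
                for b in np.linspace(model.beta_slope - 0.5, model.beta_slope + 0.5, 20):
                    for phi in np.geomspace(model.phi / 3, model.phi * 3, 15):
                        grid_best = max(grid_best, beta_loglik(a, b, phi, w, o))
            assert model.loglik >= grid_best - 1e-4

    def test_rejects_degenerate_and_invalid_input(self):
        flat = [CalibrationSample(f"s{i}", "x", "ship", w, 0.5) for i, w in enumerate((0.2, 0.5, 0.8))]
        with pytest.raises(ValueError, match="degenerate"):
            fit_beta_glm(flat)
        few = [CalibrationSample(f"s{i}", "x", "ship", 0.5, o) for i, o in enumerate((0.4, 0.5, 0.6))]
        with pytest.raises(ValueError, match="distinct"):
            fit_beta_glm(few)

    def test_boundary_observations_are_shrunk_not_fatal(self):
        rng = np.random.default_rng(0)
        config = GeneratorConfig(seed=5, ratios=(0.1, 0.5, 0.9), n_replicates_per_ratio=4)
        samples = generate_calibration_design(config)
        samples[0] = CalibrationSample("b0", samples[0].season, "ship", 0.1, 0.0)
        model = fit_beta_glm(samples)
        assert model.converged

    def test_seasonal_offset_orders_predictions(self):
        """A lower generative intercept yields a uniformly lower fitted curve."""
        march = fit_beta_glm(generate_calibration_design(
            GeneratorConfig(seed=11, alpha=-0.2, season_label="March", water_type="factory")))
        november = fit_beta_glm(generate_calibration_design(
            GeneratorConfig(seed=12, alpha=-0.7, season_label="November", water_type="factory")))
        for w in (0.1, 0.3, 0.5, 0.7, 0.9):
            assert predict_fraction(november, w)[0] < predict_fraction(march, w)[0]


class TestPredictInvert:
    def test_identity_model_prediction(self, identity_model):
        mean, lo, hi = predict_fraction(identity_model, 0.3)
        assert mean == pytest.approx(0.3, abs=1e-12)
        assert lo == mean == hi  # zero covariance collapses the band

    def test_closed_form_prediction(self):
        model = make_model(alpha=1.0, beta_slope=2.0)
        mean, _, _ = predict_fraction(model, 0.5)
        assert mean == pytest.approx(expit(1.0), abs=1e-12)

    def test_closed_form_inverse(self):
        model = make_model(alpha=1.0, beta_slope=2.0)
        w, _, _ = invert(model, 0.5)
        assert w == pytest.approx(expit(-0.5), abs=1e-12)

    def test_inverse_cross_checked_by_root_finding(self):
        from scipy.optimize import brentq

        model = make_model(alpha=1.0, beta_slope=2.0)
        w_root = brentq(lambda w: predict_fraction(model, w)[0] - 0.5, 1e-9, 1 - 1e-9, xtol=1e-14)
        assert invert(model, 0.5)[0] == pytest.approx(w_root, abs=1e-9)

    @given(
        alpha=st.floats(-2, 2),
        beta_slope=st.floats(0.2, 3),
        w=st.floats(0.001, 0.999),
    )
    @settings(max_examples=200, deadline=None)
    def test_round_trip_identity(self, alpha, beta_slope, w):
        model = make_model(alpha=alpha, beta_slope=beta_slope)
        mean, _, _ = predict_fraction(model, w)
        assert invert(model, mean)[0] == pytest.approx(w, abs=1e-10)

    def test_inverse_monotone_in_observation(self):
        model = make_model(alpha=-0.4, beta_slope=1.3)
        obs = np.linspace(0.01, 0.99, 50)
        w = [invert(model, o)[0] for o in obs]
        assert np.all(np.diff(w) > 0)

    def test_interval_contains_point_and_stays_in_unit(self, november_samples):
        model = fit_beta_glm(november_samples)
        for o in (0.05, 0.3, 0.7, 0.95):
            w, lo, hi = invert(model, o)
            assert 0.0 < lo <= w <= hi < 1.0
        for w_in in (0.05, 0.5, 0.95):
            mean, lo, hi = predict_fraction(model, w_in)
            assert 0.0 < lo <= mean <= hi < 1.0

    def test_flat_slope_refused(self):
        model = make_model(alpha=0.0, beta_slope=1e-12)
        with pytest.raises(ValueError, match="slope"):
            invert(model, 0.4)

    def test_boundary_arguments_rejected(self, identity_model):
        with pytest.raises(ValueError):
            predict_fraction(identity_model, 0.0)
        with pytest.raises(ValueError):
            invert(identity_model, 1.0)


class TestSerialization:
    def test_text_round_trip(self, november_samples):
        model = fit_beta_glm(november_samples)
        text = model_to_text(model)
        back = model_from_text(text)
        assert back.alpha == model.alpha
        assert back.beta_slope == model.beta_slope
        assert back.phi == model.phi
        np.testing.assert_array_equal(back.vcov, model.vcov)
        assert back.key == model.key


def test_shrink_keeps_interior_and_opens_boundary():
    y = np.array([0.0, 0.5, 1.0])
    z = shrink_to_open_interval(y, n=100)
    assert 0.0 < z[0] < z[1] < z[2] < 1.0
    assert z[1] == pytest.approx(0.5, abs=0.01)


def test_model_requires_positive_phi():
    with pytest.raises(ValueError):
        CalibrationModel(alpha=0.0, beta_slope=1.0, phi=0.0)
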