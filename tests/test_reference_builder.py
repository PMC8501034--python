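import json

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.interpolate import CubicHermiteSpline, PchipInterpolator

from ramangt import reference_builder as rb
from ramangt import synthetic_data as sd


class TestPchipDerivatives:
    def test_linear_values_give_constant_slope(self):
        # knots at 0,2,4,6,8: values [0,1,2,3,4] lie on a line of slope 0.5
        d = rb.pchip_derivatives(np.array([0.0, 1.0, 2.0, 3.0, 4.0]))
        np.testing.assert_allclose(d, 0.5)

    def test_alternating_values_zero_interior_and_one_sided_endpoints(self):
        d = rb.pchip_derivatives(np.array([0.0, 1.0, 0.0, 1.0, 0.0]))
        np.testing.assert_allclose(d[1:4], 0.0)
        # unclipped one-sided 3-point: (3*w1 - w2) / (2h) with w1=1, w2=-1, h=2
        assert d[0] == pytest.approx(1.0)
        assert d[-1] == pytest.approx(-1.0)

    def test_interior_harmonic_mean_of_slopes(self):
        # differences w1=1, w2=3 across knot 1 -> slopes 0.5, 1.5 ->
        # harmonic mean 2*0.5*1.5/(0.5+1.5) = 0.75
        d = rb.pchip_derivatives(np.array([0.0, 1.0, 4.0, 5.0, 6.0]))
        assert d[1] == pytest.approx(0.75)

    def test_sign_change_zeroes_interior_derivative(self):
        d = rb.pchip_derivatives(np.array([0.0, 2.0, 1.0, 3.0, 4.0]))
        assert d[1] == 0.0 and d[2] == 0.0


class TestSegmentCoeffs:
    def test_linear_data_degenerates_to_line(self):
        knots = rb.DEFAULT_KNOTS
        values = 0.5 * knots + 1.0
        derivs = np.full(5, 0.5)
        coeffs = rb.pchip_segment_coeffs(knots, values, derivs)
        np.testing.assert_allclose(coeffs[:, 0], 0.0, atol=1e-12)
        np.testing.assert_allclose(coeffs[:, 1], 0.0, atol=1e-12)
        np.testing.assert_allclose(coeffs[:, 2], 0.5, atol=1e-12)
        np.testing.assert_allclose(coeffs[:, 3], 1.0, atol=1e-12)

    def test_interpolation_and_derivative_contract_at_knots(self):
        rng = np.random.default_rng(0)
        values = rng.normal(size=5)
        derivs = rb.pchip_derivatives(values)
        coeffs = rb.pchip_segment_coeffs(rb.DEFAULT_KNOTS, values, derivs)
        for j in range(4):
            a, b, c, d = coeffs[j]
            for end, x in enumerate(rb.DEFAULT_KNOTS[j : j + 2]):
                val = a * x**3 + b * x**2 + c * x + d
                der = 3 * a * x**2 + 2 * b * x + c
                assert val == pytest.approx(values[j + end], abs=1e-10)
                assert der == pytest.approx(derivs[j + end], abs=1e-10)

    def test_finite_difference_derivative_check(self):
        rng = np.random.default_rng(1)
        values = rng.normal(size=5)
        h = 1e-7
        for xk, dk in zip(rb.DEFAULT_KNOTS[1:4], rb.pchip_derivatives(values)[1:4]):
            fd = (
                rb.evaluate_pchip(rb.DEFAULT_KNOTS, values, xk + h)
                - rb.evaluate_pchip(rb.DEFAULT_KNOTS, values, xk - h)
            ) / (2 * h)
            assert fd == pytest.approx(dk, abs=1e-5)

    def test_coincident_knots_rejected(self):
        with pytest.raises(ValueError):
            rb.pchip_segment_coeffs(
                np.array([0.0, 0.0, 4.0, 6.0, 8.0]), np.zeros(5), np.zeros(5)
            )


class TestOracleEquivalence:
    def test_interior_segments_match_reference_pchip(self):
        rng = np.random.default_rng(2)
        xs = np.linspace(2.0, 6.0, 101)
        for _ in range(25):
            values = np.sort(rng.normal(size=5))
            ours = rb.evaluate_pchip(rb.DEFAULT_KNOTS, values, xs)
            ref = PchipInterpolator(rb.DEFAULT_KNOTS, values)(xs)
            np.testing.assert_allclose(ours, ref, atol=1e-10)

    def test_full_curve_matches_hermite_spline_with_same_derivatives(self):
        rng = np.random.default_rng(3)
        xs = np.linspace(0.0, 8.0, 161)
        for _ in range(25):
            values = rng.normal(size=5)
            derivs = rb.pchip_derivatives(values)
            ref = CubicHermiteSpline(rb.DEFAULT_KNOTS, values, derivs)(xs)
            ours = rb.evaluate_pchip(rb.DEFAULT_KNOTS, values, xs)
            np.testing.assert_allclose(ours, ref, atol=1e-10)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_monotone_knots_no_interior_overshoot(self, seed):
        rng = np.random.default_rng(seed)
        values = np.sort(rng.normal(size=5))
        xs = np.linspace(2.0, 6.0, 201)
        out = rb.evaluate_pchip(rb.DEFAULT_KNOTS, values, xs)
        assert out.min() >= values.min() - 1e-10
        assert out.max() <= values.max() + 1e-10


class TestFitChannel:
    def test_exact_recovery_from_stored_fit(self):
        true_values = np.array([0.1, 0.4, 0.35, 0.6, 0.2])
        x_levels = np.arange(0.0, 8.5, 0.5)
        x_obs = np.repeat(x_levels, 4)
        y_obs = rb.evaluate_pchip(rb.DEFAULT_KNOTS, true_values, x_obs)
        fit = rb.fit_channel(x_obs, y_obs)
        np.testing.assert_allclose(fit.values, true_values, atol=1e-6)
        assert fit.rss1 <= 1e-12

    def test_constant_data_fits_constant(self):
        x_obs = np.repeat(np.arange(0.0, 8.5, 0.5), 3)
        fit = rb.fit_channel(x_obs, np.full(x_obs.size, 2.5))
        np.testing.assert_allclose(fit.values, 2.5, atol=1e-8)
        assert fit.rss1 == pytest.approx(0.0, abs=1e-14)

    def test_noisy_fit_beats_best_constant_model(self):
        rng = np.random.default_rng(4)
        x_obs = np.repeat(np.arange(0.0, 8.5, 0.5), 5)
        y_obs = np.sin(x_obs / 2) + 0.05 * rng.normal(size=x_obs.size)
        fit = rb.fit_channel(x_obs, y_obs)
        rss_constant = float(np.sum((y_obs - y_obs.mean()) ** 2))
        assert fit.rss1 <= rss_constant

    def test_single_level_rejected(self):
        with pytest.raises(ValueError):
            rb.fit_channel(np.zeros(5), np.arange(5.0))


class TestReferenceModel:
    def test_noise_free_family_recovered_exactly(self):
        spec = sd.ReferenceFamilySpec(
            noise_sd=0.0, scale_jitter=0.0, baseline_slope_sd=0.0,
            baseline_offset_sd=0.0, seed=0,
        )
        fam = sd.make_reference_family(spec)
        dataset = rb.ReferenceDataset.from_family(fam, preprocess=False)
        # a handful of channels suffices to exercise the whole fit path
        sub = rb.ReferenceDataset(
            rb.WavenumberAxis(dataset.axis.values[:6]),
            dataset.x_obs,
            dataset.Y[:, :6],
        )
        model = rb.build_reference_model(sub)
        for x in spec.ratio_levels:
            np.testing.assert_allclose(
                rb.evaluate_reference(model, x),
                fam.truth_spectrum(x)[:6],
                atol=1e-6,
            )

    def test_fitted_model_has_window_channel_count(self, fitted_model):
        assert fitted_model.n_channels == 210

    def test_fitted_knots_within_noise_error_of_truth(
        self, fitted_model, reference_family
    ):
        spec = sd.ReferenceFamilySpec()
        sigma = spec.noise_sd * float(np.abs(reference_family.truth_values).max())
        # each knot value is constrained by roughly 3 levels x 10 replicates
        se = sigma / np.sqrt(30)
        err = np.abs(
            np.vstack([f.values for f in fitted_model.channel_fits])
            - reference_family.truth_values
        )
        assert np.mean(err < 3 * se) > 0.95
        assert err.max() < 10 * se

    def test_knot_evaluation_returns_optimized_values(self, fitted_model):
        values = np.vstack([f.values for f in fitted_model.channel_fits])
        for i, x in enumerate(rb.DEFAULT_KNOTS):
            np.testing.assert_allclose(
                rb.evaluate_reference(fitted_model, x), values[:, i], atol=1e-10
            )

    def test_continuity_at_segment_boundaries(self, fitted_model):
        for x in (2.0, 4.0, 6.0):
            left = rb.evaluate_reference(fitted_model, x - 1e-9)
            right = rb.evaluate_reference(fitted_model, x + 1e-9)
            np.testing.assert_allclose(left, right, atol=1e-6)

    def test_extrapolation_rejected(self, fitted_model):
        with pytest.raises(ValueError):
            rb.evaluate_reference(fitted_model, 8.5)
        with pytest.raises(ValueError):
            rb.evaluate_reference(fitted_model, -0.1)

    def test_json_round_trip(self, fitted_model, tmp_path):
        path = tmp_path / "model.json"
        fitted_model.to_json(path)
        back = rb.ReferenceModel.from_json(path)
        assert back.n_channels == fitted_model.n_channels
        for x in (0.0, 1.3, 4.7, 8.0):
            np.testing.assert_allclose(
                rb.evaluate_reference(back, x),
                rb.evaluate_reference(fitted_model, x),
                atol=1e-12,
            )

    def test_channel_failure_carries_index(self):
        axis = rb.WavenumberAxis(np.array([2000.0, 2001.0, 2002.0]))
        bad = rb.ReferenceDataset(axis, np.zeros(4), np.ones((4, 3)))
        with pytest.raises(rb.FitError, match="channel 0"):
            rb.build_reference_model(bad)
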