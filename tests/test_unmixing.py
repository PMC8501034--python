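import numpy as np
import pytest

from ramangt import synthetic_data as sd
from ramangt import unmixing as um
from ramangt.reference_builder import evaluate_reference
from ramangt.spectral_core import Spectrum, WavenumberAxis, design_vectors


def _forward(model, x, alpha, beta, gamma, delta, b):
    y = evaluate_reference(model, x)
    ramp, ones = design_vectors(y.size)
    return alpha * y + beta * b + gamma * ramp + delta * ones


def _brute_force_amplitudes(m, y, b, n_alpha=801, n_beta=401):
    """Independent oracle: grid over alpha, beta >= 0; gamma, delta exact."""
    ramp, ones = design_vectors(m.size)
    D = np.column_stack([ramp, ones])
    pinv = np.linalg.pinv(D)
    best = None
    amax = 2 * max(1e-6, abs(float(np.dot(m, y))))
    bmax = 2 * max(1e-6, abs(float(np.dot(m, b) / (b @ b))))
    for alpha in np.linspace(0, amax, n_alpha):
        resid0 = m - alpha * y
        for beta in np.linspace(0, bmax, n_beta):
            resid1 = resid0 - beta * b
            gd = pinv @ resid1
            r = resid1 - D @ gd
            rss = float(r @ r)
            if best is None or rss < best[0]:
                best = (rss, alpha, beta)
    return best


@pytest.fixture(scope="module")
def bg(fitted_model):
    return sd.default_background_spectrum(fitted_model.axis).intensity


class TestFitAmplitudes:
    def test_exact_forward_model_recovered(self, fitted_model, bg):
        m = _forward(fitted_model, 3.0, 2.0, 0.5, 0.01, 5.0, bg)
        y = evaluate_reference(fitted_model, 3.0)
        fit = um.fit_amplitudes_given_x(m, y, bg)
        assert fit.alpha == pytest.approx(2.0, abs=1e-8)
        assert fit.beta == pytest.approx(0.5, abs=1e-8)
        assert fit.gamma == pytest.approx(0.01, abs=1e-10)
        assert fit.delta == pytest.approx(5.0, abs=1e-7)
        assert fit.rss2 <= 1e-18 * float(m @ m)

    def test_negative_signal_clamps_alpha_to_zero(self, fitted_model, bg):
        y = evaluate_reference(fitted_model, 2.0)
        m = -y + np.ones_like(y)
        fit = um.fit_amplitudes_given_x(m, y, bg)
        assert fit.alpha == 0.0
        rss_oracle, a_o, _b_o = _brute_force_amplitudes(m, y, bg, 201, 201)
        assert a_o == pytest.approx(0.0, abs=1e-9)
        assert fit.rss2 <= rss_oracle + 1e-9

    def test_zero_input_gives_zero_fit(self, fitted_model, bg):
        y = evaluate_reference(fitted_model, 1.0)
        fit = um.fit_amplitudes_given_x(np.zeros_like(y), y, bg)
        assert (fit.alpha, fit.beta, fit.gamma, fit.delta) == (0, 0, 0, 0)
        assert fit.rss2 == 0.0

    def test_random_inputs_match_brute_force_oracle(self, fitted_model, bg):
        rng = np.random.default_rng(5)
        y = evaluate_reference(fitted_model, 4.0)
        for _ in range(3):
            m = rng.normal(size=y.size)
            fit = um.fit_amplitudes_given_x(m, y, bg)
            rss_oracle, _a, _b = _brute_force_amplitudes(m, y, bg, 401, 201)
            assert fit.rss2 <= rss_oracle + 1e-6

    def test_rank_deficient_design_flagged(self, fitted_model):
        y = evaluate_reference(fitted_model, 1.0)
        ones = np.ones_like(y)  # background parallel to the intercept column
        fit = um.fit_amplitudes_given_x(ones * 2.0, y, ones)
        assert fit.rank_deficient
        assert fit.rss2 == pytest.approx(0.0, abs=1e-18)


class TestFitPixel:
    def test_noise_free_pixel_recovers_x(self, fitted_model, bg):
        m = _forward(fitted_model, 3.5, 1.5, 0.7, 1e-4, 0.02, bg)
        res = um.fit_pixel(m, fitted_model, bg)
        assert res.x == pytest.approx(3.5, abs=1e-3)
        assert res.alpha == pytest.approx(1.5, abs=1e-3)
        assert res.snr2 > 1e6

    def test_pure_background_pixel_unidentifiable(self, fitted_model, bg):
        ramp, ones = design_vectors(fitted_model.n_channels)
        m = 1.3 * bg + 0.01 * ones
        res = um.fit_pixel(m, fitted_model, bg)
        assert res.alpha == pytest.approx(0.0, abs=1e-8)
        assert res.snr2 < 1.0  # far below the identifiability gate
        assert not res.identifiable

    def test_x_invariant_under_positive_scaling(self, fitted_model, bg):
        rng = np.random.default_rng(6)
        m = _forward(fitted_model, 2.7, 1.0, 0.5, 0.0, 0.0, bg)
        m = m + 0.001 * rng.normal(size=m.size)
        r1 = um.fit_pixel(m, fitted_model, bg)
        r2 = um.fit_pixel(10.0 * m, fitted_model, bg)
        assert r2.x == pytest.approx(r1.x, abs=1e-6)
        assert r2.snr2 == pytest.approx(r1.snr2, rel=1e-6)

    def test_refinement_never_worse_than_coarse_grid(self, fitted_model, bg):
        rng = np.random.default_rng(7)
        grid = np.arange(0.0, 8.0 + 0.025, 0.05)
        for _ in range(3):
            x_true = rng.uniform(0.3, 7.7)
            m = _forward(fitted_model, x_true, 1.0, 1.0, 0.0, 0.0, bg)
            m = m + 0.005 * rng.normal(size=m.size)
            res = um.fit_pixel(m, fitted_model, bg)
            coarse = min(
                um.fit_amplitudes_given_x(
                    m, fitted_model.evaluate_many(np.array([g]))[:, 0], bg
                ).rss2
                for g in grid
            )
            assert res.rss2 <= coarse + 1e-12


class TestSnr2:
    def test_zero_alpha_gives_zero(self):
        assert um.snr2(0.0, np.ones(5), 1.0) == 0.0

    def test_exact_fit_gives_sentinel(self):
        assert um.snr2(2.0, np.ones(5), 0.0) == np.inf

    def test_value_formula(self):
        y = np.array([1.0, 2.0])
        assert um.snr2(3.0, y, 5.0) == pytest.approx(9 * 5 / 5.0)


class TestUnmixCube:
    def test_noise_free_phantom_recovered(self, fitted_model):
        spec = sd.PhantomSpec(seed=0, noise_sd=0.0, hla_rows=(),
                              height=20, width=20,
                              droplets=((10.0, 10.0, 2.0, 0.5, 8.0),))
        cube, truth = sd.make_phantom_cube(spec, fitted_model)
        images = um.unmix_cube(cube, fitted_model, truth.bg_pixel)
        sel = truth.alpha_map > 0
        assert np.abs(images["x"] - truth.x_map)[sel].max() <= 1e-3
        np.testing.assert_allclose(
            images["alpha"][sel], truth.alpha_map[sel], atol=1e-6
        )

    def test_pure_background_phantom_alpha_zero(self, fitted_model):
        spec = sd.PhantomSpec(seed=1, noise_sd=0.0, hla_rows=(), droplets=(),
                              height=12, width=12, alpha_cytosol=0.0)
        cube, truth = sd.make_phantom_cube(spec, fitted_model)
        images = um.unmix_cube(cube, fitted_model, truth.bg_pixel)
        assert np.abs(images["alpha"]).max() <= 1e-8

    def test_intensity_image_linear_in_alpha(self, fitted_model):
        base = dict(seed=0, noise_sd=0.0, hla_rows=(), droplets=(),
                    height=8, width=8, beta_range=(1.0, 1.0),
                    gamma_range=(0.0, 0.0), delta_range=(0.0, 0.0))
        c1, t1 = sd.make_phantom_cube(sd.PhantomSpec(alpha_cytosol=1.0, **base),
                                      fitted_model)
        c2, _ = sd.make_phantom_cube(sd.PhantomSpec(alpha_cytosol=2.0, **base),
                                     fitted_model)
        i1 = um.unmix_cube(c1, fitted_model, t1.bg_pixel)["intensity"]
        i2 = um.unmix_cube(c2, fitted_model, t1.bg_pixel)["intensity"]
        sel = i1 > 1e-6
        np.testing.assert_allclose(i2[sel], 2.0 * i1[sel], rtol=1e-6)

    def test_background_pixel_out_of_bounds_rejected(self, fitted_model):
        spec = sd.PhantomSpec(seed=0, height=8, width=8, droplets=(),
                              hla_rows=())
        cube, _ = sd.make_phantom_cube(spec, fitted_model)
        with pytest.raises(ValueError, match="out of bounds"):
            um.unmix_cube(cube, fitted_model, (99, 0))


class TestFlankSubtraction:
    @pytest.fixture()
    def full_axis_pair(self):
        axis = sd.make_silent_region_axis()
        w = axis.values
        bg = Spectrum(axis, 0.7 * np.exp(-0.5 * ((w - 2150) / 200.0) ** 2) + 0.2,
                      "bg")
        return axis, bg

    def test_exact_model_recovered_and_residual_zero(self, full_axis_pair):
        axis, bg = full_axis_pair
        ramp = um.flank_ramp(axis, ((1800.0, 2000.0), (2300.0, 2500.0)))
        target = Spectrum(axis, 1.7 * bg.intensity + 0.02 * ramp + 3.0)
        fit = um.subtract_background_flanks(target, bg)
        assert fit.beta == pytest.approx(1.7, abs=1e-9)
        assert fit.gamma == pytest.approx(0.02, abs=1e-12)
        assert fit.delta == pytest.approx(3.0, abs=1e-9)
        np.testing.assert_allclose(fit.subtracted.intensity, 0.0, atol=1e-9)

    def test_band_inside_window_preserved(self, full_axis_pair):
        axis, bg = full_axis_pair
        w = axis.values
        band = 0.9 * np.exp(-0.5 * ((w - 2100) / 15.0) ** 2)
        band[(w < 2000) | (w > 2300)] = 0.0
        target = Spectrum(axis, 1.2 * bg.intensity + band + 0.5)
        fit = um.subtract_background_flanks(target, bg)
        assert fit.beta == pytest.approx(1.2, abs=1e-6)
        inside = (fit.subtracted.axis.values > 2050) & (
            fit.subtracted.axis.values < 2150
        )
        expected = band[(w > 2050) & (w < 2150)]
        np.testing.assert_allclose(
            fit.subtracted.intensity[inside], expected, atol=1e-6
        )

    def test_each_flank_contributes_140_channels(self, full_axis_pair):
        axis, _ = full_axis_pair
        w = axis.values
        assert int(((w >= 1800) & (w <= 2000)).sum()) == 140
        assert int(((w >= 2300) & (w <= 2500)).sum()) == 140
        ramp = um.flank_ramp(axis, ((1800.0, 2000.0), (2300.0, 2500.0)))
        assert ramp[(w >= 1800) & (w <= 2000)].max() == 140
        assert ramp[(w >= 2300) & (w <= 2500)].min() == 141
        assert ramp[(w >= 2300) & (w <= 2500)].max() == 280

    def test_missing_flank_rejected(self, fitted_model):
        axis = fitted_model.axis  # window only, no flanks
        s = Spectrum(axis, np.ones(len(axis)))
        with pytest.raises(ValueError, match="flank"):
            um.subtract_background_flanks(s, s)
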