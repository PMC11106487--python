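"""Model evaluation, fitting, classification and size comparison."""

import numpy as np
import pytest

from nanodomain import (
    BlinkModel,
    ClusterGroundTruth,
    PairCorrelationCurve,
    classify_condition,
    compare_cluster_sizes,
    compute_pair_correlation,
    eval_clustered_model,
    eval_random_model,
    fit_clustered_model,
    fit_random_model,
    simulate_localizations_clustered,
    simulate_localizations_random,
)
from nanodomain.clusterfit import _radial_gauss_conv_weights
from nanodomain.exceptions import InsufficientDataError, ParameterError, ResolutionError


def _curve_from_model(r, g, density=1800.0):
    return PairCorrelationCurve(
        r_nm=r, g=g, bin_nm=float(r[1] - r[0]), density_per_um2=density,
        n_localizations=int(density * 16),
    )


class TestModelEvaluation:
    def test_random_model_closed_form(self):
        sigma, rho = 20.0, 2.0e-3
        r = np.array([40.0])
        expected = np.exp(-(40.0**2) / (4 * sigma**2)) / (4 * np.pi * sigma**2 * rho) + 1
        assert eval_random_model(r, sigma, rho)[0] == pytest.approx(expected, rel=1e-12)
        # origin value and tail limit
        assert eval_random_model(np.array([0.0]), sigma, rho)[0] == pytest.approx(
            1 + 1 / (4 * np.pi * sigma**2 * rho)
        )

    @pytest.mark.parametrize("model_tail_r_factor", [50.0])
    def test_both_models_tend_to_one(self, model_tail_r_factor):
        sigma, rho, a, xi = 20.0, 2.0e-3, 5.0, 33.5
        r = np.array([model_tail_r_factor * xi])
        assert abs(eval_random_model(r, sigma, rho)[0] - 1.0) < 1e-6
        assert abs(eval_clustered_model(r, sigma, rho, a, xi)[0] - 1.0) < 1e-6

    def test_zero_amplitude_reduces_to_random_model(self):
        r = np.arange(10.0, 500.0, 10.0)
        np.testing.assert_allclose(
            eval_clustered_model(r, 20.0, 2e-3, 0.0, 33.5),
            eval_random_model(r, 20.0, 2e-3),
        )

    def test_gaussian_kernel_has_unit_mass(self):
        """Convolving the constant 1 with the blur kernel returns 1."""
        r = np.arange(0.0, 400.0, 10.0)
        s, w = _radial_gauss_conv_weights(r, 20.0)
        np.testing.assert_allclose(w @ np.ones_like(s), 1.0, atol=5e-4)

    def test_narrow_kernel_limit(self):
        """For xi >> sigma_s the convolution barely changes the exponential."""
        sigma, rho, a, xi = 5.0, 2e-3, 2.0, 300.0
        r = np.arange(20.0, 500.0, 10.0)  # r > 3 sigma
        full = eval_clustered_model(r, sigma, rho, a, xi)
        approx = eval_random_model(r, sigma, rho) + a * np.exp(-r / xi)
        assert np.max(np.abs(full - approx) / approx) < 0.02

    def test_radial_and_grid_fft_routes_agree(self):
        r = np.arange(10.0, 500.0, 10.0)
        a = eval_clustered_model(r, 20.0, 2e-3, 5.0, 33.5, method="radial")
        b = eval_clustered_model(r, 20.0, 2e-3, 5.0, 33.5, method="grid")
        assert np.max(np.abs(a - b) / b) < 0.01

    def test_grid_resolution_guard(self):
        with pytest.raises(ResolutionError):
            eval_clustered_model(
                np.arange(10.0, 100.0, 10.0), 4.0, 2e-3, 5.0, 33.5,
                method="grid", grid_nm=10.0,
            )

    def test_parameter_validation(self):
        with pytest.raises(ParameterError):
            eval_random_model(np.array([1.0]), -1.0, 1e-3)
        with pytest.raises(ParameterError):
            eval_clustered_model(np.array([1.0]), 20.0, 1e-3, -0.5, 30.0)


class TestFitting:
    def test_random_fit_self_consistency(self):
        r = np.arange(10.0, 500.0, 10.0)
        sigma, rho = 20.0, 1.8e-3
        pc = _curve_from_model(r, eval_random_model(r, sigma, rho))
        fit = fit_random_model(pc)
        assert fit.sigma_s_nm == pytest.approx(sigma, rel=1e-3)
        assert fit.rho_per_nm2 == pytest.approx(rho, rel=1e-3)
        assert fit.mse < 1e-10

    def test_clustered_fit_self_consistency(self):
        r = np.arange(10.0, 500.0, 10.0)
        sigma, rho, a, xi = 20.0, 1.8e-3, 5.0, 33.5
        pc = _curve_from_model(r, eval_clustered_model(r, sigma, rho, a, xi))
        fit = fit_clustered_model(pc, sigma)
        assert fit.amplitude == pytest.approx(a, rel=1e-2)
        assert fit.xi_nm == pytest.approx(xi, rel=1e-2)
        assert fit.diameter_nm == pytest.approx(2 * xi, rel=1e-2)
        assert fit.mse < 1e-8

    def test_multistart_initialization_agreement(self):
        r = np.arange(10.0, 500.0, 10.0)
        pc = _curve_from_model(r, eval_clustered_model(r, 20.0, 1.8e-3, 5.0, 33.5))
        fits = [fit_clustered_model(pc, 20.0, xi_inits=(x0,)) for x0 in (20.0, 60.0, 150.0)]
        xis = [f.xi_nm for f in fits]
        assert max(xis) / min(xis) - 1 < 0.01

    def test_sigma_recovery_from_blinking_simulation(self, roi4um, csr_curves):
        """Eq.-1-type fits on isolated-molecule simulations recover the
        generating localization error within 10%."""
        sig = np.mean([fit_random_model(c).sigma_s_nm for c in csr_curves])
        assert abs(sig - 20.0) / 20.0 < 0.10

    def test_generating_model_fits_better_than_wrong_model(
        self, clustered_curves, pooled_sigma
    ):
        for pc in clustered_curves[:6]:
            rf = fit_random_model(pc)
            cf = fit_clustered_model(pc, pooled_sigma)
            assert cf.mse < rf.mse

    def test_too_few_bins_raises(self):
        r = np.arange(10.0, 60.0, 10.0)
        pc = _curve_from_model(r, np.ones_like(r))
        with pytest.raises(InsufficientDataError):
            fit_random_model(pc)


class TestClassification:
    def test_duplicate_curves_classified_random(self):
        r = np.arange(10.0, 500.0, 10.0)
        pc = _curve_from_model(r, eval_random_model(r, 20.0, 1.8e-3))
        cls = classify_condition([pc] * 8)
        assert cls.ks_statistic == 0.0
        assert cls.p_value == 1.0
        assert cls.verdict == "random"
        assert cls.xi_nm.size == 0

    def test_clustered_condition_detected(self, clustered_curves, pooled_sigma):
        cls = classify_condition(
            clustered_curves, sigma_mode="pooled", pooled_sigma_nm=pooled_sigma
        )
        assert cls.verdict == "clustered"
        assert cls.p_value <= 0.05
        assert abs(np.mean(cls.diameters_nm) - 67.0) / 67.0 < 0.15

    def test_csr_condition_classified_random(self, csr_curves, pooled_sigma):
        cls = classify_condition(
            csr_curves, sigma_mode="pooled", pooled_sigma_nm=pooled_sigma
        )
        assert cls.verdict == "random"

    def test_decision_is_deterministic(self, clustered_curves, pooled_sigma):
        a = classify_condition(clustered_curves, sigma_mode="pooled",
                               pooled_sigma_nm=pooled_sigma)
        b = classify_condition(clustered_curves, sigma_mode="pooled",
                               pooled_sigma_nm=pooled_sigma)
        assert a.verdict == b.verdict
        assert a.p_value == b.p_value

    def test_requires_eight_curves(self):
        r = np.arange(10.0, 500.0, 10.0)
        pc = _curve_from_model(r, eval_random_model(r, 20.0, 1.8e-3))
        with pytest.raises(InsufficientDataError):
            classify_condition([pc] * 5)


class TestSizeComparison:
    def test_identical_samples_not_significant(self):
        sizes = np.array([60.0, 65.0, 70.0, 72.0, 68.0])
        stat, p = compare_cluster_sizes(sizes, sizes)
        assert p == pytest.approx(1.0)

    def test_empty_sample_rejected(self):
        with pytest.raises(ParameterError):
            compare_cluster_sizes(np.array([]), np.array([60.0]))

    def test_shifted_and_equal_xi_conditions(self, roi4um, default_blink, pooled_sigma):
        """Fitted sizes from xi=30 vs xi=60 separate sharply; two batches at
        equal xi do not."""

        def sizes(xi, seed0, n=8):
            truth = ClusterGroundTruth(xi_nm=xi, amplitude=5.0, density_per_um2=600.0)
            out = []
            for s in range(n):
                sim = simulate_localizations_clustered(
                    roi4um, truth, default_blink, seed=seed0 + s
                )
                pc = compute_pair_correlation(sim.table)
                out.append(fit_clustered_model(pc, pooled_sigma).xi_nm)
            return np.array(out)

        s30a = sizes(30.0, 7000)
        s30b = sizes(30.0, 8000)
        s60 = sizes(60.0, 9000)
        _, p_shift = compare_cluster_sizes(s30a, s60)
        _, p_null = compare_cluster_sizes(s30a, s30b)
        assert p_shift < 0.01
        assert p_null > 0.05
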