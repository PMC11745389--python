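import itertools

import numpy as np
import pytest

from epiland.inference import (
    FourierSpectrum,
    bandpass_denoise,
    design_matrix,
    fast_wht,
    fit_global,
    fit_specific_ml,
    fourier_to_taylor,
    inverse_wh_transform,
    landscape_to_taylor,
    r_squared,
    subset_orders,
    taylor_to_fourier,
    taylor_to_landscape,
    wh_transform,
)
from epiland.landscape import EpistasisCoefficients, FitnessLandscape
from epiland.synthetic import NoiseModel, make_noisy_replicates


def random_coeffs(rng, L=5, orders=(1, 2, 3)):
    h = {i: float(rng.normal()) for i in range(L)} if 1 in orders else {}
    J = (
        {p: float(rng.normal(0, 0.5)) for p in itertools.combinations(range(L), 2)}
        if 2 in orders
        else {}
    )
    K = (
        {t: float(rng.normal(0, 0.3)) for t in itertools.combinations(range(L), 3)}
        if 3 in orders
        else {}
    )
    return EpistasisCoefficients(L, h, J, K)


class TestWalshHadamard:
    def test_constant_landscape_only_order0(self):
        ls = FitnessLandscape(4, np.full(16, 3.25))
        spec = wh_transform(ls)
        assert spec.coefficients[0] == pytest.approx(3.25)
        assert np.allclose(spec.coefficients[1:], 0.0)

    def test_order0_is_mean(self, rng):
        ls = FitnessLandscape(5, rng.normal(size=32))
        assert wh_transform(ls).coefficients[0] == pytest.approx(ls.fitness.mean())

    def test_roundtrip_identity(self, rng):
        ls = FitnessLandscape(6, rng.normal(size=64))
        back = inverse_wh_transform(wh_transform(ls))
        assert np.allclose(back.fitness, ls.fitness, rtol=1e-10, atol=1e-12)

    def test_additive_landscape_spectrum_support(self, rng):
        c = random_coeffs(rng, L=5, orders=(1,))
        spec = wh_transform(c.to_landscape())
        orders = subset_orders(5)
        assert np.allclose(spec.coefficients[orders >= 2], 0.0, atol=1e-12)
        assert np.any(np.abs(spec.coefficients[orders == 1]) > 1e-8)

    def test_parseval(self, rng):
        ls = FitnessLandscape(6, rng.normal(size=64))
        spec = wh_transform(ls)
        assert np.sum(ls.fitness**2) == pytest.approx(
            64 * np.sum(spec.coefficients**2)
        )

    def test_non_power_of_two_rejected(self):
        with pytest.raises(ValueError, match="power of two"):
            fast_wht(np.zeros(12))


class TestBasisConversion:
    def test_taylor_recovers_coefficients(self, rng):
        c = random_coeffs(rng, L=4)
        taylor = landscape_to_taylor(c.to_landscape())
        assert taylor.coefficients[1 << 2] == pytest.approx(c.h[2])
        assert taylor.coefficients[(1 << 0) | (1 << 3)] == pytest.approx(c.J[(0, 3)])
        assert taylor.coefficients[0b0111] == pytest.approx(c.K[(0, 1, 2)])

    def test_taylor_fourier_roundtrip(self, rng):
        spec = FourierSpectrum(5, rng.normal(size=32), "taylor")
        back = fourier_to_taylor(taylor_to_fourier(spec))
        assert np.allclose(back.coefficients, spec.coefficients, atol=1e-10)

    def test_order3_support_preserved_by_basis_change(self, rng):
        c = random_coeffs(rng, L=5)
        four = wh_transform(c.to_landscape())
        assert np.allclose(four.coefficients[subset_orders(5) > 3], 0.0, atol=1e-12)


class TestBandpass:
    def test_band_limited_unchanged(self, rng):
        c = random_coeffs(rng, L=5)
        ls = c.to_landscape()
        out = bandpass_denoise(wh_transform(ls), max_order=3)
        assert np.allclose(out.fitness, ls.fitness - ls.fitness[0], atol=1e-10)

    def test_injected_order4_removed(self, rng):
        c = random_coeffs(rng, L=5)
        ls = c.to_landscape()
        spec = wh_transform(ls)
        dirty = spec.coefficients.copy()
        dirty[0b01111] += 2.5  # an order-4 component
        noisy = inverse_wh_transform(FourierSpectrum(5, dirty, "fourier"))
        out = bandpass_denoise(noisy, max_order=3)
        assert np.allclose(out.fitness, ls.fitness - ls.fitness[0], atol=1e-10)

    def test_idempotent(self, rng):
        ls = FitnessLandscape(5, rng.normal(size=32))
        once = bandpass_denoise(ls, max_order=3)
        twice = bandpass_denoise(once, max_order=3)
        assert np.allclose(once.fitness, twice.fitness, atol=1e-12)

    def test_germline_rereferenced(self, rng):
        ls = FitnessLandscape(5, rng.normal(size=32))
        assert bandpass_denoise(ls, max_order=2).fitness[0] == 0.0

    def test_invalid_cutoff(self, rng):
        ls = FitnessLandscape(3, rng.normal(size=8))
        with pytest.raises(ValueError):
            bandpass_denoise(ls, max_order=7)

    def test_denoising_raises_interreplicate_r2(self, rng):
        # at L=10 the order-3 band keeps 176/1024 basis directions, so
        # truncation removes most of the replicate noise
        truth = random_coeffs(rng, L=10).to_landscape()
        reps = make_noisy_replicates(truth, NoiseModel(sigma=0.4, n_rep=2, seed=7))
        raw_r2 = r_squared(reps[0], reps[1])
        den = [
            bandpass_denoise(FitnessLandscape(10, reps[i]), max_order=3).fitness
            for i in range(2)
        ]
        assert r_squared(den[0], den[1]) > raw_r2


class TestFitSpecificML:
    def test_noiseless_recovery(self, rng):
        c = random_coeffs(rng, L=5)
        y = c.to_landscape().fitness
        fit, report = fit_specific_ml(y[None, :], max_order=3)
        assert np.allclose(fit.as_vector(), c.as_vector(), atol=1e-8)

    def test_full_order_interpolates(self, rng):
        y = rng.normal(size=16)
        y[0] = 0.0  # germline-zero is built into the design
        fit_vec = None
        X = design_matrix(4, 4)
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        assert np.allclose(X @ beta, y, atol=1e-10)

    def test_cv_selects_order3(self, rng):
        # majority vote over 10 noisy datasets at moderate sigma
        truth = random_coeffs(rng, L=6)
        ls = truth.to_landscape()
        selected = []
        for s in range(10):
            reps = make_noisy_replicates(ls, NoiseModel(sigma=0.15, n_rep=2, seed=s))
            _, report = fit_specific_ml(reps, seed=0)
            selected.append(report.selected_order)
        assert np.median(selected) == 3

    def test_interactions_shrink_with_noise(self, rng):
        truth = random_coeffs(rng, L=5, orders=(1,))
        ls = truth.to_landscape()
        excess = []
        for sigma in (0.5, 0.1, 0.01):
            reps = make_noisy_replicates(ls, NoiseModel(sigma=sigma, n_rep=2, seed=3))
            fit, _ = fit_specific_ml(reps, max_order=3)
            v = fit.as_vector()
            excess.append(np.linalg.norm(v[5:]))  # J and K part
        assert excess[0] > excess[1] > excess[2]

    def test_recovery_error_decreases_with_noise(self, rng):
        truth = random_coeffs(rng, L=5)
        ls = truth.to_landscape()
        tv = truth.as_vector()
        med_errs = []
        for sigma in (0.5, 0.1, 0.02):
            errs = []
            for s in range(20):
                reps = make_noisy_replicates(ls, NoiseModel(sigma, 2, seed=100 + s))
                fit, _ = fit_specific_ml(reps, max_order=3)
                errs.append(np.linalg.norm(fit.as_vector() - tv) / np.linalg.norm(tv))
            med_errs.append(np.median(errs))
        assert med_errs[0] > med_errs[1] > med_errs[2]

    def test_wrong_table_size(self):
        with pytest.raises(ValueError):
            fit_specific_ml(np.zeros((1, 12)), max_order=2)


class TestFitGlobal:
    def test_linear_g_recovers_h(self, rng):
        h_true = rng.normal(size=5)
        c = EpistasisCoefficients(5, {i: float(v) for i, v in enumerate(h_true)})
        model, report = fit_global(c.to_landscape())
        # h recovered up to normalization
        cos = abs(np.dot(model.h, h_true) / np.linalg.norm(h_true))
        assert cos == pytest.approx(1.0, abs=1e-6)
        assert report.r2_per_replicate[0] > 0.999

    def test_saturating_g_rank_correlation(self, rng):
        from scipy.stats import spearmanr

        h_true = np.abs(rng.normal(size=6)) + 0.2
        idx = np.arange(64)
        bits = ((idx[:, None] >> np.arange(6)[None, :]) & 1).astype(float)
        phi = bits @ h_true
        y = np.tanh(phi / phi.max() * 2.5)  # monotone saturating transform
        model, _ = fit_global(y)
        rho = spearmanr(model.latent(), phi).statistic
        assert rho > 0.99

    def test_predictions_monotone_in_latent(self, rng):
        y = rng.normal(size=32)
        model, _ = fit_global(y)
        phi = model.latent()
        order = np.argsort(phi)
        pred = model.predict()[order]
        assert np.all(np.diff(pred) >= -1e-9)

    def test_h_normalized(self, rng):
        y = rng.normal(size=32)
        model, _ = fit_global(y)
        assert np.linalg.norm(model.h) == pytest.approx(1.0)
        # orientation: latent phenotype correlates positively with fitness
        assert np.corrcoef(model.latent(), y)[0, 1] >= 0
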