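import numpy as np
import pytest

import hosbeat as hb
from hosbeat.beats import GRID
from hosbeat.hermite import (CROSSOVER_ALPHAS, GAConfig, basis_matrix, fit,
                             hermite_polynomial, normalized_error,
                             optimize_width, reconstruct)


class TestHermitePolynomial:
    @pytest.mark.parametrize("n,t,expected", [
        (0, 3.7, 1.0),        # H_0 = 1
        (1, 2.0, 4.0),        # H_1 = 2t
        (2, 1.0, 2.0),        # H_2 = 4t^2 - 2
        (3, 1.0, -4.0),       # H_3 = 8t^3 - 12t
        (4, 0.5, 1.0),        # H_4 = 16t^4 - 48t^2 + 12
    ])
    def test_known_values(self, n, t, expected):
        assert hermite_polynomial(n, t) == pytest.approx(expected, rel=1e-12)

    def test_negative_degree_rejected(self):
        with pytest.raises(ValueError):
            hermite_polynomial(-1, 0.0)

    def test_matches_numpy_hermite(self, rng):
        # cross-check the recursion against numpy's Hermite evaluation
        for n in (5, 9, 14):
            t = rng.uniform(-3, 3)
            coef = np.zeros(n + 1)
            coef[n] = 1.0
            assert hermite_polynomial(n, t) == pytest.approx(
                np.polynomial.hermite.hermval(t, coef), rel=1e-10)


class TestBasisMatrix:
    def test_shape_and_validation(self):
        b = basis_matrix(26, 12.0)
        assert b.matrix.shape == (201, 26)
        with pytest.raises(ValueError):
            basis_matrix(26, 0.0)
        with pytest.raises(ValueError):
            basis_matrix(0, 5.0)

    def test_first_column_is_gaussian_peaking_at_zero(self):
        col0 = basis_matrix(1, 10.0).matrix[:, 0]
        assert np.argmax(col0) == 100
        assert np.all(col0 > 0)
        # matches the closed form of the order-0 basis function
        expected = np.pi**-0.25 / np.sqrt(10.0) * np.exp(-GRID**2 / 200.0)
        assert np.allclose(col0, expected, atol=1e-15)

    def test_columns_match_direct_formula(self):
        # stable recursion equals the explicit normalisation x polynomial form
        sigma, N = 8.0, 12
        m = basis_matrix(N, sigma).matrix
        from math import factorial, pi, sqrt
        for n in (0, 3, 7, 11):
            direct = np.array([
                (sigma * 2**n * factorial(n) * sqrt(pi)) ** -0.5
                * hermite_polynomial(n, t / sigma) * np.exp(-t**2 / (2 * sigma**2))
                for t in GRID])
            assert np.allclose(m[:, n], direct, atol=1e-12)

    @pytest.mark.parametrize("N,sigma", [(26, 4), (26, 10), (30, 10), (30, 4)])
    def test_orthonormality_within_supported_window(self, N, sigma):
        # for sigma in [4, 10] the ±100-sample grid holds essentially all
        # basis mass up to N=30 and resolves the fastest oscillation, so the
        # discrete Gram is the identity (measured deviation <= 8e-12); it
        # degrades for larger widths (tail truncation) and for sigma <~ 3
        # (aliasing of the highest-order oscillations)
        m = basis_matrix(N, sigma).matrix
        assert np.abs(m.T @ m - np.eye(N)).max() < 1e-9

    def test_orthonormality_lost_for_wide_basis(self):
        m = basis_matrix(27, 15.0).matrix
        assert np.abs(m.T @ m - np.eye(27)).max() > 1e-2

    def test_width_parameter_dilates_envelope(self):
        # half-maximum width of the order-0 function grows with sigma
        widths = []
        for sigma in (5.0, 10.0, 15.0):
            col = basis_matrix(1, sigma).matrix[:, 0]
            widths.append(int((col > col.max() / 2).sum()))
        assert widths[0] < widths[1] < widths[2]


class TestNormalizedError:
    def test_hand_arithmetic(self):
        assert normalized_error([3.0, 4.0], [3.0, 4.0]) == 0.0
        assert normalized_error([3.0, 4.0], [0.0, 0.0]) == 1.0
        assert normalized_error([3.0, 4.0], [3.0, 0.0]) == pytest.approx(16 / 25)

    def test_zero_signal_degenerate_case(self):
        assert normalized_error([0.0, 0.0], [0.0, 0.0]) == 0.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            normalized_error([1.0], [1.0, 2.0])


class TestFit:
    def test_recovers_basis_column(self):
        basis = basis_matrix(8, 8.0)
        f = fit(basis.matrix[:, 3], basis)
        expected = np.zeros(8)
        expected[3] = 1.0
        assert np.abs(f.coefficients - expected).max() < 1e-8
        assert f.error < 1e-12

    def test_recovers_random_coefficients(self, rng):
        basis = basis_matrix(8, 8.0)
        a_true = rng.standard_normal(8)
        f = fit(basis.matrix @ a_true, basis)
        assert np.abs(f.coefficients - a_true).max() < 1e-8

    def test_zero_signal(self):
        f = fit(np.zeros(201), basis_matrix(5, 8.0))
        assert np.all(f.coefficients == 0.0) and f.error == 0.0

    def test_nonfinite_signal_rejected(self):
        sig = np.zeros(201)
        sig[0] = np.nan
        with pytest.raises(ValueError):
            fit(sig, basis_matrix(5, 8.0))

    def test_linearity(self, rng):
        basis = basis_matrix(10, 7.0)
        x, y = rng.standard_normal(201), rng.standard_normal(201)
        fa = fit(2.0 * x + 0.5 * y, basis).coefficients
        fb = 2.0 * fit(x, basis).coefficients + 0.5 * fit(y, basis).coefficients
        assert np.allclose(fa, fb, rtol=1e-10, atol=1e-10)

    def test_error_nonincreasing_in_order(self, rng):
        # nested least squares: adding basis functions never hurts
        sig = rng.standard_normal(201)
        errs = [fit(sig, basis_matrix(N, 8.0)).error for N in range(1, 41)]
        assert all(e2 <= e1 + 1e-12 for e1, e2 in zip(errs, errs[1:]))

    def test_roundtrip_reconstruction(self):
        beat = hb.generate_beat("N", seed=9)
        f = hb.model_cumulant(beat.samples, 26, GAConfig(seed=2))
        assert normalized_error(beat.samples, reconstruct(f)) == pytest.approx(
            f.error, abs=1e-12)
        # 26 coefficients + sigma reconstruct a synthetic beat accurately
        assert f.error < 0.05


class TestGeneticAlgorithm:
    def test_config_validation(self):
        with pytest.raises(ValueError):
            GAConfig(population=9)
        with pytest.raises(ValueError):
            GAConfig(mutation_prob=1.5)
        with pytest.raises(ValueError):
            GAConfig(sigma_bounds=(5.0, 2.0))

    def test_population_is_ten_every_generation(self):
        beat = hb.generate_beat("PVC", seed=1)
        cv = hb.cumulant_set(beat)[1]
        pops = []
        optimize_width(cv.values, 26, GAConfig(seed=4), track_population=pops)
        assert len(pops) >= 1
        assert all(len(p) == 10 for p in pops)

    def test_crossover_produces_eight_offspring(self):
        assert len(CROSSOVER_ALPHAS) == 8

    def test_deterministic_per_seed(self):
        cv = hb.cumulant_set(hb.generate_beat("N", seed=6))[0]
        a = optimize_width(cv.values, 26, GAConfig(seed=11))
        b = optimize_width(cv.values, 26, GAConfig(seed=11))
        assert a.sigma == b.sigma and a.error == b.error

    def test_elitism_never_worse_than_initial_best(self):
        cv = hb.cumulant_set(hb.generate_beat("RBBB", seed=8))[2]
        pops = []
        result = optimize_width(cv.values, 26, GAConfig(seed=5),
                                track_population=pops)
        initial_best = min(
            fit(cv.values, basis_matrix(26, s)).error for s in pops[0])
        assert result.error <= initial_best

    def test_sigma_stays_in_bounds(self):
        cv = hb.cumulant_set(hb.generate_beat("N", seed=6))[1]
        cfg = GAConfig(sigma_bounds=(5.0, 9.0), seed=2)
        f = optimize_width(cv.values, 26, cfg)
        assert 5.0 <= f.sigma <= 9.0

    def test_near_grid_search_optimum(self):
        # GA error within 5% relative of a 1000-point grid search
        cv = hb.cumulant_set(hb.generate_beat("LBBB", seed=13))[1]
        cfg = GAConfig(seed=21)
        lo, hi = cfg.sigma_bounds
        grid_best = min(fit(cv.values, basis_matrix(26, s)).error
                        for s in np.linspace(lo, hi, 1000))
        ga = optimize_width(cv.values, 26, cfg)
        assert ga.error <= grid_best * 1.05


class TestModelCumulant:
    def test_error_decreases_with_order(self):
        cv = hb.cumulant_set(hb.generate_beat("N", seed=3))[1]
        errs = {N: hb.model_cumulant(cv, N, GAConfig(seed=2)).error
                for N in (5, 10, 26)}
        assert errs[26] <= errs[10] <= errs[5]

    def test_system_shape_is_201_by_26(self):
        f = hb.model_cumulant(hb.cumulant_set(hb.generate_beat("N", seed=3))[0])
        assert f.order == 26 and f.coefficients.shape == (26,)
        assert basis_matrix(26, f.sigma).matrix.shape == (201, 26)

    def test_amplitude_shifted_beat_gives_identical_fit(self):
        b = hb.generate_beat("APC", seed=5)
        cfg = GAConfig(seed=7, generations=12)
        f1 = hb.model_cumulant(hb.cumulant_set(b)[1], 26, cfg)
        f2 = hb.model_cumulant(hb.cumulant_set(hb.shift_amplitude(b, 0.1))[1],
                               26, cfg)
        assert np.array_equal(f1.coefficients, f2.coefficients)
        assert f1.sigma == f2.sigma
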