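import math

import numpy as np
import pytest
from scipy.special import gamma as gamma_fn

import pangenesis as pg
from pangenesis.spectra import _model_a_vector


class TestModelA:
    def test_single_genome_carries_M_genes(self):
        for theta in (0.0, 0.5, 7.0):
            assert pg.spectrum_model_a(theta, 2000, 1).g == pytest.approx([2000.0])

    def test_zero_transfer_population_is_clonal(self):
        s = pg.spectrum_model_a(0.0, 2000, 20)
        assert s.g[-1] == 2000.0
        assert np.all(s.g[:-1] == 0.0)

    def test_hand_evaluation_theta_one_two_genomes(self):
        # g_1 = M*theta*2*(theta)_1/(theta)_2 = M; g_2 = M/2 at theta = 1
        s = pg.spectrum_model_a(1.0, 2000, 2)
        assert s.g == pytest.approx([2000.0, 1000.0], rel=1e-12)

    def test_u_shape_below_theta_one_monotone_above(self):
        u = pg.spectrum_model_a(0.3, 2000, 20).g
        assert u[0] > u[1] and u[-1] > u[-2]
        mono = pg.spectrum_model_a(3.0, 2000, 20).g
        assert np.all(np.diff(mono) < 0)

    def test_infinite_theta_every_gene_private(self):
        s = pg.spectrum_model_a(math.inf, 500, 12)
        assert s.g[0] == 500 * 12 and np.all(s.g[1:] == 0)
        capped = pg.spectrum_model_a(1e7, 500, 12)  # above the internal cap
        assert np.array_equal(capped.g, s.g)

    def test_numerically_stable_for_large_samples(self):
        g = _model_a_vector(0.5, 2000.0, 1000)
        assert np.all(np.isfinite(g)) and np.all(g >= 0)
        assert np.sum(np.arange(1, 1001) * g) == pytest.approx(1000 * 2000, rel=1e-9)

    @pytest.mark.parametrize("theta", [-0.1, float("nan")])
    def test_invalid_theta_rejected(self, theta):
        with pytest.raises(ValueError):
            pg.spectrum_model_a(theta, 2000, 20)

    def test_invalid_sizes_rejected(self):
        with pytest.raises(ValueError):
            pg.spectrum_model_a(1.0, 2000, 0)
        with pytest.raises(ValueError):
            pg.spectrum_model_a(1.0, 0, 20)


class TestConservation:
    @pytest.mark.parametrize("theta", [0.01, 0.3, 1.0, 3.0, 30.0])
    @pytest.mark.parametrize("G", [2, 13, 26])
    @pytest.mark.parametrize("M", [100, 2095])
    def test_total_gene_mass_is_G_times_M(self, theta, G, M):
        s = pg.spectrum_model_a(theta, M, G)
        assert s.total_gene_mass() == pytest.approx(G * M, rel=1e-6)


class TestShapeProperties:
    @pytest.mark.parametrize("theta,G", [(0.3, 20), (0.3, 40), (0.1, 40)])
    def test_rare_gene_flank_scales_as_one_over_k(self, theta, G):
        # k*g_k drifts by less than 5% between adjacent bins on the flank
        s = pg.spectrum_model_a(theta, 2000, G)
        kg = s.k * s.g
        kmax = G // 4
        ratios = kg[1:kmax] / kg[: kmax - 1]
        assert np.all(np.abs(ratios - 1.0) < 0.05)

    def test_mass_shifts_from_core_to_rare_with_theta(self):
        thetas = np.logspace(-2, 1.5, 25)
        g1 = [pg.spectrum_model_a(t, 1000, 15).g[0] for t in thetas]
        gG = [pg.spectrum_model_a(t, 1000, 15).g[-1] for t in thetas]
        assert np.all(np.diff(g1) > 0)
        assert np.all(np.diff(gG) < 0)


class TestModelsCD:
    def test_fully_rigid_genome(self):
        s = pg.spectrum_model_c(pg.ModelCParams(5.0, 0.0), 2000, 20)
        assert s.g[-1] == 2000.0 and np.all(s.g[:-1] == 0)

    def test_no_rigid_core_equals_model_a(self):
        c = pg.spectrum_model_c(pg.ModelCParams(0.7, 1.0), 2000, 20)
        a = pg.spectrum_model_a(0.7, 2000, 20)
        np.testing.assert_allclose(c.g, a.g, rtol=1e-12)

    def test_model_c_hand_evaluation(self):
        s = pg.spectrum_model_c(pg.ModelCParams(1.0, 0.5), 2000, 2)
        assert s.g == pytest.approx([1000.0, 1500.0], rel=1e-12)

    @pytest.mark.parametrize("lam1", [0.0, 0.25, 1.0])
    def test_equal_rates_collapse_to_model_a(self, lam1):
        d = pg.spectrum_model_d(pg.ModelDParams(0.8, 0.8, lam1), 2000, 20)
        a = pg.spectrum_model_a(0.8, 2000, 20)
        np.testing.assert_allclose(d.g, a.g, rtol=1e-12)

    def test_zero_theta2_collapses_to_model_c(self):
        d = pg.spectrum_model_d(pg.ModelDParams(1.3, 0.0, 0.4), 2000, 20)
        c = pg.spectrum_model_c(pg.ModelCParams(1.3, 0.4), 2000, 20)
        np.testing.assert_allclose(d.g, c.g, rtol=1e-12)

    def test_small_theta2_limit_continuous(self):
        d = pg.spectrum_model_d(pg.ModelDParams(1.0, 1e-9, 0.5), 2000, 2)
        assert d.g == pytest.approx([1000.0, 1500.0], rel=1e-6)

    def test_invalid_lambda_rejected(self):
        with pytest.raises(ValueError):
            pg.ModelCParams(1.0, 1.2)
        with pytest.raises(ValueError):
            pg.ModelDParams(1.0, 0.5, -0.1)

    def test_theta2_above_theta1_rejected(self):
        with pytest.raises(ValueError):
            pg.ModelDParams(0.1, 1.0, 0.5)


class TestPanCoreCurves:
    def test_single_genome_pan_equals_core_equals_M(self):
        for params in (pg.ModelAParams(0.9), pg.ModelDParams(2.0, 0.1, 0.3)):
            pan, core = pg.pan_core_curves(params, 1234, 1)
            assert pan[0] == pytest.approx(1234) and core[0] == pytest.approx(1234)

    def test_two_genome_closed_form(self):
        pan, core = pg.pan_core_curves(pg.ModelAParams(0.5), 1000, 2)
        assert pan[1] == pytest.approx(1000 * (1 + 0.5 / 1.5), rel=1e-12)
        assert core[1] == pytest.approx(1000 / 1.5, rel=1e-12)
        # pan(2) + core(2) = 2M (union + intersection of a pair)
        assert pan[1] + core[1] == pytest.approx(2000, rel=1e-12)

    def test_core_matches_size_n_spectrum_tail(self):
        theta, M = 0.4, 800
        pan, core = pg.pan_core_curves(pg.ModelAParams(theta), M, 8)
        for n in (2, 5, 8):
            s = pg.spectrum_model_a(theta, M, n)
            assert core[n - 1] == pytest.approx(s.g[-1], rel=1e-10)
            assert pan[n - 1] == pytest.approx(s.g.sum(), rel=1e-10)

    def test_asymptotic_power_law_and_log_growth(self):
        theta, M = 0.3, 1000
        pan, core = pg.pan_core_curves(pg.ModelAParams(theta), M, 1000)
        n = np.arange(1, 1001)
        # core(n)*n^theta converges to M*Gamma(theta+1)
        tail = core[-1] * 1000**theta
        assert tail == pytest.approx(M * gamma_fn(theta + 1), rel=0.02)
        # local logarithmic slope of pan(n) converges to M*theta
        slope = (pan[999] - pan[499]) / math.log(1000 / 500)
        assert slope == pytest.approx(M * theta, rel=0.02)

    def test_model_d_curve_is_weighted_sum(self):
        params = pg.ModelDParams(2.0, 0.1, 0.25)
        pan, core = pg.pan_core_curves(params, 1000, 6)
        p1, c1 = pg.pan_core_curves(pg.ModelAParams(2.0), 250, 6)
        p2, c2 = pg.pan_core_curves(pg.ModelAParams(0.1), 750, 6)
        np.testing.assert_allclose(pan, p1 + p2, rtol=1e-12)
        np.testing.assert_allclose(core, c1 + c2, rtol=1e-12)


class TestPanCoreBand:
    def test_frozen_genome_limit_has_zero_spread(self):
        band = pg.pan_core_band_model_d(pg.ModelDParams(0.0, 0.0, 0.5),
                                        200, 5, n_reps=10, seed=1)
        assert np.all(band["core_mean"] == 200)
        assert np.all(band["pan_sd"] == 0) and np.all(band["core_sd"] == 0)

    def test_first_genome_has_deterministic_size(self):
        band = pg.pan_core_band_model_d(pg.ModelDParams(3.0, 0.2, 0.3),
                                        100, 6, n_reps=50, seed=2)
        assert band["pan_sd"][0] == 0 and band["core_sd"][0] == 0
        assert np.all(band["pan_sd"] >= 0) and np.all(band["core_sd"] >= 0)

    def test_monte_carlo_band_matches_closed_form_mean(self):
        params = pg.ModelDParams(10.0, 0.1, 0.1)
        M, G_max, n_reps = 500, 10, 2000
        band = pg.pan_core_band_model_d(params, M, G_max, n_reps=n_reps, seed=3)
        pan, core = pg.pan_core_curves(params, M, G_max)
        se_pan = np.maximum(band["pan_sd"] / math.sqrt(n_reps), 1e-9)
        se_core = np.maximum(band["core_sd"] / math.sqrt(n_reps), 1e-9)
        assert np.all(np.abs(band["pan_mean"] - pan) <= 3 * se_pan + 1e-9)
        assert np.all(np.abs(band["core_mean"] - core) <= 3 * se_core + 1e-9)
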