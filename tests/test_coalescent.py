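import math

import numpy as np
import pytest

import pangenesis as pg
from pangenesis.coalescent import _tree_expected_spectrum


class TestSimulateTree:
    def test_pair_coalescence_time_is_standard_exponential(self):
        rng = np.random.default_rng(1)
        times = [pg.simulate_tree(2, 0.0, rng).root_height for _ in range(10_000)]
        mean = np.mean(times)
        se = np.std(times, ddof=1) / math.sqrt(len(times))
        assert abs(mean - 1.0) <= 3 * se

    def test_expected_total_length_constant_size(self):
        # E[L] = 2 * sum_{i=1}^{G-1} 1/i for the constant-rate coalescent
        rng = np.random.default_rng(2)
        G = 10
        lengths = [pg.simulate_tree(G, 0.0, rng).total_branch_length()
                   for _ in range(10_000)]
        expected = 2 * sum(1.0 / i for i in range(1, G))
        se = np.std(lengths, ddof=1) / math.sqrt(len(lengths))
        assert abs(np.mean(lengths) - expected) <= 3 * se

    def test_growth_compresses_the_genealogy(self):
        rng = np.random.default_rng(3)
        h0 = np.mean([pg.simulate_tree(10, 0.0, rng).root_height
                      for _ in range(2000)])
        h100 = np.mean([pg.simulate_tree(10, 100.0, rng).root_height
                        for _ in range(2000)])
        assert h100 < h0

    def test_tree_is_valid_and_ultrametric_at_leaves(self):
        tree = pg.simulate_tree(8, 2.0, np.random.default_rng(4))
        assert tree.children.shape == (7, 2)
        assert np.all(tree.times[:8] == 0.0)
        assert tree.root_height == tree.times.max()

    def test_newick_export_round_trips_topology(self):
        import dendropy

        tree = pg.simulate_tree(6, 1.0, np.random.default_rng(5))
        parsed = dendropy.Tree.get(data=tree.to_newick(), schema="newick")
        assert len(parsed.leaf_nodes()) == 6

    def test_sample_size_validation(self):
        with pytest.raises(ValueError):
            pg.simulate_tree(1, 0.0, np.random.default_rng(0))


class TestSpectrumModelB:
    def test_no_transfer_gives_pure_core(self):
        for beta in (0.0, 5.0):
            s = pg.spectrum_model_b(pg.ModelBParams(0.0, beta), 300, 8,
                                    n_trees=50, rng=1)
            assert s.g[-1] == pytest.approx(300.0)
            assert np.all(s.g[:-1] == 0.0)

    @pytest.mark.parametrize("theta0,G", [(0.1, 10), (1.0, 10), (1.0, 20)])
    def test_constant_size_limit_reproduces_ewens_form(self, theta0, G):
        s = pg.spectrum_model_b(pg.ModelBParams(theta0, 0.0), 500, G,
                                n_trees=3000, rng=10)
        a = pg.spectrum_model_a(theta0, 500, G)
        assert np.all(np.abs(s.g - a.g) <= 3 * s.se + 1e-9)

    def test_per_tree_gene_mass_is_conserved_exactly(self):
        # each leaf carries M genes in expectation for every genealogy
        rng = np.random.default_rng(6)
        for beta in (0.0, 10.0):
            tree = pg.simulate_tree(12, beta, rng)
            g = _tree_expected_spectrum(tree, 0.7, 250.0)
            mass = np.sum(np.arange(1, 13) * g)
            assert mass == pytest.approx(12 * 250.0, rel=1e-9)

    def test_seeded_runs_are_bit_identical(self):
        a = pg.spectrum_model_b(pg.ModelBParams(0.3, 5.0), 100, 6,
                                n_trees=200, rng=42)
        b = pg.spectrum_model_b(pg.ModelBParams(0.3, 5.0), 100, 6,
                                n_trees=200, rng=42)
        assert np.array_equal(a.g, b.g) and np.array_equal(a.se, b.se)

    def test_growth_symmetrizes_the_interior(self):
        # excluding the core bin, skewness of the occupancy distribution
        # shrinks as beta grows
        def interior_skew(beta):
            s = pg.spectrum_model_b(pg.ModelBParams(0.3, beta), 2000, 20,
                                    n_trees=1500, rng=7)
            w = s.g[:-1] / s.g[:-1].sum()
            k = np.arange(1, 20)
            mu = np.sum(w * k)
            var = np.sum(w * (k - mu) ** 2)
            return np.sum(w * (k - mu) ** 3) / var**1.5

        assert abs(interior_skew(100.0)) < abs(interior_skew(1.0))

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            pg.ModelBParams(-0.1, 1.0)
        with pytest.raises(ValueError):
            pg.ModelBParams(0.1, -1.0)
        with pytest.raises(ValueError):
            pg.spectrum_model_b(pg.ModelBParams(0.1, 1.0), 100, 6, n_trees=0)


class TestRareGeneExponent:
    def test_exact_power_laws_recovered(self):
        k = np.arange(1, 21, dtype=float)
        one = pg.GeneFrequencySpectrum(100.0 / k, M=50)
        two = pg.GeneFrequencySpectrum(100.0 / k**2, M=50)
        assert pg.estimate_rare_gene_exponent(one, 8) == pytest.approx(1.0)
        assert pg.estimate_rare_gene_exponent(two, 8) == pytest.approx(2.0)

    def test_constant_size_model_has_near_unit_exponent(self):
        # finite-G curvature pulls gamma slightly below 1; it converges to 1
        # as the sample grows
        gammas = [pg.estimate_rare_gene_exponent(
            pg.spectrum_model_a(0.1, 2000, G), 5) for G in (20, 100, 400)]
        assert 0.8 <= gammas[0] <= 1.1
        assert abs(gammas[2] - 1.0) < abs(gammas[0] - 1.0)
        assert gammas[2] == pytest.approx(1.0, abs=0.02)

    def test_zero_counts_demand_truncation(self):
        s = pg.GeneFrequencySpectrum([5.0, 2.0, 0.0, 0.0, 9.0], M=3)
        with pytest.raises(ValueError, match="truncate"):
            pg.estimate_rare_gene_exponent(s, 4)

    def test_k_max_validation(self):
        s = pg.spectrum_model_a(0.3, 100, 10)
        with pytest.raises(ValueError):
            pg.estimate_rare_gene_exponent(s, 2)
        with pytest.raises(ValueError):
            pg.estimate_rare_gene_exponent(s, 11)
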