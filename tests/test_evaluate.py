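"""Comparison and benchmark-scoring statistics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from copulasim import (DETruth, circular_correlation, corr_qq,
                       fdr_calibration, make_phases, mean_var_table,
                       pc_spectrum, project_onto)
from conftest import toy_counts


class TestCircularCorrelation:
    def test_identity_and_reflection(self):
        x = make_phases(12)
        assert circular_correlation(x, x) == pytest.approx(1.0)
        assert circular_correlation(x, -x) == pytest.approx(-1.0)

    def test_matches_brute_force_double_loop(self, rng):
        x = rng.uniform(0, 2 * np.pi, 6)
        y = rng.uniform(0, 2 * np.pi, 6)
        num = dx = dy = 0.0
        for i in range(6):
            for j in range(i + 1, 6):
                num += np.sin(x[i] - x[j]) * np.sin(y[i] - y[j])
                dx += np.sin(x[i] - x[j]) ** 2
                dy += np.sin(y[i] - y[j]) ** 2
        expected = num / np.sqrt(dx) / np.sqrt(dy)
        assert circular_correlation(x, y) == pytest.approx(expected,
                                                           abs=1e-12)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(shift=st.floats(-10, 10))
    def test_shift_invariance(self, shift):
        x = make_phases(8, seed=1, mode="random")
        y = make_phases(8, seed=2, mode="random")
        base = circular_correlation(x, y)
        assert circular_correlation(x + shift, y) == pytest.approx(base,
                                                                   abs=1e-9)

    def test_constant_phases_rejected(self):
        x = make_phases(5, seed=0, mode="random")
        with pytest.raises(ValueError, match="undefined"):
            circular_correlation(x, np.zeros(5))


def correlated_pair(rng, p=40, n=60, rho_strength=2.0):
    """Real matrix with one strong latent factor plus an independent sim."""
    factor = rng.standard_normal(n)
    load = rng.standard_normal(p)
    real = 500 + 40 * (rho_strength * np.outer(load, factor)
                       + rng.standard_normal((p, n)))
    indep = 500 + 40 * np.sqrt(1 + rho_strength ** 2 * load[:, None] ** 2) \
        * rng.standard_normal((p, n))
    return toy_counts(np.clip(real, 0, None)), toy_counts(np.clip(indep, 0, None))


class TestCorrQQ:
    def test_identical_inputs_on_diagonal(self, rng):
        real, _ = correlated_pair(rng)
        rq, sq = corr_qq(real, real, min_mean=0.0)
        assert np.allclose(rq, sq)

    def test_independent_sim_compressed_toward_zero(self, rng):
        real, indep = correlated_pair(rng)
        rq, sq = corr_qq(real, indep, min_mean=0.0)
        assert np.quantile(np.abs(sq), 0.9) < np.quantile(np.abs(rq), 0.9)

    def test_min_mean_filter_errors_when_empty(self, rng):
        real, sim = correlated_pair(rng)
        with pytest.raises(ValueError, match="fewer than 2"):
            corr_qq(real, sim, min_mean=1e9)


class TestPcSpectrum:
    def test_identical_columns_no_variance(self):
        c = toy_counts(np.tile([[3.0], [5.0], [9.0]], (1, 4)))
        assert np.allclose(pc_spectrum(c, 2), 0.0)

    def test_rank_one_data(self, rng):
        c = toy_counts(np.outer(rng.uniform(1, 5, 6), rng.uniform(1, 5, 5)))
        spec = pc_spectrum(c, 3)
        assert spec[0] > 1e-6 and np.allclose(spec[1:], 0.0, atol=1e-12)

    def test_matches_dense_eigendecomposition(self, rng):
        c = toy_counts(rng.uniform(0, 100, (7, 6)))
        Xc = c.values - c.values.mean(1, keepdims=True)
        evals = np.sort(np.linalg.eigvalsh(Xc @ Xc.T / 5))[::-1]
        assert np.allclose(pc_spectrum(c, 4), evals[:4], atol=1e-9)

    def test_non_increasing(self, rng):
        c = toy_counts(rng.uniform(0, 10, (10, 8)))
        assert np.all(np.diff(pc_spectrum(c, 6)) <= 1e-12)


class TestProjectOnto:
    def test_reference_projects_to_own_pc_variances(self, rng):
        real, _ = correlated_pair(rng)
        coords = project_onto(real, [])
        own = coords[0].var(axis=1, ddof=1)
        assert np.allclose(own, pc_spectrum(real, 2), atol=1e-8)

    def test_gene_order_irrelevant(self, rng):
        real, sim = correlated_pair(rng)
        shuffled = sim.reindex_genes(np.random.default_rng(0).permutation(sim.gene_ids))
        a = project_onto(real, [sim])[1]
        b = project_onto(real, [shuffled])[1]
        assert np.allclose(a, b)

    def test_gene_mismatch_rejected(self, rng):
        real, sim = correlated_pair(rng)
        other = toy_counts(sim.values, gene_ids=[f"x{i}" for i in range(sim.p)])
        with pytest.raises(ValueError, match="gene set"):
            project_onto(real, [other])

    def test_independent_sim_deflated_on_pc1(self, rng):
        real, indep = correlated_pair(rng)
        coords = project_onto(real, [indep])
        assert coords[1][0].var(ddof=1) < 0.3 * coords[0][0].var(ddof=1)


class TestFdrCalibration:
    def make_truth(self, flags):
        flags = np.asarray(flags, bool)
        return DETruth(np.array([f"g{i}" for i in range(len(flags))]), flags,
                       flags.astype(float))

    def test_all_calls_correct(self):
        truth = self.make_truth([1, 1, 0, 0])
        q = np.array([0.001, 0.002, 0.9, 0.8])
        fdp = fdr_calibration(q, truth, [0.01, 0.05, 0.1])
        assert all(v == 0.0 for v in fdp.values())

    def test_hand_counted_toy(self):
        # 10 genes; 5 significant at 0.1, of which 2 are truly null -> 0.4
        truth = self.make_truth([1, 1, 1, 0, 0, 1, 0, 0, 1, 0])
        q = np.array([0.01, 0.02, 0.05, 0.06, 0.08, 0.5, 0.6, 0.7, 0.8, 0.9])
        fdp = fdr_calibration(q, truth, [0.1])
        assert fdp[0.1] == pytest.approx(0.4)

    def test_no_discoveries_is_absent_not_zero(self):
        truth = self.make_truth([1, 0])
        fdp = fdr_calibration(np.array([0.5, np.nan]), truth, [0.01])
        assert fdp[0.01] is None

    def test_invalid_qvalues_rejected(self):
        truth = self.make_truth([1, 0])
        with pytest.raises(ValueError, match="0, 1"):
            fdr_calibration(np.array([1.5, 0.2]), truth, [0.1])


class TestMeanVarTable:
    def test_identity_pairing(self, rng):
        real, _ = correlated_pair(rng)
        tbl = mean_var_table(real, real)
        assert np.allclose(tbl.real_mean, tbl.sim_mean)
        assert np.allclose(tbl.real_var, tbl.sim_var)

    def test_doubling_counts_doubles_mean(self, rng):
        real, sim = correlated_pair(rng)
        doubled = toy_counts(2 * sim.values, gene_ids=sim.gene_ids)
        tbl = mean_var_table(real, doubled)
        tbl0 = mean_var_table(real, sim)
        assert np.allclose(tbl.sim_mean, 2 * tbl0.sim_mean)

    def test_moments_match_two_pass_oracle(self, rng):
        real, sim = correlated_pair(rng)
        tbl = mean_var_table(real, sim)
        for i in (0, 3):
            x = real.values[i]
            mean = x.sum() / len(x)
            var = ((x - mean) ** 2).sum() / (len(x) - 1)
            assert tbl.real_mean[i] == pytest.approx(mean, abs=1e-10)
            assert tbl.real_var[i] == pytest.approx(var, abs=1e-10)
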