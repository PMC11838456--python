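"""Sample generation, DE injection and time-series simulation."""

import tracemalloc

import numpy as np
import pytest

from copulasim import (CopulaModel, FactorizedCovariance, MarginalModel,
                       ReferenceModel, make_reference)


def shifted_normal_model(p, fc):
    """ReferenceModel with N(100,1) marginals: simulated values are Z' + 100,
    so their covariance equals cov(Z') while staying non-negative."""
    ids = np.array([f"g{i}" for i in range(p)])
    marg = MarginalModel("normal", ids, np.zeros(p, bool), np.zeros(p),
                         mu=np.full(p, 100.0), sd=np.ones(p))
    return ReferenceModel(marg, fc, None, ids)


class TestSimulate:
    def test_independent_model_gives_uncorrelated_genes(self):
        p = 30
        fc = FactorizedCovariance(np.ones(p), np.zeros((p, 0)), np.zeros(0))
        model = shifted_normal_model(p, fc)
        sim = model.simulate(5000, seed=0)
        corr = np.corrcoef(sim.values)
        off = corr[np.triu_indices(p, 1)]
        assert np.mean(np.abs(off)) < 0.03

    def test_latent_covariance_reproduced(self):
        # Monte-Carlo sample covariance of Z' vs dense Sigma, entrywise
        rng = np.random.default_rng(0)
        p, k = 8, 2
        U = np.linalg.qr(rng.standard_normal((p, k)))[0]
        W = np.array([2.0, 1.2])
        D = np.full(p, 0.8)
        fc = FactorizedCovariance(D, U, W)
        model = shifted_normal_model(p, fc)
        N = 20000
        sim = model.simulate(N, seed=1)
        S = np.cov(sim.values)
        sigma = fc.dense()
        se = np.sqrt((np.outer(np.diag(sigma), np.diag(sigma))
                      + sigma ** 2) / N)
        assert np.all(np.abs(S - sigma) < 3.5 * se)

    def test_seed_reproducibility(self, normal_reference):
        counts, _ = normal_reference
        model = CopulaModel(counts, "normal").fit(method="pca", seed=3)
        a = model.simulate(6, seed=11)
        b = model.simulate(6, seed=11)
        assert np.array_equal(a.values, b.values)
        assert not np.array_equal(a.values, model.simulate(6, seed=12).values)

    def test_degenerate_genes_emitted_constant(self):
        counts, _ = make_reference(p=30, n=10, k_true=1, family="poisson",
                                   seed=2)
        counts.values[4] = 9.0
        model = CopulaModel(counts, "poisson").fit(method="pca", seed=0)
        sim = model.simulate(25, seed=5)
        assert np.all(sim.values[4] == 9.0)

    def test_missing_covariance_rejected(self):
        model = shifted_normal_model(4, None)
        with pytest.raises(ValueError, match="covariance"):
            model.simulate(3, seed=0)

    def test_no_quadratic_memory_at_large_p(self):
        # 40,000 genes: generation must stay O(p (k+1)), far below any
        # p x p allocation (which would need ~12.8 GB)
        counts, _ = make_reference(p=40000, n=12, k_true=2, family="negbinom",
                                   seed=0)
        tracemalloc.start()
        model = CopulaModel(counts, "negbinom").fit(method="pca", seed=0)
        sim = model.simulate(2, seed=1)
        _, peak = tracemalloc.get_traced_memory()
        tracemalloc.stop()
        assert sim.values.shape == (40000, 2)
        assert peak < 500 * 1024 ** 2


@pytest.fixture(scope="module")
def de_model():
    counts, _ = make_reference(p=400, n=12, k_true=2, family="negbinom",
                               seed=4)
    return CopulaModel(counts, "negbinom").fit(method="pca", seed=0)


class TestInjectDe:
    def test_exact_fraction_flagged(self, de_model):
        perturbed, truth = de_model.inject_de(0.05, seed=0)
        assert truth.is_de.sum() == int(np.ceil(0.05 * 400))
        assert np.all(truth.log2fc[~truth.is_de] == 0)
        flagged = np.abs(truth.log2fc[truth.is_de])
        assert np.all((flagged >= 0.2) & (flagged <= 2.0))

    def test_unit_lfc_doubles_means(self, de_model):
        perturbed, truth = de_model.inject_de(0.1, lfc_lo=1.0, lfc_hi=1.0,
                                            seed=1)
        ratio = perturbed.marginals.mu / de_model.marginals.mu
        up = truth.log2fc > 0
        down = truth.log2fc < 0
        assert np.allclose(ratio[up], 2.0)
        assert np.allclose(ratio[down], 0.5)
        assert np.allclose(ratio[~truth.is_de], 1.0)

    def test_zero_fraction_is_identity(self, de_model):
        perturbed, truth = de_model.inject_de(0.0, seed=2)
        assert not truth.is_de.any()
        assert np.array_equal(perturbed.marginals.mu, de_model.marginals.mu)

    def test_covariance_untouched(self, de_model):
        perturbed, _ = de_model.inject_de(0.2, seed=3)
        assert np.array_equal(perturbed.covariance.D, de_model.covariance.D)
        assert np.array_equal(perturbed.covariance.U, de_model.covariance.U)

    def test_empirical_marginals_rejected(self):
        counts, _ = make_reference(p=50, n=8, k_true=1, family="normal",
                                   seed=5)
        model = CopulaModel(counts, "empirical").fit(method="pca", seed=0)
        with pytest.raises(ValueError, match="empirical"):
            model.inject_de(0.05, seed=0)


@pytest.fixture(scope="module")
def ts_model():
    counts, _ = make_reference(p=80, n=12, k_true=1, family="poisson",
                               seed=6)
    return CopulaModel(counts, "poisson").fit(method="pca", seed=0)


class TestTimeseries:
    def test_constant_profile_keeps_reference_means(self, ts_model):
        prof = np.tile(ts_model.marginals.mu[:, None], (1, 3))
        sim, times = ts_model.simulate_timeseries(prof, 300, seed=0)
        for t in range(3):
            block = sim.values[:, times == t]
            big = ts_model.marginals.mu > 5
            rel = block.mean(1)[big] / ts_model.marginals.mu[big]
            assert np.all(np.abs(rel - 1) < 0.15)

    def test_sinusoidal_gene_tracks_profile(self, ts_model):
        T = 12
        prof = np.tile(ts_model.marginals.mu[:, None], (1, T))
        base = 50.0
        phases = 2 * np.pi * np.arange(T) / T
        prof[0] = base * (1 + 0.5 * np.sin(phases))
        sim, times = ts_model.simulate_timeseries(prof, 200, seed=1)
        means = np.array([sim.values[0, times == t].mean() for t in range(T)])
        assert np.corrcoef(means, prof[0])[0, 1] > 0.98

    def test_truth_labels_and_shapes(self, ts_model):
        prof = np.tile(ts_model.marginals.mu[:, None], (1, 4))
        sim, times = ts_model.simulate_timeseries(prof, 5, seed=2,
                                                times=[0.0, 3.0, 6.0, 9.0])
        assert sim.values.shape == (80, 20)
        assert np.array_equal(np.unique(times), [0.0, 3.0, 6.0, 9.0])

    def test_negative_means_rejected(self, ts_model):
        prof = np.tile(ts_model.marginals.mu[:, None], (1, 2))
        prof[0, 0] = -1.0
        with pytest.raises(ValueError, match="non-negative"):
            ts_model.simulate_timeseries(prof, 3, seed=0)
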