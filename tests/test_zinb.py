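"""ZINB probability machinery: normalization, limits, sampler consistency."""

import numpy as np
import pytest
from scipy import stats

from snow.autodiff import Tensor
from snow.networks import ModelConfig, SnowModel
from snow.zinb import (
    ZINBParams,
    cell_log_likelihood,
    nb_log_pmf,
    sample_cell,
    sample_counts,
    zinb_log_pmf,
    zinb_log_pmf_t,
)


class TestNB:
    def test_zero_count_closed_form(self):
        # (theta/(theta+mu))^theta with mu=theta=1 is 1/2
        np.testing.assert_allclose(nb_log_pmf(0, 1.0, 1.0), np.log(0.5), rtol=1e-12)

    @pytest.mark.parametrize("mean,theta", [(3.0, 2.0), (0.5, 0.1), (10.0, 5.0)])
    def test_pmf_sums_to_one(self, mean, theta):
        y = np.arange(0, 3000)
        total = np.exp(nb_log_pmf(y, mean, theta)).sum()
        assert abs(total - 1.0) < 1e-8

    def test_poisson_limit(self):
        y = np.arange(0, 11)
        nb = np.exp(nb_log_pmf(y, 2.0, 1e6))
        pois = stats.poisson.pmf(y, 2.0)
        np.testing.assert_allclose(nb, pois, atol=1e-4)

    def test_matches_scipy_nbinom(self):
        # independent parameterization check: nbinom(n=theta, p=theta/(theta+mu))
        y = np.arange(0, 30)
        mean, theta = 4.2, 1.3
        ours = np.exp(nb_log_pmf(y, mean, theta))
        ref = stats.nbinom.pmf(y, theta, theta / (theta + mean))
        np.testing.assert_allclose(ours, ref, rtol=1e-10)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            nb_log_pmf(1, -1.0, 1.0)
        with pytest.raises(ValueError):
            nb_log_pmf(1, 1.0, 0.0)


class TestZINB:
    def test_h_one_reduces_to_nb(self):
        y = np.arange(0, 20)
        np.testing.assert_allclose(
            zinb_log_pmf(y, 3.0, 2.0, 1.0), nb_log_pmf(y, 3.0, 2.0), rtol=1e-12
        )

    def test_full_dropout_limit(self):
        h = 1e-12
        assert np.exp(zinb_log_pmf(0, 3.0, 2.0, h)) == pytest.approx(1.0, abs=1e-9)
        assert np.exp(zinb_log_pmf(5, 3.0, 2.0, h)) == pytest.approx(0.0, abs=1e-9)

    def test_pmf_sums_to_one(self):
        y = np.arange(0, 5000)
        total = np.exp(zinb_log_pmf(y, 5.0 * 0.5, 0.5, 0.7)).sum()
        assert abs(total - 1.0) < 1e-8

    def test_tensor_path_matches_numpy(self, rng):
        y = rng.poisson(3.0, (5, 4)).astype(float)
        mu = rng.uniform(0.5, 5.0, (5, 4))
        th = rng.uniform(0.2, 3.0, (5, 4))
        h = rng.uniform(0.05, 0.95, (5, 4))
        got = zinb_log_pmf_t(y, Tensor(mu), Tensor(th), Tensor(h)).data
        np.testing.assert_allclose(got, zinb_log_pmf(y, mu, th, h), rtol=1e-12)


class TestZINBParams:
    def test_rho_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            ZINBParams(rho=[[0.5, 0.4]], theta=[[1.0, 1.0]], h=[[0.5, 0.5]])

    def test_valid_params_accepted(self):
        p = ZINBParams(rho=[[0.25, 0.75]], theta=[[1.0, 2.0]], h=[[0.01, 0.99]])
        assert p.rho.shape == (1, 2)


class TestCellLogLikelihood:
    def make_params(self, rng, G=5):
        rho = rng.dirichlet(np.ones(G))[None, :]
        theta = rng.uniform(0.5, 2.0, (1, G))
        h = rng.uniform(0.1, 0.9, (1, G))
        return ZINBParams(rho=rho, theta=theta, h=h)

    def test_single_gene_reduces_to_pmf(self):
        p = ZINBParams(rho=[[1.0]], theta=[[2.0]], h=[[0.8]])
        total, per_gene = cell_log_likelihood([3], p, l_c=10)
        np.testing.assert_allclose(total, zinb_log_pmf(3, 10.0, 2.0, 0.8))
        assert per_gene.shape == (1,)

    def test_gene_permutation_invariance(self, rng):
        p = self.make_params(rng)
        x = rng.poisson(3.0, 5)
        perm = rng.permutation(5)
        t1, _ = cell_log_likelihood(x, p, 20)
        t2, _ = cell_log_likelihood(
            x[perm],
            ZINBParams(p.rho[:, perm], p.theta[:, perm], p.h[:, perm]),
            20,
        )
        assert t1 == pytest.approx(t2, rel=1e-12)

    def test_matches_per_gene_loop(self, rng):
        p = self.make_params(rng)
        x = rng.poisson(3.0, 5)
        total, per_gene = cell_log_likelihood(x, p, 20)
        loop = sum(
            float(zinb_log_pmf(x[g], p.rho[0, g] * 20, p.theta[0, g], p.h[0, g]))
            for g in range(5)
        )
        assert total == pytest.approx(loop, rel=1e-12)
        assert total == pytest.approx(per_gene.sum(), rel=1e-12)


class TestSampler:
    def test_mean_and_zero_prob_match_analytic(self, rng):
        rho, theta, h, l = 0.4, 1.5, 0.8, 10.0
        n = 100_000
        y = sample_counts(
            np.full(n, rho), np.full(n, theta), np.full(n, h), np.ones(n) * l, rng
        )
        mu = rho * l
        var = h * (mu + mu**2 / theta) + h * (1 - h) * mu**2
        se_mean = 3 * np.sqrt(var / n)
        assert abs(y.mean() - h * mu) < se_mean
        p0 = np.exp(zinb_log_pmf(0, mu, theta, h))
        se_p0 = 3 * np.sqrt(p0 * (1 - p0) / n)
        assert abs((y == 0).mean() - p0) < se_p0

    def test_nb_variance(self, rng):
        rho, theta, l = 0.6, 2.0, 10.0
        n = 200_000
        y = sample_counts(
            np.full(n, rho), np.full(n, theta), np.ones(n), np.ones(n) * l, rng
        )
        mu = rho * l
        expected_var = mu + mu**2 / theta
        assert y.var() == pytest.approx(expected_var, rel=0.05)

    def test_histogram_matches_pmf_chi2(self, rng):
        """Sampler/likelihood consistency via a chi-squared GOF test."""
        rho, theta, h, l = 0.3, 0.8, 0.7, 10.0
        n = 100_000
        y = sample_counts(
            np.full(n, rho), np.full(n, theta), np.full(n, h), np.ones(n) * l, rng
        )
        kmax = 30
        probs = np.exp(zinb_log_pmf(np.arange(kmax), rho * l, theta, h))
        probs = np.append(probs, 1.0 - probs.sum())  # tail bin
        obs = np.bincount(np.minimum(y, kmax), minlength=kmax + 1)
        keep = probs * n >= 5
        chi2 = ((obs[keep] - n * probs[keep]) ** 2 / (n * probs[keep])).sum()
        p = stats.chi2.sf(chi2, keep.sum() - 1)
        assert p > 0.01

    def test_model_path_respects_h_clamp(self, rng):
        model = SnowModel(ModelConfig(n_genes=8, hidden_width=16, latent_dim=3), rng=0)
        y = sample_cell(rng.standard_normal(3), 0.5, 100.0, model, rng)
        assert y.shape == (8,)
        assert np.all(y >= 0)
        h = model.decode_h(rng.standard_normal((10, 3)), 0.5)
        assert h.min() >= 0.01 and h.max() <= 0.99

    def test_nonpositive_library_rejected(self, rng):
        model = SnowModel(ModelConfig(n_genes=4, hidden_width=8, latent_dim=2), rng=0)
        with pytest.raises(ValueError):
            sample_cell(np.zeros(2), 0.5, 0.0, model, rng)
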