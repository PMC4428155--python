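"""Sampler correctness: conjugate updates against brute-force posteriors on
tiny instances, parameterization equivalences, shrinkage behaviour, chain
health and determinism."""

import numpy as np
import pytest

from wgrbench.heritability import estimate_h2
from wgrbench.ld_kinship import GRM, compute_grm
from wgrbench.wgr_models import (
    BayesAPrior,
    GBLUPPrior,
    MCMCConfig,
    SpikeSlabPrior,
    effective_sample_size,
    fit_bayes_a,
    fit_gblup,
    fit_spike_slab,
    predict,
)

INF = float("inf")


def _tiny_instance(seed=0, n=5, p=2):
    rng = np.random.default_rng(seed)
    X = rng.integers(0, 3, (n, p)).astype(float)
    while (X.std(axis=0) == 0).any():
        X = rng.integers(0, 3, (n, p)).astype(float)
    beta = np.array([0.8, -0.5])[:p]
    y = X @ beta + rng.normal(0, 0.5, n)
    return X, y


def _profile_loglik(y, Xc, b, sigma_e2):
    """Log-likelihood with the intercept integrated out under a flat prior
    (projection removes the grand mean)."""
    r = y - Xc @ b
    r = r - r.mean()
    return -0.5 * (r @ r) / sigma_e2


def _grid_posterior_mean(y, Xc, log_prior, sigma_e2, lim=3.0, m=161):
    """2-D quadrature posterior mean of beta for an arbitrary prior."""
    grid = np.linspace(-lim, lim, m)
    B1, B2 = np.meshgrid(grid, grid, indexing="ij")
    logp = np.empty_like(B1)
    for i in range(m):
        for j in range(m):
            b = np.array([B1[i, j], B2[i, j]])
            logp[i, j] = _profile_loglik(y, Xc, b, sigma_e2) + log_prior(b)
    w = np.exp(logp - logp.max())
    w /= w.sum()
    return np.array([(w * B1).sum(), (w * B2).sum()])


class TestGBLUP:
    def test_fixed_variance_matches_ridge_oracle(self):
        # degenerate priors (df = inf) pin the variances; posterior mean of u
        # must match closed-form BLUP G(G + lambda I)^{-1}(y - ybar)
        rng = np.random.default_rng(3)
        X = rng.integers(0, 3, (40, 30)).astype(float)
        y = rng.normal(0, 1, 40) + X[:, 0] * 0.3
        grm = compute_grm(X)
        su2, se2 = 0.6, 0.5
        prior = GBLUPPrior(df_u=INF, scale_u=su2, df_e=INF, scale_e=se2)
        mcmc = MCMCConfig(n_iter=42_000, burn_in=2_000, thin=4, seed=1)
        samples = fit_gblup(y, grm, prior, mcmc)
        lam = se2 / su2
        oracle = grm.values @ np.linalg.solve(
            grm.values + lam * np.eye(40), y - y.mean()
        )
        assert np.abs(samples.u_mean - oracle).max() < 0.07
        assert np.corrcoef(samples.u_mean, oracle)[0, 1] > 0.999

    def test_marker_form_matches_ridge_oracle(self):
        rng = np.random.default_rng(4)
        X = rng.integers(0, 3, (30, 8)).astype(float)
        y = rng.normal(0, 1, 30)
        sb2, se2 = 0.1, 0.5
        prior = GBLUPPrior(df_u=INF, scale_u=sb2 * 1.0, df_e=INF, scale_e=se2)
        # scale_u is interpreted on the genomic-variance scale; convert
        Xc = X - X.mean(axis=0)
        denom = (2 * (X.mean(0) / 2) * (1 - X.mean(0) / 2)).sum()
        prior = GBLUPPrior(df_u=INF, scale_u=sb2 * denom, df_e=INF, scale_e=se2)
        mcmc = MCMCConfig(n_iter=42_000, burn_in=2_000, thin=4, seed=2)
        samples = fit_gblup(y, X, prior, mcmc)
        lam = se2 / sb2
        oracle = np.linalg.solve(Xc.T @ Xc + lam * np.eye(8), Xc.T @ (y - y.mean()))
        np.testing.assert_allclose(samples.beta_mean, oracle, atol=0.05)

    def test_null_phenotype_low_h2(self):
        rng = np.random.default_rng(5)
        X = rng.integers(0, 3, (500, 200)).astype(float)
        y = rng.normal(0, 1, 500)
        samples = fit_gblup(y, compute_grm(X),
                            mcmc=MCMCConfig(6_000, 1_000, 5, seed=3))
        assert estimate_h2(samples).posterior_mean < 0.15

    def test_marker_and_grm_forms_agree(self):
        rng = np.random.default_rng(6)
        X = rng.integers(0, 3, (400, 300)).astype(float)
        beta = np.zeros(300)
        beta[:30] = rng.normal(0, 0.15, 30)
        y = X @ beta + rng.normal(0, 0.7, 400)
        mcmc = MCMCConfig(8_000, 2_000, 3, seed=4)
        s_marker = fit_gblup(y, X, mcmc=mcmc)
        s_grm = fit_gblup(y, compute_grm(X), mcmc=MCMCConfig(8_000, 2_000, 3, seed=5))
        scale = np.std(s_grm.u_mean)
        assert np.corrcoef(s_marker.linpred_mean, s_grm.linpred_mean)[0, 1] > 0.99
        assert np.sqrt(np.mean((s_marker.linpred_mean - s_grm.linpred_mean) ** 2)) < 0.2 * scale
        h_m = estimate_h2(s_marker).posterior_mean
        h_g = estimate_h2(s_grm).posterior_mean
        assert h_m == pytest.approx(h_g, abs=0.05)

    def test_non_psd_grm_rejected(self):
        values = np.array([[1.0, 2.0, 0.0], [2.0, 1.0, 0.0], [0.0, 0.0, 1.0]])
        bad = GRM(values=values, denominator=1.0,
                  individual_ids=np.array(["a", "b", "c"]),
                  source_loci=np.arange(1))
        with pytest.raises(ValueError, match="positive semidefinite"):
            fit_gblup(np.array([0.1, -0.2, 0.0]), bad,
                      mcmc=MCMCConfig(100, 50, 1, seed=0))

    def test_too_few_records_rejected(self):
        with pytest.raises(ValueError):
            fit_gblup(np.array([1.0, 2.0]), np.zeros((2, 2)))


class TestBruteForcePosteriors:
    """Gibbs posterior means vs quadrature on a 5-individual, 2-marker
    instance, run for each of the three effect priors (residual variance
    pinned so the oracle is a clean 2-D integral)."""

    se2 = 0.3

    def _gibbs_vs_grid(self, fit_fn, log_prior, seed=11):
        X, y = _tiny_instance(seed=seed)
        Xc = X - X.mean(axis=0)
        oracle = _grid_posterior_mean(y, Xc, log_prior, self.se2)
        samples = fit_fn(y, X)
        np.testing.assert_allclose(samples.beta_mean, oracle, atol=0.04)

    def test_gblup_conjugate_updates(self):
        sb2 = 0.25

        def log_prior(b):
            return -0.5 * (b @ b) / sb2

        def fit(y, X):
            denom = (2 * (X.mean(0) / 2) * (1 - X.mean(0) / 2)).sum()
            prior = GBLUPPrior(df_u=INF, scale_u=sb2 * denom,
                               df_e=INF, scale_e=self.se2)
            return fit_gblup(y, X, prior, MCMCConfig(60_000, 4_000, 4, seed=21))

        self._gibbs_vs_grid(fit, log_prior)

    def test_bayes_a_conjugate_updates(self):
        df, S0 = 5.0, 0.2
        from scipy import stats

        def log_prior(b):
            # augmentation beta | s2 ~ N(0, s2) with s2 ~ InvChi2(df, sum S0)
            # marginalizes to a t with df dof and scale sqrt(S0/df)
            return stats.t.logpdf(b, df, scale=np.sqrt(S0 / df)).sum()

        def fit(y, X):
            prior = BayesAPrior(df=df, S0=S0, s0_shape=None,
                                df_e=INF, scale_e=self.se2)
            return fit_bayes_a(y, X, prior, MCMCConfig(60_000, 4_000, 4, seed=22))

        self._gibbs_vs_grid(fit, log_prior)

    def test_spike_slab_two_normal_updates(self):
        pi, s_slab, s_spike = 0.4, 0.5, 0.005

        def log_prior(b):
            comp = pi * np.exp(-0.5 * b**2 / s_slab) / np.sqrt(s_slab) + (
                1 - pi
            ) * np.exp(-0.5 * b**2 / s_spike) / np.sqrt(s_spike)
            return np.log(comp).sum()

        def fit(y, X):
            prior = SpikeSlabPrior(
                variant="george_mcculloch", pi_fixed=pi,
                df_gamma=INF, scale_gamma=s_slab,
                df_alpha=INF, scale_alpha=s_spike,
                df_e=INF, scale_e=self.se2,
            )
            return fit_spike_slab(y, X, prior, MCMCConfig(60_000, 4_000, 4, seed=23))

        self._gibbs_vs_grid(fit, log_prior)

    def test_point_mass_updates_vs_config_enumeration(self):
        # point-mass mixture: enumerate the 4 inclusion configurations and
        # integrate each continuous part on a grid
        pi, s_slab = 0.4, 0.5
        X, y = _tiny_instance(seed=11)
        Xc = X - X.mean(axis=0)
        grid = np.linspace(-3, 3, 801)
        dg = grid[1] - grid[0]

        def gauss(b):
            return np.exp(-0.5 * b**2 / s_slab) / np.sqrt(2 * np.pi * s_slab)

        weights, means = [], []
        for cfg in [(0, 0), (1, 0), (0, 1), (1, 1)]:
            prior_w = pi ** sum(cfg) * (1 - pi) ** (2 - sum(cfg))
            if cfg == (0, 0):
                w = prior_w * np.exp(_profile_loglik(y, Xc, np.zeros(2), self.se2))
                m = np.zeros(2)
            elif cfg == (1, 1):
                B1, B2 = np.meshgrid(grid, grid, indexing="ij")
                logp = np.array(
                    [
                        [
                            _profile_loglik(y, Xc, np.array([b1, b2]), self.se2)
                            for b2 in grid
                        ]
                        for b1 in grid[:: 4]
                    ]
                )
                # coarser in b1 for speed
                g1 = grid[::4]
                pw = np.exp(logp) * gauss(g1)[:, None] * gauss(grid)[None, :]
                w = prior_w * pw.sum() * (g1[1] - g1[0]) * dg
                m = np.array(
                    [
                        (pw * g1[:, None]).sum() / pw.sum(),
                        (pw * grid[None, :]).sum() / pw.sum(),
                    ]
                )
            else:
                k = 0 if cfg == (1, 0) else 1
                ll = np.array(
                    [
                        _profile_loglik(
                            y, Xc, np.array([b, 0.0]) if k == 0 else np.array([0.0, b]),
                            self.se2,
                        )
                        for b in grid
                    ]
                )
                pw = np.exp(ll) * gauss(grid)
                w = prior_w * pw.sum() * dg
                m = np.zeros(2)
                m[k] = (pw * grid).sum() / pw.sum()
            weights.append(w)
            means.append(m)
        weights = np.array(weights)
        oracle = (weights[:, None] * np.array(means)).sum(0) / weights.sum()

        prior = SpikeSlabPrior(
            pi_fixed=pi, background=False,
            df_gamma=INF, scale_gamma=s_slab, df_e=INF, scale_e=self.se2,
        )
        samples = fit_spike_slab(y, X, prior, MCMCConfig(60_000, 4_000, 4, seed=24))
        np.testing.assert_allclose(samples.beta_mean, oracle, atol=0.04)


class TestBayesA:
    def test_df_validation(self):
        with pytest.raises(ValueError):
            BayesAPrior(df=2.0)

    def test_large_df_approaches_gblup(self):
        rng = np.random.default_rng(8)
        X = rng.integers(0, 3, (200, 60)).astype(float)
        y = X @ rng.normal(0, 0.12, 60) + rng.normal(0, 0.8, 200)
        denom = (2 * (X.mean(0) / 2) * (1 - X.mean(0) / 2)).sum()
        target = 0.5 * y.var()  # prior genomic variance on both models
        s_g = fit_gblup(y, X, GBLUPPrior(df_u=INF, scale_u=target),
                        MCMCConfig(30_000, 5_000, 5, seed=7))
        big_df = 4_000.0
        s_a = fit_bayes_a(
            y, X,
            BayesAPrior(df=big_df, S0=(big_df - 2) * target / denom, s0_shape=None),
            MCMCConfig(30_000, 5_000, 5, seed=77),
        )
        assert np.corrcoef(s_a.linpred_mean, s_g.linpred_mean)[0, 1] > 0.99
        slope = np.polyfit(s_g.linpred_mean, s_a.linpred_mean, 1)[0]
        assert slope == pytest.approx(1.0, abs=0.15)

    def test_large_effect_shrunk_less_than_gblup(self):
        # effect-size-dependent shrinkage: a single strong QTL among nulls
        rng = np.random.default_rng(9)
        X = rng.integers(0, 3, (400, 120)).astype(float)
        y = X[:, 60] * 0.9 + rng.normal(0, 0.6, 400)
        mcmc = MCMCConfig(8_000, 2_000, 3, seed=8)
        s_g = fit_gblup(y, X, mcmc=mcmc)
        s_a = fit_bayes_a(y, X, mcmc=mcmc)
        assert abs(s_a.beta_mean[60]) > abs(s_g.beta_mean[60])

    def test_seed_reproducibility(self):
        X, y = _tiny_instance(seed=10, n=30, p=2)
        mcmc = MCMCConfig(2_000, 500, 3, seed=9)
        a = fit_bayes_a(y, X, mcmc=mcmc)
        b = fit_bayes_a(y, X, mcmc=mcmc)
        np.testing.assert_array_equal(a.S0, b.S0)
        np.testing.assert_array_equal(a.beta_mean, b.beta_mean)


class TestSpikeSlab:
    def test_pi_one_no_background_reduces_to_gblup(self):
        rng = np.random.default_rng(12)
        X = rng.integers(0, 3, (300, 150)).astype(float)
        beta = rng.normal(0, 0.08, 150)
        y = X @ beta + rng.normal(0, 0.7, 300)
        mcmc = MCMCConfig(8_000, 2_000, 3, seed=11)
        s_g = fit_gblup(y, X, mcmc=mcmc)
        prior = SpikeSlabPrior(pi_fixed=1.0, background=False)
        s_s = fit_spike_slab(y, X, prior, mcmc)
        assert np.corrcoef(s_g.linpred_mean, s_s.linpred_mean)[0, 1] > 0.995
        rms = np.sqrt(np.mean((s_g.linpred_mean - s_s.linpred_mean) ** 2))
        assert rms < 0.15 * np.std(s_g.u_mean)

    def test_true_effect_recall_by_inclusion_probability(self):
        rng = np.random.default_rng(13)
        n, p, k = 1_000, 510, 10
        X = rng.integers(0, 3, (n, p)).astype(float)
        true = rng.choice(p, k, replace=False)
        beta = np.zeros(p)
        beta[true] = rng.normal(0, 0.35, k)
        y = X @ beta + rng.normal(0, 0.7, n)
        samples = fit_spike_slab(y, X, mcmc=MCMCConfig(12_000, 2_000, 5, seed=12))
        top = np.argsort(samples.pip)[-k:]
        recall = np.intersect1d(top, true).size / k
        assert recall >= 0.7

    def test_degenerate_pi_support_rejected(self):
        with pytest.raises(ValueError):
            SpikeSlabPrior(pi_fixed=0.0)

    def test_seed_reproducibility(self):
        X, y = _tiny_instance(seed=14, n=40, p=2)
        mcmc = MCMCConfig(2_000, 500, 3, seed=13)
        a = fit_spike_slab(y, X, mcmc=mcmc)
        b = fit_spike_slab(y, X, mcmc=mcmc)
        np.testing.assert_array_equal(a.pi, b.pi)
        np.testing.assert_array_equal(a.pip, b.pip)


@pytest.fixture(scope="module")
def fits():
    rng = np.random.default_rng(15)
    X = rng.integers(0, 3, (150, 60)).astype(float)
    y = X @ rng.normal(0, 0.1, 60) + rng.normal(0, 0.7, 150)
    mcmc = MCMCConfig(3_000, 1_000, 4, seed=14)
    return {
        "gblup": fit_gblup(y, X, mcmc=mcmc),
        "bayes_a": fit_bayes_a(y, X, mcmc=mcmc),
        "spike_slab": fit_spike_slab(y, X, mcmc=mcmc),
    }


class TestChainHealth:
    def test_retained_draw_count(self, fits):
        for s in fits.values():
            assert s.n_draws == (3_000 - 1_000) // 4

    def test_variance_draws_positive(self, fits):
        for s in fits.values():
            assert (s.sigma_e2 > 0).all()
        assert (fits["gblup"].sigma_g2 > 0).all()
        assert (fits["bayes_a"].S0 > 0).all()
        pi = fits["spike_slab"].pi
        assert ((pi > 0) & (pi <= 1)).all()

    def test_ess_reported(self, fits):
        for s in fits.values():
            ess = s.ess()
            assert all(v > 0 for v in ess.values())

    def test_stability_across_seeds(self):
        rng = np.random.default_rng(16)
        X = rng.integers(0, 3, (300, 100)).astype(float)
        y = X @ rng.normal(0, 0.1, 100) + rng.normal(0, 0.7, 300)
        h2s = [
            estimate_h2(
                fit_gblup(y, X, mcmc=MCMCConfig(6_000, 1_000, 5, seed=s))
            ).posterior_mean
            for s in (1, 2, 3)
        ]
        assert max(h2s) - min(h2s) < 0.04

    def test_label_equivariance_at_mc_level(self):
        rng = np.random.default_rng(17)
        X = rng.integers(0, 3, (250, 40)).astype(float)
        y = X[:, 5] * 0.5 + rng.normal(0, 0.7, 250)
        perm = rng.permutation(40)
        mcmc = MCMCConfig(12_000, 2_000, 5, seed=15)
        a = fit_bayes_a(y, X, mcmc=mcmc).beta_mean
        b = fit_bayes_a(y, X[:, perm], mcmc=mcmc).beta_mean
        unpermuted = np.empty(40)
        unpermuted[perm] = b
        assert np.corrcoef(a, unpermuted)[0, 1] > 0.98


class TestPredict:
    def test_training_row_reproduces_fit(self):
        rng = np.random.default_rng(18)
        X = rng.integers(0, 3, (120, 50)).astype(float)
        y = X @ rng.normal(0, 0.15, 50) + rng.normal(0, 0.5, 120)
        samples = fit_gblup(y, X, mcmc=MCMCConfig(4_000, 1_000, 3, seed=16))
        np.testing.assert_allclose(
            predict(samples, X), samples.linpred_mean, atol=1e-8
        )

    def test_null_posterior_predicts_intercept(self):
        rng = np.random.default_rng(19)
        X = rng.integers(0, 3, (100, 20)).astype(float)
        y = np.full(100, 3.0) + rng.normal(0, 0.01, 100)
        samples = fit_gblup(y, X, mcmc=MCMCConfig(4_000, 1_000, 3, seed=17))
        pred = predict(samples, rng.integers(0, 3, (10, 20)).astype(float))
        np.testing.assert_allclose(pred, 3.0, atol=0.2)

    def test_grm_and_marker_forms_predict_alike(self):
        rng = np.random.default_rng(20)
        X = rng.integers(0, 3, (250, 120)).astype(float)
        y = X @ rng.normal(0, 0.1, 120) + rng.normal(0, 0.6, 250)
        trn, tst = np.arange(200), np.arange(200, 250)
        mcmc = MCMCConfig(8_000, 2_000, 3, seed=18)
        grm = compute_grm(X)
        grm_trn = GRM(grm.values[np.ix_(trn, trn)], grm.denominator,
                      grm.individual_ids[trn], grm.source_loci)
        s_grm = fit_gblup(y[trn], grm_trn, mcmc=mcmc)
        s_mrk = fit_gblup(y[trn], X[trn], mcmc=mcmc)
        p_grm = predict(s_grm, grm.values[np.ix_(tst, trn)])
        p_mrk = predict(s_mrk, X[tst])
        assert np.corrcoef(p_grm, p_mrk)[0, 1] > 0.98
        assert np.abs(p_grm - p_mrk).max() < 0.35 * np.std(y)

    def test_locus_mismatch_rejected(self):
        X, y = _tiny_instance(seed=21, n=30, p=2)
        samples = fit_bayes_a(y, X, mcmc=MCMCConfig(400, 100, 1, seed=19))
        with pytest.raises(ValueError, match="locus mismatch"):
            predict(samples, np.zeros((5, 3)))


class TestESS:
    def test_iid_chain_near_n(self):
        x = np.random.default_rng(0).normal(size=2_000)
        assert effective_sample_size(x) > 1_000

    def test_sticky_chain_small(self):
        rng = np.random.default_rng(1)
        x = np.empty(2_000)
        x[0] = 0.0
        for i in range(1, 2_000):
            x[i] = 0.99 * x[i - 1] + rng.normal(0, 0.1)
        assert effective_sample_size(x) < 200

    def test_invalid_mcmc_config(self):
        with pytest.raises(ValueError):
            MCMCConfig(n_iter=100, burn_in=100)
        with pytest.raises(ValueError):
            MCMCConfig(n_iter=100, burn_in=10, thin=0)
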