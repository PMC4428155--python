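"""Bayesian whole-genome regression samplers: GBLUP, Bayes A, Spike-Slab.

All three models share the additive likelihood

    y_i = mu + sum_j Xc_ij beta_j + eps_i,   eps_i ~ N(0, sigma_e^2),

with mean-centered dosage columns Xc (centering by the column mean equals
centering by twice the sample allele frequency) and differ only in the prior
on the marker effects:

* GBLUP: beta_j ~iid N(0, sigma_beta^2) -- homogeneous (ridge-type)
  shrinkage.  Also available in the mathematically equivalent form of a
  single random effect u ~ N(0, sigma_u^2 G) with G a genomic relationship
  matrix, sampled in the eigenbasis of G so each iteration is O(n).
* Bayes A: beta_j ~iid scaled-t(df, S0), handled through the normal /
  scaled-inverse-chi^2 augmentation beta_j | s2_j ~ N(0, s2_j),
  s2_j ~ ScInvChi2(df, S0) -- effect-size-dependent shrinkage.
* Spike-Slab: the BSLMM decomposition beta_j = alpha_j + gamma_j with a
  dense background alpha_j ~ N(0, sigma_a^2) and sparse effects
  gamma_j ~ pi N(0, sigma_g^2) + (1 - pi) delta_0.  The classical
  George-McCulloch two-normal mixture is available as a variant.

Variance components carry scaled-inverse-chi^2 priors; a degrees-of-freedom
of ``inf`` pins the component at its scale (used for the fixed-variance
oracle checks).  Default scales follow the usual proportion-of-variance rule:
the prior mode of the genetic (residual) variance is set to R2 (1 - R2)
times the sample phenotypic variance, with R2 = 0.5.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .genotype_sim import GenotypeMatrix
from .ld_kinship import GRM


@dataclass(frozen=True)
class MCMCConfig:
    n_iter: int = 12_000
    burn_in: int = 2_000
    thin: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.burn_in >= self.n_iter:
            raise ValueError("burn_in must be smaller than n_iter")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if (self.n_iter - self.burn_in) % self.thin:
            raise ValueError("(n_iter - burn_in) must be a multiple of thin")

    @property
    def n_retained(self) -> int:
        return (self.n_iter - self.burn_in) // self.thin


def _check_df_scale(df: float, scale: float | None, name: str) -> None:
    if not df > 0:
        raise ValueError(f"{name}: degrees of freedom must be positive")
    if scale is not None and scale <= 0:
        raise ValueError(f"{name}: scale must be positive")


@dataclass(frozen=True)
class GBLUPPrior:
    df_u: float = 5.0
    scale_u: float | None = None
    df_e: float = 5.0
    scale_e: float | None = None
    r2: float = 0.5

    def __post_init__(self) -> None:
        _check_df_scale(self.df_u, self.scale_u, "sigma_u^2 prior")
        _check_df_scale(self.df_e, self.scale_e, "sigma_e^2 prior")


@dataclass(frozen=True)
class BayesAPrior:
    df: float = 5.0
    S0: float | None = None
    df_e: float = 5.0
    scale_e: float | None = None
    r2: float = 0.5
    #: S0 gets a Gamma(s0_shape, rate) hyperprior with the rate solved so that
    #: E(S0) equals the proportion-of-variance rule; set to None to keep S0
    #: fixed at that rule instead.  Sampling S0 lets the scaled-t adapt its
    #: global scale to the architecture, which is what gives Bayes A its
    #: effect-size-dependent shrinkage advantage in sparse settings.
    s0_shape: float | None = 1.1

    def __post_init__(self) -> None:
        if not self.df > 2:
            raise ValueError(
                "Bayes A requires df > 2 (E(sigma_beta^2) = S0/(df-2) undefined)"
            )
        _check_df_scale(self.df_e, self.scale_e, "sigma_e^2 prior")
        if self.S0 is not None and self.S0 <= 0:
            raise ValueError("S0 must be positive")


@dataclass(frozen=True)
class SpikeSlabPrior:
    variant: str = "bslmm"  # or "george_mcculloch"
    pi_bounds: tuple[float, float] | None = None  # default (1/p, 1) at fit time
    pi_fixed: float | None = None
    df_gamma: float = 5.0          # slab variance prior
    scale_gamma: float | None = None
    df_alpha: float = 5.0          # background (bslmm) / spike (GM) variance prior
    scale_alpha: float | None = None
    df_e: float = 5.0
    scale_e: float | None = None
    r2: float = 0.5
    sparse_share: float = 0.5      # prior split of genetic variance sparse/background
    background: bool = True        # bslmm only: include the dense background
    spike_scale_ratio: float = 1e-3  # GM default spike scale relative to slab

    def __post_init__(self) -> None:
        if self.variant not in ("bslmm", "george_mcculloch"):
            raise ValueError(f"unknown spike-slab variant {self.variant!r}")
        if self.pi_fixed is not None and not 0.0 < self.pi_fixed <= 1.0:
            raise ValueError("pi support must lie in (0, 1]")
        if self.pi_bounds is not None:
            lo, hi = self.pi_bounds
            if not 0.0 < lo <= hi <= 1.0:
                raise ValueError("pi support must lie in (0, 1]")
        _check_df_scale(self.df_gamma, self.scale_gamma, "slab variance prior")
        _check_df_scale(self.df_alpha, self.scale_alpha, "background variance prior")
        _check_df_scale(self.df_e, self.scale_e, "sigma_e^2 prior")


@dataclass
class PosteriorSamples:
    """Retained MCMC draws plus posterior-mean summaries of one model fit."""

    model: str
    form: str                      # "marker" or "grm"
    config: MCMCConfig
    mu: np.ndarray
    sigma_e2: np.ndarray
    var_g: np.ndarray              # per-draw empirical variance of genetic values
    u_mean: np.ndarray             # posterior-mean genetic values (training)
    linpred_mean: np.ndarray
    sigma_g2: np.ndarray | None = None
    # marker-form payload
    beta_mean: np.ndarray | None = None
    center: np.ndarray | None = None
    freqs: np.ndarray | None = None
    denom: float | None = None
    sigma_beta2: np.ndarray | None = None
    S0: np.ndarray | None = None
    df: float | None = None
    pi: np.ndarray | None = None
    sigma_alpha2: np.ndarray | None = None
    sigma_gamma2: np.ndarray | None = None
    pip: np.ndarray | None = None
    # grm-form payload for prediction
    eigvals: np.ndarray | None = None
    eigvecs: np.ndarray | None = None
    a_mean: np.ndarray | None = None

    @property
    def n_draws(self) -> int:
        return self.mu.size

    def ess(self) -> dict[str, float]:
        """Effective sample size of the key scalar chains."""
        out = {"mu": effective_sample_size(self.mu),
               "sigma_e2": effective_sample_size(self.sigma_e2)}
        if self.sigma_g2 is not None:
            out["sigma_g2"] = effective_sample_size(self.sigma_g2)
        if self.pi is not None:
            out["pi"] = effective_sample_size(self.pi)
        return out


def effective_sample_size(x: np.ndarray) -> float:
    """ESS via Geyer's initial positive sequence estimator."""
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 4 or x.std() == 0:
        return float(n)
    a = x - x.mean()
    acov = np.correlate(a, a, mode="full")[n - 1:] / n
    rho = acov / acov[0]
    s = 0.0
    for k in range(1, n // 2):
        pair = rho[2 * k - 1] + rho[2 * k] if 2 * k < n else rho[2 * k - 1]
        if pair <= 0:
            break
        s += pair
    return float(min(n, n / (1.0 + 2.0 * s)))


def _draw_variance(rng, df, scale, ss, k) -> float:
    """Scaled-inverse-chi^2 conditional draw; df = inf pins at the scale."""
    if math.isinf(df):
        return float(scale)
    return float((df * scale + ss) / rng.chisquare(df + k))


def _resolve_scale(scale, df, target_mode):
    """Scale such that the prior mode df*S/(df+2) equals target_mode."""
    if scale is not None:
        return float(scale)
    if math.isinf(df):
        return float(target_mode)
    return float(target_mode * (df + 2.0) / df)


def _prep_marker_matrix(X):
    if isinstance(X, GenotypeMatrix):
        X = X.dosages
    X = np.asarray(X, dtype=float)
    center = X.mean(axis=0)
    freqs = center / 2.0
    Xt = np.ascontiguousarray((X - center).T)
    xx = np.einsum("ij,ij->i", Xt, Xt)
    denom = float((2.0 * freqs * (1.0 - freqs)).sum())
    return Xt, xx, center, freqs, denom


def _retained_iter(mcmc: MCMCConfig):
    for t in range(1, mcmc.n_iter + 1):
        keep = t > mcmc.burn_in and (t - mcmc.burn_in) % mcmc.thin == 0
        yield t, keep


def _log_odds(pi: float) -> float:
    if pi >= 1.0:
        return np.inf
    return math.log(pi / (1.0 - pi))


def _update_pi_mh(pi, n_in, p, lo, hi, rng, step=0.5) -> float:
    """Metropolis step for pi under a log-uniform prior on [lo, hi]."""
    lp = math.log(pi)
    prop = lp + step * rng.normal()
    if not (math.log(lo) <= prop <= math.log(hi)):
        return pi
    pi_new = math.exp(prop)
    ll_new = n_in * prop + (p - n_in) * math.log1p(-pi_new) if pi_new < 1 else (
        -np.inf if n_in < p else n_in * prop)
    ll_old = n_in * lp + (p - n_in) * math.log1p(-pi) if pi < 1 else (
        -np.inf if n_in < p else n_in * lp)
    if math.log(rng.random()) < ll_new - ll_old:
        return pi_new
    return pi


# ---------------------------------------------------------------------------
# GBLUP
# ---------------------------------------------------------------------------

def fit_gblup(y, input, prior: GBLUPPrior | None = None,
              mcmc: MCMCConfig | None = None) -> PosteriorSamples:
    """Gibbs sampler for the GBLUP model.

    ``input`` may be a GRM (random-effect form, sampled in the eigenbasis of
    G) or a dosage matrix / GenotypeMatrix (explicit regression on markers).
    The two parameterizations are mathematically equivalent and their
    training predictions agree within Monte Carlo error.
    """
    prior = prior or GBLUPPrior()
    mcmc = mcmc or MCMCConfig()
    y = np.asarray(y, dtype=float)
    if y.size < 3:
        raise ValueError("need at least 3 phenotypes")
    if isinstance(input, GRM):
        return _fit_gblup_grm(y, input, prior, mcmc)
    return _fit_gblup_marker(y, input, prior, mcmc)


def _fit_gblup_grm(y, grm: GRM, prior, mcmc) -> PosteriorSamples:
    n = y.size
    if grm.values.shape != (n, n):
        raise ValueError("GRM dimension does not match phenotype vector")
    w, V = np.linalg.eigh(grm.values)
    tol = 1e-8 * max(w.max(), 1.0)
    if w.min() < -1e-6 * max(w.max(), 1.0):
        raise ValueError("GRM is not positive semidefinite")
    w = np.clip(w, 0.0, None)
    active = w > tol
    rank = int(active.sum())
    rng = np.random.default_rng(mcmc.seed)
    var_y = y.var()
    S_u = _resolve_scale(prior.scale_u, prior.df_u, prior.r2 * var_y)
    S_e = _resolve_scale(prior.scale_e, prior.df_e, (1 - prior.r2) * var_y)

    yt = V.T @ y
    ones_t = V.T @ np.ones(n)
    mu = float(y.mean())
    a = np.zeros(n)
    sig_u2, sig_e2 = S_u, S_e

    R = mcmc.n_retained
    mu_d = np.empty(R); se_d = np.empty(R); su_d = np.empty(R); vg_d = np.empty(R)
    a_sum = np.zeros(n)
    k = 0
    for t, keep in _retained_iter(mcmc):
        prec = 1.0 / sig_e2 + 1.0 / (sig_u2 * np.where(active, w, np.inf))
        mean = ((yt - mu * ones_t) / sig_e2) / prec
        a = mean + rng.standard_normal(n) / np.sqrt(prec)
        a[~active] = 0.0
        # intercept
        resid_mean = y.mean() - (ones_t @ a) / n
        mu = resid_mean + math.sqrt(sig_e2 / n) * rng.standard_normal()
        # variance components
        ss_u = float((a[active] ** 2 / w[active]).sum())
        sig_u2 = _draw_variance(rng, prior.df_u, S_u, ss_u, rank)
        r = yt - mu * ones_t - a
        sig_e2 = _draw_variance(rng, prior.df_e, S_e, float(r @ r), n)
        if keep:
            mu_d[k] = mu; se_d[k] = sig_e2; su_d[k] = sig_u2
            vg_d[k] = float(a @ a) / n - ((ones_t @ a) / n) ** 2
            a_sum += a
            k += 1
    a_mean = a_sum / R
    u_mean = V @ a_mean
    return PosteriorSamples(
        model="gblup", form="grm", config=mcmc,
        mu=mu_d, sigma_e2=se_d, sigma_g2=su_d, var_g=vg_d,
        u_mean=u_mean, linpred_mean=mu_d.mean() + u_mean,
        eigvals=w, eigvecs=V, a_mean=a_mean,
    )


def _fit_gblup_marker(y, X, prior, mcmc) -> PosteriorSamples:
    Xt, xx, center, freqs, denom = _prep_marker_matrix(X)
    p, n = Xt.shape
    if n != y.size:
        raise ValueError("dosage matrix and phenotype dimensions differ")
    rng = np.random.default_rng(mcmc.seed)
    var_y = y.var()
    S_b = _resolve_scale(prior.scale_u, prior.df_u, prior.r2 * var_y) / denom
    S_e = _resolve_scale(prior.scale_e, prior.df_e, (1 - prior.r2) * var_y)

    beta = np.zeros(p)
    mu = float(y.mean())
    e = y - mu
    sig_b2, sig_e2 = S_b, S_e
    var_beta = np.empty(p)

    R = mcmc.n_retained
    mu_d = np.empty(R); se_d = np.empty(R); sb_d = np.empty(R); vg_d = np.empty(R)
    beta_sum = np.zeros(p); u_sum = np.zeros(n)
    k = 0
    for t, keep in _retained_iter(mcmc):
        var_beta[:] = sig_b2
        _kernels.sweep_normal(Xt, xx, e, beta, var_beta, sig_e2, rng.standard_normal(p))
        mu_new = mu + e.mean() + math.sqrt(sig_e2 / n) * rng.standard_normal()
        e += mu - mu_new
        mu = mu_new
        sig_b2 = _draw_variance(rng, prior.df_u, S_b, float(beta @ beta), p)
        sig_e2 = _draw_variance(rng, prior.df_e, S_e, float(e @ e), n)
        if keep:
            g = y - mu - e
            mu_d[k] = mu; se_d[k] = sig_e2; sb_d[k] = sig_b2
            vg_d[k] = g.var()
            beta_sum += beta; u_sum += g
            k += 1
    beta_mean = beta_sum / R
    u_mean = u_sum / R
    return PosteriorSamples(
        model="gblup", form="marker", config=mcmc,
        mu=mu_d, sigma_e2=se_d, sigma_g2=denom * sb_d, var_g=vg_d,
        u_mean=u_mean, linpred_mean=mu_d.mean() + u_mean,
        beta_mean=beta_mean, center=center, freqs=freqs, denom=denom,
        sigma_beta2=sb_d,
    )


# ---------------------------------------------------------------------------
# Bayes A
# ---------------------------------------------------------------------------

def fit_bayes_a(y, X, prior: BayesAPrior | None = None,
                mcmc: MCMCConfig | None = None) -> PosteriorSamples:
    """Gibbs sampler for Bayes A (scaled-t prior via variance augmentation).

    S0 follows the sum-of-squares parametrization of the inverse-chi^2
    (prior mean of sigma_beta_j^2 is S0/(df - 2)), so the conditional update
    is sigma_beta_j^2 = (S0 + beta_j^2) / chi2(df + 1).  When
    ``prior.s0_shape`` is set, S0 itself is sampled from its conjugate Gamma
    conditional.
    """
    prior = prior or BayesAPrior()
    mcmc = mcmc or MCMCConfig()
    y = np.asarray(y, dtype=float)
    if y.size < 3:
        raise ValueError("need at least 3 phenotypes")
    Xt, xx, center, freqs, denom = _prep_marker_matrix(X)
    p, n = Xt.shape
    if n != y.size:
        raise ValueError("dosage matrix and phenotype dimensions differ")
    rng = np.random.default_rng(mcmc.seed)
    var_y = y.var()
    df = prior.df
    S0_default = prior.r2 * var_y * (df - 2.0) / denom
    S0 = float(prior.S0) if prior.S0 is not None else S0_default
    S_e = _resolve_scale(prior.scale_e, prior.df_e, (1 - prior.r2) * var_y)
    sample_s0 = prior.s0_shape is not None
    if sample_s0:
        s0_rate = prior.s0_shape / S0

    beta = np.zeros(p)
    s2 = np.full(p, S0 / (df - 2.0))
    mu = float(y.mean())
    e = y - mu
    sig_e2 = S_e

    R = mcmc.n_retained
    mu_d = np.empty(R); se_d = np.empty(R); s0_d = np.empty(R); vg_d = np.empty(R)
    beta_sum = np.zeros(p); u_sum = np.zeros(n)
    k = 0
    for t, keep in _retained_iter(mcmc):
        _kernels.sweep_normal(Xt, xx, e, beta, s2, sig_e2, rng.standard_normal(p))
        s2 = (S0 + beta ** 2) / rng.chisquare(df + 1.0, size=p)
        if sample_s0:
            S0 = rng.gamma(prior.s0_shape + 0.5 * p * df,
                           1.0 / (s0_rate + 0.5 * (1.0 / s2).sum()))
        mu_new = mu + e.mean() + math.sqrt(sig_e2 / n) * rng.standard_normal()
        e += mu - mu_new
        mu = mu_new
        sig_e2 = _draw_variance(rng, prior.df_e, S_e, float(e @ e), n)
        if keep:
            g = y - mu - e
            mu_d[k] = mu; se_d[k] = sig_e2; s0_d[k] = S0
            vg_d[k] = g.var()
            beta_sum += beta; u_sum += g
            k += 1
    beta_mean = beta_sum / R
    u_mean = u_sum / R
    return PosteriorSamples(
        model="bayes_a", form="marker", config=mcmc,
        mu=mu_d, sigma_e2=se_d, var_g=vg_d,
        u_mean=u_mean, linpred_mean=mu_d.mean() + u_mean,
        beta_mean=beta_mean, center=center, freqs=freqs, denom=denom,
        S0=s0_d, df=df,
    )


# ---------------------------------------------------------------------------
# Spike-Slab
# ---------------------------------------------------------------------------

def fit_spike_slab(y, X, prior: SpikeSlabPrior | None = None,
                   mcmc: MCMCConfig | None = None) -> PosteriorSamples:
    """Gibbs sampler for the Spike-Slab model.

    Default variant is the BSLMM decomposition: every marker carries a dense
    background effect alpha_j ~ N(0, sigma_a^2) (so u = Xc alpha is the
    polygenic term) and, with probability pi, an extra sparse effect
    gamma_j ~ N(0, sigma_g^2).  ``variant="george_mcculloch"`` fits the pure
    two-normal mixture instead.
    """
    prior = prior or SpikeSlabPrior()
    mcmc = mcmc or MCMCConfig()
    y = np.asarray(y, dtype=float)
    if y.size < 3:
        raise ValueError("need at least 3 phenotypes")
    Xt, xx, center, freqs, denom = _prep_marker_matrix(X)
    p, n = Xt.shape
    if n != y.size:
        raise ValueError("dosage matrix and phenotype dimensions differ")
    rng = np.random.default_rng(mcmc.seed)
    var_y = y.var()
    pi_lo, pi_hi = prior.pi_bounds if prior.pi_bounds is not None else (1.0 / p, 1.0)
    pi0 = prior.pi_fixed if prior.pi_fixed is not None else math.sqrt(pi_lo * pi_hi)
    use_background = prior.background and prior.variant == "bslmm"

    share_sparse = prior.sparse_share if use_background else 1.0
    S_g = _resolve_scale(prior.scale_gamma, prior.df_gamma,
                         share_sparse * prior.r2 * var_y / (pi0 * denom))
    if prior.variant == "bslmm":
        S_a = _resolve_scale(prior.scale_alpha, prior.df_alpha,
                             (1.0 - share_sparse) * prior.r2 * var_y / denom)
        S_a = max(S_a, 1e-12)
    else:
        S_a = _resolve_scale(prior.scale_alpha, prior.df_alpha,
                             prior.spike_scale_ratio * S_g)
    S_e = _resolve_scale(prior.scale_e, prior.df_e, (1 - prior.r2) * var_y)

    mu = float(y.mean())
    e = y - mu
    sig_e2 = S_e
    pi = pi0
    alpha = np.zeros(p)
    gamma = np.zeros(p)
    incl = np.zeros(p, dtype=np.int8)
    sig_a2, sig_g2 = S_a, S_g
    var_alpha = np.empty(p)

    R = mcmc.n_retained
    mu_d = np.empty(R); se_d = np.empty(R); pi_d = np.empty(R); vg_d = np.empty(R)
    sa_d = np.empty(R); sg_d = np.empty(R)
    beta_sum = np.zeros(p); u_sum = np.zeros(n); pip_sum = np.zeros(p)
    k = 0
    for t, keep in _retained_iter(mcmc):
        if prior.variant == "bslmm":
            if use_background:
                var_alpha[:] = sig_a2
                _kernels.sweep_normal(Xt, xx, e, alpha, var_alpha, sig_e2,
                                      rng.standard_normal(p))
                sig_a2 = _draw_variance(rng, prior.df_alpha, S_a,
                                        float(alpha @ alpha), p)
            n_in = _kernels.sweep_point_mass(
                Xt, xx, e, gamma, incl, sig_g2, sig_e2, _log_odds(pi),
                rng.standard_normal(p), rng.random(p))
            ss_g = float(gamma @ gamma)
        else:
            n_in = _kernels.sweep_two_normal(
                Xt, xx, e, gamma, incl, sig_g2, sig_a2, sig_e2, _log_odds(pi),
                rng.standard_normal(p), rng.random(p))
            slab = incl.astype(bool)
            ss_g = float((gamma[slab] ** 2).sum())
            sig_a2 = _draw_variance(rng, prior.df_alpha, S_a,
                                    float((gamma[~slab] ** 2).sum()), p - n_in)
        sig_g2 = _draw_variance(rng, prior.df_gamma, S_g, ss_g, n_in)
        if prior.pi_fixed is None:
            pi = _update_pi_mh(pi, n_in, p, pi_lo, pi_hi, rng)
        mu_new = mu + e.mean() + math.sqrt(sig_e2 / n) * rng.standard_normal()
        e += mu - mu_new
        mu = mu_new
        sig_e2 = _draw_variance(rng, prior.df_e, S_e, float(e @ e), n)
        if keep:
            g = y - mu - e
            mu_d[k] = mu; se_d[k] = sig_e2; pi_d[k] = pi
            sa_d[k] = sig_a2; sg_d[k] = sig_g2
            vg_d[k] = g.var()
            beta_sum += alpha + gamma
            pip_sum += incl
            u_sum += g
            k += 1
    beta_mean = beta_sum / R
    u_mean = u_sum / R
    return PosteriorSamples(
        model="spike_slab", form="marker", config=mcmc,
        mu=mu_d, sigma_e2=se_d, var_g=vg_d,
        u_mean=u_mean, linpred_mean=mu_d.mean() + u_mean,
        beta_mean=beta_mean, center=center, freqs=freqs, denom=denom,
        pi=pi_d, sigma_alpha2=sa_d, sigma_gamma2=sg_d, pip=pip_sum / R,
    )


# ---------------------------------------------------------------------------
# Prediction
# ---------------------------------------------------------------------------

def predict(samples: PosteriorSamples, new: np.ndarray) -> np.ndarray:
    """Posterior-mean genetic prediction for new individuals.

    For marker-form fits ``new`` is a dosage matrix on the same loci; for
    GRM-form fits it is the TST x TRN cross-relationship block and the
    prediction is mu + G_cross G^+ u_hat (pseudo-inverse via the stored
    eigendecomposition).
    """
    if isinstance(new, GenotypeMatrix):
        new = new.dosages
    new = np.asarray(new, dtype=float)
    mu_hat = float(samples.mu.mean())
    if samples.form == "marker":
        if new.shape[1] != samples.beta_mean.size:
            raise ValueError("locus mismatch between fit and prediction data")
        return mu_hat + (new - samples.center) @ samples.beta_mean
    if new.shape[1] != samples.a_mean.size:
        raise ValueError("cross-relationship block does not match training set")
    w = samples.eigvals
    coef = np.where(w > 1e-8 * max(w.max(), 1.0), samples.a_mean / np.where(w > 0, w, 1.0), 0.0)
    return mu_hat + new @ (samples.eigvecs @ coef)
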