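"""Genomic-heritability estimators, one per whole-genome regression model.

Genomic heritability h_G^2 is the proportion of phenotypic variance captured
by regression on the available genotypes.  Each estimator summarizes the
posterior draw-wise, so every draw lies in [0, 1] by construction:

* GBLUP:      h_G^2 = sigma_g^2 / (sigma_g^2 + sigma_e^2) per draw;
* Bayes A:    sigma_g^2 = sum_j 2 p_j (1 - p_j) S0 / (df - 2) plugged into
              the same ratio (S0 per draw when it carries a hyperprior);
* Spike-Slab: the PVE form V(Xb + u) / (V(Xb + u) + sigma_e^2) with V(.) the
              empirical variance of the genetic values over training
              individuals in that draw.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .wgr_models import PosteriorSamples


@dataclass(frozen=True)
class HeritabilityEstimate:
    method: str
    posterior_mean: float
    posterior_sd: float
    n_draws: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.posterior_mean <= 1.0:
            raise ValueError("posterior mean heritability must lie in [0, 1]")
        if self.posterior_sd < 0:
            raise ValueError("posterior sd must be non-negative")


def _summarize(method: str, draws: np.ndarray) -> HeritabilityEstimate:
    draws = np.asarray(draws, dtype=float)
    return HeritabilityEstimate(
        method=method,
        posterior_mean=float(draws.mean()),
        posterior_sd=float(draws.std(ddof=1)) if draws.size > 1 else 0.0,
        n_draws=draws.size,
    )


def h2_gblup(samples: PosteriorSamples) -> HeritabilityEstimate:
    """Posterior of sigma_g^2 / (sigma_g^2 + sigma_e^2) under GBLUP."""
    if samples.sigma_g2 is None or samples.sigma_e2 is None:
        raise ValueError("GBLUP heritability needs sigma_g2 and sigma_e2 draws")
    draws = samples.sigma_g2 / (samples.sigma_g2 + samples.sigma_e2)
    return _summarize("gblup", draws)


def h2_bayes_a(samples: PosteriorSamples,
               freqs: np.ndarray | None = None,
               df: float | None = None) -> HeritabilityEstimate:
    """Bayes A genomic heritability from the prior-expected marker variance.

    The genomic variance is sum_j 2 p_j (1 - p_j) * S0/(df - 2), evaluated
    per draw when S0 is sampled (plug-in when fixed, in which case all S0
    draws coincide).
    """
    if samples.S0 is None:
        raise ValueError("Bayes A heritability needs S0 draws")
    df = samples.df if df is None else df
    if df is None or df <= 2:
        raise ValueError("Bayes A heritability requires df > 2")
    if freqs is None:
        freqs = samples.freqs
    freqs = np.asarray(freqs, dtype=float)
    denom = float((2.0 * freqs * (1.0 - freqs)).sum())
    sigma_g2 = denom * samples.S0 / (df - 2.0)
    draws = sigma_g2 / (sigma_g2 + samples.sigma_e2)
    return _summarize("bayes_a", draws)


def h2_spike_slab(samples: PosteriorSamples) -> HeritabilityEstimate:
    """Spike-Slab PVE: per-draw V(genetic values) over training individuals
    against the residual variance of that draw."""
    if samples.var_g is None:
        raise ValueError("Spike-Slab heritability needs linear-predictor draws")
    total = samples.var_g + samples.sigma_e2
    draws = np.where(total > 0, samples.var_g / np.where(total > 0, total, 1.0), 0.0)
    return _summarize("spike_slab", draws)


def estimate_h2(samples: PosteriorSamples) -> HeritabilityEstimate:
    """Dispatch to the estimator matching the fitted model."""
    if samples.model == "gblup":
        return h2_gblup(samples)
    if samples.model == "bayes_a":
        return h2_bayes_a(samples)
    if samples.model == "spike_slab":
        return h2_spike_slab(samples)
    raise ValueError(f"no heritability estimator for model {samples.model!r}")
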