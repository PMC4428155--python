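"""Scaled-down study designs for the benchmark's headline quantities.

Each function runs one self-contained experiment end to end (simulate
genotypes, build a trait, fit models, score) at desk scale, preserving the
structural ratios of the full-size design (training size vs number of causal
loci, marker:record ratio, heritability and variance-partition settings)
while keeping runtimes in the minutes.  All randomness flows from the single
``seed`` argument.
"""

from __future__ import annotations

import numpy as np

from .evaluation import accuracy, training_r2
from .genotype_sim import (
    LOW_MAF_POOL_LAW,
    HaplotypePoolSpec,
    minor_allele_frequencies,
    simulate_genotypes,
)
from .heritability import estimate_h2
from .ld_kinship import GRM, compute_grm, filter_test_by_relatedness
from .trait_sim import (
    ArchitectureSpec,
    SamplingScheme,
    assign_effects,
    partition_markers_qtl,
    sample_qtl,
    simulate_phenotypes,
    simulate_scenario_trait,
)
from .wgr_models import MCMCConfig, fit_bayes_a, fit_gblup, fit_spike_slab, predict

_DEFAULT_MCMC = dict(n_iter=12_000, burn_in=2_000, thin=5)


def _seed(base: int, *offsets: int) -> int:
    return int(np.random.SeedSequence([int(base), *map(int, offsets)])
               .generate_state(1)[0] % (2**31))


def _grm_subset(grm: GRM, idx: np.ndarray) -> GRM:
    return GRM(
        values=grm.submatrix(idx),
        denominator=grm.denominator,
        individual_ids=grm.individual_ids[idx],
        source_loci=grm.source_loci,
    )


def low_maf_stratification(
    n_qtl: int = 500, pool_size: int = 20_000, n_seeds: int = 20, seed: int = 0
) -> float:
    """Mean percentage of LOW-MAF-sampled QTL falling below MAF 0.05.

    The pool MAFs are drawn from the low-frequency-enriched law, which
    populates every stratum amply at this pool size.
    """
    fractions = []
    for k in range(n_seeds):
        rng = np.random.default_rng(_seed(seed, 1, k))
        pool = LOW_MAF_POOL_LAW.sample(pool_size, rng)
        qtl = sample_qtl(pool, SamplingScheme.LOW_MAF, n_qtl, seed=_seed(seed, 2, k))
        fractions.append(100.0 * float((pool[qtl.qtl_indices] < 0.05).mean()))
    return float(np.mean(fractions))


def variance_targets(
    n: int = 2_000,
    n_qtl: int = 500,
    n_large: int = 50,
    pve_large: float = 0.75,
    n_seeds: int = 30,
    seed: int = 0,
) -> dict[str, float]:
    """Mean realized residual variance, heritability and large-QTL variance
    share over replicate traits at the standard h2 = 0.5 / V(eps) = 0.5
    settings."""
    arch = ArchitectureSpec(n_large=n_large, pve_large=pve_large,
                            target_h2=0.5, residual_variance=0.5)
    res_var, h2, pve = [], [], []
    for k in range(n_seeds):
        spec = HaplotypePoolSpec(
            n_blocks=25, markers_per_block=n_qtl // 25,
            within_block_switch_prob=0.1, seed=_seed(seed, 11, k),
        )
        G = simulate_genotypes(spec, n)
        Z = G.dosages.astype(float)
        effects, large = assign_effects(
            minor_allele_frequencies(G), arch, seed=_seed(seed, 12, k)
        )
        trait = simulate_phenotypes(Z, effects, arch.residual_variance,
                                    seed=_seed(seed, 13, k), large_set=large)
        res_var.append(trait.residuals.var())
        h2.append(trait.realized_h2)
        pve.append(trait.realized_pve)
    return {
        "residual_variance": float(np.mean(res_var)),
        "realized_h2": float(np.mean(h2)),
        "realized_pve": float(np.mean(pve)),
    }


def gblup_h2_perfect_ld(
    n: int = 1_500,
    n_loci: int = 500,
    n_replicates: int = 10,
    seed: int = 0,
    mcmc_kwargs: dict | None = None,
) -> float:
    """Mean GBLUP posterior-mean heritability fitting causal genotypes only.

    Infinitesimal architecture at h2 = 0.5: with the causal loci in the
    model there is no missing heritability, so the mean estimate should sit
    on the simulated value.
    """
    mcmc_kwargs = {**_DEFAULT_MCMC, **(mcmc_kwargs or {})}
    arch = ArchitectureSpec(target_h2=0.5, residual_variance=0.5)
    estimates = []
    for k in range(n_replicates):
        spec = HaplotypePoolSpec(
            n_blocks=25, markers_per_block=n_loci // 25,
            within_block_switch_prob=0.1, seed=_seed(seed, 21, k),
        )
        G = simulate_genotypes(spec, n)
        Z = G.dosages.astype(float)
        effects, large = assign_effects(
            minor_allele_frequencies(G), arch, seed=_seed(seed, 22, k)
        )
        trait = simulate_phenotypes(Z, effects, arch.residual_variance,
                                    seed=_seed(seed, 23, k), large_set=large)
        samples = fit_gblup(
            trait.phenotypes, compute_grm(Z),
            mcmc=MCMCConfig(seed=_seed(seed, 24, k), **mcmc_kwargs),
        )
        estimates.append(estimate_h2(samples).posterior_mean)
    return float(np.mean(estimates))


def spike_slab_perfect_ld_accuracy(
    n_trn: int = 2_000,
    n_candidates: int = 200,
    n_qtl: int = 400,
    n_large: int = 40,
    pve_large: float = 0.75,
    n_replicates: int = 10,
    threshold: float = 0.125,
    seed: int = 0,
    mcmc_kwargs: dict | None = None,
) -> dict[str, float]:
    """Mean test-set correlation of Spike-Slab predictions, causal genotypes
    only, simple architecture (40 of 400 QTL carrying 75% of V_g).

    The holdout group is filtered to genomic relationship <= 1/8 with every
    training individual; relatedness is estimated genome-wide (causal panel
    plus independent background marker blocks), as the trait loci alone are
    far too few to estimate kinship.
    """
    mcmc_kwargs = {**_DEFAULT_MCMC, **(mcmc_kwargs or {})}
    n = n_trn + n_candidates
    arch = ArchitectureSpec(n_large=n_large, pve_large=pve_large,
                            target_h2=0.5, residual_variance=0.5)
    corrs, retained = [], []
    for k in range(n_replicates):
        causal = simulate_genotypes(
            HaplotypePoolSpec(n_blocks=20, markers_per_block=n_qtl // 20,
                              within_block_switch_prob=0.1,
                              seed=_seed(seed, 31, k)),
            n,
        )
        background = simulate_genotypes(
            HaplotypePoolSpec(n_blocks=6, markers_per_block=300,
                              within_block_switch_prob=0.5,
                              seed=_seed(seed, 32, k)),
            n,
        )
        Z = causal.dosages.astype(float)
        effects, large = assign_effects(
            minor_allele_frequencies(causal), arch, seed=_seed(seed, 33, k)
        )
        trait = simulate_phenotypes(Z, effects, arch.residual_variance,
                                    seed=_seed(seed, 34, k), large_set=large)
        y = trait.phenotypes
        rng = np.random.default_rng(_seed(seed, 35, k))
        perm = rng.permutation(n)
        trn, cand = perm[n_candidates:], perm[:n_candidates]
        grm = compute_grm(np.hstack([Z, background.dosages.astype(float)]))
        keep = filter_test_by_relatedness(grm.submatrix(cand, trn), threshold)
        tst = cand[keep]
        samples = fit_spike_slab(
            y[trn], Z[trn], mcmc=MCMCConfig(seed=_seed(seed, 36, k), **mcmc_kwargs)
        )
        corrs.append(accuracy(y[tst], predict(samples, Z[tst])))
        retained.append(tst.size)
    return {
        "mean_test_correlation": float(np.mean(corrs)),
        "mean_retained": float(np.mean(retained)),
    }


def gblup_training_r2_overfit(
    n: int = 1_265,
    n_loci: int = 1_200,
    n_replicates: int = 2,
    seed: int = 0,
    mcmc_kwargs: dict | None = None,
) -> float:
    """Mean GBLUP training R^2 at the full design's marker:record ratio
    (~0.95), h2 = 0.5, causal genotypes fitted.  Values above the simulated
    heritability quantify overfitting of the training records."""
    mcmc_kwargs = {**_DEFAULT_MCMC, **(mcmc_kwargs or {})}
    arch = ArchitectureSpec(target_h2=0.5, residual_variance=0.5)
    r2s = []
    for k in range(n_replicates):
        spec = HaplotypePoolSpec(
            n_blocks=30, markers_per_block=n_loci // 30,
            within_block_switch_prob=0.1, seed=_seed(seed, 41, k),
        )
        G = simulate_genotypes(spec, n)
        Z = G.dosages.astype(float)
        effects, large = assign_effects(
            minor_allele_frequencies(G), arch, seed=_seed(seed, 42, k)
        )
        trait = simulate_phenotypes(Z, effects, arch.residual_variance,
                                    seed=_seed(seed, 43, k), large_set=large)
        samples = fit_gblup(
            trait.phenotypes, compute_grm(Z),
            mcmc=MCMCConfig(seed=_seed(seed, 44, k), **mcmc_kwargs),
        )
        r2s.append(training_r2(trait.phenotypes, samples.linpred_mean))
    return float(np.mean(r2s))


def method_ordering_markers_only(
    n: int = 750,
    n_trn: int = 600,
    n_panel_markers: int = 3_000,
    n_qtl: int = 50,
    n_large: int = 5,
    pve_large: float = 0.75,
    n_replicates: int = 4,
    seed: int = 0,
    mcmc_kwargs: dict | None = None,
) -> dict[str, float]:
    """Mean test correlation per method, markers only, simple architecture.

    The design keeps many more markers than records and an extremely sparse
    signal, the regime in which variable selection (Spike-Slab) and
    effect-size-dependent shrinkage (Bayes A) are expected to beat the
    homogeneous shrinkage of GBLUP.
    """
    mcmc_kwargs = {**dict(n_iter=8_000, burn_in=2_000, thin=3),
                   **(mcmc_kwargs or {})}
    arch = ArchitectureSpec(n_large=n_large, pve_large=pve_large,
                            target_h2=0.5, residual_variance=0.5)
    out = {m: [] for m in ("gblup", "bayes_a", "spike_slab")}
    for k in range(n_replicates):
        spec = HaplotypePoolSpec(
            n_blocks=90, markers_per_block=(n_panel_markers + 600) // 90,
            within_block_switch_prob=0.01, freq_autocorr=0.6,
            seed=_seed(seed, 51, k),
        )
        G = simulate_genotypes(spec, n)
        marker_idx, pool_idx = partition_markers_qtl(
            G, n_panel_markers, seed=_seed(seed, 52, k)
        )
        _, trait = simulate_scenario_trait(
            G, pool_idx, SamplingScheme.RAND, n_qtl, arch, seed=_seed(seed, 53, k)
        )
        y = trait.phenotypes
        rng = np.random.default_rng(_seed(seed, 54, k))
        perm = rng.permutation(n)
        trn, tst = perm[:n_trn], perm[n_trn:]
        X = G.dosages[:, marker_idx].astype(float)
        grm = compute_grm(X)
        sg = fit_gblup(y[trn], _grm_subset(grm, trn),
                       mcmc=MCMCConfig(seed=_seed(seed, 55, k), **mcmc_kwargs))
        out["gblup"].append(accuracy(y[tst], predict(sg, grm.submatrix(tst, trn))))
        sa = fit_bayes_a(y[trn], X[trn],
                         mcmc=MCMCConfig(seed=_seed(seed, 56, k), **mcmc_kwargs))
        out["bayes_a"].append(accuracy(y[tst], predict(sa, X[tst])))
        ss = fit_spike_slab(y[trn], X[trn],
                            mcmc=MCMCConfig(seed=_seed(seed, 57, k), **mcmc_kwargs))
        out["spike_slab"].append(accuracy(y[tst], predict(ss, X[tst])))
    return {m: float(np.mean(v)) for m, v in out.items()}


def data_used_degradation(
    n: int = 900,
    n_trn: int = 750,
    n_panel_markers: int = 600,
    n_qtl: int = 120,
    n_large: int = 12,
    pve_large: float = 0.75,
    n_replicates: int = 3,
    seed: int = 0,
    mcmc_kwargs: dict | None = None,
) -> dict[str, dict[str, float]]:
    """Mean test correlation by data-used set (QTL only, markers+QTL,
    markers only) for GBLUP and Spike-Slab under moderately weak marker-QTL
    LD: accuracy should degrade as causal genotypes are replaced by markers
    in imperfect LD."""
    mcmc_kwargs = {**dict(n_iter=6_000, burn_in=1_000, thin=5),
                   **(mcmc_kwargs or {})}
    arch = ArchitectureSpec(n_large=n_large, pve_large=pve_large,
                            target_h2=0.5, residual_variance=0.5)
    out = {m: {d: [] for d in ("qtl", "markers_qtl", "markers")}
           for m in ("gblup", "spike_slab")}
    for k in range(n_replicates):
        spec = HaplotypePoolSpec(
            n_blocks=40, markers_per_block=30,
            within_block_switch_prob=0.2, seed=_seed(seed, 61, k),
        )
        G = simulate_genotypes(spec, n)
        marker_idx, pool_idx = partition_markers_qtl(
            G, n_panel_markers, seed=_seed(seed, 62, k)
        )
        qtl, trait = simulate_scenario_trait(
            G, pool_idx, SamplingScheme.RAND, n_qtl, arch, seed=_seed(seed, 63, k)
        )
        y = trait.phenotypes
        rng = np.random.default_rng(_seed(seed, 64, k))
        perm = rng.permutation(n)
        trn, tst = perm[:n_trn], perm[n_trn:]
        loci = {
            "qtl": qtl.qtl_indices,
            "markers_qtl": np.sort(np.concatenate([marker_idx, qtl.qtl_indices])),
            "markers": marker_idx,
        }
        for di, (data_used, idx) in enumerate(loci.items()):
            X = G.dosages[:, idx].astype(float)
            grm = compute_grm(X)
            sg = fit_gblup(
                y[trn], _grm_subset(grm, trn),
                mcmc=MCMCConfig(seed=_seed(seed, 65, k, di), **mcmc_kwargs),
            )
            out["gblup"][data_used].append(
                accuracy(y[tst], predict(sg, grm.submatrix(tst, trn)))
            )
            ss = fit_spike_slab(
                y[trn], X[trn],
                mcmc=MCMCConfig(seed=_seed(seed, 66, k, di), **mcmc_kwargs),
            )
            out["spike_slab"][data_used].append(
                accuracy(y[tst], predict(ss, X[tst]))
            )
    return {m: {d: float(np.mean(v)) for d, v in per.items()}
            for m, per in out.items()}
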