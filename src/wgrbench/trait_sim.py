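"""Additive trait simulation: marker/QTL partition, QTL sampling schemes,
genetic-architecture scenarios and phenotype construction.

The trait model is y_i = sum_j Z_ij beta_j + eps_i with raw allele dosages
Z_ij in {0,1,2}, normal QTL effects and normal residuals.  Effect variances
are solved in closed form from the realized allele frequencies of the drawn
QTL so that, under Hardy-Weinberg / linkage-equilibrium expectations, the
genetic variance hits V_g = sigma_e^2 * h2 / (1 - h2) and the designated
large-effect QTL contribute the requested share (pve) of V_g.  Realized
heritability still varies across replicates through sampling noise and LD
among QTL; no post-hoc rescaling is applied unless explicitly requested.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

from .genotype_sim import GenotypeMatrix, minor_allele_frequencies


class SamplingScheme(str, Enum):
    RAND = "RAND"
    LOW_MAF = "LOW_MAF"


#: LOW-MAF stratification: 75% of QTL with MAF < 0.05, 25% with MAF in
#: [0.05, 0.15), none above 0.15.
LOW_MAF_STRATA: tuple[tuple[tuple[float, float], float], ...] = (
    ((0.0, 0.05), 0.75),
    ((0.05, 0.15), 0.25),
)


class StratumExhaustedError(RuntimeError):
    """A MAF stratum does not contain enough pool loci to fill its quota."""


@dataclass(frozen=True)
class QTLSample:
    pool_indices: np.ndarray
    qtl_indices: np.ndarray
    scheme: SamplingScheme
    seed: int

    def __post_init__(self) -> None:
        if not np.isin(self.qtl_indices, self.pool_indices).all():
            raise ValueError("qtl_indices must be a subset of pool_indices")
        if np.unique(self.qtl_indices).size != self.qtl_indices.size:
            raise ValueError("duplicate QTL indices")


@dataclass(frozen=True)
class ArchitectureSpec:
    """Genetic architecture: how many large-effect QTL and how much genetic
    variance they carry.

    ``n_large = 0`` with ``pve_large = 0`` is the infinitesimal architecture
    (all effects exchangeable from one normal).
    """

    n_large: int = 0
    pve_large: float = 0.0
    target_h2: float = 0.5
    residual_variance: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 <= self.pve_large <= 1.0:
            raise ValueError("pve_large must be in [0, 1]")
        if (self.n_large == 0) != (self.pve_large == 0.0):
            raise ValueError("n_large = 0 iff pve_large = 0")
        if not 0.0 < self.target_h2 < 1.0:
            raise ValueError("target_h2 must be in (0, 1)")
        if self.residual_variance <= 0:
            raise ValueError("residual_variance must be positive")

    @property
    def genetic_variance(self) -> float:
        """Target V_g implied by h2 and the residual variance."""
        return self.residual_variance * self.target_h2 / (1.0 - self.target_h2)


@dataclass
class TraitRealization:
    effects: np.ndarray
    large_set: np.ndarray
    genetic_values: np.ndarray
    residuals: np.ndarray
    phenotypes: np.ndarray
    realized_h2: float
    realized_pve: float


def partition_markers_qtl(
    G: GenotypeMatrix | int, n_markers: int, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Randomly split loci into a marker set and a QTL pool (disjoint,
    exhaustive, deterministic given the seed)."""
    total = G if isinstance(G, (int, np.integer)) else G.n_markers
    if n_markers >= total:
        raise ValueError("n_markers must be smaller than the number of loci")
    perm = np.random.default_rng(seed).permutation(total)
    return np.sort(perm[:n_markers]), np.sort(perm[n_markers:])


def sample_qtl(
    pool_mafs: np.ndarray,
    scheme: SamplingScheme | str,
    n_qtl: int,
    strata: tuple = LOW_MAF_STRATA,
    seed: int = 0,
    pool_indices: np.ndarray | None = None,
) -> QTLSample:
    """Draw QTL from a pool, uniformly (RAND) or stratified by MAF (LOW_MAF).

    Stratum quotas are target_proportion * n_qtl rounded to integers, with the
    last stratum absorbing the rounding remainder.  Loci above the top stratum
    bound are never sampled under LOW_MAF.
    """
    scheme = SamplingScheme(scheme)
    pool_mafs = np.asarray(pool_mafs)
    if pool_indices is None:
        pool_indices = np.arange(pool_mafs.size)
    pool_indices = np.asarray(pool_indices)
    if n_qtl > pool_mafs.size:
        raise ValueError("n_qtl exceeds pool size")
    rng = np.random.default_rng(seed)
    if scheme is SamplingScheme.RAND:
        chosen = rng.choice(pool_mafs.size, size=n_qtl, replace=False)
    else:
        counts = [int(round(prop * n_qtl)) for (_, prop) in strata]
        counts[-1] = n_qtl - sum(counts[:-1])
        chosen_parts = []
        for ((low, high), _), count in zip(strata, counts):
            members = np.flatnonzero((pool_mafs >= low) & (pool_mafs < high))
            if members.size < count:
                raise StratumExhaustedError(
                    f"stratum MAF in [{low}, {high}) has {members.size} loci, "
                    f"needs {count}"
                )
            chosen_parts.append(rng.choice(members, size=count, replace=False))
        chosen = np.concatenate(chosen_parts)
    return QTLSample(
        pool_indices=pool_indices,
        qtl_indices=np.sort(pool_indices[chosen]),
        scheme=scheme,
        seed=seed,
    )


def solve_effect_variances(
    qtl_mafs: np.ndarray, large_set: np.ndarray, arch: ArchitectureSpec
) -> tuple[float, float]:
    """Closed-form effect variances hitting V_g and the pve partition.

    Under HWE/LE, a QTL with frequency p and effect variance s2 contributes
    2 p (1-p) s2 to the genetic variance, so
        sigma2_L = pve * V_g / sum_large 2p(1-p)
        sigma2_S = (1 - pve) * V_g / sum_small 2p(1-p).
    """
    qtl_mafs = np.asarray(qtl_mafs, dtype=float)
    het = 2.0 * qtl_mafs * (1.0 - qtl_mafs)
    if het.sum() <= 0:
        raise ValueError("all QTL monomorphic; cannot scale effects")
    is_large = np.zeros(qtl_mafs.size, dtype=bool)
    is_large[np.asarray(large_set, dtype=int)] = True
    v_g = arch.genetic_variance
    if arch.n_large == 0:
        return 0.0, v_g / het.sum()
    denom_l = het[is_large].sum()
    denom_s = het[~is_large].sum()
    if denom_l <= 0 or (denom_s <= 0 and arch.pve_large < 1.0):
        raise ValueError("monomorphic effect stratum")
    sigma2_l = arch.pve_large * v_g / denom_l
    sigma2_s = 0.0 if arch.pve_large == 1.0 else (1.0 - arch.pve_large) * v_g / denom_s
    return sigma2_l, sigma2_s


def assign_effects(
    qtl_mafs: np.ndarray, arch: ArchitectureSpec, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Draw normal QTL effects under the architecture scenario.

    The large-effect set is drawn uniformly among the QTL, independent of
    MAF.  Returns (effects, large_set indices into the QTL vector).
    """
    qtl_mafs = np.asarray(qtl_mafs, dtype=float)
    n_qtl = qtl_mafs.size
    if arch.n_large > n_qtl:
        raise ValueError("n_large exceeds the number of QTL")
    rng = np.random.default_rng(seed)
    large_set = np.sort(rng.choice(n_qtl, size=arch.n_large, replace=False))
    sigma2_l, sigma2_s = solve_effect_variances(qtl_mafs, large_set, arch)
    effects = rng.normal(0.0, np.sqrt(sigma2_s) if sigma2_s > 0 else 0.0, size=n_qtl)
    if arch.n_large:
        effects[large_set] = rng.normal(0.0, np.sqrt(sigma2_l), size=arch.n_large)
    return effects, large_set


def simulate_phenotypes(
    Z: np.ndarray,
    effects: np.ndarray,
    residual_variance: float,
    seed: int,
    large_set: np.ndarray | None = None,
    exact_h2: float | None = None,
) -> TraitRealization:
    """Construct phenotypes y = Z beta + eps with iid normal residuals.

    ``exact_h2`` (unit-test helper) rescales the effect vector so the realized
    heritability equals the given value exactly; by default effects are used
    as drawn and the realized h2 varies with Monte Carlo noise.
    """
    Z = np.asarray(Z, dtype=float)
    effects = np.asarray(effects, dtype=float)
    if Z.shape[1] != effects.size:
        raise ValueError("dosage matrix and effect vector dimensions differ")
    rng = np.random.default_rng(seed)
    residuals = rng.normal(0.0, np.sqrt(residual_variance), size=Z.shape[0])
    g = Z @ effects
    if exact_h2 is not None:
        # solve s so that var(s g) / var(s g + eps) = exact_h2, accounting
        # for the sample covariance between g and eps
        h = exact_h2
        v_g, v_e = g.var(), residuals.var()
        c = np.mean((g - g.mean()) * (residuals - residuals.mean()))
        if v_g <= 0:
            raise ValueError("cannot rescale a zero-variance genetic signal")
        scale = (h * c + np.sqrt(h * h * c * c + h * (1 - h) * v_g * v_e)) / (
            v_g * (1 - h)
        )
        effects = effects * scale
        g = Z @ effects
    y = g + residuals
    if large_set is not None and np.asarray(large_set).size:
        large_set = np.asarray(large_set, dtype=int)
        small = np.setdiff1d(np.arange(effects.size), large_set)
        var_l = (Z[:, large_set] @ effects[large_set]).var()
        var_s = (Z[:, small] @ effects[small]).var()
        realized_pve = var_l / (var_l + var_s) if (var_l + var_s) > 0 else 0.0
    else:
        large_set = np.array([], dtype=int)
        realized_pve = 0.0
    return TraitRealization(
        effects=effects,
        large_set=large_set,
        genetic_values=g,
        residuals=residuals,
        phenotypes=y,
        realized_h2=float(g.var() / y.var()) if y.var() > 0 else 0.0,
        realized_pve=float(realized_pve),
    )


def simulate_scenario_trait(
    G: GenotypeMatrix,
    pool_idx: np.ndarray,
    scheme: SamplingScheme | str,
    n_qtl: int,
    arch: ArchitectureSpec,
    seed: int,
) -> tuple[QTLSample, TraitRealization]:
    """Convenience: sample QTL from a pool of panel loci and simulate a trait."""
    pool_idx = np.asarray(pool_idx)
    pool_mafs = minor_allele_frequencies(G.dosages[:, pool_idx])
    qtl = sample_qtl(
        pool_mafs, scheme, n_qtl, seed=seed, pool_indices=pool_idx
    )
    Z = G.dosages[:, qtl.qtl_indices].astype(float)
    qtl_mafs = minor_allele_frequencies(Z)
    effects, large_set = assign_effects(qtl_mafs, arch, seed=seed + 1)
    trait = simulate_phenotypes(
        Z, effects, arch.residual_variance, seed=seed + 2, large_set=large_set
    )
    return qtl, trait
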