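"""Synthetic diploid SNP panels with block LD structure and a tunable MAF spectrum.

The generator uses a founder-mosaic haplotype model: within each LD block a
small pool of founder haplotypes is constructed, and each sampled haplotype is
a mosaic of founders with a per-adjacent-marker switch probability.  A switch
probability of 0 forces every marker in a block onto the same founder (perfect
LD between same-frequency markers); a switch probability of 0.5 gives, in
effect, free recombination.  Blocks are independent by construction: the
founder mosaic resets between blocks.

Founder alleles are generated by a frequency-threshold rule: founder ``f``
carries the minor allele at marker ``m`` iff its (per-block shuffled) quantile
lies below the marker's target frequency.  This makes the founder-pool allele
frequency track the target frequency up to 1/(2*n_founders) quantization and
makes markers with equal target frequency perfectly correlated in the founder
pool, which is what gives the mosaic its high-LD regime.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd


class MonomorphicPanelError(RuntimeError):
    """Raised when a degenerate MAF law keeps producing monomorphic loci."""


@dataclass(frozen=True)
class MAFLaw:
    """Parametric law for minor-allele frequencies on (0, 0.5].

    family:
        ``"uniform"``  -- uniform on [low, high];
        ``"beta"``     -- Beta(a, b) rescaled from (0, 1) to (low, high);
        ``"mixture"``  -- finite mixture of other MAFLaw components.
    """

    family: str = "beta"
    low: float = 0.005
    high: float = 0.5
    a: float = 1.0
    b: float = 1.0
    components: tuple["MAFLaw", ...] = ()
    weights: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if self.family not in ("uniform", "beta", "mixture"):
            raise ValueError(f"unknown MAF law family {self.family!r}")
        if self.family == "mixture":
            if not self.components or len(self.components) != len(self.weights):
                raise ValueError("mixture law needs matching components and weights")
            if not np.isclose(sum(self.weights), 1.0):
                raise ValueError("mixture weights must sum to 1")
        else:
            if not (0.0 <= self.low < self.high <= 0.5):
                raise ValueError("MAF law support must satisfy 0 <= low < high <= 0.5")
            if self.family == "beta" and (self.a <= 0 or self.b <= 0):
                raise ValueError("beta shape parameters must be positive")

    def sample(self, size: int, rng: np.random.Generator) -> np.ndarray:
        if self.family == "uniform":
            return rng.uniform(self.low, self.high, size)
        if self.family == "beta":
            return self.low + (self.high - self.low) * rng.beta(self.a, self.b, size)
        choice = rng.choice(len(self.components), size=size, p=np.asarray(self.weights))
        out = np.empty(size)
        for k, comp in enumerate(self.components):
            idx = np.flatnonzero(choice == k)
            out[idx] = comp.sample(idx.size, rng)
        return out


#: Common-variant spectrum for marker loci (median ~0.22, mimicking a
#: genotyping array after a MAF >= 0.01 quality filter).
COMMON_MARKER_LAW = MAFLaw("beta", low=0.005, high=0.5, a=1.0, b=1.2)

#: Low-frequency-enriched spectrum for a QTL pool (most mass below 0.15).
LOW_MAF_POOL_LAW = MAFLaw("beta", low=0.005, high=0.5, a=0.5, b=3.5)

#: Mixture used for whole panels from which a QTL pool will be drawn: keeps a
#: common-variant marker spectrum while guaranteeing enough rare loci to fill
#: the LOW-MAF sampling strata at desk scale.
PANEL_MIXTURE_LAW = MAFLaw(
    "mixture",
    components=(COMMON_MARKER_LAW, LOW_MAF_POOL_LAW),
    weights=(0.7, 0.3),
)


@dataclass(frozen=True)
class HaplotypePoolSpec:
    """Specification of the founder-mosaic haplotype pool.

    ``within_block_switch_prob`` is the per-adjacent-marker probability that a
    haplotype re-draws its founder, and is the single knob controlling how
    fast r^2 decays with marker distance inside a block.
    """

    n_founder_haplotypes: int = 200
    n_blocks: int = 10
    markers_per_block: int = 50
    within_block_switch_prob: float = 0.05
    maf_law: MAFLaw = field(default_factory=lambda: COMMON_MARKER_LAW)
    seed: int = 0
    #: probability that an adjacent marker reuses the previous marker's target
    #: frequency; with identical frequencies the founder-threshold rule gives
    #: those neighbours r^2 -> 1 at low switch probability, mimicking the very
    #: strong flanking LD of dense arrays.
    freq_autocorr: float = 0.0

    def __post_init__(self) -> None:
        if min(self.n_founder_haplotypes, self.n_blocks, self.markers_per_block) < 1:
            raise ValueError("counts must be positive")
        if not 0.0 <= self.within_block_switch_prob <= 1.0:
            raise ValueError("within_block_switch_prob must be in [0, 1]")
        if not 0.0 <= self.freq_autocorr <= 1.0:
            raise ValueError("freq_autocorr must be in [0, 1]")

    @property
    def n_markers(self) -> int:
        return self.n_blocks * self.markers_per_block


@dataclass
class GenotypeMatrix:
    """n_individuals x n_markers allele-dosage matrix with marker metadata."""

    dosages: np.ndarray
    marker_ids: np.ndarray
    chromosome: np.ndarray
    position_bp: np.ndarray
    allele_labels: np.ndarray
    individual_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be a 2-D matrix")
        if not np.isin(self.dosages, (0, 1, 2)).all():
            raise ValueError("dosages must take values in {0, 1, 2}")
        p = self.dosages.shape[1]
        for name in ("marker_ids", "chromosome", "position_bp"):
            arr = np.asarray(getattr(self, name))
            if arr.shape[0] != p:
                raise ValueError(f"{name} length must equal the number of markers")
            setattr(self, name, arr)
        self.allele_labels = np.asarray(self.allele_labels).reshape(p, 2)
        if np.unique(self.marker_ids).size != p:
            raise ValueError("duplicate marker_ids")
        for chrom in np.unique(self.chromosome):
            pos = self.position_bp[self.chromosome == chrom]
            if pos.size > 1 and not (np.diff(pos) > 0).all():
                raise ValueError(f"positions not strictly increasing on chromosome {chrom}")
        if self.individual_ids is None:
            self.individual_ids = np.array(
                [f"ind_{i + 1:05d}" for i in range(self.dosages.shape[0])]
            )
        self.individual_ids = np.asarray(self.individual_ids)
        if self.individual_ids.shape[0] != self.dosages.shape[0]:
            raise ValueError("individual_ids length must equal the number of individuals")

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_markers(self) -> int:
        return self.dosages.shape[1]

    def subset_loci(self, idx: np.ndarray) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return GenotypeMatrix(
            dosages=self.dosages[:, idx],
            marker_ids=self.marker_ids[idx],
            chromosome=self.chromosome[idx],
            position_bp=self.position_bp[idx],
            allele_labels=self.allele_labels[idx],
            individual_ids=self.individual_ids,
        )

    def subset_individuals(self, idx: np.ndarray) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return GenotypeMatrix(
            dosages=self.dosages[idx],
            marker_ids=self.marker_ids,
            chromosome=self.chromosome,
            position_bp=self.position_bp,
            allele_labels=self.allele_labels,
            individual_ids=self.individual_ids[idx],
        )


def _founder_alleles(p_target: np.ndarray, quantiles: np.ndarray) -> np.ndarray:
    """Founder allele matrix (n_founders x n_markers) by frequency threshold."""
    return (quantiles[:, None] < p_target[None, :]).astype(np.int8)


def _mosaic_paths(
    n_haplotypes: int, n_markers: int, switch_prob: float, n_founders: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Founder-index path for each haplotype across a block.

    The switch probability acts like a recombination fraction: the founder is
    re-drawn (uniformly, so with no memory of the previous founder) with
    probability min(2 * switch_prob, 1), which makes 0.5 exactly free
    recombination and 0 a single founder per block.
    """
    draws = rng.integers(0, n_founders, size=(n_haplotypes, n_markers))
    if n_markers == 1:
        return draws
    redraw = min(2.0 * switch_prob, 1.0)
    switch = rng.random((n_haplotypes, n_markers)) < redraw
    switch[:, 0] = True
    cols = np.arange(n_markers)[None, :]
    last_switch = np.maximum.accumulate(np.where(switch, cols, 0), axis=1)
    rows = np.arange(n_haplotypes)[:, None]
    return draws[rows, last_switch]


def simulate_genotypes(spec: HaplotypePoolSpec, n_individuals: int) -> GenotypeMatrix:
    """Simulate a diploid SNP panel from a founder-mosaic haplotype pool.

    Monomorphic columns are regenerated with fresh target frequencies (keeping
    the already-drawn mosaic paths, so the LD structure of neighbouring loci
    is untouched).  If a degenerate ``maf_law`` keeps yielding monomorphic
    loci the failure is reported via :class:`MonomorphicPanelError` rather
    than passed downstream.
    """
    if n_individuals < 2:
        raise ValueError("need at least 2 individuals")
    rng = np.random.default_rng(spec.seed)
    F = spec.n_founder_haplotypes
    M = spec.markers_per_block
    blocks = []
    chroms = []
    positions = []
    for b in range(spec.n_blocks):
        quantiles = rng.permutation((np.arange(F) + 0.5) / F)
        p_target = spec.maf_law.sample(M, rng)
        if spec.freq_autocorr > 0 and M > 1:
            repeat = rng.random(M) < spec.freq_autocorr
            repeat[0] = False
            fill = np.maximum.accumulate(np.where(~repeat, np.arange(M), 0))
            p_target = p_target[fill]
        paths = _mosaic_paths(2 * n_individuals, M, spec.within_block_switch_prob, F, rng)
        cols = np.arange(M)[None, :]
        alleles = _founder_alleles(p_target, quantiles)
        hap = alleles[paths, cols]
        dose = hap[0::2] + hap[1::2]
        # regenerate monomorphic columns (same mosaic, fresh frequency); after
        # a few threshold-rule tries fall back to Bernoulli founder alleles,
        # since the carrier set under the threshold rule is fixed and may
        # never intersect the founders a column's paths visit
        for attempt in range(60):
            mono = np.flatnonzero(dose.min(axis=0) == dose.max(axis=0))
            if mono.size == 0:
                break
            p_new = spec.maf_law.sample(mono.size, rng)
            if attempt < 10:
                alleles[:, mono] = _founder_alleles(p_new, quantiles)
            else:
                alleles[:, mono] = (
                    rng.random((F, mono.size)) < p_new[None, :]
                ).astype(np.int8)
            hap_new = alleles[paths[:, mono], mono[None, :]]
            dose[:, mono] = hap_new[0::2] + hap_new[1::2]
        else:
            raise MonomorphicPanelError(
                "maf_law keeps producing monomorphic loci; panel not emitted"
            )
        blocks.append(dose.astype(np.int8))
        chroms.append(np.full(M, str(b + 1)))
        positions.append(10_000 * (np.arange(M) + 1))
    dosages = np.concatenate(blocks, axis=1)
    n_markers = spec.n_markers
    return GenotypeMatrix(
        dosages=dosages,
        marker_ids=np.array([f"snp_{j + 1:06d}" for j in range(n_markers)]),
        chromosome=np.concatenate(chroms),
        position_bp=np.concatenate(positions).astype(np.int64),
        allele_labels=np.tile(np.array([["A", "B"]]), (n_markers, 1)),
    )


def minor_allele_frequencies(G: GenotypeMatrix | np.ndarray) -> np.ndarray:
    """Per-locus minor allele frequency, folded to [0, 0.5]."""
    X = G.dosages if isinstance(G, GenotypeMatrix) else np.asarray(G)
    if X.shape[0] < 1:
        raise ValueError("need at least one individual")
    freq = X.mean(axis=0) / 2.0
    return np.minimum(freq, 1.0 - freq)


def maf_percentile_summary(
    mafs: np.ndarray, percentiles: tuple[float, ...] = (5, 10, 25, 50, 95)
) -> pd.DataFrame:
    """Empirical MAF percentiles, one column per requested percentile."""
    mafs = np.asarray(mafs)
    if mafs.size == 0:
        raise ValueError("empty MAF vector")
    values = np.percentile(mafs, percentiles)
    return pd.DataFrame([values], columns=[f"{q:g}%" for q in percentiles])
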