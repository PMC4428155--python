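"""Quality-control filters: per-SNP missingness, per-individual missingness,
and a minor-allele-frequency floor, applied in that order.

The order matters: MAF is computed after removing high-missingness SNPs and
individuals, so a borderline locus can change sides depending on who remains.
Missingness bounds are closed (>= threshold removes), the MAF bound is strict
(< maf_min removes).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genotype_sim import GenotypeMatrix


class EmptyPanelError(RuntimeError):
    """All loci or all individuals were removed by quality control."""


@dataclass(frozen=True)
class QCReport:
    n_snps_removed_missingness: int
    n_individuals_removed_missingness: int
    n_snps_removed_maf: int
    n_remaining_snps: int
    n_remaining_individuals: int
    snp_miss_max: float
    ind_miss_max: float
    maf_min: float

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def apply_qc(
    G: GenotypeMatrix,
    missing_mask: np.ndarray | None = None,
    snp_miss_max: float = 0.01,
    ind_miss_max: float = 0.05,
    maf_min: float = 0.01,
) -> tuple[GenotypeMatrix, np.ndarray, QCReport]:
    """Filter a panel; returns (filtered panel, filtered mask, report)."""
    for name, thr in (("snp_miss_max", snp_miss_max),
                      ("ind_miss_max", ind_miss_max), ("maf_min", maf_min)):
        if not 0.0 <= thr <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1]")
    n0, p0 = G.dosages.shape
    if missing_mask is None:
        missing_mask = np.zeros((n0, p0), dtype=bool)
    missing_mask = np.asarray(missing_mask, dtype=bool)

    # 1. SNPs by missingness (closed bound: >= removes)
    snp_keep = np.flatnonzero(missing_mask.mean(axis=0) < snp_miss_max)
    n_snp_miss = p0 - snp_keep.size
    G = G.subset_loci(snp_keep)
    mask = missing_mask[:, snp_keep]

    # 2. individuals by missingness on the surviving SNPs
    if G.n_markers == 0:
        raise EmptyPanelError("all SNPs removed by the missingness filter")
    ind_keep = np.flatnonzero(mask.mean(axis=1) < ind_miss_max)
    n_ind_miss = n0 - ind_keep.size
    if ind_keep.size == 0:
        raise EmptyPanelError("all individuals removed by the missingness filter")
    G = G.subset_individuals(ind_keep)
    mask = mask[ind_keep]

    # 3. MAF floor, computed on non-missing calls of the remaining panel
    with np.errstate(invalid="ignore"):
        obs = np.where(mask, np.nan, G.dosages.astype(float))
        freq = np.nanmean(obs, axis=0) / 2.0
    maf = np.minimum(freq, 1.0 - freq)
    maf_keep = np.flatnonzero(maf >= maf_min)
    n_snp_maf = G.n_markers - maf_keep.size
    if maf_keep.size == 0:
        raise EmptyPanelError("all SNPs removed by the MAF filter")
    G = G.subset_loci(maf_keep)
    mask = mask[:, maf_keep]

    report = QCReport(
        n_snps_removed_missingness=n_snp_miss,
        n_individuals_removed_missingness=n_ind_miss,
        n_snps_removed_maf=n_snp_maf,
        n_remaining_snps=G.n_markers,
        n_remaining_individuals=G.n_individuals,
        snp_miss_max=snp_miss_max,
        ind_miss_max=ind_miss_max,
        maf_min=maf_min,
    )
    return G, mask, report


def mean_impute(G: GenotypeMatrix, missing_mask: np.ndarray) -> np.ndarray:
    """Dosage matrix with missing entries replaced by the locus mean
    (float output; used before model fitting on real-data panels)."""
    X = G.dosages.astype(float)
    mask = np.asarray(missing_mask, dtype=bool)
    if not mask.any():
        return X
    obs = np.where(mask, np.nan, X)
    col_means = np.nanmean(obs, axis=0)
    return np.where(mask, col_means, X)
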