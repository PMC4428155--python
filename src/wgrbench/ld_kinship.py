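"""Pairwise LD diagnostics, genomic relationship matrices, and the
relatedness filter used to build validation sets.

The GRM follows the VanRaden construction: dosages are centered by twice the
allele frequency and cross-multiplied, with denominator sum_j 2 p_j (1 - p_j),
so that the mean diagonal is ~1 under HWE and off-diagonals estimate genomic
relationships on the familiar scale (0.5 full sibs, 0.125 cousins, ...).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .genotype_sim import GenotypeMatrix


class ConstantLocusError(ValueError):
    """r^2 is undefined for a monomorphic dosage vector."""


class MonomorphicLocusError(ValueError):
    """The GRM denominator needs every locus to be polymorphic."""


@dataclass
class GRM:
    values: np.ndarray
    denominator: float
    individual_ids: np.ndarray
    source_loci: np.ndarray

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def submatrix(self, rows: np.ndarray, cols: np.ndarray | None = None) -> np.ndarray:
        cols = rows if cols is None else cols
        return self.values[np.ix_(np.asarray(rows), np.asarray(cols))]


@dataclass
class FlankingLDSummary:
    """Per-QTL r^2 with the flanking markers plus the usual summaries."""

    r2_values: np.ndarray
    mean: float
    sd: float
    quantiles: dict[float, float]

    @classmethod
    def from_values(cls, r2: np.ndarray) -> "FlankingLDSummary":
        r2 = np.asarray(r2, dtype=float)
        qs = (5, 25, 50, 75, 95)
        return cls(
            r2_values=r2,
            mean=float(r2.mean()) if r2.size else float("nan"),
            sd=float(r2.std(ddof=1)) if r2.size > 1 else float("nan"),
            quantiles={q: float(np.percentile(r2, q)) for q in qs} if r2.size else {},
        )


def pairwise_r2(x1: np.ndarray, x2: np.ndarray) -> float:
    """Squared Pearson correlation between two dosage vectors."""
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    if x1.shape != x2.shape:
        raise ValueError("dosage vectors must have equal length")
    if x1.std() == 0 or x2.std() == 0:
        raise ConstantLocusError("r^2 undefined for a constant dosage vector")
    r = np.corrcoef(x1, x2)[0, 1]
    return float(r * r)


def flanking_ld(
    G: GenotypeMatrix, marker_set: np.ndarray, qtl_set: np.ndarray
) -> FlankingLDSummary:
    """r^2 between each QTL and its two flanking markers (nearest by bp on
    each side, within the QTL's chromosome).

    Edge QTL with no marker on one side contribute only the existing flank.
    A marker sharing the QTL's position counts as the left flank (lower index
    wins).  Monomorphic columns are skipped rather than propagating NaN.
    """
    marker_set = np.asarray(marker_set)
    qtl_set = np.asarray(qtl_set)
    if np.intersect1d(marker_set, qtl_set).size:
        raise ValueError("marker and QTL sets must be disjoint")
    X = G.dosages
    values = []
    for chrom in np.unique(G.chromosome[qtl_set]):
        m_chr = marker_set[G.chromosome[marker_set] == chrom]
        q_chr = qtl_set[G.chromosome[qtl_set] == chrom]
        if m_chr.size == 0:
            continue
        order = np.argsort(G.position_bp[m_chr], kind="stable")
        m_chr = m_chr[order]
        m_pos = G.position_bp[m_chr]
        for q in q_chr:
            if X[:, q].std() == 0:
                continue
            k = int(np.searchsorted(m_pos, G.position_bp[q], side="right"))
            for flank in (m_chr[k - 1] if k > 0 else None,
                          m_chr[k] if k < m_chr.size else None):
                if flank is None or X[:, flank].std() == 0:
                    continue
                values.append(pairwise_r2(X[:, q], X[:, flank]))
    return FlankingLDSummary.from_values(np.asarray(values))


def compute_grm(
    X: np.ndarray | GenotypeMatrix,
    freqs: np.ndarray | None = None,
    weights: np.ndarray | None = None,
    individual_ids: np.ndarray | None = None,
    source_loci: np.ndarray | None = None,
) -> GRM:
    """Genomic relationship matrix G = Xc Xc' / sum_j 2 p_j (1 - p_j).

    ``freqs`` defaults to the sample allele frequencies; ``weights`` is a
    per-locus multiplier applied to the centered columns before the
    cross-product (hook for externally computed LD-adjusted weights).
    """
    if isinstance(X, GenotypeMatrix):
        if individual_ids is None:
            individual_ids = X.individual_ids
        X = X.dosages
    X = np.asarray(X, dtype=float)
    if freqs is None:
        freqs = X.mean(axis=0) / 2.0
    freqs = np.asarray(freqs, dtype=float)
    het = 2.0 * freqs * (1.0 - freqs)
    if (het <= 0).any():
        raise MonomorphicLocusError("monomorphic locus in GRM input")
    denom = float(het.sum())
    Xc = X - 2.0 * freqs
    if weights is not None:
        Xc = Xc * np.asarray(weights, dtype=float)
    values = (Xc @ Xc.T) / denom
    if individual_ids is None:
        individual_ids = np.array([f"ind_{i + 1:05d}" for i in range(X.shape[0])])
    if source_loci is None:
        source_loci = np.arange(X.shape[1])
    return GRM(
        values=values,
        denominator=denom,
        individual_ids=np.asarray(individual_ids),
        source_loci=np.asarray(source_loci),
    )


def filter_test_by_relatedness(G_cross: np.ndarray, threshold: float) -> np.ndarray:
    """Indices of candidate rows whose maximum relationship to any training
    individual does not exceed the threshold (the paper-style 1/8 bound)."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    G_cross = np.asarray(G_cross)
    keep = np.flatnonzero(G_cross.max(axis=1) <= threshold)
    if keep.size == 0:
        warnings.warn("relatedness filter retained no validation individuals")
    return keep
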