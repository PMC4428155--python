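"""Replicated training-testing validation with kinship filtering, accuracy
metrics, cross-method aggregation and paired comparisons.

The validation design follows the repeated-holdout scheme used for distantly
related individuals: each replicate randomly sets aside a candidate
validation group, then keeps only candidates whose maximum genomic
relationship to any training individual does not exceed a threshold
(default 1/8), so that prediction accuracy is not inflated by close
relatives straddling the split.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .ld_kinship import GRM, filter_test_by_relatedness


@dataclass(frozen=True)
class SplitPlan:
    replicate_id: int
    trn_indices: np.ndarray
    tst_candidate_indices: np.ndarray
    tst_retained_indices: np.ndarray
    threshold: float
    seed: int

    def __post_init__(self) -> None:
        if np.intersect1d(self.trn_indices, self.tst_candidate_indices).size:
            raise ValueError("training and candidate sets must be disjoint")
        if not np.isin(self.tst_retained_indices, self.tst_candidate_indices).all():
            raise ValueError("retained set must be a subset of the candidates")


def make_splits(
    n: int,
    n_tst_candidates: int,
    n_replicates: int,
    grm: GRM,
    threshold: float = 0.125,
    seed: int = 0,
) -> list[SplitPlan]:
    """Random disjoint TRN / TST-candidate splits with relatedness filtering.

    Deterministic given the seed; replicate seeds are derived from the master
    seed and recorded on each plan.  Raises if the filter empties every
    replicate's validation set.
    """
    if n_tst_candidates >= n:
        raise ValueError("n_tst_candidates must be smaller than n")
    master = np.random.default_rng(seed)
    rep_seeds = master.integers(0, 2**31 - 1, size=n_replicates)
    plans: list[SplitPlan] = []
    for rep, rep_seed in enumerate(rep_seeds):
        rng = np.random.default_rng(int(rep_seed))
        perm = rng.permutation(n)
        cand = np.sort(perm[:n_tst_candidates])
        trn = np.sort(perm[n_tst_candidates:])
        keep = filter_test_by_relatedness(grm.submatrix(cand, trn), threshold)
        plans.append(
            SplitPlan(
                replicate_id=rep,
                trn_indices=trn,
                tst_candidate_indices=cand,
                tst_retained_indices=cand[keep],
                threshold=threshold,
                seed=int(rep_seed),
            )
        )
    if all(p.tst_retained_indices.size == 0 for p in plans):
        raise RuntimeError("relatedness filter emptied every validation set")
    return plans


def _check_pair(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.size < 3:
        raise ValueError("need two equal-length vectors of at least 3 values")
    if a.std() == 0 or b.std() == 0:
        raise ValueError("correlation undefined for a constant vector")
    return a, b


def accuracy(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """Pearson product-moment correlation between observed and predicted."""
    a, b = _check_pair(y_true, y_pred)
    return float(np.corrcoef(a, b)[0, 1])


def training_r2(y_trn: np.ndarray, fitted: np.ndarray) -> float:
    """Squared correlation between training phenotypes and fitted values."""
    return accuracy(y_trn, fitted) ** 2


def pairwise_method_comparison(
    records: pd.DataFrame,
    value: str = "test_correlation",
    match_on: tuple[str, ...] = ("replicate_id",),
) -> pd.DataFrame:
    """Per-replicate paired differences between methods plus a two-sided
    Wilcoxon signed-rank test.

    Differences are matched on ``match_on`` (replicate id, plus scenario
    columns when several scenarios are pooled).  When every difference is
    zero the test is degenerate and reported as such (p = NaN).
    """
    match_on = [c for c in match_on if c in records.columns]
    methods = sorted(records["method"].unique())
    rows = []
    for i, ma in enumerate(methods):
        for mb in methods[i + 1:]:
            a = records[records["method"] == ma].set_index(match_on)[value]
            b = records[records["method"] == mb].set_index(match_on)[value]
            common = a.index.intersection(b.index)
            if len(common) != len(a) or len(common) != len(b):
                raise ValueError(f"unmatched replicates for pair ({ma}, {mb})")
            diff = (a.loc[common] - b.loc[common]).to_numpy()
            if np.allclose(diff, 0.0):
                stat, pval, degenerate = 0.0, float("nan"), True
            else:
                res = stats.wilcoxon(diff, alternative="two-sided")
                stat, pval, degenerate = float(res.statistic), float(res.pvalue), False
            rows.append(
                {
                    "method_a": ma,
                    "method_b": mb,
                    "n": diff.size,
                    "mean_diff": float(diff.mean()),
                    "q25": float(np.percentile(diff, 25)),
                    "median": float(np.median(diff)),
                    "q75": float(np.percentile(diff, 75)),
                    "statistic": stat,
                    "p_value": pval,
                    "degenerate": degenerate,
                }
            )
    return pd.DataFrame(rows)


def aggregate(records: pd.DataFrame) -> pd.DataFrame:
    """Mean/SD of heritability, training R2 and test correlation by
    scenario x method x data-used cell."""
    if records.empty:
        raise ValueError("no records to aggregate")
    keys = [c for c in ("scenario", "method", "data_used") if c in records.columns]
    metrics = [c for c in ("h2_estimate", "train_r2", "test_correlation")
               if c in records.columns]
    out = records.groupby(keys, as_index=False)[metrics].agg(["mean", "std"])
    out.columns = ["_".join(c).rstrip("_") for c in out.columns.to_flat_index()]
    return out


def verify_no_leak(plan: SplitPlan, grm: GRM) -> bool:
    """Post-hoc check that every retained TST individual respects the bound."""
    if plan.tst_retained_indices.size == 0:
        return True
    block = grm.submatrix(plan.tst_retained_indices, plan.trn_indices)
    return bool((block.max(axis=1) <= plan.threshold).all())
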