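"""Cross-validation folds, accuracy, Wilcoxon signed-rank, average ranks.

The benchmarking protocol this module implements scores each method by
classification accuracy under stratified k-fold cross-validation (or a fixed
train/test split), compares paired method scores with the Wilcoxon
signed-rank test, and summarizes many-method comparisons by the average rank
across datasets (rank 1 = best accuracy, midranks for ties; lower is
better).

The Wilcoxon test drops zero differences, uses midranks for tied absolute
differences, and computes the exact p-value by full enumeration of the 2^n
sign assignments for n <= 15, switching to the normal approximation with
continuity and tie correction for larger n.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "FoldAssignment",
    "ResultsTable",
    "make_folds",
    "accuracy",
    "wilcoxon_signed_rank",
    "average_rank",
]

_EXACT_N_MAX = 15


@dataclass(frozen=True)
class FoldAssignment:
    """Fold index per sample under a named protocol (5CV, 10CV or TrTe)."""

    assignment: np.ndarray
    n_folds: int
    protocol: str

    def fold_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.assignment == fold)


def make_folds(labels, n_folds: int = 5, protocol: str = "5CV", seed: int = 0,
               test_mask=None) -> FoldAssignment:
    """Stratified, seeded fold assignment.

    CV protocols stratify by class so per-class fold sizes differ by at most
    one.  ``TrTe`` instead encodes a fixed predefined partition: samples with
    ``test_mask`` true get fold 1 (test), the rest fold 0 (train).
    """
    labels = np.asarray(labels)
    if protocol == "TrTe":
        if test_mask is None:
            raise ValueError("TrTe protocol requires test_mask")
        assignment = np.asarray(test_mask).astype(int)
        return FoldAssignment(assignment, 2, "TrTe")
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2 for CV protocols")
    _, counts = np.unique(labels, return_counts=True)
    if counts.min() < n_folds:
        raise ValueError("a class has fewer samples than folds")
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    assignment = np.empty(len(labels), dtype=int)
    for fold, (_, test_idx) in enumerate(skf.split(np.zeros(len(labels)), labels)):
        assignment[test_idx] = fold
    return FoldAssignment(assignment, n_folds, protocol)


def accuracy(pred, labels) -> float:
    """Percent of samples whose argmax class equals the label.

    Accepts a ProbabilityMatrix or a raw (n, k) array; argmax ties break
    toward the lowest class index.
    """
    values = getattr(pred, "values", pred)
    values = np.asarray(values)
    labels = np.asarray(labels)
    if len(values) != len(labels):
        raise ValueError("prediction and label lengths differ")
    return float(100.0 * np.mean(values.argmax(axis=1) == labels))


def _signed_ranks(x, y):
    d = np.asarray(x, dtype=float) - np.asarray(y, dtype=float)
    d = d[d != 0.0]
    if d.size == 0:
        raise ValueError("all differences are zero")
    if d.size < 5:
        raise ValueError("need at least 5 nonzero differences")
    ranks = rankdata(np.abs(d))  # midranks for ties
    w_plus = float(np.sum(ranks[d > 0]))
    return d, ranks, w_plus


def wilcoxon_signed_rank(x, y, alternative: str = "two-sided") -> float:
    """Wilcoxon signed-rank p-value for paired scores.

    ``alternative='greater'`` tests whether x tends to exceed y.  Exact by
    enumeration of all sign assignments for n <= 15; normal approximation
    with continuity and tie correction otherwise.
    """
    if alternative not in ("two-sided", "greater", "less"):
        raise ValueError(f"unknown alternative {alternative!r}")
    d, ranks, w_plus = _signed_ranks(x, y)
    n = d.size
    if n <= _EXACT_N_MAX:
        # distribution of W+ over all 2^n equally likely sign patterns
        bits = (np.arange(2 ** n)[:, None] >> np.arange(n)) & 1
        sums = bits @ ranks
        eps = 1e-12
        p_ge = np.mean(sums >= w_plus - eps)
        p_le = np.mean(sums <= w_plus + eps)
        if alternative == "greater":
            return float(p_ge)
        if alternative == "less":
            return float(p_le)
        return float(min(1.0, 2.0 * min(p_ge, p_le)))
    mean = n * (n + 1) / 4.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    var = (n * (n + 1) * (2 * n + 1) / 24.0
           - np.sum(tie_counts ** 3 - tie_counts) / 48.0)
    sd = np.sqrt(var)
    from scipy.stats import norm
    if alternative == "greater":
        return float(norm.sf((w_plus - mean - 0.5) / sd))
    if alternative == "less":
        return float(norm.cdf((w_plus - mean + 0.5) / sd))
    z = (w_plus - mean - 0.5 * np.sign(w_plus - mean)) / sd
    return float(min(1.0, 2.0 * norm.sf(abs(z))))


@dataclass
class ResultsTable:
    """Accuracy values indexed by method (rows) and dataset (columns)."""

    accuracies: pd.DataFrame

    def __post_init__(self) -> None:
        vals = self.accuracies.to_numpy(dtype=float)
        finite = vals[np.isfinite(vals)]
        if finite.size and (finite.min() < 0 or finite.max() > 100):
            raise ValueError("accuracies must lie in [0, 100]")

    @classmethod
    def from_csv(cls, path) -> "ResultsTable":
        return cls(pd.read_csv(path, index_col=0))

    def to_csv(self, path, with_average: bool = True) -> None:
        df = self.accuracies.copy()
        if with_average:
            df["Avg"] = df.mean(axis=1)
        df.to_csv(path)

    def per_dataset_ranks(self) -> pd.DataFrame:
        """Rank per dataset: 1 = highest accuracy, midranks for ties."""
        if self.accuracies.isna().any().any():
            raise ValueError("table has missing cells")
        vals = self.accuracies.to_numpy(dtype=float)
        ranks = np.apply_along_axis(
            lambda col: rankdata(-col, method="average"), 0, vals)
        return pd.DataFrame(ranks, index=self.accuracies.index,
                            columns=self.accuracies.columns)


def average_rank(table: ResultsTable) -> pd.Series:
    """Average of the per-dataset ranks for each method (lower is better)."""
    ranks = table.per_dataset_ranks()
    return ranks.mean(axis=1).sort_values()
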