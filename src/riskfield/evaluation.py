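"""AUC with the Mann-Whitney tie-aware kernel, ROC curves, K-fold utilities.

AUC is defined pairwise: over all (case, control) score pairs, a case scoring
strictly above a control contributes 1, a tie contributes 0.5.  Production
uses midranks (O(n log n)); that is exactly equivalent to the double loop.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

__all__ = ["RocResult", "auc", "roc_curve", "kfold_split", "stratified_kfold"]


def _check(scores: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be 1-D and the same length")
    if not np.isin(labels, (0, 1)).all():
        raise ValueError("labels must be binary 0/1")
    if labels.min() == labels.max():
        raise ValueError("AUC needs at least one case and one control")
    return scores, labels.astype(bool)


def auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Probability (with half credit for ties) that a case outscores a control."""
    scores, case = _check(scores, labels)
    n1 = int(case.sum())
    n0 = case.size - n1
    ranks = rankdata(scores)  # midranks
    u = ranks[case].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


@dataclass
class RocResult:
    auc: float
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray

    @property
    def points(self) -> list[tuple[float, float]]:
        return list(zip(self.fpr.tolist(), self.tpr.tolist()))

    def to_tsv(self, path: str) -> None:
        import pandas as pd

        pd.DataFrame({"fpr": self.fpr, "tpr": self.tpr, "threshold": self.thresholds}).to_csv(
            path, sep="\t", index=False
        )


def roc_curve(scores: np.ndarray, labels: np.ndarray) -> RocResult:
    """ROC points at every unique score; trapezoidal area equals :func:`auc`."""
    from sklearn.metrics import roc_curve as _sk_roc

    scores, case = _check(scores, labels)
    fpr, tpr, thr = _sk_roc(case.astype(int), scores, drop_intermediate=False)
    if fpr[-1] != 1.0 or tpr[-1] != 1.0:  # pragma: no cover - sklearn guarantees this
        fpr = np.append(fpr, 1.0)
        tpr = np.append(tpr, 1.0)
        thr = np.append(thr, -np.inf)
    area = float(np.trapezoid(tpr, fpr))
    return RocResult(auc=area, fpr=fpr, tpr=tpr, thresholds=thr)


def kfold_split(n: int, K: int, seed: int) -> list[tuple[np.ndarray, np.ndarray]]:
    """Seeded random K-way partition; validation sizes differ by at most one."""
    if not 2 <= K <= n:
        raise ValueError(f"need 2 <= K <= n, got K={K}, n={n}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    folds = np.array_split(perm, K)
    out = []
    for val in folds:
        mask = np.ones(n, dtype=bool)
        mask[val] = False
        out.append((np.flatnonzero(mask), np.sort(val)))
    return out


def stratified_kfold(labels: np.ndarray, K: int, seed: int) -> list[tuple[np.ndarray, np.ndarray]]:
    """K folds with cases and controls spread as evenly as possible.

    Stratification avoids single-class validation folds in small or
    unbalanced samples; folds are a seeded random partition within each class.
    """
    labels = np.asarray(labels)
    n = labels.size
    if not 2 <= K <= n:
        raise ValueError(f"need 2 <= K <= n, got K={K}, n={n}")
    rng = np.random.default_rng(seed)
    assign = np.empty(n, dtype=np.intp)
    for cls in (0, 1):
        idx = np.flatnonzero(labels == cls)
        idx = rng.permutation(idx)
        assign[idx] = np.arange(idx.size) % K
    out = []
    for k in range(K):
        val = np.flatnonzero(assign == k)
        out.append((np.flatnonzero(assign != k), val))
    return out
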