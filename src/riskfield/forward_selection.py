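"""Greedy forward selection of (gene, weight scheme) pairs by AUC.

The algorithm starts from the covariate-only (null) model and at each step
tries every remaining gene under every configured weight scheme, refits gamma
for the enlarged model, and keeps the pair whose in-sample AUC is largest
(ties broken by gene input order, then scheme order UW < BETA < WSS < LOG).
Model size is then chosen by stratified K-fold cross-validation: each fold
re-runs the forward path on its training part, validation AUC is averaged per
model size, and the smallest size attaining the maximum mean validation AUC
wins.  The final model is the forward path of that size refit on all data.

Candidate evaluation never forms N x N similarity matrices: only the vectors
S_k y (row-centered in the default ``adjusted`` estimator; see frf_model) are
needed, computed as O(n m) matrix-vector products.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .data_io import compute_maf
from .evaluation import auc, stratified_kfold
from .exceptions import ModelFitError
from .frf_model import FRFModel, _design, _solve, fit_frf, fit_mean_model
from .similarity import (
    WeightScheme,
    cross_similarity_action,
    similarity_action,
    weight_vector,
)

__all__ = ["ForwardStep", "ForwardPath", "forward_step", "forward_path", "select_model_size", "forward_select"]

AUC_TIE_TOL = 1e-10


@dataclass
class ForwardStep:
    gene: str
    scheme: WeightScheme
    auc: float
    gamma: np.ndarray  # refit over all genes selected up to and including this step
    delta: np.ndarray = field(default_factory=lambda: np.empty(0))


@dataclass
class ForwardPath:
    steps: list[ForwardStep]
    cv_auc_by_size: np.ndarray | None = None
    cv_auc_se_by_size: np.ndarray | None = None
    chosen_size: int | None = None

    @property
    def selected(self) -> list[tuple[str, WeightScheme]]:
        k = len(self.steps) if self.chosen_size is None else self.chosen_size
        return [(s.gene, s.scheme) for s in self.steps[:k]]

    def to_tsv(self, path: str, header_lines: list[str] | None = None) -> None:
        with open(path, "w") as fh:
            for line in header_lines or []:
                fh.write(f"# {line}\n")
            fh.write("step\tgene\tscheme\tstep_auc\tcv_auc_mean\tcv_auc_se\tchosen\n")
            for i, s in enumerate(self.steps, start=1):
                have_cv = self.cv_auc_by_size is not None and i < len(self.cv_auc_by_size)
                cv = f"{self.cv_auc_by_size[i]:.6f}" if have_cv else "NA"
                se = (
                    f"{self.cv_auc_se_by_size[i]:.6f}"
                    if have_cv and self.cv_auc_se_by_size is not None
                    else "NA"
                )
                chosen = int(self.chosen_size is not None and i <= self.chosen_size)
                fh.write(f"{i}\t{s.gene}\t{s.scheme.name}\t{s.auc:.6f}\t{cv}\t{se}\t{chosen}\n")


class _KernelCache:
    """Per-training-set cache of frozen weights and the estimating-equation columns.

    Variants monomorphic in this training set are masked per gene (their
    MAF-based weights are undefined); the mask is shared across schemes.
    """

    def __init__(
        self,
        gene_dosages: dict[str, np.ndarray],
        schemes: list[WeightScheme],
        y: np.ndarray,
        mu: np.ndarray,
        covariates: np.ndarray | None,
        estimator: str = "adjusted",
        centered: bool = False,
    ) -> None:
        self.genes = list(gene_dosages)
        self.schemes = list(schemes)
        self.estimator = estimator
        self.y = np.asarray(y, dtype=np.float64)
        self.mu = np.asarray(mu, dtype=np.float64)
        self.r = self.y - self.mu
        self.X = _design(len(self.y), covariates) if estimator == "adjusted" else None
        n = len(self.y)
        self.masked: dict[str, np.ndarray] = {}
        self.kept: dict[str, np.ndarray] = {}
        self.weights: dict[tuple[str, str], np.ndarray] = {}
        self.z: dict[tuple[str, str], np.ndarray] = {}
        self.plain_target = self.r if centered else self.y
        for gene, d in gene_dosages.items():
            d = np.asarray(d, dtype=np.float64)
            maf = compute_maf(d)
            kept = np.flatnonzero(np.nan_to_num(maf, nan=0.0) > 0.0)
            if kept.size == 0:
                raise ModelFitError(f"gene {gene!r} has no polymorphic variant in this split")
            dm = d[:, kept]
            self.masked[gene] = dm
            self.kept[gene] = kept
            for scheme in schemes:
                w = weight_vector(maf[kept], scheme)
                self.weights[(gene, scheme.name)] = w
                if estimator == "adjusted":
                    rowmean = similarity_action(dm, w, np.ones(n)) / (n - 1)
                    self.z[(gene, scheme.name)] = similarity_action(dm, w, self.r) - rowmean * (
                        self.r.sum() - self.r
                    )
                else:
                    self.z[(gene, scheme.name)] = similarity_action(dm, w, self.plain_target)

    def fit(self, pairs: list[tuple[str, WeightScheme]]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Refit (delta, gamma) for a gene set; returns (delta, gamma, in-sample scores)."""
        Z = np.column_stack([self.z[(g, s.name)] for g, s in pairs])
        delta, gamma = _solve(Z, self.r, self.X, strict=False)
        scores = self.mu + Z @ gamma
        if self.X is not None:
            scores = scores + self.X @ delta
        return delta, gamma, scores

    def z_validation(self, gene: str, scheme: WeightScheme, val_dosages: np.ndarray) -> np.ndarray:
        """Estimating-equation column for validation subjects, frozen training weights.

        ``val_dosages`` uses the gene's full input column layout; the cache's
        training-time polymorphism mask is applied here.
        """
        d = np.asarray(val_dosages, dtype=np.float64)[:, self.kept[gene]]
        w = self.weights[(gene, scheme.name)]
        dm = self.masked[gene]
        if self.estimator == "adjusted":
            z = cross_similarity_action(dm, d, w, self.r)
            rowmean = cross_similarity_action(dm, d, w, np.ones(dm.shape[0])) / dm.shape[0]
            return z - rowmean * self.r.sum()
        return cross_similarity_action(dm, d, w, self.plain_target)


def forward_step(
    y: np.ndarray,
    covariates: np.ndarray | None,
    current: list[tuple[str, WeightScheme]],
    candidates: list[str],
    schemes: list[WeightScheme],
    gene_dosages: dict[str, np.ndarray],
    *,
    estimator: str = "adjusted",
    centered: bool = False,
    _cache: "_KernelCache | None" = None,
) -> tuple[str, WeightScheme, float]:
    """One greedy step: the (gene, scheme) pair maximizing in-sample AUC.

    Ties (within 1e-10) go to the earliest candidate gene, then the earliest
    scheme in the configured order.
    """
    if not candidates:
        raise ValueError("no candidate genes left")
    if not schemes:
        raise ValueError("no weight schemes configured")
    if _cache is None:
        y = np.asarray(y, dtype=np.float64)
        _, mu = fit_mean_model(y, covariates)
        _cache = _KernelCache(gene_dosages, schemes, y, mu, covariates, estimator, centered)
    y_int = _cache.y.astype(int)
    best: tuple[float, str, WeightScheme] | None = None
    failures: list[str] = []
    for gene in candidates:
        for scheme in schemes:
            try:
                _, _, scores = _cache.fit(current + [(gene, scheme)])
                a = auc(scores, y_int)
            except Exception as exc:  # aggregate and keep trying other candidates
                failures.append(f"{gene}/{scheme.name}: {exc}")
                continue
            if best is None or a > best[0] + AUC_TIE_TOL:
                best = (a, gene, scheme)
    if best is None:
        raise ModelFitError("every candidate fit failed: " + "; ".join(failures))
    return best[1], best[2], best[0]


def forward_path(
    y: np.ndarray,
    covariates: np.ndarray | None,
    gene_dosages: dict[str, np.ndarray],
    schemes: list[WeightScheme],
    max_size: int,
    *,
    estimator: str = "adjusted",
    centered: bool = False,
    _cache: "_KernelCache | None" = None,
) -> ForwardPath:
    """Run forward steps up to ``max_size`` genes, never revisiting a gene."""
    if max_size > len(gene_dosages):
        raise ValueError("max_size exceeds the number of genes")
    if _cache is None and max_size > 0:
        y = np.asarray(y, dtype=np.float64)
        _, mu = fit_mean_model(y, covariates)
        _cache = _KernelCache(gene_dosages, schemes, y, mu, covariates, estimator, centered)
    steps: list[ForwardStep] = []
    current: list[tuple[str, WeightScheme]] = []
    remaining = list(gene_dosages)
    for _ in range(max_size):
        gene, scheme, step_auc = forward_step(
            y, covariates, current, remaining, schemes, gene_dosages,
            estimator=estimator, centered=centered, _cache=_cache,
        )
        current.append((gene, scheme))
        remaining.remove(gene)
        delta, gamma, _ = _cache.fit(current)
        steps.append(ForwardStep(gene=gene, scheme=scheme, auc=step_auc, gamma=gamma, delta=delta))
    return ForwardPath(steps=steps)


def select_model_size(
    y: np.ndarray,
    covariates: np.ndarray | None,
    gene_dosages: dict[str, np.ndarray],
    schemes: list[WeightScheme],
    K: int = 5,
    seed: int = 0,
    max_size: int | None = None,
    *,
    estimator: str = "adjusted",
    centered: bool = False,
) -> ForwardPath:
    """Forward path with the model size chosen by K-fold cross-validation.

    Each fold re-runs the forward path on its training part and scores its
    validation part at every size (size 0 = mean model, AUC 0.5 by ties);
    the chosen size is the smallest one attaining the maximum mean validation
    AUC.  The returned path is refit on all data, annotated with
    ``cv_auc_by_size`` and ``chosen_size``.
    """
    if K < 2:
        raise ValueError("K must be at least 2")
    y = np.asarray(y, dtype=np.float64)
    if max_size is None:
        max_size = len(gene_dosages)
    folds = stratified_kfold(y.astype(int), K, seed)
    per_fold: list[np.ndarray] = []
    for tr, va in folds:
        y_va = y[va].astype(int)
        if y_va.min() == y_va.max():
            warnings.warn("validation fold has a single class; skipped")
            continue
        y_tr = y[tr]
        cov_tr = covariates[tr] if covariates is not None and np.size(covariates) else None
        cov_va = covariates[va] if covariates is not None and np.size(covariates) else None
        beta, mu_tr = fit_mean_model(y_tr, cov_tr)
        gd_tr = {g: np.asarray(d)[tr] for g, d in gene_dosages.items()}
        cache = _KernelCache(gd_tr, schemes, y_tr, mu_tr, cov_tr, estimator, centered)
        path = forward_path(
            y_tr, cov_tr, gd_tr, schemes, max_size,
            estimator=estimator, centered=centered, _cache=cache,
        )
        X_va = _design(va.size, cov_va)
        mu_va = 1.0 / (1.0 + np.exp(-(X_va @ beta)))
        zval = {
            (s.gene, s.scheme.name): cache.z_validation(
                s.gene, s.scheme, np.asarray(gene_dosages[s.gene])[va]
            )
            for s in path.steps
        }
        aucs = np.empty(max_size + 1)
        aucs[0] = auc(mu_va, y_va) if np.ptp(mu_va) > 0 else 0.5
        for size in range(1, max_size + 1):
            st = path.steps[size - 1]
            Zv = np.column_stack([zval[(p.gene, p.scheme.name)] for p in path.steps[:size]])
            scores = mu_va + Zv @ st.gamma
            if estimator == "adjusted":
                scores = scores + X_va @ st.delta
            aucs[size] = auc(scores, y_va)
        per_fold.append(aucs)
    if not per_fold:
        raise ModelFitError("every cross-validation fold was single-class")
    cv_mean = np.mean(per_fold, axis=0)
    cv_se = (
        np.std(per_fold, axis=0, ddof=1) / np.sqrt(len(per_fold))
        if len(per_fold) > 1
        else np.zeros_like(cv_mean)
    )
    best = cv_mean.max()
    chosen = int(np.flatnonzero(cv_mean >= best - AUC_TIE_TOL)[0])
    final = forward_path(
        y, covariates, gene_dosages, schemes, max_size, estimator=estimator, centered=centered
    )
    final.cv_auc_by_size = cv_mean
    final.cv_auc_se_by_size = cv_se
    final.chosen_size = chosen
    return final


def forward_select(
    y: np.ndarray,
    covariates: np.ndarray | None,
    gene_dosages: dict[str, np.ndarray],
    schemes: list[WeightScheme],
    K: int = 5,
    seed: int = 0,
    max_size: int | None = None,
    gene_variant_ids: dict[str, list[str]] | None = None,
    *,
    estimator: str = "adjusted",
    centered: bool = False,
) -> tuple[ForwardPath, FRFModel]:
    """Convenience wrapper: CV-sized forward selection plus the final refit model."""
    path = select_model_size(
        y, covariates, gene_dosages, schemes,
        K=K, seed=seed, max_size=max_size, estimator=estimator, centered=centered,
    )
    if path.chosen_size == 0:
        beta, mu = fit_mean_model(y, covariates)
        model = FRFModel(
            beta=beta,
            components=[],
            gamma=np.empty(0),
            train_y=np.asarray(y, dtype=np.int8),
            train_mu=mu,
            estimator=estimator,
            centered=centered,
        )
    else:
        model = fit_frf(
            y, covariates, gene_dosages, path.selected, gene_variant_ids,
            estimator=estimator, centered=centered, strict=False,
        )
    return path, model
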