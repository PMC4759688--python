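"""SVM comparators: raw-dosage SVM and the MSVM pre-selection pipeline.

MSVM screens each common variant (training MAF >= 0.05) with a two-sided
Fisher exact test on the 2x2 allele-count table (minor/major x case/control),
keeps those with p < 0.001, collapses each gene's rare variants (MAF < 0.05)
into a binary carrier indicator (the CMC construction), and trains a linear
support vector machine on the combined feature matrix.  The plain SVM uses
all raw dosages.  Decision values serve as real-valued risk scores for AUC.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from math import comb

import numpy as np

from .data_io import GenotypeMatrix
from .exceptions import ModelFitError

__all__ = [
    "MsvmFeatureSpec",
    "fisher_exact_2x2",
    "preselect_common",
    "cmc_collapse",
    "fit_svm",
    "fit_msvm",
    "SvmClassifier",
    "MsvmModel",
]

MAF_THRESHOLD = 0.05
P_THRESHOLD = 0.001


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher exact p-value by exact hypergeometric enumeration.

    All tables sharing the observed margins have probability
    C(r1, a) C(r2, c1 - a) / C(n, c1); the two-sided p sums those with
    probability <= the observed one.  The shared denominator makes the cutoff
    an exact integer comparison, so no floating-point rounding enters until
    the final division.  A zero margin makes every table equally (un)likely,
    so p = 1 is returned with a warning.
    """
    t = np.asarray(table)
    if t.shape != (2, 2) or np.any(t < 0) or not np.issubdtype(t.dtype, np.integer):
        raise ValueError("expected a 2x2 table of non-negative integers")
    a, b = int(t[0, 0]), int(t[0, 1])
    c, d = int(t[1, 0]), int(t[1, 1])
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    if min(r1, r2, c1, b + d) == 0:
        warnings.warn("Fisher table has a zero margin; p = 1")
        return 1.0
    lo, hi = max(0, c1 - r2), min(r1, c1)
    nums = [comb(r1, x) * comb(r2, c1 - x) for x in range(lo, hi + 1)]
    obs = nums[a - lo]
    return sum(v for v in nums if v <= obs) / comb(n, c1)


@dataclass
class MsvmFeatureSpec:
    """Frozen training-time feature recipe for MSVM."""

    selected_common_variants: list[str]
    collapse_genes: list[str]
    rare_variants_by_gene: dict[str, list[str]] = field(default_factory=dict)
    flip_mask: np.ndarray | None = None  # training minor-allele orientation
    maf_threshold: float = MAF_THRESHOLD
    p_threshold: float = P_THRESHOLD


def _oriented(g: GenotypeMatrix, flip: np.ndarray) -> np.ndarray:
    d = np.array(g.dosages, copy=True)
    d[:, flip] = 2.0 - d[:, flip]
    return d


def preselect_common(
    g: GenotypeMatrix,
    y: np.ndarray,
    maf_threshold: float = MAF_THRESHOLD,
    p_threshold: float = P_THRESHOLD,
) -> MsvmFeatureSpec:
    """Fisher screening of common variants plus the rare-collapse gene list.

    Allele-count tables: minor vs major allele counts in cases vs controls
    (2N alleles per group).  Rare variants (MAF below the threshold) are never
    tested; they enter through the per-gene CMC indicator instead.
    """
    y = np.asarray(y).astype(bool)
    p_coded = np.nanmean(g.dosages, axis=0) / 2.0
    flip = p_coded > 0.5
    d = _oriented(g, flip)
    maf = np.nanmean(d, axis=0) / 2.0
    common = maf >= maf_threshold
    n_case, n_ctrl = int(y.sum()), int((~y).sum())
    selected: list[str] = []
    for j in np.flatnonzero(common):
        a = int(round(d[y, j].sum()))
        b = int(round(d[~y, j].sum()))
        tab = np.array([[a, 2 * n_case - a], [b, 2 * n_ctrl - b]])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            p = fisher_exact_2x2(tab)
        if p < p_threshold:
            selected.append(g.variant_ids[j])
    rare_by_gene: dict[str, list[str]] = {}
    for j in np.flatnonzero(~common):
        gene = g.gene_of_variant.get(g.variant_ids[j])
        if gene is not None and maf[j] > 0:
            rare_by_gene.setdefault(gene, []).append(g.variant_ids[j])
    return MsvmFeatureSpec(
        selected_common_variants=selected,
        collapse_genes=sorted(rare_by_gene),
        rare_variants_by_gene=rare_by_gene,
        flip_mask=flip,
        maf_threshold=maf_threshold,
        p_threshold=p_threshold,
    )


def cmc_collapse(
    dosages_gene: np.ndarray, mafs: np.ndarray, maf_threshold: float = MAF_THRESHOLD
) -> np.ndarray:
    """Binary carrier indicator over a gene's rare variants (the CMC step).

    value_i = 1 iff subject i carries at least one minor allele at any rare
    variant; a gene with no rare variant yields an all-zero column (warned).
    """
    d = np.asarray(dosages_gene, dtype=np.float64)
    mafs = np.asarray(mafs, dtype=np.float64)
    if mafs.shape != (d.shape[1],):
        raise ValueError("MAF vector must align with the gene's variant columns")
    rare = mafs < maf_threshold
    if not rare.any():
        warnings.warn("gene has no rare variant; CMC column is all zero")
        return np.zeros(d.shape[0])
    return (d[:, rare] > 0).any(axis=1).astype(np.float64)


@dataclass
class SvmClassifier:
    """Thin wrapper around a fitted maximum-margin classifier."""

    svc: object
    feature_names: list[str] = field(default_factory=list)

    def decision_scores(self, features: np.ndarray) -> np.ndarray:
        return np.asarray(self.svc.decision_function(np.asarray(features, dtype=np.float64)))


def fit_svm(
    features: np.ndarray, y: np.ndarray, kernel: str = "linear", C: float = 1.0
) -> SvmClassifier:
    """Linear (by default) SVM on a precomputed feature matrix."""
    from sklearn.svm import SVC

    X = np.asarray(features, dtype=np.float64)
    y = np.asarray(y)
    if X.ndim != 2 or X.shape[1] == 0:
        raise ModelFitError("SVM needs a non-empty 2-D feature matrix")
    svc = SVC(kernel=kernel, C=C)
    svc.fit(X, y)
    return SvmClassifier(svc=svc)


@dataclass
class MsvmModel:
    spec: MsvmFeatureSpec
    classifier: SvmClassifier
    _col_of: dict[str, int] = field(default_factory=dict)

    def features(self, g: GenotypeMatrix) -> np.ndarray:
        """Build the MSVM feature matrix for any dataset with the frozen recipe."""
        col = {v: j for j, v in enumerate(g.variant_ids)}
        missing = [v for v in self.spec.selected_common_variants if v not in col]
        if missing:
            raise ModelFitError(f"new data lacks selected common variants, e.g. {missing[0]!r}")
        d = _oriented(g, self._realign_flip(g))
        blocks = []
        if self.spec.selected_common_variants:
            blocks.append(d[:, [col[v] for v in self.spec.selected_common_variants]])
        for gene in self.spec.collapse_genes:
            vids = [v for v in self.spec.rare_variants_by_gene[gene] if v in col]
            if not vids:
                blocks.append(np.zeros((g.n_subjects, 1)))
                continue
            blocks.append((d[:, [col[v] for v in vids]] > 0).any(axis=1).astype(np.float64)[:, None])
        if not blocks:
            raise ModelFitError("MSVM retained no features")
        return np.column_stack(blocks)

    def _realign_flip(self, g: GenotypeMatrix) -> np.ndarray:
        # Frozen training orientation, re-indexed to the new variant order.
        train_flip = dict(zip(self._col_of, self.spec.flip_mask))
        return np.array([bool(train_flip.get(v, False)) for v in g.variant_ids])

    def predict_scores(self, g: GenotypeMatrix) -> np.ndarray:
        return self.classifier.decision_scores(self.features(g))


def fit_msvm(
    g: GenotypeMatrix,
    y: np.ndarray,
    maf_threshold: float = MAF_THRESHOLD,
    p_threshold: float = P_THRESHOLD,
    C: float = 1.0,
) -> MsvmModel:
    """Fisher pre-selection + CMC collapsing + linear SVM.

    If the common-variant screen retains nothing, the model falls back to the
    CMC columns alone (with a warning).
    """
    spec = preselect_common(g, y, maf_threshold, p_threshold)
    if not spec.selected_common_variants:
        warnings.warn("no common variant passed pre-selection; using CMC features only")
    model = MsvmModel(spec=spec, classifier=None, _col_of={v: j for j, v in enumerate(g.variant_ids)})
    X = model.features(g)
    model.classifier = fit_svm(X, y, C=C)
    return model


def fit_svm_on_genotypes(g: GenotypeMatrix, y: np.ndarray, C: float = 1.0) -> SvmClassifier:
    """The plain comparator: linear SVM on all raw dosages."""
    return fit_svm(g.dosages, y, C=C)
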