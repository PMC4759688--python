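"""Synthetic case-control replicates with a rare-skewed MAF spectrum.

A replicate carries a configurable number of causal and noise genes of ~200
SNVs each.  Variant MAFs are log-uniform on [0.001, 0.5] (about 63% of mass
below MAF 0.05, matching the strong rare-variant skew of deep-sequencing
panels); genotypes are independent Binomial(2, MAF) draws (Hardy-Weinberg, no
linkage disequilibrium).  Phenotypes follow an additive logistic model over
the causal SNVs; the intercept is calibrated by root finding so the expected
prevalence hits its target, and the effect scale can be calibrated so the
true-linear-predictor ("oracle") AUC hits a target, since headline accuracy
is best stated relative to the information actually in the data.

Effect-size shapes S1-S4 mirror the four weight schemes: equal effects (S1),
Beta(1,25)-density weights (S2), 1/sqrt(q(1-q)) weights (S3), |log10 q|
weights (S4).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit

from .data_io import GenotypeMatrix, compute_maf
from .evaluation import auc
from .exceptions import CalibrationError

__all__ = [
    "SimConfig",
    "SimReplicate",
    "simulate_mafs",
    "simulate_genotypes",
    "assign_effects",
    "simulate_phenotypes",
    "calibrate_effect_scale",
    "make_replicate",
]

DISEASE_MODELS = ("S1", "S2", "S3", "S4")
#: fraction of a log-uniform([1e-3, 0.5]) draw below 0.05 (closed form)
LOG_UNIFORM_RARE_MASS = np.log10(0.05 / 0.001) / np.log10(0.5 / 0.001)


@dataclass
class SimConfig:
    """Study-design parameters for one synthetic replicate.

    Defaults reproduce the reference design: a 1092-subject panel split
    750 train / 342 test, 2 causal genes + 3 noise genes of 200 SNVs each,
    balanced prevalence.  ``effect_scale=None`` means "calibrate per replicate
    so the oracle linear-predictor AUC is ``oracle_auc_target``".
    """

    n_subjects: int = 1092
    n_causal_genes: int = 2
    n_noise_genes: int = 3
    snvs_per_gene: int = 200
    causal_fraction: float = 1.0 / 3.0
    disease_model: str = "S1"
    effect_scale: float | None = None
    oracle_auc_target: float = 0.80
    prevalence_target: float = 0.5
    train_fraction: float = 750.0 / 1092.0
    maf_low: float = 0.001
    maf_high: float = 0.5
    sign_flip_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.disease_model not in DISEASE_MODELS:
            raise ValueError(f"disease_model must be one of {DISEASE_MODELS}")
        if not 0.0 < self.causal_fraction <= 1.0:
            raise ValueError("causal_fraction must lie in (0, 1]")
        for name in ("n_subjects", "n_causal_genes", "n_noise_genes", "snvs_per_gene"):
            if getattr(self, name) < 0 or (name in ("n_subjects", "snvs_per_gene") and getattr(self, name) <= 0):
                raise ValueError(f"{name} must be positive")


@dataclass
class SimReplicate:
    """One synthetic dataset plus full generative provenance."""

    config: SimConfig
    genotypes: GenotypeMatrix
    gene_names: list[str]
    true_mafs: np.ndarray  # generating (designed) MAF per variant
    causal_mask: np.ndarray  # bool per variant
    effects: np.ndarray  # beta_l per variant, zero off the causal mask
    intercept: float
    effect_scale: float
    y: np.ndarray
    oracle_scores: np.ndarray = field(repr=False)
    train_idx: np.ndarray = field(repr=False)
    test_idx: np.ndarray = field(repr=False)

    def gene_dosages(self, idx: np.ndarray | None = None) -> dict[str, np.ndarray]:
        gd = {}
        for gene, cols in self.genotypes.gene_indices().items():
            d = self.genotypes.dosages[:, cols]
            gd[gene] = d if idx is None else d[idx]
        return {g: gd[g] for g in self.gene_names}

    @property
    def y_train(self) -> np.ndarray:
        return self.y[self.train_idx]

    @property
    def y_test(self) -> np.ndarray:
        return self.y[self.test_idx]


def simulate_mafs(
    m: int, rng: np.random.Generator | int, low: float = 0.001, high: float = 0.5
) -> np.ndarray:
    """Log-uniform MAFs on [low, high]; heavily skewed towards rare variants."""
    if m < 1:
        raise ValueError("need at least one variant")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    u = rng.uniform(np.log10(low), np.log10(high), size=m)
    return 10.0**u


def simulate_genotypes(
    n: int, mafs: np.ndarray, rng: np.random.Generator | int, max_resample: int = 10
) -> tuple[np.ndarray, np.ndarray]:
    """HWE dosages ~ Binomial(2, maf), independent across variants (no LD).

    Columns monomorphic in the sample are redrawn up to ``max_resample``
    times; stubborn ones are flagged in the returned keep mask (and should be
    dropped by the caller).
    """
    mafs = np.asarray(mafs, dtype=np.float64)
    if np.any(mafs <= 0) or np.any(mafs > 0.5):
        raise ValueError("MAFs must lie in (0, 0.5]")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    d = rng.binomial(2, mafs, size=(n, mafs.size)).astype(np.float64)
    for _ in range(max_resample):
        mono = np.flatnonzero(d.min(axis=0) == d.max(axis=0))
        if mono.size == 0:
            break
        d[:, mono] = rng.binomial(2, mafs[mono], size=(n, mono.size))
    keep = d.min(axis=0) != d.max(axis=0)
    if not keep.all():
        warnings.warn(f"{int((~keep).sum())} variants stayed monomorphic after resampling; dropping")
    return d, keep


def assign_effects(
    mafs: np.ndarray,
    causal_mask: np.ndarray,
    disease_model: str,
    effect_scale: float,
    sign_flip_fraction: float = 0.0,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Per-variant effect sizes under S1-S4; zero for non-causal variants."""
    mafs = np.asarray(mafs, dtype=np.float64)
    mask = np.asarray(causal_mask, dtype=bool)
    if mask.shape != mafs.shape:
        raise ValueError("causal mask and MAF vector lengths differ")
    beta = np.zeros_like(mafs)
    q = mafs[mask]
    if disease_model == "S1":
        base = np.ones_like(q)
    elif disease_model == "S2":
        from scipy.stats import beta as beta_dist

        base = beta_dist.pdf(q, 1, 25)
    elif disease_model == "S3":
        base = 1.0 / np.sqrt(q * (1.0 - q))
    elif disease_model == "S4":
        base = np.abs(np.log10(q))
    else:
        raise ValueError(f"unknown disease model {disease_model!r}")
    beta[mask] = effect_scale * base
    if sign_flip_fraction > 0.0:
        rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
        flip = rng.random(mask.sum()) < sign_flip_fraction
        sub = beta[mask]
        sub[flip] *= -1.0
        beta[mask] = sub
    return beta


def _calibrate_intercept(eta: np.ndarray, target: float) -> float:
    """beta0 such that mean logistic(beta0 + eta) == target, by Brent root finding."""
    if not 0.0 < target < 1.0:
        raise CalibrationError("prevalence target must lie in (0, 1)")

    def f(b0: float) -> float:
        return float(expit(b0 + eta).mean() - target)

    # bracket from the linear-predictor range: at lo every p ~ 0, at hi every p ~ 1
    lo = -float(np.max(eta)) - 40.0
    hi = -float(np.min(eta)) + 40.0
    if f(lo) > 0 or f(hi) < 0:  # pragma: no cover - logistic saturates inside the bracket
        raise CalibrationError("cannot bracket the prevalence intercept; reduce effect_scale")
    return float(brentq(f, lo, hi, xtol=1e-10))


def simulate_phenotypes(
    dosages: np.ndarray,
    effects: np.ndarray,
    rng: np.random.Generator | int,
    intercept: float | None = None,
    prevalence_target: float = 0.5,
) -> tuple[np.ndarray, float, np.ndarray]:
    """Additive logistic phenotypes: p_i = logistic(b0 + sum_l beta_l g_il).

    If ``intercept`` is None it is calibrated so that mean(p) equals the
    prevalence target (to well under +-0.01).  Returns (y, intercept, p).
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    eta = np.asarray(dosages, dtype=np.float64) @ np.asarray(effects, dtype=np.float64)
    if intercept is None:
        intercept = _calibrate_intercept(eta, prevalence_target)
    p = expit(intercept + eta)
    y = (rng.random(p.size) < p).astype(np.int8)
    return y, float(intercept), p


def calibrate_effect_scale(
    dosages: np.ndarray,
    base_effects: np.ndarray,
    rng: np.random.Generator | int,
    target_auc: float = 0.80,
    prevalence_target: float = 0.5,
    max_scale: float = 512.0,
    iterations: int = 60,
) -> float:
    """Bisect the effect scale so the oracle-score AUC hits ``target_auc``.

    The oracle score of subject i is its true linear predictor
    eta_i = sum_l beta_l g_il; for each candidate scale the intercept is
    re-calibrated, phenotypes are generated from one fixed uniform draw, and
    the AUC of eta against those phenotypes is measured.  AUC is monotone in
    the scale up to sampling steps, so bisection converges to the target.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    eta1 = np.asarray(dosages, dtype=np.float64) @ np.asarray(base_effects, dtype=np.float64)
    if np.ptp(eta1) == 0:
        raise CalibrationError("all oracle scores identical; no signal to calibrate")
    u = rng.random(eta1.size)  # frozen uniforms make the objective a deterministic step function

    def oracle_auc(c: float) -> float:
        b0 = _calibrate_intercept(c * eta1, prevalence_target)
        y = (u < expit(b0 + c * eta1)).astype(int)
        if y.min() == y.max():
            return 0.5
        return auc(eta1, y)

    lo, hi = 0.0, 1.0
    while oracle_auc(hi) < target_auc:
        hi *= 2.0
        if hi > max_scale:
            raise CalibrationError(
                f"oracle AUC {oracle_auc(max_scale):.3f} below target {target_auc} even at "
                f"scale {max_scale}; increase the causal burden or lower the target"
            )
    for _ in range(iterations):
        mid = 0.5 * (lo + hi)
        if oracle_auc(mid) < target_auc:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def make_replicate(config: SimConfig) -> SimReplicate:
    """Build one full replicate: genes, masks, effects, phenotypes, split."""
    ss = np.random.SeedSequence(config.seed)
    r_maf, r_geno, r_mask, r_scale, r_pheno, r_split, r_sign = [
        np.random.default_rng(s) for s in ss.spawn(7)
    ]
    gene_names = [f"C{i + 1}" for i in range(config.n_causal_genes)] + [
        f"N{i + 1}" for i in range(config.n_noise_genes)
    ]
    if not gene_names:
        raise ValueError("need at least one gene")

    blocks, vids, gov = [], [], {}
    true_mafs, causal_mask = [], []
    for gene in gene_names:
        mafs = simulate_mafs(config.snvs_per_gene, r_maf, config.maf_low, config.maf_high)
        d, keep = simulate_genotypes(config.n_subjects, mafs, r_geno)
        d, mafs = d[:, keep], mafs[keep]
        m = mafs.size
        mask = np.zeros(m, dtype=bool)
        if gene.startswith("C"):
            n_causal = max(1, round(m * config.causal_fraction))
            mask[r_mask.choice(m, size=n_causal, replace=False)] = True
        blocks.append(d)
        true_mafs.append(mafs)
        causal_mask.append(mask)
        ids = [f"{gene}_v{j + 1}" for j in range(m)]
        vids.extend(ids)
        gov.update({v: gene for v in ids})

    dosages = np.hstack(blocks)
    true_mafs = np.concatenate(true_mafs)
    causal_mask = np.concatenate(causal_mask)
    subject_ids = [f"S{i + 1}" for i in range(config.n_subjects)]

    base = assign_effects(
        true_mafs, causal_mask, config.disease_model, 1.0,
        config.sign_flip_fraction, r_sign,
    )
    if config.effect_scale is not None:
        scale = float(config.effect_scale)
    elif not causal_mask.any():
        scale = 0.0
    else:
        scale = calibrate_effect_scale(
            dosages, base, r_scale,
            target_auc=config.oracle_auc_target,
            prevalence_target=config.prevalence_target,
        )
    effects = scale * base
    y, intercept, p = simulate_phenotypes(
        dosages, effects, r_pheno, prevalence_target=config.prevalence_target
    )

    perm = r_split.permutation(config.n_subjects)
    n_train = int(round(config.n_subjects * config.train_fraction))
    train_idx = np.sort(perm[:n_train])
    test_idx = np.sort(perm[n_train:])

    g = GenotypeMatrix(dosages, subject_ids, vids, gov, maf=compute_maf(dosages))
    return SimReplicate(
        config=config,
        genotypes=g,
        gene_names=gene_names,
        true_mafs=true_mafs,
        causal_mask=causal_mask,
        effects=effects,
        intercept=intercept,
        effect_scale=scale,
        y=y,
        oracle_scores=dosages @ effects,
        train_idx=train_idx,
        test_idx=test_idx,
    )
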