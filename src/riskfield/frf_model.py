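"""The random-field conditional model for binary phenotypes.

Each subject's phenotype is modeled as its GLM mean plus a weighted sum of the
other subjects' phenotypes, the weights being gene-level genetic similarities:

    Y = mu + sum_k gamma_k S_k Y + e,       mu_i = logistic(X_i beta),

with S_k the k-th gene's similarity matrix (zero diagonal).  Given mu from an
independent-Bernoulli logistic fit, gamma is the root of the unbiased
estimating equations Z' (Y - mu - Z gamma) = 0 with identity working
covariance; the model is linear in gamma, so the root is a least-squares
solution.  A new subject a is scored as

    score_a = mu_a + sum_k gamma_k z_a^(k)

over the training subjects, using weights frozen at training time.  Scores
are real-valued risk scores used for ranking (AUC), not probabilities.

Two instantiations of the Z columns are provided:

``plain``
    z_k = S_k y (or S_k (y - mu) with ``centered=True``), the literal
    autoregressive form, solved without additional columns.

``adjusted`` (default)
    z_k,i = sum_{j != i} (s_ij - s-bar_i)(y_j - mu_j) with s-bar_i the row
    mean of the off-diagonal similarities, solved jointly with the
    mean-model design columns.  An IBS kernel has a large constant baseline
    (most pairs share most alleles), and the zero diagonal then injects a
    -s-bar (y_i - mu_i) self-exclusion term into S_k y whose magnitude
    swamps the genuine neighbor signal once mu is estimated: gamma acquires
    a systematic negative bias and in-sample scores track y_i even for
    noise genes.  Row-centering cancels that term exactly, and the design
    columns absorb the nonzero means of the z columns that the plain solve
    would otherwise cancel with offsetting gammas.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np

from .data_io import compute_maf
from .exceptions import ModelFitError, SingularModelError
from .similarity import (
    GeneSimilarity,
    WeightScheme,
    cross_similarity_action,
    similarity_matrix,
    weight_vector,
)

__all__ = [
    "GeneComponent",
    "FRFModel",
    "fit_mean_model",
    "estimate_gamma",
    "fit_frf",
    "predict",
    "save_model",
    "load_model",
]

GRADIENT_TOL = 1e-8
MAX_ITER = 100
ORTHOGONALITY_TOL = 1e-8
ESTIMATORS = ("adjusted", "plain")


@dataclass
class GeneComponent:
    """One selected gene: frozen weights, variant list and training dosages."""

    gene: str
    scheme: WeightScheme
    variant_ids: list[str]
    kept_columns: np.ndarray  # indices into the gene's input dosage columns
    weights: np.ndarray
    train_dosages: np.ndarray = field(repr=False)


@dataclass
class FRFModel:
    beta: np.ndarray
    components: list[GeneComponent]
    gamma: np.ndarray
    train_y: np.ndarray
    train_mu: np.ndarray
    delta: np.ndarray | None = None  # linear mean correction (adjusted estimator)
    covariate_names: list[str] = field(default_factory=list)
    estimator: str = "adjusted"
    centered: bool = False  # plain estimator only

    @property
    def genes(self) -> list[tuple[str, str]]:
        return [(c.gene, c.scheme.name) for c in self.components]

    def __post_init__(self) -> None:
        if len(self.gamma) != len(self.components):
            raise ModelFitError("gamma length must equal the number of gene components")
        if self.estimator not in ESTIMATORS:
            raise ModelFitError(f"estimator must be one of {ESTIMATORS}")


def _logistic(x):
    from scipy.special import expit

    return expit(x)


def _design(n: int, covariates: np.ndarray | None) -> np.ndarray:
    if covariates is None or np.size(covariates) == 0:
        return np.ones((n, 1))
    return np.column_stack([np.ones(n), np.asarray(covariates, dtype=np.float64)])


def fit_mean_model(
    y: np.ndarray, covariates: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Independent-Bernoulli logistic fit of the mean model.

    Returns (beta, mu) with beta = (intercept, covariate coefficients) and
    mu_i = logistic(intercept + X_i beta).  With no covariates this is the
    closed-form intercept-only fit, mu_i = mean(y).
    """
    y = np.asarray(y, dtype=np.float64)
    if not np.isin(y, (0, 1)).all():
        raise ModelFitError("phenotype must be binary 0/1")
    p = y.mean()
    if p in (0.0, 1.0):
        raise ModelFitError("phenotype has a single class; the logistic mean model is undefined")
    if covariates is None or np.size(covariates) == 0:
        beta = np.array([np.log(p / (1 - p))])
        return beta, np.full(y.shape, p)

    import statsmodels.api as sm

    X = _design(len(y), covariates)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name the pivoted-out columns (0 = intercept)
        _, r = np.linalg.qr(X)
        bad = [j for j in range(X.shape[1]) if abs(r[min(j, r.shape[0] - 1), j]) < 1e-10]
        raise ModelFitError(f"covariate design is rank deficient; suspect columns {bad}")
    with warnings.catch_warnings():
        warnings.simplefilter("error")
        try:
            res = sm.GLM(y, X, family=sm.families.Binomial()).fit(
                maxiter=MAX_ITER, tol=GRADIENT_TOL
            )
        except Exception as exc:
            raise ModelFitError(
                f"logistic mean model failed to converge ({exc}); check for separation "
                "or remove the offending covariate"
            ) from exc
    mu = np.asarray(res.fittedvalues, dtype=np.float64)
    if np.any(mu < 1e-10) or np.any(mu > 1 - 1e-10):
        raise ModelFitError(
            "fitted means at 0/1: covariates perfectly separate the phenotype; "
            "remove the offending covariate"
        )
    return np.asarray(res.params), mu


def _solve(
    Z: np.ndarray, r: np.ndarray, X: np.ndarray | None, strict: bool
) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares root of the estimating equations; returns (delta, gamma).

    With X given the solve is over [X, Z] and delta is the coefficient on X;
    otherwise delta is empty.
    """
    A = Z if X is None else np.hstack([X, Z])
    coef, _, rank, _ = np.linalg.lstsq(A, r, rcond=None)
    if rank < A.shape[1]:
        if strict:
            raise SingularModelError(
                f"estimating-equation design is singular (rank {rank} < {A.shape[1]}); "
                "check for duplicated genes or degenerate similarities"
            )
        warnings.warn("singular estimating-equation design; returning the minimum-norm solution")
    p = 0 if X is None else X.shape[1]
    return coef[:p], coef[p:]


def adjusted_z(sim_matrix: np.ndarray, resid: np.ndarray) -> np.ndarray:
    """Row-centered kernel column: z_i = sum_{j!=i} (s_ij - s-bar_i) resid_j."""
    n = sim_matrix.shape[0]
    rowmean = sim_matrix.sum(axis=1) / (n - 1)
    return sim_matrix @ resid - rowmean * (resid.sum() - resid)


def estimate_gamma(
    y: np.ndarray,
    mu: np.ndarray,
    sims: list[GeneSimilarity] | list[np.ndarray],
    *,
    centered: bool = False,
    strict: bool = True,
) -> np.ndarray:
    """Solve the plain estimating equations Z'(y - mu - Z gamma) = 0 for gamma.

    Z's k-th column is S_k y (or S_k (y - mu) in centered mode) and the
    least-squares solution satisfies Z'(y - mu - Z gamma-hat) = 0 to
    numerical tolerance.  In strict mode a rank-deficient Z (e.g. a
    duplicated gene/weight) is an error; otherwise the minimum-norm solution
    is returned with a warning.  This is the literal autoregressive form; the
    fitting pipelines default to the ``adjusted`` variant (see module notes).
    """
    y = np.asarray(y, dtype=np.float64)
    mu = np.asarray(mu, dtype=np.float64)
    if not sims:
        raise ValueError("need at least one gene similarity")
    mats = [s.matrix if isinstance(s, GeneSimilarity) else np.asarray(s, float) for s in sims]
    target = (y - mu) if centered else y
    Z = np.column_stack([m @ target for m in mats])
    _, gamma = _solve(Z, y - mu, None, strict)
    resid_orth = np.abs(Z.T @ (y - mu - Z @ gamma)).max()
    if resid_orth > ORTHOGONALITY_TOL * max(1.0, np.abs(Z).max() * len(y)):
        warnings.warn(f"estimating-equation residual not orthogonal to Z (max {resid_orth:.2e})")
    return gamma


def fit_frf(
    y: np.ndarray,
    covariates: np.ndarray | None,
    gene_dosages: dict[str, np.ndarray],
    gene_schemes: list[tuple[str, WeightScheme]],
    gene_variant_ids: dict[str, list[str]] | None = None,
    *,
    estimator: str = "adjusted",
    centered: bool = False,
    strict: bool = True,
) -> FRFModel:
    """Fit the full model: logistic mean, per-gene kernels, gamma.

    ``gene_schemes`` fixes both which genes enter and the model order of
    gamma.  Per gene, variants monomorphic in the training data are dropped
    (their weights are undefined) and training-MAF weights are frozen.
    """
    if not gene_schemes:
        raise ValueError("gene_schemes must name at least one (gene, scheme) pair")
    if estimator not in ESTIMATORS:
        raise ValueError(f"estimator must be one of {ESTIMATORS}")
    y = np.asarray(y, dtype=np.float64)
    beta, mu = fit_mean_model(y, covariates)
    r = y - mu
    components: list[GeneComponent] = []
    z_cols: list[np.ndarray] = []
    for gene, scheme in gene_schemes:
        if gene not in gene_dosages:
            raise KeyError(f"gene {gene!r} missing from gene_dosages")
        d = np.asarray(gene_dosages[gene], dtype=np.float64)
        maf = compute_maf(d)
        kept = np.flatnonzero(np.nan_to_num(maf, nan=0.0) > 0.0)
        if kept.size == 0:
            raise ModelFitError(f"gene {gene!r} has no polymorphic variant in the training data")
        d = d[:, kept]
        w = weight_vector(maf[kept], scheme)
        vids = (
            [gene_variant_ids[gene][j] for j in kept.tolist()]
            if gene_variant_ids and gene in gene_variant_ids
            else [f"{gene}:{j}" for j in kept.tolist()]
        )
        components.append(GeneComponent(gene, scheme, vids, kept, w, d))
        S = similarity_matrix(d, w, gene=gene, scheme=scheme).matrix
        if estimator == "adjusted":
            z_cols.append(adjusted_z(S, r))
        else:
            z_cols.append(S @ (r if centered else y))
    Z = np.column_stack(z_cols)
    if estimator == "adjusted":
        X = _design(len(y), covariates)
        delta, gamma = _solve(Z, r, X, strict)
    else:
        delta, gamma = _solve(Z, r, None, strict)
        delta = None
    return FRFModel(
        beta=beta,
        components=components,
        gamma=gamma,
        train_y=y.astype(np.int8),
        train_mu=mu,
        delta=delta,
        estimator=estimator,
        centered=centered,
    )


def predict(
    model: FRFModel,
    new_covariates: np.ndarray | None,
    new_gene_dosages: dict[str, np.ndarray],
) -> np.ndarray:
    """Risk scores for new subjects under a fitted model.

    score_a = mu_a (+ X_a delta) + sum_k gamma_k z_a^(k), with the mean from
    the frozen beta and similarities under the frozen training weights.  New
    gene matrices must have the same column layout as the training input (or
    already be restricted to the kept training variants).
    """
    if model.components:
        n_new = None
        for c in model.components:
            if c.gene not in new_gene_dosages:
                raise KeyError(f"gene {c.gene!r} missing from new data")
            n_new = np.asarray(new_gene_dosages[c.gene]).shape[0]
    else:
        if new_covariates is not None and np.size(new_covariates):
            n_new = np.asarray(new_covariates).shape[0]
        elif new_gene_dosages:
            n_new = np.asarray(next(iter(new_gene_dosages.values()))).shape[0]
        else:
            raise ValueError("cannot infer the number of new subjects")
    if new_covariates is None or np.size(new_covariates) == 0:
        if len(model.beta) != 1:
            raise ValueError("model was fit with covariates; new covariates required")
        mu_new = np.full(n_new, _logistic(model.beta[0]))
        X_new = np.ones((n_new, 1))
    else:
        X_new = _design(n_new, new_covariates)
        mu_new = _logistic(X_new @ model.beta)
    y_train = model.train_y.astype(np.float64)
    resid = y_train - model.train_mu
    scores = mu_new.astype(np.float64)
    if model.estimator == "adjusted" and model.delta is not None and model.components:
        scores = scores + X_new @ model.delta
    n_train = y_train.size
    for gamma_k, comp in zip(model.gamma, model.components):
        d_new = np.asarray(new_gene_dosages[comp.gene], dtype=np.float64)
        if d_new.shape[1] == len(comp.kept_columns):
            pass  # already restricted to the kept training variants
        elif d_new.shape[1] > int(comp.kept_columns.max()):
            d_new = d_new[:, comp.kept_columns]
        else:
            raise ValueError(
                f"gene {comp.gene!r}: new data has {d_new.shape[1]} variants, "
                f"expected the training layout ({len(comp.kept_columns)} kept columns)"
            )
        if model.estimator == "adjusted":
            z = cross_similarity_action(comp.train_dosages, d_new, comp.weights, resid)
            rowmean = (
                cross_similarity_action(comp.train_dosages, d_new, comp.weights, np.ones(n_train))
                / n_train
            )
            z = z - rowmean * resid.sum()
        else:
            target = resid if model.centered else y_train
            z = cross_similarity_action(comp.train_dosages, d_new, comp.weights, target)
        scores = scores + gamma_k * z
    return scores


def save_model(model: FRFModel, path: str) -> None:
    """Serialize a fitted model losslessly to JSON."""
    doc = {
        "format": "riskfield-frf-model",
        "version": 1,
        "beta": model.beta.tolist(),
        "covariate_names": model.covariate_names,
        "estimator": model.estimator,
        "centered": model.centered,
        "delta": None if model.delta is None else model.delta.tolist(),
        "gamma": model.gamma.tolist(),
        "train_y": model.train_y.astype(int).tolist(),
        "train_mu": model.train_mu.tolist(),
        "components": [
            {
                "gene": c.gene,
                "scheme": {"name": c.scheme.name, "beta_a": c.scheme.beta_a, "beta_b": c.scheme.beta_b},
                "variant_ids": c.variant_ids,
                "kept_columns": c.kept_columns.tolist(),
                "weights": c.weights.tolist(),
                "train_dosages": c.train_dosages.tolist(),
            }
            for c in model.components
        ],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


def load_model(path: str) -> FRFModel:
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("format") != "riskfield-frf-model":
        raise ValueError(f"{path} is not a riskfield model file")
    comps = [
        GeneComponent(
            gene=c["gene"],
            scheme=WeightScheme(c["scheme"]["name"], c["scheme"]["beta_a"], c["scheme"]["beta_b"]),
            variant_ids=list(c["variant_ids"]),
            kept_columns=np.asarray(c["kept_columns"], dtype=np.intp),
            weights=np.asarray(c["weights"], dtype=np.float64),
            train_dosages=np.asarray(c["train_dosages"], dtype=np.float64),
        )
        for c in doc["components"]
    ]
    return FRFModel(
        beta=np.asarray(doc["beta"], dtype=np.float64),
        components=comps,
        gamma=np.asarray(doc["gamma"], dtype=np.float64),
        train_y=np.asarray(doc["train_y"], dtype=np.int8),
        train_mu=np.asarray(doc["train_mu"], dtype=np.float64),
        delta=None if doc["delta"] is None else np.asarray(doc["delta"], dtype=np.float64),
        covariate_names=list(doc["covariate_names"]),
        estimator=doc.get("estimator", "plain"),
        centered=bool(doc["centered"]),
    )
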