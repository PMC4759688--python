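"""Replicate sweeps comparing the random-field model with the SVM baselines.

Pure orchestration: simulate a replicate, fit each method on the training
split, score the held-out split, and collect AUCs plus selection diagnostics
(which genes and weight schemes the forward algorithm kept).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .baselines import fit_msvm, fit_svm_on_genotypes
from .evaluation import auc
from .forward_selection import forward_select
from .frf_model import predict
from .similarity import WeightScheme, default_schemes
from .simulate import SimConfig, SimReplicate, make_replicate

__all__ = ["ReplicateResult", "run_frf_on_replicate", "run_replicates", "summarize"]


@dataclass
class ReplicateResult:
    seed: int
    frf_train_auc: float
    frf_test_auc: float
    svm_test_auc: float | None
    msvm_test_auc: float | None
    selected: list[tuple[str, str]]  # (gene, scheme name) in selection order
    chosen_size: int
    n_noise_excluded: int
    oracle_test_auc: float


def run_frf_on_replicate(
    rep: SimReplicate,
    schemes: list[WeightScheme] | None = None,
    K: int = 5,
    cv_seed: int = 0,
    centered: bool = False,
):
    """Forward-selected model on the training split; returns (path, model, scores)."""
    schemes = schemes or default_schemes()
    gd_train = rep.gene_dosages(rep.train_idx)
    path, model = forward_select(
        rep.y_train, None, gd_train, schemes, K=K, seed=cv_seed, centered=centered
    )
    gd_test = rep.gene_dosages(rep.test_idx)
    test_scores = predict(model, None, gd_test)
    train_scores = predict(model, None, gd_train)
    return path, model, train_scores, test_scores


def run_replicates(
    n_replicates: int,
    config: SimConfig,
    base_seed: int = 0,
    schemes: list[WeightScheme] | None = None,
    K: int = 5,
    with_svm: bool = True,
    with_msvm: bool = True,
) -> list[ReplicateResult]:
    """Run the three methods on ``n_replicates`` fresh replicates.

    Replicate r uses simulation seed derived from (base_seed, r); the CV fold
    seed is tied to the same stream so runs are fully reproducible.
    """
    results: list[ReplicateResult] = []
    ss = np.random.SeedSequence(base_seed)
    child_seeds = [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(n_replicates)]
    for r, seed in enumerate(child_seeds):
        rep = make_replicate(replace(config, seed=seed))
        path, model, train_scores, test_scores = run_frf_on_replicate(
            rep, schemes=schemes, K=K, cv_seed=seed + 1
        )
        y_tr, y_te = rep.y_train, rep.y_test
        frf_train = auc(train_scores, y_tr)
        frf_test = auc(test_scores, y_te)
        svm_test = msvm_test = None
        g_train = rep.genotypes.subset(subjects=rep.train_idx)
        g_test = rep.genotypes.subset(subjects=rep.test_idx)
        if with_svm:
            svm = fit_svm_on_genotypes(g_train, y_tr)
            svm_test = auc(svm.decision_scores(g_test.dosages), y_te)
        if with_msvm:
            import warnings

            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                msvm = fit_msvm(g_train, y_tr)
            msvm_test = auc(msvm.predict_scores(g_test), y_te)
        selected = [(g, s.name) for g, s in path.selected]
        noise_genes = {g for g in rep.gene_names if g.startswith("N")}
        excluded = noise_genes - {g for g, _ in selected}
        ptp = np.ptp(rep.oracle_scores[rep.test_idx])
        oracle_test = (
            auc(rep.oracle_scores[rep.test_idx], y_te) if ptp > 0 else 0.5
        )
        results.append(
            ReplicateResult(
                seed=seed,
                frf_train_auc=frf_train,
                frf_test_auc=frf_test,
                svm_test_auc=svm_test,
                msvm_test_auc=msvm_test,
                selected=selected,
                chosen_size=path.chosen_size or 0,
                n_noise_excluded=len(excluded),
                oracle_test_auc=oracle_test,
            )
        )
    return results


def summarize(results: list[ReplicateResult]) -> dict[str, float]:
    """Mean AUCs, selection rates, and their standard errors over replicates."""
    n = len(results)
    frf = np.array([r.frf_test_auc for r in results])
    out = {
        "n_replicates": float(n),
        "frf_mean_test_auc": float(frf.mean()),
        "frf_se_test_auc": float(frf.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0,
        "oracle_mean_test_auc": float(np.mean([r.oracle_test_auc for r in results])),
        "excluded_noise_gene_rate": float(np.mean([r.n_noise_excluded >= 1 for r in results])),
        "mean_chosen_size": float(np.mean([r.chosen_size for r in results])),
    }
    svm = [r.svm_test_auc for r in results if r.svm_test_auc is not None]
    if svm:
        out["svm_mean_test_auc"] = float(np.mean(svm))
    msvm = [r.msvm_test_auc for r in results if r.msvm_test_auc is not None]
    if msvm:
        out["msvm_mean_test_auc"] = float(np.mean(msvm))
    causal_schemes = [s for r in results for g, s in r.selected if g.startswith("C")]
    if causal_schemes:
        out["causal_beta_or_wss_rate"] = float(
            np.mean([s in ("BETA", "WSS") for s in causal_schemes])
        )
    return out
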