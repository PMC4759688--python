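import numpy as np
import pytest

import riskfield as rf
from riskfield.exceptions import ModelFitError, SingularModelError
from riskfield.frf_model import (
    FRFModel,
    GeneComponent,
    estimate_gamma,
    fit_frf,
    fit_mean_model,
    load_model,
    predict,
    save_model,
)
from riskfield.similarity import WeightScheme, similarity_matrix


class TestFitMeanModel:
    def test_intercept_only_is_case_rate(self):
        y = np.array([1] * 30 + [0] * 70)
        beta, mu = fit_mean_model(y)
        np.testing.assert_allclose(mu, 0.3)
        assert beta[0] == pytest.approx(np.log(0.3 / 0.7))

    def test_single_class_rejected(self):
        with pytest.raises(ModelFitError, match="single class"):
            fit_mean_model(np.ones(10))

    def test_saturated_binary_covariate_recovers_group_rates(self):
        x = np.array([0] * 50 + [1] * 50, float)
        y = np.concatenate([np.repeat([0, 1], [40, 10]), np.repeat([0, 1], [20, 30])])
        _, mu = fit_mean_model(y, x[:, None])
        np.testing.assert_allclose(mu[:50], 0.2, atol=1e-6)
        np.testing.assert_allclose(mu[50:], 0.6, atol=1e-6)

    def test_rank_deficient_design_rejected(self):
        x = np.column_stack([np.arange(20.0), 2 * np.arange(20.0)])
        y = np.array([0, 1] * 10)
        with pytest.raises(ModelFitError, match="rank deficient"):
            fit_mean_model(y, x)


def _toy_similarity(n, rng):
    s = rng.uniform(0.1, 0.9, (n, n))
    s = (s + s.T) / 2
    np.fill_diagonal(s, 0.0)
    return s


class TestEstimateGamma:
    def test_exact_linear_relation_recovers_half(self, rng):
        # y - mu = 0.5 * S y exactly => gamma-hat = 0.5
        y = np.array([1.0, 0.0, 1.0, 0.0, 1.0, 1.0, 0.0, 0.0])
        S = _toy_similarity(8, rng)
        mu = y - 0.5 * (S @ y)
        gamma = estimate_gamma(y, mu, [S])
        assert gamma[0] == pytest.approx(0.5, abs=1e-10)

    def test_zero_similarity_strict_error(self):
        y = np.array([1.0, 0.0, 1.0, 0.0])
        with pytest.raises(SingularModelError):
            estimate_gamma(y, np.full(4, 0.5), [np.zeros((4, 4))])

    def test_hand_solved_normal_equation(self):
        y = np.array([1.0, 1.0, 0.0, 0.0])
        mu = np.full(4, 0.5)
        S = np.array(
            [[0.0, 0.8, 0.2, 0.1], [0.8, 0.0, 0.3, 0.2], [0.2, 0.3, 0.0, 0.7], [0.1, 0.2, 0.7, 0.0]]
        )
        z = S @ y
        expected = float(z @ (y - mu)) / float(z @ z)
        gamma = estimate_gamma(y, mu, [S])
        assert gamma[0] == pytest.approx(expected, abs=1e-12)

    def test_orthogonality_on_random_fits(self, rng):
        # Z'(y - mu - Z gamma) = 0 is the estimating equation itself
        for _ in range(20):
            n = int(rng.integers(10, 40))
            y = (rng.random(n) < 0.5).astype(float)
            if y.min() == y.max():
                continue
            mu = np.full(n, y.mean())
            sims = [_toy_similarity(n, rng) for _ in range(3)]
            gamma = estimate_gamma(y, mu, sims, strict=False)
            Z = np.column_stack([s @ y for s in sims])
            resid = y - mu - Z @ gamma
            assert np.abs(Z.T @ resid).max() < 1e-8


class TestFitFrf:
    def test_noise_gene_gamma_near_zero(self, rng):
        n = 600
        y = (rng.random(n) < 0.5).astype(float)
        noise = rng.binomial(2, 0.2, size=(n, 30)).astype(float)
        m = fit_frf(y, None, {"G": noise}, [("G", WeightScheme("UW"))], strict=False)
        assert abs(m.gamma[0]) < 1.0  # scaled by tiny kernel variance; sign is noise

    def test_duplicated_gene_strict_singularity(self, rng):
        y = np.array([1.0, 0.0] * 10)
        d = rng.binomial(2, 0.3, size=(20, 5)).astype(float)
        with pytest.raises(SingularModelError):
            fit_frf(
                y, None, {"A": d, "B": d},
                [("A", WeightScheme("UW")), ("B", WeightScheme("UW"))], strict=True,
            )

    def test_phenotype_clustered_gene_dominates(self, rng):
        # gene A separates cases from controls perfectly; gene B is noise
        y = np.array([1.0] * 20 + [0.0] * 20)
        a = np.zeros((40, 4))
        a[:20] = 2.0
        b = rng.binomial(2, 0.3, size=(40, 4)).astype(float)
        m = fit_frf(
            y, None, {"A": a, "B": b},
            [("A", WeightScheme("UW")), ("B", WeightScheme("UW"))], strict=False,
        )
        assert abs(m.gamma[0]) > abs(m.gamma[1])

    def test_monomorphic_variants_masked(self, rng):
        y = np.array([1.0, 0.0] * 15)
        d = rng.binomial(2, 0.3, size=(30, 4)).astype(float)
        d[:, 2] = 0.0
        m = fit_frf(y, None, {"A": d}, [("A", WeightScheme("WSS"))], strict=False)
        assert m.components[0].kept_columns.tolist() == [0, 1, 3]


class TestPredict:
    def _plain_model(self, gamma, train_dosages, train_y, mu=0.5):
        comp = GeneComponent(
            gene="G",
            scheme=WeightScheme("UW"),
            variant_ids=[f"G:{j}" for j in range(train_dosages.shape[1])],
            kept_columns=np.arange(train_dosages.shape[1]),
            weights=np.ones(train_dosages.shape[1]),
            train_dosages=train_dosages,
        )
        return FRFModel(
            beta=np.array([np.log(mu / (1 - mu))]),
            components=[comp],
            gamma=np.asarray(gamma, float),
            train_y=np.asarray(train_y, np.int8),
            train_mu=np.full(len(train_y), mu),
            estimator="plain",
        )

    def test_zero_gamma_reduces_to_glm(self, rng):
        d = rng.binomial(2, 0.3, (6, 3)).astype(float)
        m = self._plain_model([0.0], d, [1, 0, 1, 0, 1, 0])
        scores = predict(m, None, {"G": rng.binomial(2, 0.3, (4, 3)).astype(float)})
        np.testing.assert_array_equal(scores, np.full(4, 0.5))

    def test_hand_arithmetic_prediction(self):
        # train y = (1, 0), gamma 0.4, cross-similarities (0.9, 0.1), mu 0.5
        train = np.array([[0.3], [1.9]])
        m = self._plain_model([0.4], train, [1, 0])
        scores = predict(m, None, {"G": np.array([[0.1]])})
        assert scores[0] == pytest.approx(0.5 + 0.4 * (0.9 * 1 + 0.1 * 0), abs=1e-12)

    def test_duplicate_of_training_case_scores_above_mean(self):
        train = np.array([[2.0, 2.0], [0.0, 0.0]])
        m = self._plain_model([0.5], train, [1, 0])
        scores = predict(m, None, {"G": train[[0]]})
        assert scores[0] > 0.5

    def test_missing_gene_rejected(self):
        m = self._plain_model([0.1], np.array([[1.0], [0.0]]), [1, 0])
        with pytest.raises(KeyError, match="'G'"):
            predict(m, None, {"H": np.array([[1.0]])})


class TestAdjustedEstimatorInvariances:
    def test_label_flip_complements_scores_and_keeps_gamma(self, rng):
        cfg = rf.SimConfig(
            n_subjects=200, n_causal_genes=1, n_noise_genes=1, snvs_per_gene=30,
            causal_fraction=0.5, disease_model="S1", oracle_auc_target=0.85, seed=77,
        )
        rep = rf.make_replicate(cfg)
        gd = rep.gene_dosages()
        sel = [("C1", WeightScheme("UW")), ("N1", WeightScheme("UW"))]
        y = rep.y.astype(float)
        m1 = fit_frf(y, None, gd, sel, strict=False)
        m2 = fit_frf(1 - y, None, gd, sel, strict=False)
        np.testing.assert_allclose(m1.gamma, m2.gamma, atol=1e-8)
        new = {g: d[:40] for g, d in gd.items()}
        np.testing.assert_allclose(predict(m2, None, new), 1 - predict(m1, None, new), atol=1e-8)

    def test_gamma_positive_for_predictive_gene_across_replicates(self):
        hits = 0
        for s in range(100):
            cfg = rf.SimConfig(
                n_subjects=200, n_causal_genes=1, n_noise_genes=0, snvs_per_gene=40,
                causal_fraction=0.5, disease_model="S1", oracle_auc_target=0.85,
                seed=10_000 + s,
            )
            rep = rf.make_replicate(cfg)
            m = fit_frf(
                rep.y.astype(float), None, rep.gene_dosages(),
                [("C1", WeightScheme("UW"))], strict=False,
            )
            hits += m.gamma[0] > 0
        assert hits >= 90


class TestSerialization:
    def test_round_trip_is_lossless(self, tmp_path, rng):
        y = (rng.random(30) < 0.5).astype(float)
        y[:2] = [0, 1]
        d = rng.binomial(2, 0.25, size=(30, 8)).astype(float)
        m = fit_frf(y, None, {"A": d}, [("A", WeightScheme("BETA"))], strict=False)
        path = tmp_path / "model.json"
        save_model(m, str(path))
        back = load_model(str(path))
        np.testing.assert_array_equal(back.beta, m.beta)
        np.testing.assert_array_equal(back.gamma, m.gamma)
        np.testing.assert_array_equal(back.delta, m.delta)
        np.testing.assert_array_equal(back.components[0].train_dosages, d)
        new = {"A": rng.binomial(2, 0.25, size=(5, 8)).astype(float)}
        np.testing.assert_array_equal(predict(back, None, new), predict(m, None, new))


def test_null_model_reduces_to_logistic(rng):
    """With zero genes the model is exactly the covariate-only logistic fit."""
    y = np.array([0, 1] * 25)
    beta, mu = fit_mean_model(y)
    m = FRFModel(beta=beta, components=[], gamma=np.empty(0), train_y=y.astype(np.int8), train_mu=mu)
    scores = predict(m, None, {"any": rng.binomial(2, 0.3, (7, 3)).astype(float)})
    np.testing.assert_allclose(scores, 0.5)
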