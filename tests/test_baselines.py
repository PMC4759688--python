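from math import comb

import numpy as np
import pytest

from riskfield.baselines import (
    cmc_collapse,
    fisher_exact_2x2,
    fit_msvm,
    fit_svm,
    fit_svm_on_genotypes,
    preselect_common,
)
from riskfield.evaluation import auc

from .conftest import make_genotypes


def fisher_oracle(a, b, c, d):
    """Brute force: enumerate every table with the observed margins."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    obs = comb(r1, a) * comb(r2, c)
    total = 0
    for x in range(0, c1 + 1):
        yy = c1 - x
        if x > r1 or yy > r2:
            continue
        prob_num = comb(r1, x) * comb(r2, yy)
        if prob_num <= obs:
            total += prob_num
    return total / comb(n, c1)


class TestFisherExact:
    def test_balanced_table_is_one(self):
        assert fisher_exact_2x2([[5, 5], [5, 5]]) == 1.0

    def test_extreme_table_closed_form(self):
        assert fisher_exact_2x2([[10, 0], [0, 10]]) == pytest.approx(2 / comb(20, 10), rel=1e-15)

    def test_hand_table_matches_enumeration(self):
        assert fisher_exact_2x2([[8, 2], [3, 7]]) == fisher_oracle(8, 2, 3, 7)

    def test_zero_margin_warns_p_one(self):
        with pytest.warns(UserWarning, match="zero margin"):
            assert fisher_exact_2x2([[0, 0], [3, 7]]) == 1.0

    def test_matches_scipy_on_random_tables(self, rng):
        from scipy.stats import fisher_exact

        for _ in range(200):
            t = rng.integers(0, 15, size=(2, 2))
            if min(t.sum(0).min(), t.sum(1).min()) == 0:
                continue
            assert fisher_exact_2x2(t) == pytest.approx(fisher_exact(t)[1], rel=1e-9)

    def test_negative_or_float_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact_2x2([[1.5, 2], [3, 4]])
        with pytest.raises(ValueError):
            fisher_exact_2x2([[-1, 2], [3, 4]])


class TestPreselectCommon:
    def _dataset(self, n_case=100, n_ctrl=100, rng=None):
        rng = rng or np.random.default_rng(1)
        y = np.array([1] * n_case + [0] * n_ctrl)
        n = n_case + n_ctrl
        rare = rng.binomial(2, 0.01, size=(n, 3)).astype(float)
        rare[0, 0] = 1.0  # keep polymorphic
        null_common = rng.binomial(2, 0.3, size=(n, 2)).astype(float)
        assoc = np.concatenate([np.full(n_case, 2.0), np.zeros(n_ctrl)])[:, None]
        d = np.hstack([rare, null_common, assoc])
        genes = ["geneA"] * 3 + ["geneB"] * 3
        return make_genotypes(d, genes=genes), y

    def test_rare_variants_never_tested(self):
        g, y = self._dataset()
        spec = preselect_common(g, y)
        rare_ids = {"v1", "v2", "v3"}
        assert rare_ids.isdisjoint(spec.selected_common_variants)
        assert set(spec.rare_variants_by_gene.get("geneA", [])) <= rare_ids

    def test_planted_association_retained_null_excluded(self):
        g, y = self._dataset()
        spec = preselect_common(g, y)
        assert "v6" in spec.selected_common_variants
        assert "v4" not in spec.selected_common_variants

    def test_identical_counts_give_p_one_and_exclusion(self):
        y = np.array([1] * 10 + [0] * 10)
        col = np.array(([0.0, 1.0] * 5) * 2)[:, None]  # same counts in both groups
        g = make_genotypes(np.hstack([col, col[::-1]]), genes=["g", "g"])
        spec = preselect_common(g, y)
        assert spec.selected_common_variants == []

    def test_threshold_monotonicity(self):
        g, y = self._dataset()
        loose = preselect_common(g, y, p_threshold=0.05)
        strict = preselect_common(g, y, p_threshold=0.0005)
        assert set(strict.selected_common_variants) <= set(loose.selected_common_variants)


class TestCmcCollapse:
    def test_carrier_indicator(self):
        d = np.array([[0, 0, 1], [0, 0, 0]], float)
        out = cmc_collapse(d, np.array([0.01, 0.02, 0.03]))
        assert out.tolist() == [1.0, 0.0]

    def test_rare_mask_applied(self):
        # rare sites are 2 and 5 only; subject carries alleles elsewhere
        d = np.array([[2, 0, 0, 1, 0]], float)
        mafs = np.array([0.3, 0.01, 0.2, 0.3, 0.02])
        assert cmc_collapse(d, mafs)[0] == 0.0

    def test_no_rare_variants_warns_zero_column(self):
        with pytest.warns(UserWarning, match="no rare variant"):
            out = cmc_collapse(np.array([[1.0], [2.0]]), np.array([0.4]))
        assert out.tolist() == [0.0, 0.0]

    def test_order_invariance(self, rng):
        d = rng.binomial(2, 0.05, size=(20, 6)).astype(float)
        mafs = rng.uniform(0.001, 0.2, 6)
        perm = rng.permutation(6)
        np.testing.assert_array_equal(
            cmc_collapse(d, mafs), cmc_collapse(d[:, perm], mafs[perm])
        )


class TestSvmModels:
    def test_separable_data_perfect_training_auc(self):
        X = np.array([[0.0, 0.0], [0.1, 0.2], [2.0, 2.0], [1.9, 2.2]])
        y = np.array([0, 0, 1, 1])
        clf = fit_svm(X, y)
        assert auc(clf.decision_scores(X), y) == 1.0

    def test_null_features_give_chance_level_auc(self, rng):
        aucs = []
        for _ in range(20):
            X = rng.integers(0, 3, size=(500, 50)).astype(float)
            y = rng.integers(0, 2, 500)
            Xt = rng.integers(0, 3, size=(300, 50)).astype(float)
            yt = rng.integers(0, 2, 300)
            aucs.append(auc(fit_svm(X, y).decision_scores(Xt), yt))
        assert 0.4 < np.mean(aucs) < 0.6

    def test_msvm_rare_carrier_signal(self, rng):
        # cases are exactly the rare-allele carriers; the CMC column is sufficient
        n = 400
        n_case = 30
        y = np.concatenate([np.ones(n_case, int), np.zeros(n - n_case, int)])
        rare = np.zeros((n, 5))
        for i in range(n_case):  # one rare allele each, spread over 5 rare sites
            rare[i, i % 5] = 1.0
        common = rng.binomial(2, 0.3, size=(n, 5)).astype(float)  # null commons
        g = make_genotypes(np.hstack([rare, common]), genes=["g1"] * 5 + ["g2"] * 5)
        idx = rng.permutation(n)
        train, test = idx[:260], idx[260:]
        with pytest.warns(UserWarning, match="no common variant"):
            model = fit_msvm(g.subset(subjects=train), y[train])
        scores = model.predict_scores(g.subset(subjects=test))
        assert auc(scores, y[test]) > 0.9

    def test_svm_on_genotypes_uses_all_dosages(self, rng):
        d = rng.binomial(2, 0.3, size=(40, 6)).astype(float)
        y = rng.permutation([0, 1] * 20)
        g = make_genotypes(d)
        clf = fit_svm_on_genotypes(g, y)
        assert clf.decision_scores(d).shape == (40,)
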