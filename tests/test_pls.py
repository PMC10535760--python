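"""PLS2C classifier, metrics, cross-validation, permutation test,
post-transformation and VIP."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from lfnmr import pls


def _random_model(rng, n=20, p=6, A=2):
    X = rng.standard_normal((n, p))
    y = np.concatenate([np.ones(n // 2), -np.ones(n - n // 2)])
    X[y > 0, 0] += rng.uniform(0.5, 2.0)
    return pls.fit_pls2c(X, y, A, positive=1.0), X, y


class TestFitPLS2C:
    def test_univariate_single_component_equals_ols(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal((15, 1))
        y = np.where(rng.random(15) < 0.5, 1.0, -1.0)
        y[:2], y[2:4] = 1.0, -1.0
        model = pls.fit_pls2c(x, y, 1, positive=1.0)
        xc = x[:, 0] - x[:, 0].mean()
        beta = (xc @ (y - y.mean())) / (xc @ xc)
        expected = beta * xc + y.mean()
        assert np.allclose(pls.decision_scores(model, x), expected, atol=1e-8)

    def test_scores_mutually_orthogonal(self):
        rng = np.random.default_rng(1)
        model, _, _ = _random_model(rng, A=4, p=8)
        G = model.T.T @ model.T
        assert np.abs(G - np.diag(np.diag(G))).max() < 1e-10

    def test_weights_unit_norm(self):
        rng = np.random.default_rng(2)
        model, _, _ = _random_model(rng, A=3, p=8)
        assert np.allclose(np.linalg.norm(model.W, axis=0), 1.0, atol=1e-12)

    def test_regression_vector_reproduces_nipals_fit(self):
        rng = np.random.default_rng(3)
        model, X, y = _random_model(rng, A=3, p=8)
        yhat_b = pls.decision_scores(model, X)
        yhat_scores = model.T @ model.q + model.y_mean
        assert np.allclose(yhat_b, yhat_scores, atol=1e-10)

    def test_matches_sklearn_pls_regression(self):
        sklearn = pytest.importorskip("sklearn.cross_decomposition")
        rng = np.random.default_rng(4)
        model, X, y = _random_model(rng, n=24, p=10, A=3)
        sk = sklearn.PLSRegression(n_components=3, scale=False).fit(X, y)
        assert np.allclose(
            pls.decision_scores(model, X), sk.predict(X).ravel(), atol=1e-10
        )

    def test_separable_data_perfect_in_fit_mcc(self, separable_data):
        X, y = separable_data
        model = pls.fit_pls2c(X, y, 2)
        labels, scores = pls.classify(model, X)
        coded = model.coded_y(y)
        assert pls.mcc_from_predictions(coded, np.where(scores >= 0, 1, -1)) == 1.0

    def test_single_class_rejected(self):
        X = np.random.default_rng(5).standard_normal((8, 3))
        with pytest.raises(ValueError):
            pls.fit_pls2c(X, np.ones(8), 1)

    def test_excess_components_rejected(self):
        X = np.random.default_rng(6).standard_normal((6, 3))
        y = np.array([1.0, 1.0, 1.0, -1.0, -1.0, -1.0])
        with pytest.raises(ValueError):
            pls.fit_pls2c(X, y, 5)


class TestClassify:
    def test_training_data_reproduces_fitted_labels(self, separable_data):
        X, y = separable_data
        model = pls.fit_pls2c(X, y, 2)
        labels, scores = pls.classify(model, X)
        assert np.array_equal(labels, np.where(scores >= 0, "sepsis", "control"))

    def test_zero_score_goes_to_positive_class(self):
        rng = np.random.default_rng(7)
        model, X, y = _random_model(rng)
        x0 = model.x_mean - model.y_mean * model.b / (model.b @ model.b)
        labels, scores = pls.classify(model, x0[None, :])
        assert abs(scores[0]) < 1e-10
        assert labels[0] == 1.0  # positive class of the ±1 coding

    def test_feature_permutation_equivariance(self):
        rng = np.random.default_rng(8)
        model, X, y = _random_model(rng, p=7)
        perm = rng.permutation(7)
        Xp = X[:, perm]
        model_p = pls.fit_pls2c(Xp, y, model.A, positive=1.0)
        assert np.allclose(
            pls.decision_scores(model, X), pls.decision_scores(model_p, Xp), atol=1e-10
        )

    def test_dimension_mismatch_rejected(self):
        rng = np.random.default_rng(9)
        model, X, _ = _random_model(rng)
        with pytest.raises(ValueError):
            pls.classify(model, X[:, :-1])


class TestMCC:
    @pytest.mark.parametrize(
        "tp,fp,tn,fn,expected",
        [
            (7, 0, 10, 1, 0.892),  # one sepsis error of 8 vs 10
            (7, 1, 9, 1, 0.775),   # one error in each group
            (5, 2, 8, 3, 0.433),   # three and two errors
            (8, 0, 10, 0, 1.0),
        ],
    )
    def test_worked_examples(self, tp, fp, tn, fn, expected):
        assert pls.compute_mcc(tp, fp, tn, fn) == pytest.approx(expected, abs=5e-4)

    def test_empty_marginal_gives_zero(self):
        assert pls.compute_mcc(0, 0, 5, 5) == 0.0

    @given(
        tp=st.integers(0, 50),
        fp=st.integers(0, 50),
        tn=st.integers(0, 50),
        fn=st.integers(0, 50),
    )
    @settings(deadline=None, max_examples=200, derandomize=True)
    def test_bounded_and_symmetric(self, tp, fp, tn, fn):
        v = pls.compute_mcc(tp, fp, tn, fn)
        assert -1.0 <= v <= 1.0
        # swapping the roles of the two classes leaves MCC unchanged
        assert v == pytest.approx(pls.compute_mcc(tn, fn, tp, fp), abs=1e-12)


class TestAUC:
    def test_perfect_ranking(self):
        scores = np.array([0.9, 0.8, 0.2, 0.1])
        labels = np.array([1, 1, -1, -1])
        assert pls.compute_auc(scores, labels) == 1.0

    def test_all_ties_give_half(self):
        assert pls.compute_auc(np.ones(6), np.array([1, 1, 1, -1, -1, -1])) == 0.5

    def test_pair_counting_example(self):
        scores = np.array([0.9, 0.8, 0.4, 0.7, 0.3])
        labels = np.array([1, 1, 1, -1, -1])
        assert pls.compute_auc(scores, labels) == pytest.approx(5 / 6)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            pls.compute_auc(np.ones(3), np.ones(3))

    @given(st.integers(0, 2**31 - 1))
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_complement_symmetry(self, seed):
        gen = np.random.default_rng(seed)
        scores = gen.standard_normal(12)
        labels = np.concatenate([np.ones(5), -np.ones(7)])
        a = pls.compute_auc(scores, labels)
        assert pls.compute_auc(-scores, labels) == pytest.approx(1 - a, abs=1e-12)


class TestRepeatedCV:
    def test_separable_data_high_mcc_cv(self, separable_data):
        X, y = separable_data
        rep = pls.repeated_cv(X, y, 2, repeats=5, folds=5, seed=0)
        assert rep.summarize("mcc")[1] >= 0.95

    def test_same_seed_identical_report(self, separable_data):
        X, y = separable_data
        r1 = pls.repeated_cv(X, y, 3, repeats=3, seed=42)
        r2 = pls.repeated_cv(X, y, 3, repeats=3, seed=42)
        assert np.array_equal(r1.mcc_cv, r2.mcc_cv)
        assert np.array_equal(r1.auc_cv, r2.auc_cv)

    def test_null_data_mcc_near_zero(self):
        # a single null dataset fluctuates by ~0.15; the mean over several
        # independent null datasets pins the expectation near zero
        rng = np.random.default_rng(10)
        y = np.concatenate([np.ones(20), -np.ones(20)])
        vals = []
        for seed in range(6):
            X = rng.standard_normal((40, 10))
            rep = pls.repeated_cv(X, y, 2, repeats=10, folds=5, seed=seed)
            vals.append(rep.summarize("mcc")[1])
        assert abs(np.mean(vals)) <= 0.15

    def test_class_smaller_than_fold_count_rejected(self):
        X = np.random.default_rng(11).standard_normal((7, 3))
        y = np.array([1.0, 1.0, 1.0, -1.0, -1.0, -1.0, -1.0])
        with pytest.raises(ValueError):
            pls.repeated_cv(X, y, 1, folds=5)


class TestSelectNcomp:
    @pytest.mark.parametrize(
        "curve,expected",
        [
            ((0.2, 0.5, 0.4), 2),
            ((0.1, 0.2, 0.3), 3),   # still rising at the end
            ((0.5, 0.5, 0.3), 1),   # plateau resolves to the smaller A
            ((0.6, 0.2, 0.1), 1),
        ],
    )
    def test_first_maximum_rule(self, curve, expected):
        rep = pls.CVReport(
            mcc_cv=np.tile(curve, (3, 1)),
            auc_cv=np.tile(curve, (3, 1)),
            repeats=3,
            folds=5,
            seed=0,
        )
        assert pls.select_ncomp(rep) == expected

    def test_empty_report_rejected(self):
        rep = pls.CVReport(
            mcc_cv=np.empty((0, 0)), auc_cv=np.empty((0, 0)), repeats=0, folds=5, seed=0
        )
        with pytest.raises(ValueError):
            pls.select_ncomp(rep)


class TestPermutationTest:
    def test_floor_when_observed_beats_all_permutations(self, separable_data):
        X, y = separable_data
        p = pls.permutation_test(X, y, "mcc", 2, n_perm=49, seed=0)
        assert p == pytest.approx(1 / 50)

    def test_p_never_below_formula_floor(self):
        rng = np.random.default_rng(12)
        X = rng.standard_normal((20, 5))
        y = np.concatenate([np.ones(10), -np.ones(10)])
        p = pls.permutation_test(X, y, "mcc", 1, n_perm=19, seed=3)
        assert p >= 1 / 20

    def test_constant_labels_rejected(self):
        X = np.random.default_rng(13).standard_normal((10, 4))
        with pytest.raises(ValueError):
            pls.permutation_test(X, np.ones(10), "mcc", 1, n_perm=10)

    def test_unknown_statistic_rejected(self, separable_data):
        X, y = separable_data
        with pytest.raises(ValueError):
            pls.permutation_test(X, y, "f1", 1, n_perm=10)


class TestPostTransform:
    def test_single_component_model_is_identity_case(self):
        rng = np.random.default_rng(14)
        model, X, y = _random_model(rng, A=1)
        pt = pls.post_transform(model)
        t = model.T[:, 0]
        assert abs(abs(np.corrcoef(pt.t_p, t)[0, 1]) - 1.0) < 1e-12
        assert pt.T_o.shape[1] == 0

    @pytest.mark.parametrize("seed", range(10))
    def test_fitted_values_invariant_and_orthogonality(self, seed):
        rng = np.random.default_rng(seed)
        A = rng.integers(1, 5)
        model, X, y = _random_model(rng, n=24, p=9, A=int(A))
        pt = pls.post_transform(model)
        yhat_pre = pls.decision_scores(model, X)
        yhat_post = pt.t_p * (pt.t_p @ (yhat_pre - model.y_mean)) + model.y_mean
        assert np.abs(yhat_pre - yhat_post).max() < 1e-10
        if pt.T_o.size:
            c = pt.T_o.T @ (yhat_pre - yhat_pre.mean())
            assert np.abs(c).max() < 1e-10

    def test_score_space_is_preserved(self):
        rng = np.random.default_rng(15)
        model, X, y = _random_model(rng, A=3, p=8)
        pt = pls.post_transform(model)
        basis = np.column_stack([pt.t_p, pt.T_o])
        # projection of T onto the rotated basis reproduces T
        proj = basis @ (basis.T @ model.T)
        assert np.allclose(proj, model.T, atol=1e-8)


class TestPredictiveBlock:
    def test_rank_one_and_in_column_space(self):
        rng = np.random.default_rng(16)
        model, X, y = _random_model(rng, A=3, p=8)
        pt = pls.post_transform(model)
        B = pls.predictive_block(pt)
        assert np.linalg.matrix_rank(B) == 1
        Xc = X - X.mean(axis=0)
        # each row of B lies in the row space of Xc
        resid = B - Xc @ np.linalg.lstsq(Xc, B, rcond=None)[0]
        assert np.abs(resid).max() < 1e-8

    def test_single_component_equals_score_loading_product(self):
        rng = np.random.default_rng(17)
        model, X, y = _random_model(rng, A=1)
        pt = pls.post_transform(model)
        assert np.allclose(
            pls.predictive_block(pt), model.T @ model.P.T, atol=1e-10
        )


class TestVIP:
    def test_normalization_identity(self):
        rng = np.random.default_rng(18)
        for _ in range(5):
            model, _, _ = _random_model(rng, p=9, A=3)
            vip = pls.compute_vip(model)
            assert (vip**2).sum() == pytest.approx(9, abs=1e-9)

    def test_two_variable_single_component_formula(self):
        # X built so the single NIPALS weight vector is ∝ (1, 0)
        rng = np.random.default_rng(19)
        n = 30
        y = np.concatenate([np.ones(15), -np.ones(15)])
        X = np.column_stack([y * 2.0 + 0.01 * rng.standard_normal(n), np.zeros(n)])
        model = pls.fit_pls2c(X, y, 1, positive=1.0)
        vip = pls.compute_vip(model)
        assert vip[0] == pytest.approx(np.sqrt(2), abs=1e-6)
        assert vip[1] == pytest.approx(0.0, abs=1e-6)

    def test_equal_weights_give_unit_vip(self):
        n, p = 40, 5
        y = np.concatenate([np.ones(20), -np.ones(20)])
        X = np.tile(y[:, None], (1, p)) + 0.0
        model = pls.fit_pls2c(X + 1e-9, y, 1, positive=1.0)
        assert np.allclose(pls.compute_vip(model), 1.0, atol=1e-6)
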