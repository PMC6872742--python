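"""LASSO selection, logistic fitting, AUC, and the CV protocol."""

import numpy as np
import pandas as pd
import pytest

from seg2surv.features import FeatureTable
from seg2surv.survival import (
    balanced_folds,
    classification_metrics,
    cross_validate,
    external_validate,
    fit_logistic,
    fit_survival_pipeline,
    lambda_grid,
    lasso_select,
    roc_auc,
    solve_lasso,
)


def _table(values):
    values = np.asarray(values, dtype=float)
    idx = pd.DataFrame(
        {"modality": "CT", "x": 0, "y": 0, "z": 0, "channel": range(values.shape[1])}
    )
    return FeatureTable(values, idx, [f"P{i}" for i in range(values.shape[0])])


def brute_force_auc(scores, labels):
    """Pair counting: P(score_pos > score_neg), ties 1/2."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


class TestLasso:
    def test_huge_penalty_selects_nothing(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((40, 6))
        y = rng.integers(0, 2, 40).astype(float)
        lam_max = lambda_grid(
            (X - X.mean(0)) / X.std(0), y
        )[0]
        fit = lasso_select(X, y, lambdas=np.array([lam_max * 1.01]), seed=1)
        assert fit.selected_indices.size == 0

    def test_orthonormal_design_matches_soft_threshold(self):
        rng = np.random.default_rng(2)
        n, p = 24, 6
        Q, _ = np.linalg.qr(rng.standard_normal((n, p)))  # Q'Q = I
        y = rng.standard_normal(n)
        lam = 0.3
        beta, _ = solve_lasso(Q, y, lam, fit_intercept=False)
        xty = Q.T @ y
        expected = np.sign(xty) * np.maximum(np.abs(xty) - lam / 2.0, 0.0)
        np.testing.assert_allclose(beta, expected, atol=1e-8)

    def test_informative_feature_survives_noise(self):
        hits = 0
        n_trials = 12
        for seed in range(n_trials):
            rng = np.random.default_rng(100 + seed)
            n = 100
            signal = rng.standard_normal(n)
            p = 1 / (1 + np.exp(-2.5 * signal))
            y = (rng.random(n) < p).astype(float)
            X = np.column_stack([signal] + [rng.standard_normal(n) for _ in range(9)])
            fit = lasso_select(X, y, seed=seed)
            hits += 0 in fit.selected_indices
        assert hits / n_trials >= 0.9

    def test_permuted_labels_select_few_features(self):
        rng = np.random.default_rng(3)
        n = 80
        X = rng.standard_normal((n, 10))
        y = rng.integers(0, 2, n).astype(float)
        counts = []
        for seed in range(5):
            fit = lasso_select(X, np.random.default_rng(seed).permutation(y), seed=seed)
            counts.append(fit.selected_indices.size)
        assert np.mean(counts) <= 2.0

    def test_single_class_rejected(self):
        X = np.random.default_rng(4).standard_normal((10, 3))
        with pytest.raises(ValueError, match="single class"):
            lasso_select(X, np.ones(10), seed=0)

    def test_lambda_path_sparsity_monotone(self):
        rng = np.random.default_rng(5)
        X = rng.standard_normal((50, 8))
        y = (rng.random(50) < 0.5).astype(float)
        Z = (X - X.mean(0)) / X.std(0)
        lams = lambda_grid(Z, y, n_lambdas=12)
        sizes = [np.count_nonzero(solve_lasso(Z, y, lam)[0]) for lam in lams]
        assert all(a <= b + 1e-9 for a, b in zip(sizes, sizes[1:]))  # lams descend


class TestLogistic:
    def test_zero_model_predicts_half(self):
        model = fit_logistic(np.zeros((10, 0)), np.array([0, 1] * 5))
        assert model.predict_survival(np.zeros((3, 0)))[0] == pytest.approx(0.5)

    def test_separable_data_triggers_ridge_fallback(self):
        x = np.concatenate([np.zeros(10), np.ones(10)])[:, None]
        y = np.concatenate([np.zeros(10), np.ones(10)]).astype(int)
        model = fit_logistic(x, y)
        assert model.ridge_fallback
        p = model.predict_survival(x)
        assert p[:10].max() < 0.1 and p[10:].min() > 0.9

    def test_parameter_recovery_within_three_se(self):
        rng = np.random.default_rng(6)
        n = 500
        x = rng.standard_normal(n)
        beta0, beta1 = 0.4, 1.2
        p = 1 / (1 + np.exp(-(beta0 + beta1 * x)))
        y = (rng.random(n) < p).astype(int)
        model = fit_logistic(x[:, None], y)
        # rough SE scale for logistic slopes at n=500
        se = np.sqrt(4 / n) * 2
        assert abs(model.betas[0] - beta1) < 3 * se + 0.3
        assert abs(model.beta0 - beta0) < 3 * se + 0.3

    def test_nonfinite_features_rejected(self):
        X = np.array([[1.0], [np.nan]])
        with pytest.raises(ValueError):
            fit_logistic(X, np.array([0, 1]))


class TestAUC:
    def test_perfect_separation(self):
        assert roc_auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == 1.0

    def test_all_ties_is_half(self):
        assert roc_auc([0.5] * 6, [0, 1, 0, 1, 0, 1]) == 0.5

    def test_hand_example(self):
        assert roc_auc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1]) == pytest.approx(0.75)

    def test_matches_brute_force_pair_counting(self):
        rng = np.random.default_rng(7)
        scores = rng.random(40)
        scores[rng.random(40) < 0.3] = 0.5  # inject ties
        labels = rng.integers(0, 2, 40)
        assert roc_auc(scores, labels) == pytest.approx(
            brute_force_auc(scores, labels), abs=1e-12
        )

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(8)
        scores = rng.random(30)
        labels = rng.integers(0, 2, 30)
        assert roc_auc(np.exp(5 * scores), labels) == pytest.approx(
            roc_auc(scores, labels)
        )

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.9], [1, 1])


class TestFolds:
    def test_balanced_test_sets(self):
        rng = np.random.default_rng(9)
        y = (rng.random(90) < 0.65).astype(int)  # unbalanced cohort
        folds = balanced_folds(y, n_folds=6, seed=1)
        sizes = set()
        for f in folds:
            labels = y[f]
            assert (labels == 0).sum() == (labels == 1).sum()
            sizes.add(len(f))
        assert len(sizes) == 1
        flat = np.concatenate(folds)
        assert len(flat) == len(set(flat))  # disjoint

    def test_assignment_depends_only_on_labels_and_seed(self):
        y = np.array([0, 1] * 30)
        a = balanced_folds(y, 6, seed=3)
        b = balanced_folds(y, 6, seed=3)
        for fa, fb in zip(a, b):
            np.testing.assert_array_equal(fa, fb)

    def test_insufficient_minority_class_explicit_error(self):
        y = np.array([1] * 50 + [0] * 4)
        with pytest.raises(ValueError, match="minority class"):
            balanced_folds(y, n_folds=6, seed=0)


def _signal_table(rng, n=60, n_noise=12, slope=2.5):
    signal = rng.standard_normal(n)
    p = 1 / (1 + np.exp(-slope * signal))
    y = (rng.random(n) < p).astype(int)
    cols = [signal + 0.05 * rng.standard_normal(n) for _ in range(3)]
    cols += [rng.standard_normal(n) for _ in range(n_noise)]
    return _table(np.column_stack(cols)), y


class TestCrossValidate:
    def test_planted_signal_recovered(self):
        table, y = _signal_table(np.random.default_rng(10))
        rep = cross_validate(table, y, n_folds=4, k_range=range(2, 6), n_init=5, seed=11)
        assert rep.mean("auc") > 0.7
        assert set(rep.metrics.columns) == {"accuracy", "sensitivity", "specificity", "auc"}
        assert ((rep.summary["ci_low"] <= rep.summary["ci_high"]).all())

    def test_null_labels_give_chance_auc(self):
        rng = np.random.default_rng(12)
        table = _table(rng.standard_normal((72, 10)))
        y = np.array([0, 1] * 36)
        rep = cross_validate(table, y, n_folds=4, k_range=range(2, 5), n_init=3, seed=13)
        assert 0.3 < rep.mean("auc") < 0.7

    def test_leakage_proof_artifacts(self):
        """Corrupting held-out rows must not move any training artifact."""
        table, y = _signal_table(np.random.default_rng(14), n=48, n_noise=8)
        rep1 = cross_validate(table, y, n_folds=3, k_range=range(2, 5), n_init=3, seed=15)
        fold0 = rep1.folds[0]
        corrupted = table.values.copy()
        corrupted[fold0] = 1e3 * np.random.default_rng(99).standard_normal(
            corrupted[fold0].shape
        )
        table2 = FeatureTable(corrupted, table.feature_index, table.patient_ids)
        rep2 = cross_validate(table2, y, n_folds=3, k_range=range(2, 5), n_init=3, seed=15)
        a1, a2 = rep1.artifacts[0], rep2.artifacts[0]
        assert a1.k_opt == a2.k_opt
        np.testing.assert_array_equal(a1.medoid_columns, a2.medoid_columns)
        np.testing.assert_array_equal(
            a1.lasso.selected_indices, a2.lasso.selected_indices
        )
        np.testing.assert_allclose(a1.model.betas, a2.model.betas, rtol=1e-10)
        assert a1.model.beta0 == pytest.approx(a2.model.beta0, rel=1e-10)


class TestExternalValidation:
    def test_resubstitution_equals_internal_metrics(self):
        table, y = _signal_table(np.random.default_rng(16), n=50, n_noise=6)
        model, _ = fit_survival_pipeline(table, y, k_range=range(2, 5), n_init=3, seed=17)
        ext = external_validate(model, table, y)
        p = model.predict_from_table(table)
        internal = classification_metrics(p, y)
        assert ext == internal

    def test_modality_subset_table_works(self):
        table, y = _signal_table(np.random.default_rng(18), n=50, n_noise=6)
        model, _ = fit_survival_pipeline(table, y, k_range=range(2, 5), n_init=3, seed=19)
        # shuffle column order; provenance matching must still find features
        perm = np.random.default_rng(20).permutation(table.n_features)
        shuffled = table.subset_columns(perm)
        ext = external_validate(model, shuffled, y)
        base = external_validate(model, table, y)
        assert ext == base

    def test_missing_features_rejected_with_list(self):
        table, y = _signal_table(np.random.default_rng(21), n=50, n_noise=6)
        model, _ = fit_survival_pipeline(table, y, k_range=range(2, 5), n_init=3, seed=22)
        if model.betas.size == 0:
            pytest.skip("intercept-only model on this fixture")
        reduced = table.subset_columns(
            [c for c in range(table.n_features) if c not in model.table_columns]
        )
        with pytest.raises(ValueError, match="missing required features"):
            external_validate(model, reduced, y)

    def test_permuted_external_labels_give_chance_auc(self):
        table, y = _signal_table(np.random.default_rng(23), n=80, n_noise=6)
        model, _ = fit_survival_pipeline(table, y, k_range=range(2, 5), n_init=3, seed=24)
        rng = np.random.default_rng(25)
        aucs = [
            external_validate(model, table, rng.permutation(y))["auc"] for _ in range(20)
        ]
        assert abs(np.mean(aucs) - 0.5) < 0.1
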