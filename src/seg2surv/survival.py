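"""LASSO feature selection and logistic survival prediction with a
leakage-safe, class-balanced 6-fold cross-validation protocol.

The selection stage is squared-loss LASSO on the binary outcome
(1 = alive, 0 = dead): min_b ||y - Xb||^2 + lambda ||b||_1, with lambda
chosen by inner cross-validation; features are standardized internally and
coefficients reported on the standardized scale. Surviving features enter a
maximum-likelihood logistic model y = 1 / (1 + exp(-(b0 + sum b_i x_i))).

Conventions fixed across the package: labels are 1 = alive; *sensitivity*
is the correct prediction of death over all death cases (computed on the
0 class) and *specificity* the correct prediction of survival over all
survival cases. Test folds are class-balanced: each fold holds equally many
survivors and deaths, and the remaining majority-class cases only ever
appear in training folds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import Lasso, LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import KFold

from .cluster import drop_constant_features, silhouette_sweep
from .features import FeatureTable

log = logging.getLogger(__name__)


@dataclass
class LassoFit:
    """Squared-loss LASSO fit over the medoid feature pool."""

    lam: float  # chosen penalty (objective ||y-Xb||^2 + lam*||b||_1)
    beta: np.ndarray  # coefficients on the standardized scale
    intercept: float
    selected_indices: np.ndarray  # columns with nonzero beta
    cv_curve: pd.DataFrame  # lambda -> mean inner-CV validation MSE
    mean: np.ndarray  # per-feature standardization offsets
    scale: np.ndarray  # per-feature standardization scales


def lambda_grid(X: np.ndarray, y: np.ndarray, n_lambdas: int = 50, decades: float = 4.0) -> np.ndarray:
    """Log-spaced penalty grid from lambda_max (empty model) down ``decades``.

    For the objective ||y - Xb||^2 + lam ||b||_1 on standardized X and
    centered y, the smallest penalty with an all-zero solution is
    lam_max = 2 max|X'y|.
    """
    yc = y - y.mean()
    lam_max = 2.0 * float(np.abs(X.T @ yc).max())
    if lam_max <= 0:
        lam_max = 1.0
    return np.geomspace(lam_max, lam_max * 10.0**-decades, n_lambdas)


def solve_lasso(X: np.ndarray, y: np.ndarray, lam: float, fit_intercept: bool = True):
    """Coordinate-descent solution of min_b ||y - Xb||^2 + lam ||b||_1.

    Thin wrapper translating the penalty into scikit-learn's 1/(2n)-scaled
    objective (alpha = lam / (2n)). On an orthonormal design (X'X = I,
    no intercept) the solution is the soft-threshold S(X'y, lam/2).
    """
    n = X.shape[0]
    model = Lasso(alpha=lam / (2 * n), fit_intercept=fit_intercept, max_iter=50_000, tol=1e-10)
    model.fit(X, y)
    return model.coef_.copy(), float(model.intercept_) if fit_intercept else 0.0


def _standardize(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mean = X.mean(axis=0)
    scale = X.std(axis=0)
    scale[scale == 0] = 1.0
    return (X - mean) / scale, mean, scale


def lasso_select(
    X: np.ndarray,
    labels: np.ndarray,
    lambdas: np.ndarray | None = None,
    inner_cv_folds: int = 5,
    seed: int = 0,
) -> LassoFit:
    """Select survival-related features by inner-CV-tuned LASSO.

    ``X`` is the reduced (medoid) feature matrix, ``labels`` the binary
    outcome (1 = alive). The penalty minimizing the mean inner-CV validation
    MSE wins; the fit is then refit on all rows at that penalty. Coordinate
    descent is delegated to scikit-learn with the penalty rescaled
    (sklearn's alpha = lambda / (2 n)).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(labels, dtype=float)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("X and labels are inconsistent")
    if not np.isfinite(X).all():
        raise ValueError("non-finite feature values")
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("labels contain a single class; LASSO selection is undefined")
    if min((y == c).sum() for c in classes) < 2:
        raise ValueError("need at least 2 cases of each class")
    Z, mean, scale = _standardize(X)
    if lambdas is None:
        lambdas = lambda_grid(Z, y)
    n = len(y)
    folds = min(inner_cv_folds, n)
    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    errs = np.zeros((len(lambdas), folds))
    for f, (tr, va) in enumerate(kf.split(Z)):
        for i, lam in enumerate(lambdas):
            model = Lasso(alpha=lam / (2 * len(tr)), max_iter=50_000)
            model.fit(Z[tr], y[tr])
            errs[i, f] = float(((model.predict(Z[va]) - y[va]) ** 2).mean())
    mean_err = errs.mean(axis=1)
    best = int(np.argmin(mean_err))
    lam = float(lambdas[best])
    final = Lasso(alpha=lam / (2 * n), max_iter=50_000)
    final.fit(Z, y)
    beta = final.coef_.copy()
    return LassoFit(
        lam=lam,
        beta=beta,
        intercept=float(final.intercept_),
        selected_indices=np.flatnonzero(beta != 0),
        cv_curve=pd.DataFrame({"lambda": lambdas, "mean_val_mse": mean_err}),
        mean=mean,
        scale=scale,
    )


@dataclass
class SurvivalModel:
    """Logistic survival model over LASSO-selected, standardized features.

    ``feature_provenance`` rows identify each selected feature by
    (modality, bottleneck position, channel) so the model can be applied to
    any table exposing those columns; ``table_columns`` are the column
    indices in the table the model was fit on.
    """

    beta0: float
    betas: np.ndarray
    mean: np.ndarray
    scale: np.ndarray
    table_columns: np.ndarray
    feature_provenance: pd.DataFrame | None = None
    horizon_label: str = "2OS"
    ridge_fallback: bool = False

    def predict_survival(self, X_selected: np.ndarray) -> np.ndarray:
        """P(alive) from the raw selected-feature matrix."""
        from scipy.special import expit

        X_selected = np.atleast_2d(np.asarray(X_selected, dtype=float))
        z = (X_selected - self.mean) / self.scale
        return expit(self.beta0 + z @ self.betas)

    def predict_from_table(self, table: FeatureTable) -> np.ndarray:
        cols = match_features(self, table)
        return self.predict_survival(table.values[:, cols])


def match_features(model: SurvivalModel, table: FeatureTable) -> np.ndarray:
    """Locate the model's selected features in a (possibly different) table."""
    if model.feature_provenance is None:
        return model.table_columns
    key_cols = ["modality", "x", "y", "z", "channel"]
    lookup = {
        tuple(row): i
        for i, row in enumerate(table.feature_index[key_cols].itertuples(index=False))
    }
    cols, missing = [], []
    for row in model.feature_provenance[key_cols].itertuples(index=False):
        key = tuple(row)
        if key in lookup:
            cols.append(lookup[key])
        else:
            missing.append(key)
    if missing:
        raise ValueError(f"feature table is missing required features: {missing}")
    return np.asarray(cols, dtype=int)


def fit_logistic(
    X: np.ndarray,
    labels: np.ndarray,
    mean: np.ndarray | None = None,
    scale: np.ndarray | None = None,
    table_columns: np.ndarray | None = None,
    feature_provenance: pd.DataFrame | None = None,
    horizon_label: str = "2OS",
) -> SurvivalModel:
    """Maximum-likelihood logistic fit of survival on selected features.

    With zero features the model degrades to intercept-only (prevalence
    logit). Perfectly separable data (non-convergent or exploding ML fit)
    falls back to a lightly ridge-penalized fit, logged.
    """
    y = np.asarray(labels, dtype=int)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.size and not np.isfinite(X).all():
        raise ValueError("non-finite feature values")
    n, p = (X.shape[0], X.shape[1]) if X.size else (len(y), 0)
    if mean is None:
        mean = np.zeros(p)
    if scale is None:
        scale = np.ones(p)
    if table_columns is None:
        table_columns = np.arange(p)
    if p == 0:
        rate = float(np.clip(y.mean(), 1e-6, 1 - 1e-6))
        return SurvivalModel(
            beta0=float(np.log(rate / (1 - rate))),
            betas=np.zeros(0),
            mean=np.zeros(0),
            scale=np.ones(0),
            table_columns=np.zeros(0, dtype=int),
            feature_provenance=feature_provenance,
            horizon_label=horizon_label,
        )
    Z = (X - mean) / scale
    ridge_fallback = False
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("error", ConvergenceWarning)
        try:
            clf = LogisticRegression(C=np.inf, solver="lbfgs", max_iter=2000)
            clf.fit(Z, y)
            # on standardized features a slope this steep means (quasi-)separation
            if np.abs(clf.coef_).max() > 10.0:
                raise ConvergenceWarning("coefficients diverged (separation)")
        except (ConvergenceWarning, Exception):
            log.info("logistic ML fit unstable (likely separation); ridge fallback engaged")
            ridge_fallback = True
            clf = LogisticRegression(C=1e4, solver="lbfgs", max_iter=2000)
            clf.fit(Z, y)
    # sklearn orders classes ascending, so coef_ is for P(y=1) = P(alive)
    return SurvivalModel(
        beta0=float(clf.intercept_[0]),
        betas=clf.coef_[0].copy(),
        mean=np.asarray(mean, dtype=float),
        scale=np.asarray(scale, dtype=float),
        table_columns=np.asarray(table_columns, dtype=int),
        feature_provenance=feature_provenance,
        horizon_label=horizon_label,
        ridge_fallback=ridge_fallback,
    )


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Rank-based AUC: P(random positive scores above random negative),
    ties counted 1/2. Labels must contain both classes."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("AUC undefined with a single class")
    return float(roc_auc_score(labels, scores))


def classification_metrics(p_alive: np.ndarray, labels: np.ndarray, threshold: float = 0.5) -> dict:
    """Accuracy / sensitivity / specificity / AUC at the given threshold.

    Sensitivity is computed on the death class (label 0): the fraction of
    deaths predicted dead; specificity on survivors.
    """
    y = np.asarray(labels, dtype=int)
    pred_alive = np.asarray(p_alive) >= threshold
    death, alive = y == 0, y == 1
    return {
        "accuracy": float((pred_alive == (y == 1)).mean()),
        "sensitivity": float((~pred_alive[death]).mean()) if death.any() else float("nan"),
        "specificity": float(pred_alive[alive].mean()) if alive.any() else float("nan"),
        "auc": roc_auc(np.asarray(p_alive), y),
    }


def balanced_folds(labels: np.ndarray, n_folds: int = 6, seed: int = 0) -> list[np.ndarray]:
    """Class-balanced test folds over a possibly unbalanced cohort.

    Each fold's test set holds the same number of survivors and deaths
    (within +-1 across folds when counts do not divide evenly); leftover
    majority-class cases appear only in training sets. Assignment depends
    only on labels and seed, never on features.
    """
    y = np.asarray(labels, dtype=int)
    rng = np.random.default_rng(seed)
    idx0 = rng.permutation(np.flatnonzero(y == 0))
    idx1 = rng.permutation(np.flatnonzero(y == 1))
    n_min = min(len(idx0), len(idx1))
    per_fold = n_min // n_folds
    if per_fold < 1:
        raise ValueError(
            f"cannot build {n_folds} class-balanced test folds: minority class has "
            f"only {n_min} cases ({n_folds} needed)"
        )
    folds = []
    for f in range(n_folds):
        sel = slice(f * per_fold, (f + 1) * per_fold)
        folds.append(np.sort(np.concatenate([idx0[sel], idx1[sel]])))
    return folds


@dataclass
class FoldArtifacts:
    """Training-fold artifacts retained for leakage auditing."""

    fold: int
    test_indices: np.ndarray
    k_opt: int
    medoid_columns: np.ndarray  # original table column indices
    lasso: LassoFit
    model: SurvivalModel
    metrics: dict


@dataclass
class CVReport:
    """Per-fold and aggregate cross-validation metrics."""

    metrics: pd.DataFrame  # rows = folds, columns = metric names
    summary: pd.DataFrame  # mean, sd, ci_low, ci_high per metric
    folds: list[np.ndarray]
    artifacts: list[FoldArtifacts]
    horizon_label: str

    def mean(self, metric: str) -> float:
        return float(self.metrics[metric].mean())


def _summarize(metrics: pd.DataFrame) -> pd.DataFrame:
    mean = metrics.mean()
    sd = metrics.std(ddof=1)
    half = 1.96 * sd / np.sqrt(len(metrics))
    return pd.DataFrame(
        {"mean": mean, "sd": sd, "ci_low": mean - half, "ci_high": mean + half}
    )


def fit_survival_pipeline(
    table: FeatureTable,
    labels: np.ndarray,
    k_range=range(2, 11),
    n_init: int = 10,
    seed: int = 0,
    horizon_label: str = "2OS",
) -> tuple[SurvivalModel, dict]:
    """Clustering -> LASSO -> logistic on one training cohort.

    Returns the fitted model plus a dict of intermediate artifacts
    (clustering curve, chosen k, medoid columns, LASSO fit).
    """
    X = table.values
    keep = drop_constant_features(X)
    kr = [k for k in k_range if k <= max(2, keep.size - 1)]
    k_opt, curve, results = silhouette_sweep(X[:, keep], kr, n_init=n_init, seed=seed)
    medoid_cols = keep[results[k_opt].medoid_indices]
    reduced = table.subset_columns(medoid_cols)
    fit = lasso_select(reduced.values, labels, seed=seed)
    sel = fit.selected_indices
    model = fit_logistic(
        reduced.values[:, sel],
        labels,
        mean=fit.mean[sel],
        scale=fit.scale[sel],
        table_columns=medoid_cols[sel],
        feature_provenance=reduced.feature_index.iloc[sel].reset_index(drop=True),
        horizon_label=horizon_label,
    )
    artifacts = {
        "k_opt": k_opt,
        "silhouette_curve": curve,
        "medoid_columns": medoid_cols,
        "lasso": fit,
        "clustering": results[k_opt],
    }
    return model, artifacts


def cross_validate(
    table: FeatureTable,
    labels: np.ndarray,
    horizon_label: str = "2OS",
    n_folds: int = 6,
    k_range=range(2, 11),
    n_init: int = 10,
    seed: int = 0,
) -> CVReport:
    """Class-balanced k-fold CV of the full survival stage.

    Feature clustering, LASSO selection, and logistic fitting are re-run
    from scratch on each fold's training portion only; the held-out fold
    contributes nothing to any training artifact (no leakage). Metrics are
    summarized as mean +- 1.96 sd / sqrt(n_folds) 95% confidence intervals.
    """
    y = np.asarray(labels, dtype=int)
    folds = balanced_folds(y, n_folds=n_folds, seed=seed)
    rows, artifacts = [], []
    for f, test_idx in enumerate(folds):
        train_mask = np.ones(len(y), bool)
        train_mask[test_idx] = False
        train_idx = np.flatnonzero(train_mask)
        sub = FeatureTable(
            table.values[train_idx], table.feature_index, [table.patient_ids[i] for i in train_idx]
        )
        model, art = fit_survival_pipeline(
            sub, y[train_idx], k_range=k_range, n_init=n_init,
            seed=seed + 1000 * (f + 1), horizon_label=horizon_label,
        )
        if model.table_columns.size:
            p_alive = model.predict_survival(table.values[np.ix_(test_idx, model.table_columns)])
        else:
            p_alive = np.full(len(test_idx), 1.0 / (1.0 + np.exp(-model.beta0)))
        m = classification_metrics(p_alive, y[test_idx])
        rows.append(m)
        artifacts.append(
            FoldArtifacts(
                fold=f,
                test_indices=test_idx,
                k_opt=art["k_opt"],
                medoid_columns=art["medoid_columns"],
                lasso=art["lasso"],
                model=model,
                metrics=m,
            )
        )
    metrics = pd.DataFrame(rows)
    return CVReport(
        metrics=metrics,
        summary=_summarize(metrics),
        folds=folds,
        artifacts=artifacts,
        horizon_label=horizon_label,
    )


def external_validate(model: SurvivalModel, table: FeatureTable, labels: np.ndarray) -> dict:
    """Frozen-model evaluation on an external cohort (no refitting).

    The external table must provide every selected feature (matched by
    provenance); e.g. a CT-only table satisfies a CT-only model.
    """
    y = np.asarray(labels, dtype=int)
    if model.betas.size == 0:
        p_alive = np.full(len(y), 1.0 / (1.0 + np.exp(-model.beta0)))
    else:
        p_alive = model.predict_from_table(table)
    return classification_metrics(p_alive, y)
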