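"""Sparse linear classifier evaluation: repeated nested CV, cross-study
transfer, leave-one-dataset-out, and the train x test prediction matrix.

The unit of evaluation is a *bundle* of L1-regularized logistic models — one
per (repeat x fold) of a repeated stratified cross-validation — together with
the frozen abundance normalization of the training cohort. Within-cohort
performance is the median over repeats of the AUC of pooled held-out
predictions; external cohorts are scored by the per-sample median predicted
probability over all models in the bundle. The regularization strength of
each model is chosen by an inner cross-validation to maximize AUC, subject
to the model retaining at least five nonzero coefficients.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import l1_min_c

from .tables import AbundanceTable, SampleMetadata, merge_cohorts
from .transforms import AbundanceNormalizer


def auc_roc(scores, labels) -> float:
    """Area under the ROC curve (Mann-Whitney formulation; ties count 0.5)."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("AUC undefined: only one class present")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def _fit_lasso(x: np.ndarray, y: np.ndarray, lam: float) -> LogisticRegression:
    model = LogisticRegression(
        l1_ratio=1.0, C=1.0 / lam, solver="liblinear", max_iter=200, tol=1e-4,
        random_state=0,
    )
    model.fit(x, y)
    return model


class SparseEnsembleClassifier(BaseEstimator, ClassifierMixin):
    """Bundle of lasso logistic models from repeated stratified CV.

    Parameters
    ----------
    level : feature level of the input abundance table ("species"/"KO"/"EC"),
        which sets the max-abundance cutoff and log pseudocount of the frozen
        normalization.
    folds, repeats : outer cross-validation scheme (5 x 100 at release scale).
    min_nonzero : minimum nonzero coefficients a selected model must retain.
    n_lambda : size of the descending log-spaced regularization grid.
    inner_folds : folds of the inner CV used to score each lambda.
    random_state : root seed; every split and every model derives from it.

    Fitted attributes
    -----------------
    normalizer_ : the frozen training-cohort normalization.
    models_ : list of fitted ``LogisticRegression`` (length repeats x folds).
    lambdas_ : chosen regularization strength per model.
    cv_auc_per_repeat_ : AUC of pooled held-out predictions, one per repeat.
    cv_auc_ : median of ``cv_auc_per_repeat_``.
    """

    def __init__(self, level: str = "species", folds: int = 5, repeats: int = 100,
                 min_nonzero: int = 5, n_lambda: int = 30, inner_folds: int = 5,
                 random_state: int = 0):
        self.level = level
        self.folds = folds
        self.repeats = repeats
        self.min_nonzero = min_nonzero
        self.n_lambda = n_lambda
        self.inner_folds = inner_folds
        self.random_state = random_state

    def _lambda_grid(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        # largest lambda that keeps any coefficient nonzero, then descend
        lam_max = 1.0 / l1_min_c(x, y, loss="log")
        return np.geomspace(lam_max, lam_max / 1e3, self.n_lambda)

    def _select_and_fit(self, x: np.ndarray, y: np.ndarray,
                        seed: int) -> tuple[LogisticRegression, float]:
        """Inner-CV lambda selection under the sparsity constraint, then refit."""
        lambdas = self._lambda_grid(x, y)
        inner = StratifiedKFold(n_splits=self.inner_folds, shuffle=True, random_state=seed)
        scores = np.zeros(len(lambdas))
        counts = np.zeros(len(lambdas))
        for tr, va in inner.split(x, y):
            if len(np.unique(y[va])) < 2:
                continue
            for i, lam in enumerate(lambdas):
                model = _fit_lasso(x[tr], y[tr], lam)
                if np.count_nonzero(model.coef_) == 0:
                    scores[i] += 0.5
                else:
                    scores[i] += roc_auc_score(y[va], model.decision_function(x[va]))
                counts[i] += 1
        mean_auc = np.where(counts > 0, scores / np.maximum(counts, 1), 0.5)
        target = min(self.min_nonzero, x.shape[1])
        # refit candidates in descending inner-AUC order (ties -> sparser model,
        # i.e. larger lambda = lower index) until the sparsity constraint holds
        order = np.lexsort((np.arange(len(lambdas)), -mean_auc))
        best_fallback = None
        best_nnz = -1
        for i in order:
            model = _fit_lasso(x, y, lambdas[i])
            nnz = int(np.count_nonzero(model.coef_))
            if nnz >= target:
                return model, float(lambdas[i])
            if nnz > best_nnz:
                best_fallback, best_nnz = (model, float(lambdas[i])), nnz
        warnings.warn(
            f"no lambda reached {target} nonzero coefficients; "
            f"using the densest model ({best_nnz} nonzero)",
            stacklevel=2,
        )
        return best_fallback

    def fit(self, X: AbundanceTable, y) -> "SparseEnsembleClassifier":
        labels = np.asarray(pd.Series(y).loc[X.sample_ids] if isinstance(y, pd.Series) else y)
        labels = labels.astype(int)
        classes, counts = np.unique(labels, return_counts=True)
        if len(classes) != 2:
            raise ValueError("binary labels required")
        if counts.min() < self.folds:
            raise ValueError(
                f"minority class ({counts.min()} samples) too small for "
                f"{self.folds}-fold stratification"
            )
        self.normalizer_ = AbundanceNormalizer(level=self.level).fit(X)
        matrix = self.normalizer_.transform(X)

        root = np.random.SeedSequence(self.random_state)
        repeat_seeds = root.generate_state(2 * self.repeats) % (2**31 - 1)
        self.models_, self.lambdas_ = [], []
        self.cv_auc_per_repeat_ = []
        for rep in range(self.repeats):
            outer = StratifiedKFold(
                n_splits=self.folds, shuffle=True, random_state=int(repeat_seeds[2 * rep])
            )
            held_scores = np.zeros(len(labels))
            for fold, (tr, te) in enumerate(outer.split(matrix, labels)):
                inner_seed = int((repeat_seeds[2 * rep + 1] + fold) % (2**31 - 1))
                model, lam = self._select_and_fit(matrix[tr], labels[tr], inner_seed)
                self.models_.append(model)
                self.lambdas_.append(lam)
                held_scores[te] = model.predict_proba(matrix[te])[:, 1]
            self.cv_auc_per_repeat_.append(auc_roc(held_scores, labels))
        self.cv_auc_ = float(np.median(self.cv_auc_per_repeat_))
        self.classes_ = classes
        return self

    def predict_proba(self, X: AbundanceTable) -> np.ndarray:
        """Per-sample median predicted probability over every model in the bundle."""
        matrix = self.normalizer_.transform(X)
        probs = np.stack([m.predict_proba(matrix)[:, 1] for m in self.models_])
        p1 = np.median(probs, axis=0)
        return np.column_stack([1.0 - p1, p1])

    def predict(self, X: AbundanceTable) -> np.ndarray:
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)


def train_cv(
    table: AbundanceTable, labels: pd.Series, folds: int = 5, repeats: int = 100,
    min_nonzero: int = 5, seed: int = 0,
) -> tuple[SparseEnsembleClassifier, list[float]]:
    """Fit a model bundle on one cohort; returns (bundle, per-repeat CV AUCs)."""
    labels = labels.loc[labels.index.intersection(table.data.index)]
    sub = AbundanceTable(table.data.loc[labels.index], table.level, table.cohort)
    bundle = SparseEnsembleClassifier(
        level=table.level, folds=folds, repeats=repeats, min_nonzero=min_nonzero,
        random_state=seed,
    ).fit(sub, labels)
    return bundle, bundle.cv_auc_per_repeat_


def predict_external(
    bundle: SparseEnsembleClassifier, table: AbundanceTable, labels: pd.Series
) -> float:
    """Median-of-models transfer AUC on an external cohort."""
    labels = labels.loc[labels.index.intersection(table.data.index)]
    sub = AbundanceTable(table.data.loc[labels.index], table.level, table.cohort)
    scores = bundle.predict_proba(sub)[:, 1]
    return auc_roc(scores, labels.to_numpy())


def lodo(
    tables: dict[str, AbundanceTable], metadata: SampleMetadata, outcome: str = "orr",
    folds: int = 5, repeats: int = 100, seed: int = 0,
) -> dict[str, float]:
    """Leave-one-dataset-out AUC per held-out cohort.

    For each cohort, the remaining cohorts are pooled into a single training
    set, the usual repeated-CV bundle is fitted on the pool, and the held-out
    cohort is scored by median-of-models transfer. Single-class held-out
    cohorts are skipped with a warning.
    """
    if len(tables) < 2:
        raise ValueError("LODO needs at least two cohorts")
    out: dict[str, float] = {}
    for i, held in enumerate(sorted(tables)):
        held_labels = metadata.labels(outcome, tables[held].sample_ids)
        if held_labels.nunique() < 2:
            warnings.warn(f"cohort {held!r} has a single {outcome} class; skipped",
                          stacklevel=2)
            continue
        pool = merge_cohorts([tables[c] for c in sorted(tables) if c != held])
        pool_labels = metadata.labels(outcome, pool.sample_ids)
        bundle, _ = train_cv(pool, pool_labels, folds=folds, repeats=repeats,
                             seed=seed + i)
        out[held] = predict_external(bundle, tables[held], held_labels)
    return out


def prediction_matrix(
    tables: dict[str, AbundanceTable], metadata: SampleMetadata, outcome: str = "orr",
    folds: int = 5, repeats: int = 100, seed: int = 0,
) -> pd.DataFrame:
    """Train x test AUC grid: CV on the diagonal, transfer off it, LODO row.

    Rows are training cohorts (plus a final ``LODO`` row); columns are test
    cohorts. Entry [i, j] with i != j is the transfer AUC of cohort i's
    bundle on cohort j; the diagonal is the within-cohort median CV AUC.
    """
    cohorts = sorted(tables)
    if len(cohorts) < 2:
        raise ValueError("a prediction matrix needs at least two cohorts")
    grid = pd.DataFrame(np.nan, index=cohorts + ["LODO"], columns=cohorts)
    bundles: dict[str, SparseEnsembleClassifier] = {}
    for i, cohort in enumerate(cohorts):
        labels = metadata.labels(outcome, tables[cohort].sample_ids)
        if labels.nunique() < 2:
            warnings.warn(f"cohort {cohort!r} has a single {outcome} class; skipped",
                          stacklevel=2)
            continue
        bundle, _ = train_cv(tables[cohort], labels, folds=folds, repeats=repeats,
                             seed=seed + 1000 + i)
        bundles[cohort] = bundle
        grid.loc[cohort, cohort] = bundle.cv_auc_
    for train_cohort, bundle in bundles.items():
        for test_cohort in cohorts:
            if test_cohort == train_cohort:
                continue
            test_labels = metadata.labels(outcome, tables[test_cohort].sample_ids)
            if test_labels.nunique() < 2:
                continue
            grid.loc[train_cohort, test_cohort] = predict_external(
                bundle, tables[test_cohort], test_labels
            )
    for cohort, value in lodo(tables, metadata, outcome, folds=folds,
                              repeats=repeats, seed=seed).items():
        grid.loc["LODO", cohort] = value
    return grid


def covariate_prediction(
    tables: dict[str, AbundanceTable], metadata: SampleMetadata, covariate: str,
    positive: str = "yes", folds: int = 5, repeats: int = 100, seed: int = 0,
) -> dict[str, float]:
    """LODO prediction of a binary clinical covariate from abundances.

    Identical machinery to response prediction: the covariate simply replaces
    the outcome label (1 = ``positive``).
    """
    col = metadata.data[covariate].dropna()
    relabeled = SampleMetadata(
        metadata.data.assign(orr=np.where(metadata.data[covariate] == positive, "R", "NR"))
    )
    relabeled.data.loc[~relabeled.data.index.isin(col.index), "orr"] = np.nan
    return lodo(tables, relabeled, outcome="orr", folds=folds, repeats=repeats, seed=seed)
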