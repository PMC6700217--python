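"""Penalized classification of drinking phenotype from LFP features.

The model is L1-penalized (lasso) logistic regression evaluated by
random 4-fold cross-validation repeated 100 times, with the penalty
strength chosen per training fold by inner cross-validation under the
minimum-mean-deviance rule (the glmnet default). Chance performance is
benchmarked by re-running the entire procedure on label permutations,
and single-feature information content is ranked by repeating the scheme
with unpenalized one-predictor logistic models, each against its own
permutation null.

Because every distribution is seeded, results are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import KFold, StratifiedKFold
from sklearn.preprocessing import StandardScaler

from .phenotype import PhenotypeLabels

__all__ = [
    "CohortTable",
    "ModelResult",
    "PermutationResult",
    "cv_lasso_accuracy",
    "permutation_null",
    "compare_real_vs_null",
    "single_feature_importance",
]

# glmnet-style penalty path: wide range, strong penalties included so the
# inner CV can select the null (all-zero) model under pure noise.
DEFAULT_CS = np.logspace(-2.0, 2.0, 15)
POSITIVE_CLASS = "HD"


@dataclass
class CohortTable:
    """Subjects x features matrix joined to HD/LD labels."""

    features: pd.DataFrame  # index: subject_id
    labels: pd.Series  # index: subject_id, values 'HD'/'LD'

    def __post_init__(self) -> None:
        self.labels = self.labels.reindex(self.features.index)
        if self.labels.isna().any():
            raise ValueError("every subject needs a label")
        if self.features.isna().any().any():
            raise ValueError("feature table contains missing values")
        counts = self.labels.value_counts()
        if len(counts) < 2 or counts.min() < 2:
            raise ValueError("need at least 2 subjects per class")

    @classmethod
    def from_vectors(cls, vectors, labels: PhenotypeLabels) -> "CohortTable":
        feats = pd.DataFrame({v.subject_id: v.values for v in vectors}).T
        return cls(features=feats, labels=labels.to_series().reindex(feats.index))

    @property
    def n_subjects(self) -> int:
        return len(self.features)

    @property
    def y(self) -> np.ndarray:
        """Binary outcome: 1 for the high-drinking class."""
        return (self.labels.to_numpy() == POSITIVE_CLASS).astype(int)

    @property
    def X(self) -> np.ndarray:
        return self.features.to_numpy(dtype=float)

    def with_labels(self, y: np.ndarray) -> "CohortTable":
        lab = pd.Series(
            np.where(np.asarray(y).astype(int) == 1, "HD", "LD"),
            index=self.features.index,
        )
        return CohortTable(features=self.features, labels=lab)


@dataclass
class ModelResult:
    """Repeated cross-validated accuracy of one model configuration."""

    mean_cv_accuracy: float
    per_repetition_accuracies: np.ndarray
    selected_features: pd.Series  # fraction of fits with nonzero coefficient
    seed: int
    folds: int

    def __post_init__(self) -> None:
        acc = np.asarray(self.per_repetition_accuracies, dtype=float)
        if np.any((acc < 0) | (acc > 1)):
            raise ValueError("accuracies must lie in [0, 1]")


@dataclass
class PermutationResult:
    """Real vs. label-permuted accuracy distributions with percentile CIs."""

    real: ModelResult
    null_accuracies: np.ndarray
    real_mean: float = field(init=False)
    null_mean: float = field(init=False)
    real_ci: Tuple[float, float] = field(init=False)
    null_ci: Tuple[float, float] = field(init=False)

    def __post_init__(self) -> None:
        self.null_accuracies = np.asarray(self.null_accuracies, dtype=float)
        self.real_mean = float(self.real.mean_cv_accuracy)
        self.null_mean = float(self.null_accuracies.mean())
        self.real_ci = tuple(
            np.percentile(self.real.per_repetition_accuracies, [2.5, 97.5])
        )
        self.null_ci = tuple(np.percentile(self.null_accuracies, [2.5, 97.5]))


def _lasso(C: float) -> LogisticRegression:
    # fixed random_state: liblinear's internal shuffling must not break
    # bit-reproducibility
    return LogisticRegression(
        l1_ratio=1.0, C=C, solver="liblinear", max_iter=1000, random_state=0
    )


def _mean_deviance(y_true: np.ndarray, proba: np.ndarray) -> float:
    p = np.clip(proba, 1e-15, 1 - 1e-15)
    return float(-np.mean(y_true * np.log(p) + (1 - y_true) * np.log(1 - p)))


def _fit_lasso_inner_cv(
    Xtr: np.ndarray,
    ytr: np.ndarray,
    seed: int,
    Cs: np.ndarray = DEFAULT_CS,
    inner_folds: int = 3,
) -> LogisticRegression:
    """Fit an L1 logistic model with C chosen by inner-CV minimum mean deviance.

    ``Cs`` are ordered weakest penalty last; ties break toward the
    strongest penalty (smallest C), mirroring glmnet's preference for
    sparser models. Refits on the full training data at the chosen C.
    """
    counts = np.bincount(ytr, minlength=2)
    k = int(min(inner_folds, counts[counts > 0].min()))
    if k >= 2:
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        dev = np.zeros(len(Cs))
        for tr, va in skf.split(Xtr, ytr):
            for i, C in enumerate(Cs):
                m = _lasso(C).fit(Xtr[tr], ytr[tr])
                col = list(m.classes_).index(1) if 1 in m.classes_ else None
                if col is None:
                    proba = np.zeros(len(va))
                else:
                    proba = m.predict_proba(Xtr[va])[:, col]
                dev[i] += _mean_deviance(ytr[va], proba)
        best_c = float(Cs[int(np.argmin(dev))])
    else:  # too few of one class for an inner split: use the median penalty
        best_c = float(np.median(Cs))
    return _lasso(best_c).fit(Xtr, ytr)


def _predict_hd(model, Xt: np.ndarray) -> np.ndarray:
    """Class prediction at probability threshold 0.5, ties toward HD."""
    if 1 not in model.classes_:
        return np.zeros(len(Xt), dtype=int)
    proba = model.predict_proba(Xt)[:, list(model.classes_).index(1)]
    return (proba >= 0.5).astype(int)


def _draw_folds(y: np.ndarray, folds: int, seed: int):
    """Plain random fold assignment, re-drawn until every training set
    contains both classes.

    Folds are not stratified: the permutation chance level of repeated CV
    on a 7/6 cohort reflects the negative correlation between a training
    fold's class balance and its held-out subjects, which stratification
    would remove.
    """
    fold_rng = np.random.default_rng(seed)
    while True:
        fold_seed = int(fold_rng.integers(0, 2**31 - 1))
        splits = list(
            KFold(n_splits=folds, shuffle=True, random_state=fold_seed).split(y)
        )
        if all(np.unique(y[train]).size == 2 for train, _ in splits):
            return splits


def _repeated_cv(
    X: np.ndarray,
    y: np.ndarray,
    folds: int,
    repetitions: int,
    seed: int,
    fit_fn,
) -> Tuple[np.ndarray, List]:
    """Repeated random k-fold CV; returns per-repetition pooled accuracy.

    ``fit_fn(X_train, y_train, rep_seed) -> fitted model`` supplies the
    learner; features are standardized inside each training fold.
    """
    n = len(y)
    if folds > n:
        raise ValueError("folds cannot exceed the number of subjects")
    rng = np.random.default_rng(seed)
    rep_seeds = rng.integers(0, 2**31 - 1, size=repetitions)
    accs = np.empty(repetitions)
    fitted = []
    for r, rs in enumerate(rep_seeds):
        splits = _draw_folds(y, folds, int(rs))
        preds = np.empty(n, dtype=int)
        for train, test in splits:
            scaler = StandardScaler().fit(X[train])
            Xtr = scaler.transform(X[train])
            Xte = scaler.transform(X[test])
            model = fit_fn(Xtr, y[train], int(rs))
            preds[test] = _predict_hd(model, Xte)
            fitted.append(model)
        accs[r] = float(np.mean(preds == y))
    return accs, fitted


def cv_lasso_accuracy(
    table: CohortTable,
    folds: int = 4,
    repetitions: int = 100,
    seed: int = 0,
    inner_folds: int = 3,
) -> ModelResult:
    """Repeated cross-validated accuracy of the lasso logistic model.

    Per repetition, subjects are split into random folds (re-drawn if a
    training set lacks a class); for each
    held-out fold an L1-penalized logistic model is fit on the remaining
    folds (features standardized on the training folds only) with the
    penalty chosen by inner CV minimizing mean deviance. Accuracy pools
    the held-out predictions over folds; the headline number is the mean
    over repetitions.
    """
    if repetitions < 1:
        raise ValueError("repetitions must be at least 1")
    X, y = table.X, table.y

    def fit(Xtr, ytr, rs):
        return _fit_lasso_inner_cv(Xtr, ytr, rs, inner_folds=inner_folds)

    accs, fitted = _repeated_cv(X, y, folds, repetitions, seed, fit)
    nonzero = np.zeros(X.shape[1])
    for model in fitted:
        nonzero += (np.abs(model.coef_[0]) > 0).astype(float)
    selected = pd.Series(nonzero / len(fitted), index=table.features.columns)
    return ModelResult(
        mean_cv_accuracy=float(accs.mean()),
        per_repetition_accuracies=accs,
        selected_features=selected,
        seed=seed,
        folds=folds,
    )


def permutation_null(
    table: CohortTable,
    n_permutations: int = 100,
    folds: int = 4,
    repetitions: int = 100,
    seed: int = 0,
) -> PermutationResult:
    """Benchmark the real model against label permutations.

    Each permutation shuffles the class labels (features untouched) and
    re-runs the full repeated-CV lasso procedure with fresh fold draws;
    the null distribution collects the per-permutation mean accuracies.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be at least 1")
    rng = np.random.default_rng(seed)
    real_seed = int(rng.integers(0, 2**31 - 1))
    real = cv_lasso_accuracy(table, folds=folds, repetitions=repetitions, seed=real_seed)
    null = np.empty(n_permutations)
    y = table.y
    for i in range(n_permutations):
        y_perm = rng.permutation(y)
        perm_seed = int(rng.integers(0, 2**31 - 1))
        res = cv_lasso_accuracy(
            table.with_labels(y_perm), folds=folds, repetitions=repetitions, seed=perm_seed
        )
        null[i] = res.mean_cv_accuracy
    return PermutationResult(real=real, null_accuracies=null)


def compare_real_vs_null(result: PermutationResult) -> Dict[str, object]:
    """Decision summary: does the real model outperform chance?

    The model outperforms when its mean accuracy exceeds the null
    distribution's 97.5th percentile. Means and 95% percentile intervals
    are reported in percent.
    """
    null_upper = float(np.percentile(result.null_accuracies, 97.5))
    return {
        "outperforms_chance": bool(result.real_mean > null_upper),
        "real_mean_pct": 100.0 * result.real_mean,
        "real_ci_pct": [100.0 * v for v in result.real_ci],
        "null_mean_pct": 100.0 * result.null_mean,
        "null_ci_pct": [100.0 * v for v in result.null_ci],
        "null_upper_pct": 100.0 * null_upper,
    }


def _single_feature_estimator(seed: int) -> LogisticRegression:
    return LogisticRegression(C=np.inf, solver="lbfgs", max_iter=500)


def single_feature_importance(
    table: CohortTable,
    folds: int = 4,
    repetitions: int = 20,
    n_permutations: int = 50,
    seed: int = 0,
) -> pd.DataFrame:
    """Exhaustive one-predictor logistic regressions, each with its own null.

    Every feature is evaluated alone by the same repeated-CV accuracy
    scheme (unpenalized logistic regression) and compared against a
    per-feature label-permutation null; a feature is flagged informative
    when its real mean accuracy exceeds its null 95th percentile. Rows
    are ranked by real mean accuracy (rank 1 = most informative).
    """
    if table.features.shape[1] < 1:
        raise ValueError("need at least one feature")
    X, y = table.X, table.y
    rng = np.random.default_rng(seed)

    def fit(Xtr, ytr, rs):
        return _single_feature_estimator(rs).fit(Xtr, ytr)

    rows = []
    for j, name in enumerate(table.features.columns):
        Xj = X[:, [j]]
        real_seed = int(rng.integers(0, 2**31 - 1))
        real_accs, _ = _repeated_cv(Xj, y, folds, repetitions, real_seed, fit)
        null_means = np.empty(n_permutations)
        for i in range(n_permutations):
            y_perm = rng.permutation(y)
            perm_seed = int(rng.integers(0, 2**31 - 1))
            accs, _ = _repeated_cv(Xj, y_perm, folds, repetitions, perm_seed, fit)
            null_means[i] = accs.mean()
        real_mean = float(real_accs.mean())
        null_95 = float(np.quantile(null_means, 0.95))
        rows.append(
            {
                "feature": name,
                "real_mean_accuracy": real_mean,
                "null_mean_accuracy": float(null_means.mean()),
                "null_95": null_95,
                "exceeds_null_95": bool(real_mean > null_95),
            }
        )
    out = pd.DataFrame(rows).sort_values(
        "real_mean_accuracy", ascending=False, kind="mergesort"
    )
    out["rank"] = np.arange(1, len(out) + 1)
    return out.set_index("feature")
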