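"""Gesture action vs morph as single categorical predictors of goal.

A naive Bayes classifier with one categorical feature reduces to
argmax_y P(y) * P(level | y): per predictor level the smoothed
class-conditional probabilities are estimated with Laplace smoothing
(alpha = 1 by default) and, optionally, after upsampling the training
rows so every target category matches the largest one (rebalancing gives
minority goals such as travel a chance against the dominant play goal).
Evaluation is stratified 10-fold cross-validation with two aggregate
accuracies: token-level (share of correctly classified tokens) and
goal-level (unweighted mean of per-goal recalls).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.model_selection import StratifiedKFold
from sklearn.utils.validation import check_is_fitted


class CategoricalNaiveBayes(ClassifierMixin, BaseEstimator):
    """Naive Bayes over a single categorical predictor.

    Parameters
    ----------
    alpha : float
        Laplace smoothing constant for the conditional level
        probabilities.
    upsample : bool
        If True, training rows are resampled (with replacement, seeded)
        so every target class matches the largest class's count before
        estimation.
    random_state : int
        Seed for the upsampling resampler.

    Attributes
    ----------
    classes_ : ndarray
        Target categories.
    class_log_prior_ : ndarray
        Log P(y) (estimated after any upsampling).
    feature_levels_ : list
        Predictor levels seen in training.
    cond_log_prob_ : ndarray of shape (n_classes, n_levels)
        Log P(level | y), rows summing to 1 in probability space.
    """

    def __init__(self, alpha: float = 1.0, upsample: bool = False,
                 random_state: int = 0):
        self.alpha = alpha
        self.upsample = upsample
        self.random_state = random_state

    def fit(self, X, y):
        x = np.asarray(X).ravel().astype(object)
        y = np.asarray(y).astype(object)
        if len(x) != len(y):
            raise ValueError("X and y length mismatch")
        classes, y_codes = np.unique(y, return_inverse=True)
        if len(classes) < 2:
            # degenerate but allowed inside CV folds: prior-only model
            pass
        if self.upsample:
            rng = np.random.default_rng(self.random_state)
            counts = np.bincount(y_codes, minlength=len(classes))
            target_n = counts.max()
            idx_all = []
            for k in range(len(classes)):
                idx = np.flatnonzero(y_codes == k)
                if len(idx) < target_n:
                    extra = rng.choice(idx, size=target_n - len(idx), replace=True)
                    idx = np.concatenate([idx, extra])
                idx_all.append(idx)
            sel = np.concatenate(idx_all)
            x, y_codes = x[sel], y_codes[sel]

        levels, x_codes = np.unique(x, return_inverse=True)
        n_c, n_l = len(classes), len(levels)
        counts = np.zeros((n_c, n_l))
        np.add.at(counts, (y_codes, x_codes), 1.0)
        class_counts = counts.sum(axis=1)
        self.classes_ = classes
        self.class_log_prior_ = np.log(class_counts / class_counts.sum())
        cond = (counts + self.alpha) / (
            class_counts[:, None] + self.alpha * n_l
        )
        self.cond_log_prob_ = np.log(cond)
        self.feature_levels_ = list(levels)
        self._level_index = {lv: i for i, lv in enumerate(levels)}
        return self

    def predict_log_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "classes_")
        x = np.asarray(X).ravel().astype(object)
        out = np.tile(self.class_log_prior_, (len(x), 1))
        for i, lv in enumerate(x):
            j = self._level_index.get(lv)
            if j is not None:
                out[i] += self.cond_log_prob_[:, j]
            # unseen level: prior-only prediction
        norm = out - out.max(axis=1, keepdims=True)
        return norm - np.log(np.exp(norm).sum(axis=1, keepdims=True))

    def predict_proba(self, X) -> np.ndarray:
        return np.exp(self.predict_log_proba(X))

    def predict(self, X) -> np.ndarray:
        return self.classes_[np.argmax(self.predict_log_proba(X), axis=1)]


def fit_naive_bayes(df: pd.DataFrame, predictor: str, target: str,
                    smoothing: float = 1.0, upsample: bool = False,
                    random_state: int = 0) -> CategoricalNaiveBayes:
    """Fit the single-predictor NB model on a token DataFrame."""
    model = CategoricalNaiveBayes(alpha=smoothing, upsample=upsample,
                                  random_state=random_state)
    return model.fit(df[predictor].to_numpy(), df[target].to_numpy())


@dataclass
class CVResult:
    """Cross-validation outcome for one predictor.

    ``token_accuracy`` is the mean over folds of the per-fold share of
    correctly classified tokens; ``per_class_recall`` pools predictions
    over all folds; ``class_mean_accuracy`` is the unweighted mean of
    those recalls ("goal-level accuracy"); ``chance_level`` is 1 / number
    of target categories.
    """

    predictor: str
    fold_accuracies: list[float]
    token_accuracy: float
    per_class_recall: dict[str, float]
    class_mean_accuracy: float
    chance_level: float
    n_tokens: int
    predictions: pd.DataFrame = field(repr=False, default=None)


def _stratified_folds(y: np.ndarray, folds: int, seed: int):
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    return list(skf.split(np.zeros(len(y)), y))


def cross_validate_predictor(df: pd.DataFrame, predictor: str, target: str,
                             folds: int = 10, seed: int = 0,
                             upsample: bool = False, smoothing: float = 1.0,
                             fold_indices=None) -> CVResult:
    """Stratified k-fold CV of the single-predictor NB classifier.

    Tokens with unknown targets must be removed beforehand. Folds are
    stratified by target and seeded; ``fold_indices`` lets callers reuse
    identical folds across predictors.
    """
    y = df[target].to_numpy()
    if len(df) < folds:
        raise ValueError("need at least as many tokens as folds")
    if fold_indices is None:
        fold_indices = _stratified_folds(y, folds, seed)
    x = df[predictor].to_numpy()

    fold_acc = []
    pred_all = np.empty(len(df), dtype=object)
    for f, (tr, te) in enumerate(fold_indices):
        model = CategoricalNaiveBayes(
            alpha=smoothing, upsample=upsample, random_state=seed + 1000 * f,
        ).fit(x[tr], y[tr])
        pred = model.predict(x[te])
        pred_all[te] = pred
        fold_acc.append(float((pred == y[te]).mean()))

    recalls = {}
    for cls in np.unique(y):
        mask = y == cls
        recalls[str(cls)] = float((pred_all[mask] == y[mask]).mean())
    preds = pd.DataFrame({"true": y, "pred": pred_all, "predictor_value": x})
    return CVResult(
        predictor=predictor,
        fold_accuracies=fold_acc,
        token_accuracy=float(np.mean(fold_acc)),
        per_class_recall=recalls,
        class_mean_accuracy=float(np.mean(list(recalls.values()))),
        chance_level=1.0 / len(np.unique(y)),
        n_tokens=len(df),
        predictions=preds,
    )


@dataclass
class PredictorComparison:
    action: CVResult
    morph: CVResult
    per_class: pd.DataFrame          # target class, recall_action, recall_morph
    morph_only_classes: list[str]    # classes predicted correctly only under morphs


def compare_predictors(df: pd.DataFrame, target: str = "goal",
                       action_col: str = "gesture_action",
                       morph_col: str = "morph", folds: int = 10,
                       seed: int = 0, upsample: bool = True,
                       smoothing: float = 1.0) -> PredictorComparison:
    """Cross-validate action vs morph as goal predictors on identical folds."""
    y = df[target].to_numpy()
    fold_indices = _stratified_folds(y, folds, seed)
    res_a = cross_validate_predictor(df, action_col, target, folds=folds,
                                     seed=seed, upsample=upsample,
                                     smoothing=smoothing, fold_indices=fold_indices)
    res_m = cross_validate_predictor(df, morph_col, target, folds=folds,
                                     seed=seed, upsample=upsample,
                                     smoothing=smoothing, fold_indices=fold_indices)
    classes = sorted(set(res_a.per_class_recall) | set(res_m.per_class_recall))
    per_class = pd.DataFrame({
        "target_class": classes,
        "recall_action": [res_a.per_class_recall.get(c, 0.0) for c in classes],
        "recall_morph": [res_m.per_class_recall.get(c, 0.0) for c in classes],
    })
    morph_only = per_class.loc[
        (per_class["recall_action"] == 0.0) & (per_class["recall_morph"] > 0.0),
        "target_class",
    ].tolist()
    return PredictorComparison(
        action=res_a, morph=res_m, per_class=per_class,
        morph_only_classes=morph_only,
    )
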