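"""Nested repeated stratified cross-validation, scaling, metrics, and the
permutation significance test.

The evaluation protocol is nested 10x10-fold CV: ten independent
repetitions of stratified 10-fold cross-validation, with feature scaling
and hyperparameter tuning performed inside each training partition, and
confusion counts recorded per held-out fold.  Reported metrics are means
and standard deviations over the 100 folds.  Significance of the mean test
accuracy is assessed by re-running the whole procedure under randomly
permuted class labels and applying the add-one permutation p-value
estimator p = (1 + b) / (1 + m), which can never return zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Protocol, Sequence

import numpy as np
from sklearn.model_selection import StratifiedKFold, KFold

from .elm import elm_predict, elm_train, tune_hidden_nodes

METRIC_NAMES = ("accuracy", "sensitivity", "specificity", "npv", "ppv", "f1")


# ---------------------------------------------------------------------------
# scaling

def minmax_scale_fit_apply(train: np.ndarray, test: np.ndarray | None = None):
    """Per-feature affine map sending the train min to -1 and the train max
    to +1; the same map is applied to ``test`` (whose values may then fall
    outside [-1, 1]).  A constant train feature maps to 0 everywhere.

    Returns ``(train_scaled, test_scaled, (mins, maxs))``; ``test_scaled``
    is None when no test matrix is given.
    """
    train = np.asarray(train, dtype=float)
    if train.size == 0:
        raise ValueError("train matrix is empty")
    mins = train.min(axis=0)
    maxs = train.max(axis=0)
    span = maxs - mins
    safe = np.where(span == 0, 1.0, span)

    def apply(X):
        scaled = 2.0 * (np.asarray(X, dtype=float) - mins) / safe - 1.0
        scaled[:, span == 0] = 0.0
        return scaled

    return apply(train), (apply(test) if test is not None else None), (mins, maxs)


# ---------------------------------------------------------------------------
# folds

def stratified_folds(y: np.ndarray, n_folds: int, seed: int,
                     *, stratified: bool = True):
    """Deterministic shuffled (stratified) k-fold assignment.

    Returns a list of ``(train_idx, test_idx)`` pairs.  With
    stratification, per-class counts across folds differ by at most one;
    each class must have at least ``n_folds`` members.
    """
    y = np.asarray(y)
    if stratified:
        _, counts = np.unique(y, return_counts=True)
        if counts.min() < n_folds:
            raise ValueError(
                f"smallest class has {counts.min()} members < {n_folds} folds")
        splitter = StratifiedKFold(n_splits=n_folds, shuffle=True,
                                   random_state=seed)
    else:
        splitter = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
    return list(splitter.split(np.zeros((len(y), 1)), y))


def repeat_split_seed(seed: int, repeat: int) -> int:
    """Seed of the fold splitter for one CV repetition."""
    return (seed + 100_003 * (repeat + 1)) % (2**31)


def fold_train_seed(seed: int, repeat: int, fold: int) -> int:
    """Seed handed to the classifier for one (repeat, fold) cell."""
    return (seed + 1_299_709 * (repeat + 1) + 15_485_863 * (fold + 1)) % (2**31)


# ---------------------------------------------------------------------------
# classifier interface

class ClassifierSpec(Protocol):
    """Anything nested_cv can evaluate: a fit/predict pair with a seed."""

    def fit(self, X: np.ndarray, y: np.ndarray, seed: int): ...

    def predict(self, model, X: np.ndarray) -> np.ndarray: ...


@dataclass(frozen=True)
class ELMSpec:
    """ELM classifier specification for the CV driver.

    Either a fixed ``n_hidden`` or a ``search_range`` of hidden-node
    candidates (tuned by inner stratified CV at fit time) must be given.
    """

    n_hidden: int | None = None
    search_range: tuple[int, ...] | None = None
    activation: str = "sigmoid"
    inner_folds: int = 10

    def __post_init__(self):
        if self.n_hidden is None and not self.search_range:
            raise ValueError("give n_hidden or a search_range")

    def resolve_n_hidden(self, X, y, seed: int) -> int:
        if self.search_range and len(self.search_range) > 1:
            best, _ = tune_hidden_nodes(X, y, self.search_range,
                                        n_folds=self.inner_folds, seed=seed,
                                        activation=self.activation)
            return best
        if self.search_range:
            return self.search_range[0]
        return self.n_hidden

    def fit(self, X, y, seed: int):
        return elm_train(X, y, self.resolve_n_hidden(X, y, seed), seed,
                         activation=self.activation)

    def fit_fixed(self, X, y, n_hidden: int, seed: int):
        return elm_train(X, y, n_hidden, seed, activation=self.activation)

    def predict(self, model, X):
        return elm_predict(model, X)


@dataclass(frozen=True)
class SklearnSpec:
    """Adapter for comparison classifiers (SVM, LDA, random forest...).

    ``factory`` builds an unfitted estimator; a ``random_state`` parameter
    is seeded per fold when the estimator exposes one.
    """

    factory: object

    def fit(self, X, y, seed: int):
        est = self.factory()
        if "random_state" in est.get_params():
            est.set_params(random_state=seed)
        return est.fit(X, y)

    def predict(self, model, X):
        return model.predict(X)


# ---------------------------------------------------------------------------
# metrics

@dataclass(frozen=True)
class ConfusionCounts:
    """Binary confusion counts; the positive class is the patient group
    (the larger label under the 0 = control / 1 = patient encoding)."""

    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @classmethod
    def from_predictions(cls, y_true, y_pred, positive) -> "ConfusionCounts":
        y_true = np.asarray(y_true)
        y_pred = np.asarray(y_pred)
        pos_t = y_true == positive
        pos_p = y_pred == positive
        return cls(tp=int((pos_t & pos_p).sum()),
                   tn=int((~pos_t & ~pos_p).sum()),
                   fp=int((~pos_t & pos_p).sum()),
                   fn=int((pos_t & ~pos_p).sum()))


@dataclass(frozen=True)
class MetricSet:
    """The six confusion-matrix metrics; a 0/0 ratio is NaN (undefined) and
    is excluded from aggregation rather than coerced to 0 or 1."""

    accuracy: float
    sensitivity: float
    specificity: float
    npv: float
    ppv: float
    f1: float

    def as_dict(self) -> dict:
        return {name: getattr(self, name) for name in METRIC_NAMES}


def _ratio(num: int, den: int) -> float:
    return num / den if den > 0 else math.nan


def confusion_metrics(counts: ConfusionCounts) -> MetricSet:
    """Accuracy, sensitivity, specificity, NPV, PPV and F1 from counts:

    * accuracy    = (TP + TN) / (TP + TN + FP + FN)
    * sensitivity = TP / (TP + FN)
    * specificity = TN / (FP + TN)
    * NPV         = TN / (FN + TN)
    * PPV         = TP / (TP + FP)
    * F1          = 2 TP / (2 TP + FP + FN)
    """
    if counts.total == 0:
        raise ValueError("empty confusion matrix")
    c = counts
    return MetricSet(
        accuracy=_ratio(c.tp + c.tn, c.total),
        sensitivity=_ratio(c.tp, c.tp + c.fn),
        specificity=_ratio(c.tn, c.fp + c.tn),
        npv=_ratio(c.tn, c.fn + c.tn),
        ppv=_ratio(c.tp, c.tp + c.fp),
        f1=_ratio(2 * c.tp, 2 * c.tp + c.fp + c.fn),
    )


# ---------------------------------------------------------------------------
# nested CV

@dataclass(frozen=True)
class CVConfig:
    """Protocol knobs for nested repeated cross-validation.

    ``scaling_mode='per_fold_train'`` fits the [-1, 1] scaler on each
    training partition only (no leakage); ``'global'`` fits it once on the
    full matrix, replicating pipelines that scale before splitting;
    ``'none'`` passes features through untouched, for matrices that are
    already scaled (per-fold rescaling of a weighted fused matrix would
    cancel its block weights).
    ``tuning_mode='inner'`` tunes hyperparameters by inner CV on the
    training partition; ``'paper_replication'`` selects them by accuracy on
    the outer test fold.
    """

    n_folds: int = 10
    n_repeats: int = 10
    seed: int = 0
    scaling_mode: str = "per_fold_train"
    tuning_mode: str = "inner"
    stratified: bool = True

    def __post_init__(self):
        if self.n_folds < 2 or self.n_repeats < 1:
            raise ValueError("need n_folds >= 2 and n_repeats >= 1")
        if self.scaling_mode not in ("per_fold_train", "global", "none"):
            raise ValueError(f"unknown scaling_mode {self.scaling_mode!r}")
        if self.tuning_mode not in ("inner", "paper_replication"):
            raise ValueError(f"unknown tuning_mode {self.tuning_mode!r}")


@dataclass(frozen=True)
class CVResult:
    """Per-fold confusion counts plus aggregated metrics."""

    fold_counts: tuple          # of (repeat, fold, ConfusionCounts)
    metric_means: dict
    metric_stds: dict
    train_accuracy_mean: float
    chosen_hyperparams: tuple = ()

    @property
    def mean_test_accuracy(self) -> float:
        return self.metric_means["accuracy"]

    def pooled_counts(self) -> ConfusionCounts:
        """Sum of all per-fold counts (count-weighted aggregate)."""
        return ConfusionCounts(
            tp=sum(c.tp for _, _, c in self.fold_counts),
            tn=sum(c.tn for _, _, c in self.fold_counts),
            fp=sum(c.fp for _, _, c in self.fold_counts),
            fn=sum(c.fn for _, _, c in self.fold_counts),
        )


def _aggregate(per_fold_metrics: list[MetricSet]):
    means, stds = {}, {}
    for name in METRIC_NAMES:
        vals = np.array([m.as_dict()[name] for m in per_fold_metrics])
        vals = vals[~np.isnan(vals)]
        means[name] = float(vals.mean()) if vals.size else math.nan
        stds[name] = float(vals.std()) if vals.size else math.nan
    return means, stds


def nested_cv(X: np.ndarray, y: np.ndarray, clf: ClassifierSpec,
              config: CVConfig) -> CVResult:
    """Run the full nested repeated-CV protocol for one feature matrix.

    For every repeat r and fold f: scale per ``config.scaling_mode``, tune
    per ``config.tuning_mode``, train on the training partition with the
    fold seed, predict the held-out fold, and record confusion counts.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.shape[0] != len(y):
        raise ValueError("X rows do not align with labels")
    positive = np.unique(y)[-1]

    global_scaled = None
    if config.scaling_mode == "global":
        global_scaled, _, _ = minmax_scale_fit_apply(X)

    fold_counts = []
    per_fold_metrics = []
    train_accs = []
    chosen = []
    for r in range(config.n_repeats):
        splits = stratified_folds(y, config.n_folds,
                                  repeat_split_seed(config.seed, r),
                                  stratified=config.stratified)
        for f, (tr, te) in enumerate(splits):
            if config.scaling_mode == "global":
                Xtr, Xte = global_scaled[tr], global_scaled[te]
            elif config.scaling_mode == "none":
                Xtr, Xte = X[tr], X[te]
            else:
                Xtr, Xte, _ = minmax_scale_fit_apply(X[tr], X[te])
            seed = fold_train_seed(config.seed, r, f)
            try:
                if (config.tuning_mode == "paper_replication"
                        and getattr(clf, "search_range", None)
                        and len(clf.search_range) > 1):
                    model, pred, n_hidden = _fit_by_outer_fold(
                        clf, Xtr, y[tr], Xte, y[te], seed)
                    chosen.append((r, f, n_hidden))
                else:
                    model = clf.fit(Xtr, y[tr], seed)
                    pred = clf.predict(model, Xte)
                    if hasattr(model, "n_hidden"):
                        chosen.append((r, f, model.n_hidden))
            except Exception as exc:
                raise RuntimeError(
                    f"classifier failed at repeat {r}, fold {f}: {exc}") from exc
            counts = ConfusionCounts.from_predictions(y[te], pred, positive)
            fold_counts.append((r, f, counts))
            per_fold_metrics.append(confusion_metrics(counts))
            train_pred = clf.predict(model, Xtr)
            train_accs.append(float((train_pred == y[tr]).mean()))

    means, stds = _aggregate(per_fold_metrics)
    return CVResult(fold_counts=tuple(fold_counts), metric_means=means,
                    metric_stds=stds,
                    train_accuracy_mean=float(np.mean(train_accs)),
                    chosen_hyperparams=tuple(chosen))


def _fit_by_outer_fold(clf, Xtr, ytr, Xte, yte, seed):
    """Hyperparameter choice by outer test-fold accuracy (replication mode;
    reuses held-out data for tuning and is therefore optimistically biased)."""
    best = (-1.0, None, None, None)
    for n_hidden in clf.search_range:
        model = clf.fit_fixed(Xtr, ytr, n_hidden, seed)
        pred = clf.predict(model, Xte)
        acc = float((pred == yte).mean())
        if acc > best[0]:
            best = (acc, model, pred, n_hidden)
    return best[1], best[2], best[3]


# ---------------------------------------------------------------------------
# permutation test

@dataclass(frozen=True)
class PermutationResult:
    observed_stat: float
    n_permutations: int
    n_as_extreme: int

    @property
    def p_value(self) -> float:
        """Add-one estimator (1 + b) / (1 + m); never returns zero, and at
        10,000 permutations its floor is 1/10,001 ~ 0.0001."""
        return (1 + self.n_as_extreme) / (1 + self.n_permutations)


def permutation_test(X, y, clf: ClassifierSpec, config: CVConfig,
                     n_permutations: int, seed: int) -> PermutationResult:
    """Permutation significance of the nested-CV mean test accuracy.

    The observed statistic is the mean test accuracy on the true labels;
    each permutation re-runs the identical CV procedure (splits, scaling,
    tuning) on randomly permuted labels.  Permuted statistics >= the
    observed one count as extreme (ties count against significance).
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    y = np.asarray(y)
    observed = nested_cv(X, y, clf, config).mean_test_accuracy
    rng = np.random.default_rng(seed)
    extreme = 0
    for _ in range(n_permutations):
        y_perm = rng.permutation(y)
        stat = nested_cv(X, y_perm, clf, config).mean_test_accuracy
        if stat >= observed:
            extreme += 1
    return PermutationResult(observed_stat=observed,
                             n_permutations=n_permutations,
                             n_as_extreme=extreme)
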