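"""Weighted multimodal feature fusion.

The fusion scheme assigns each measure a scalar weight derived from how
well that measure alone classifies the cohort.  With A_i the per-measure
cross-validated test accuracies and A_max their maximum, the residual is
R_i = A_max - A_i and the weight

    W_i = 1 - R_i = 1 - A_max + A_i,

so the best measure gets weight exactly 1 and every weight lies in [0, 1]
(for accuracies in [0, 1]).  Three concatenation variants are provided:

* simple concatenation      — blocks side by side, unweighted;
* simple weighted           — each block multiplied by its weight;
* hybrid weighted           — the cortical blocks are weighted and jointly
  divided by the sum of their weights, likewise the subcortical +
  whole-brain blocks, and the group-ICA connectivity block is appended
  unweighted.

Each measure is min-max scaled to [-1, 1] *before* weighting and the fused
matrix is not rescaled afterwards: per-feature rescaling after weighting
would cancel the scalar weights exactly, leaving the classifier blind to
them.  A ``rescale_after_fusion`` flag exists to demonstrate that
cancellation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from dataclasses import replace

from .datamodel import MultimodalDataset
from .evaluation import (ConfusionCounts, CVConfig, CVResult, ClassifierSpec,
                         _aggregate, confusion_metrics, fold_train_seed,
                         minmax_scale_fit_apply, nested_cv,
                         repeat_split_seed, stratified_folds)

#: Published per-measure ELM nested-CV test accuracies for the twelve
#: measures of the 144-subject schizophrenia-vs-control study this package
#: reimplements (structural FreeSurfer measures, global-connectivity ROI
#: averages, and group-ICA connectivity).  These are the inputs of the
#: weight formula's worked example; keys are weight keys.
REFERENCE_MEASURE_ACCURACIES = {
    "Thickness": 0.9114,
    "Thickness STD": 0.9048,
    "Surface Area": 0.8813,
    "Volume": 0.9063,
    "Curvature": 0.9238,
    "WM": 0.8956,
    "Cortical GCOR": 0.9057,
    "SC Volume": 0.8989,
    "SC Intensity": 0.8990,
    "SC GCOR": 0.9124,
    "Overall Volume": 0.9105,
    "Group ICA": 0.9295,
}


@dataclass(frozen=True)
class AccuracyVector:
    """Per-measure accuracies A_i keyed by weight key, with A_max and the
    residuals R_i = A_max - A_i."""

    accuracies: dict

    def __post_init__(self):
        if not self.accuracies:
            raise ValueError("accuracy vector is empty")
        for key, a in self.accuracies.items():
            if not 0.0 <= a <= 1.0:
                raise ValueError(f"accuracy of {key!r} is {a}, outside [0, 1]")

    @property
    def a_max(self) -> float:
        return max(self.accuracies.values())

    @property
    def residuals(self) -> dict:
        amax = self.a_max
        return {k: amax - a for k, a in self.accuracies.items()}


@dataclass(frozen=True)
class WeightVector:
    """Fusion weights W_i in [0, 1] keyed by weight key; the most accurate
    measure's weight is exactly 1."""

    weights: dict

    def __post_init__(self):
        for key, w in self.weights.items():
            if not 0.0 <= w <= 1.0 + 1e-12:
                raise ValueError(f"weight of {key!r} is {w}, outside [0, 1]")

    def __getitem__(self, key: str) -> float:
        return self.weights[key]

    def rounded(self, ndigits: int = 4) -> dict:
        """Display rounding; weights are used at full precision internally."""
        return {k: round(w, ndigits) for k, w in self.weights.items()}


def compute_weights(acc: AccuracyVector) -> WeightVector:
    """W_i = 1 - A_max + A_i, at full precision.

    Shift-consistent: adding a constant to every A_i leaves W unchanged,
    since W depends on A_i only through A_i - A_max.
    """
    amax = acc.a_max
    return WeightVector({k: 1.0 - amax + a for k, a in acc.accuracies.items()})


def reference_weights() -> WeightVector:
    """Weights computed from the published per-measure accuracies."""
    return compute_weights(AccuracyVector(dict(REFERENCE_MEASURE_ACCURACIES)))


def per_measure_accuracy(dataset: MultimodalDataset, clf: ClassifierSpec,
                         config: CVConfig) -> AccuracyVector:
    """Nested-CV mean test accuracy of each weighted measure on its own.

    Measures sharing a weight key (the whole-brain intensity and
    global-connectivity blocks reuse their subcortical counterparts'
    weights) are concatenated and evaluated as one unit, so the vector has
    one entry per weight key.
    """
    y = dataset.labels.y
    out = {}
    for key in dataset.weight_keys:
        blocks = [m.values for m in dataset.measures if m.weight_key == key]
        X = np.hstack(blocks)
        out[key] = nested_cv(X, y, clf, config).mean_test_accuracy
    return AccuracyVector(out)


def _block(m, scale: bool) -> np.ndarray:
    if not scale:
        return m.values
    scaled, _, _ = minmax_scale_fit_apply(m.values)
    return scaled


def simple_concat(dataset: MultimodalDataset,
                  subset: list[str] | None = None, *,
                  scale: bool = True) -> np.ndarray:
    """Column-wise concatenation of measure blocks in dataset order;
    ``subset`` restricts to the named measures.  ``scale`` applies the
    per-measure [-1, 1] min-max scaling (on by default, as everywhere in
    the fusion pipeline)."""
    labels = subset if subset is not None else dataset.measure_labels
    unknown = [l for l in labels if l not in dataset.measure_labels]
    if unknown:
        raise KeyError(f"unknown measure labels {unknown}")
    if not labels:
        raise ValueError("empty measure subset")
    keep = [m for m in dataset.measures if m.label in set(labels)]
    return np.hstack([_block(m, scale) for m in keep])


def simple_weighted_concat(dataset: MultimodalDataset,
                           weights: WeightVector, *,
                           scale: bool = True) -> np.ndarray:
    """Each scaled block multiplied by its measure's scalar weight, then
    concatenated: [W1*M1 || W2*M2 || ... || W12*M12]."""
    _require_weights(dataset, weights, include_gica=True)
    return np.hstack([weights[m.weight_key] * _block(m, scale)
                      for m in dataset.measures])


def hybrid_weighted_concat(dataset: MultimodalDataset, weights: WeightVector,
                           *, scale: bool = True,
                           rescale_after_fusion: bool = False) -> np.ndarray:
    """Anatomically-normalized weighted concatenation.

    The cortical blocks are weighted and divided by the sum of the cortical
    weights; the subcortical and whole-brain blocks are weighted and
    divided by the sum of the *distinct* weights used there (whole-brain
    intensity and connectivity share their subcortical counterparts'
    weights); group-ICA connectivity features are appended unweighted.
    Column count equals that of simple concatenation.

    ``rescale_after_fusion`` re-applies per-feature [-1, 1] scaling to the
    fused matrix, which cancels the weighting; it exists only to
    demonstrate that effect.
    """
    _require_weights(dataset, weights)
    cortical = [m for m in dataset.measures if m.group == "cortical"]
    subcort = [m for m in dataset.measures
               if m.group in ("subcortical", "wholebrain")]
    gica = [m for m in dataset.measures if m.group == "gica"]
    if not cortical or not subcort:
        raise ValueError(
            "hybrid concatenation needs both cortical and subcortical measures")

    def norm_block(measures):
        distinct = {m.weight_key for m in measures}
        wsum = sum(weights[k] for k in distinct)
        return np.hstack([weights[m.weight_key] * _block(m, scale)
                          for m in measures]) / wsum

    blocks = [norm_block(cortical), norm_block(subcort)]
    if gica:
        blocks.append(np.hstack([_block(m, scale) for m in gica]))
    fused = np.hstack(blocks)
    if rescale_after_fusion:
        fused, _, _ = minmax_scale_fit_apply(fused)
    return fused


def column_weights(dataset: MultimodalDataset, weights: WeightVector,
                   method: str = "hybrid") -> np.ndarray:
    """Per-column multiplier vector equivalent to a fusion method.

    Because the [-1, 1] min-max scaling is per feature, every fusion
    variant factors into "scale each column, then multiply it by a
    scalar"; this returns those scalars in dataset column order (``simple``
    -> all ones, ``weighted`` -> the block's weight, ``hybrid`` -> the
    block's weight over the sum of its anatomical group's distinct
    weights, 1 for group-ICA columns).
    """
    if method not in ("simple", "weighted", "hybrid"):
        raise ValueError(f"unknown fusion method {method!r}")
    if method == "simple":
        return np.ones(sum(m.n_features for m in dataset.measures))
    _require_weights(dataset, weights, include_gica=(method == "weighted"))
    if method == "hybrid":
        cortical = {m.weight_key for m in dataset.measures
                    if m.group == "cortical"}
        subcort = {m.weight_key for m in dataset.measures
                   if m.group in ("subcortical", "wholebrain")}
        if not cortical or not subcort:
            raise ValueError("hybrid concatenation needs both cortical and "
                             "subcortical measures")
        denom = {**{k: sum(weights[j] for j in cortical) for k in cortical},
                 **{k: sum(weights[j] for j in subcort) for k in subcort}}
    cols = []
    for m in dataset.measures:
        if method == "hybrid" and m.group == "gica":
            w = 1.0
        elif method == "hybrid":
            w = weights[m.weight_key] / denom[m.weight_key]
        else:
            w = weights[m.weight_key]
        cols.append(np.full(m.n_features, w))
    return np.concatenate(cols)


def nested_cv_fused(dataset: MultimodalDataset, clf: ClassifierSpec,
                    config: CVConfig, *, method: str = "hybrid",
                    weights: WeightVector | None = None,
                    weight_config: CVConfig | None = None) -> CVResult:
    """Nested CV of a fused feature matrix without weight leakage.

    With ``weights=None`` (the default), the per-measure accuracies — and
    hence the fusion weights — are re-estimated inside each outer training
    partition, so no held-out subject influences the weights applied to
    it.  Passing a precomputed ``weights`` instead reproduces the simpler
    protocol that estimates the weights once on the whole cohort (which
    reuses test subjects in weight estimation and is optimistically
    biased).

    Feature scaling follows ``config.scaling_mode``; the scalar column
    multipliers from :func:`column_weights` are applied *after* scaling,
    never rescaled away.  ``weight_config`` controls the inner weight-
    estimation CV (default: one repeat of the outer protocol).
    """
    X = np.hstack([m.values for m in dataset.measures])
    y = dataset.labels.y
    if weight_config is None:
        weight_config = replace(config, n_repeats=1)

    key_columns = {}
    start = 0
    for m in dataset.measures:
        key_columns.setdefault(m.weight_key, []).extend(
            range(start, start + m.n_features))
        start += m.n_features

    global_scaled = None
    if config.scaling_mode == "global":
        global_scaled, _, _ = minmax_scale_fit_apply(X)

    positive = np.unique(y)[-1]
    fold_counts, per_fold_metrics, train_accs = [], [], []
    for r in range(config.n_repeats):
        splits = stratified_folds(y, config.n_folds,
                                  repeat_split_seed(config.seed, r),
                                  stratified=config.stratified)
        for f, (tr, te) in enumerate(splits):
            seed = fold_train_seed(config.seed, r, f)
            if weights is None and method != "simple":
                accs = {}
                for key, cols in key_columns.items():
                    wcfg = replace(weight_config, seed=seed)
                    accs[key] = nested_cv(X[np.ix_(tr, cols)], y[tr], clf,
                                          wcfg).mean_test_accuracy
                fold_w = compute_weights(AccuracyVector(accs))
            else:
                fold_w = weights
            colw = column_weights(dataset, fold_w, method)
            if config.scaling_mode == "global":
                Xtr, Xte = global_scaled[tr], global_scaled[te]
            elif config.scaling_mode == "none":
                Xtr, Xte = X[tr], X[te]
            else:
                Xtr, Xte, _ = minmax_scale_fit_apply(X[tr], X[te])
            model = clf.fit(Xtr * colw, y[tr], seed)
            pred = clf.predict(model, Xte * colw)
            counts = ConfusionCounts.from_predictions(y[te], pred, positive)
            fold_counts.append((r, f, counts))
            per_fold_metrics.append(confusion_metrics(counts))
            train_pred = clf.predict(model, Xtr * colw)
            train_accs.append(float((train_pred == y[tr]).mean()))

    means, stds = _aggregate(per_fold_metrics)
    return CVResult(fold_counts=tuple(fold_counts), metric_means=means,
                    metric_stds=stds,
                    train_accuracy_mean=float(np.mean(train_accs)))


def _require_weights(dataset: MultimodalDataset, weights: WeightVector,
                     *, include_gica: bool = False) -> None:
    needed = {m.weight_key for m in dataset.measures
              if include_gica or m.group != "gica"}
    missing = sorted(needed - set(weights.weights))
    if missing:
        raise KeyError(f"no weight for measures {missing}")
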