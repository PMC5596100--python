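"""Extreme learning machine (ELM) binary classifier.

A single-hidden-layer feedforward network whose input weights and biases
are drawn at random and never trained; only the output weights are
learned, as the minimum-norm least-squares solution of H @ beta = T with
H the hidden-layer activation matrix and T the one-hot +/-1 target matrix.
The sole hyperparameter is the number of hidden nodes, tuned by scanning a
range of candidates with inner cross-validation.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np

ACTIVATIONS = {
    "sigmoid": lambda a: 1.0 / (1.0 + np.exp(-a)),
    "tanh": np.tanh,
}

#: relative singular-value cutoff for the pseudo-inverse
PINV_RCOND = 1e-12


@dataclass(frozen=True)
class ELMModel:
    """Fitted ELM: frozen random hidden layer plus learned output weights."""

    n_hidden: int
    input_weights: np.ndarray   # n_hidden x d
    biases: np.ndarray          # n_hidden
    output_weights: np.ndarray  # n_hidden x c
    activation: str
    classes: tuple            # ordered class encoding; ties -> classes[0]
    seed: int

    @property
    def n_features(self) -> int:
        return self.input_weights.shape[1]

    def hidden(self, X: np.ndarray) -> np.ndarray:
        return ACTIVATIONS[self.activation](X @ self.input_weights.T + self.biases)

    def scores(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.n_features:
            raise ValueError(
                f"expected {self.n_features} features, got shape {X.shape}")
        return self.hidden(X) @ self.output_weights

    def save(self, path) -> None:
        payload = {
            "n_hidden": self.n_hidden,
            "input_weights": self.input_weights.tolist(),
            "biases": self.biases.tolist(),
            "output_weights": self.output_weights.tolist(),
            "activation": self.activation,
            "classes": list(self.classes),
            "seed": self.seed,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def load(cls, path) -> "ELMModel":
        with open(path) as fh:
            p = json.load(fh)
        return cls(
            n_hidden=p["n_hidden"],
            input_weights=np.asarray(p["input_weights"], dtype=float),
            biases=np.asarray(p["biases"], dtype=float),
            output_weights=np.asarray(p["output_weights"], dtype=float),
            activation=p["activation"],
            classes=tuple(p["classes"]),
            seed=p["seed"],
        )


def elm_train(X: np.ndarray, y: np.ndarray, n_hidden: int, seed: int,
              *, activation: str = "sigmoid") -> ELMModel:
    """Fit an ELM on (ideally [-1, 1]-scaled) features.

    Input weights and biases are drawn uniformly on [-1, 1] from a
    generator seeded with ``seed``, so the fit is fully deterministic given
    ``(X, y, n_hidden, seed)``.  Targets are encoded one-hot in {-1, +1}
    and the output weights are ``pinv(H) @ T``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if n_hidden < 1:
        raise ValueError(f"n_hidden must be >= 1, got {n_hidden}")
    if activation not in ACTIVATIONS:
        raise ValueError(f"unknown activation {activation!r}")
    classes = tuple(np.unique(y).tolist())
    if len(classes) < 2:
        raise ValueError("training labels contain a single class")
    n, d = X.shape
    rng = np.random.default_rng(seed)
    W = rng.uniform(-1.0, 1.0, size=(n_hidden, d))
    b = rng.uniform(-1.0, 1.0, size=n_hidden)
    H = ACTIVATIONS[activation](X @ W.T + b)
    T = np.full((n, len(classes)), -1.0)
    for k, c in enumerate(classes):
        T[y == c, k] = 1.0
    beta = np.linalg.pinv(H, rcond=PINV_RCOND) @ T
    return ELMModel(n_hidden=n_hidden, input_weights=W, biases=b,
                    output_weights=beta, activation=activation,
                    classes=classes, seed=seed)


def elm_predict(model: ELMModel, X: np.ndarray) -> np.ndarray:
    """Predict class of the maximal output-node score; ties go to the
    first class in the model's class encoding."""
    scores = model.scores(X)
    # argmax returns the first index on ties, which is classes[0]
    idx = np.argmax(scores, axis=1)
    return np.asarray(model.classes, dtype=object)[idx]


def tune_hidden_nodes(X, y, search_range, *, n_folds: int = 10, seed: int = 0,
                      activation: str = "sigmoid"):
    """Scan hidden-node candidates by stratified CV on the training data.

    Returns ``(best_n, profile)`` where ``profile`` is the mean CV accuracy
    per candidate in search order; ties break toward the first maximizer.
    A candidate at least as large as the inner-training size is still
    evaluated (the pseudo-inverse handles the underdetermined system) but
    triggers an overfitting warning.
    """
    from sklearn.model_selection import StratifiedKFold

    search_range = list(search_range)
    if not search_range:
        raise ValueError("search_range must be nonempty")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if len(search_range) == 1:
        return search_range[0], [float("nan")]

    _, counts = np.unique(y, return_counts=True)
    k = min(n_folds, int(counts.min()))
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    splits = list(skf.split(X, y))
    inner_train = min(len(tr) for tr, _ in splits)
    big = [c for c in search_range if c >= inner_train]
    if big:
        warnings.warn(
            f"hidden-node candidates {big} are >= the inner training size "
            f"({inner_train}); exact interpolation is likely", stacklevel=2)

    profile = []
    for j, n_hidden in enumerate(search_range):
        correct = total = 0
        for f, (tr, te) in enumerate(splits):
            model = elm_train(X[tr], y[tr], n_hidden,
                              seed=seed + 7919 * f + 104729 * j,
                              activation=activation)
            correct += int((elm_predict(model, X[te]) == y[te]).sum())
            total += len(te)
        profile.append(correct / total)
    best = search_range[int(np.argmax(profile))]
    return best, profile
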