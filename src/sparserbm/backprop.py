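"""From-scratch backpropagation baselines: softmax regression and a one-hidden-layer MLP.

Both networks share one code path parameterised by the hidden-layer width:
``hidden_units=None`` gives plain multinomial logistic regression (a softmax
output layer on the raw features), an integer gives a multilayer perceptron
with one logistic-sigmoid hidden layer.  Training is mini-batch stochastic
gradient descent on the mean cross-entropy, with no regularisation,
momentum or early stopping — the point of these baselines is to expose how
far plain error backpropagation overfits, so nothing is done to help it
generalise.

Gradients are exact and derived by hand (softmax + cross-entropy gives the
usual ``p - onehot(y)`` output delta; the sigmoid hidden layer backpropagates
``delta W_out * a * (1 - a)``); the test-suite checks every coordinate
against central finite differences.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit, softmax
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

__all__ = [
    "NetParams",
    "NetTrainConfig",
    "forward",
    "cross_entropy",
    "backprop_gradients",
    "SGDNetClassifier",
    "fit",
    "predict",
]


def _as_float(x) -> np.ndarray:
    arr = np.asarray(x)
    return arr if arr.dtype.kind == "f" else arr.astype(float)


@dataclass
class NetParams:
    """Ordered (weights, bias) pairs; one layer for LR, two for the MLP.

    Hidden layers use the logistic sigmoid, the output layer softmax.
    """

    layers: list[tuple[np.ndarray, np.ndarray]]

    def __post_init__(self):
        if len(self.layers) not in (1, 2):
            raise ValueError("supported architectures have 1 (LR) or 2 (MLP) layers")
        self.layers = [(_as_float(W), _as_float(b)) for W, b in self.layers]
        for k, (W, b) in enumerate(self.layers):
            if W.ndim != 2 or b.shape != (W.shape[1],):
                raise ValueError(f"layer {k}: bias length must match weight columns")
            if not (np.all(np.isfinite(W)) and np.all(np.isfinite(b))):
                raise ValueError("network parameters must be finite")
        for (W1, _), (W2, _) in zip(self.layers, self.layers[1:]):
            if W1.shape[1] != W2.shape[0]:
                raise ValueError("consecutive layer dimensions do not chain")

    @property
    def n_classes(self) -> int:
        return self.layers[-1][0].shape[1]

    def copy(self) -> "NetParams":
        return NetParams([(W.copy(), b.copy()) for W, b in self.layers])


@dataclass(frozen=True)
class NetTrainConfig:
    """Hyper-parameters of mini-batch SGD."""

    learning_rate: float = 0.1
    batch_size: int = 50
    epochs: int = 200
    seed: int = 0

    def __post_init__(self):
        if not self.learning_rate > 0:
            raise ValueError("learning_rate must be positive")
        if self.batch_size < 1 or self.epochs < 0:
            raise ValueError("batch_size must be >= 1 and epochs >= 0")


def _activations(params: NetParams, X: np.ndarray) -> list[np.ndarray]:
    """Layer outputs, input first, softmax probabilities last."""
    X = np.atleast_2d(np.asarray(X, dtype=params.layers[0][0].dtype))
    if X.shape[1] != params.layers[0][0].shape[0]:
        raise ValueError(
            f"expected {params.layers[0][0].shape[0]} features, got {X.shape[1]}"
        )
    acts = [X]
    for k, (W, b) in enumerate(params.layers):
        z = acts[-1] @ W + b
        acts.append(softmax(z, axis=1) if k == len(params.layers) - 1 else expit(z))
    return acts


def forward(params: NetParams, X: np.ndarray) -> np.ndarray:
    """Class-probability table; each row is a softmax output summing to 1."""
    return _activations(params, X)[-1]


def cross_entropy(params: NetParams, X: np.ndarray, y: np.ndarray) -> float:
    """Mean negative log-probability of the true class."""
    p = forward(params, X)
    y = np.asarray(y, dtype=int)
    return float(-np.mean(np.log(np.clip(p[np.arange(len(y)), y], 1e-300, None))))


def backprop_gradients(params: NetParams, X: np.ndarray, y: np.ndarray) -> NetParams:
    """Exact gradients of the mean cross-entropy, mirroring the layer structure."""
    y = np.asarray(y, dtype=int)
    if np.any(y < 0) or np.any(y >= params.n_classes):
        raise ValueError("labels out of range for the output layer")
    acts = _activations(params, X)
    n = acts[0].shape[0]
    if y.shape != (n,):
        raise ValueError("y length must match the number of rows of X")
    # output delta of softmax + cross-entropy
    delta = acts[-1].copy()
    delta[np.arange(n), y] -= 1.0
    delta /= n
    grads: list[tuple[np.ndarray, np.ndarray]] = []
    for k in range(len(params.layers) - 1, -1, -1):
        W, _ = params.layers[k]
        grads.append((acts[k].T @ delta, delta.sum(axis=0)))
        if k > 0:
            a = acts[k]  # sigmoid hidden activations
            delta = (delta @ W.T) * a * (1.0 - a)
    grads.reverse()
    return NetParams(grads)


class SGDNetClassifier(ClassifierMixin, BaseEstimator):
    """Softmax regression (``hidden_units=None``) or one-hidden-layer MLP,
    trained by plain mini-batch SGD on cross-entropy.

    Parameters
    ----------
    hidden_units : int or None
        Width of the single sigmoid hidden layer; ``None`` removes it,
        yielding multinomial logistic regression.
    learning_rate, batch_size, n_epochs : SGD hyper-parameters.
    random_state : int or None
        Seeds the Gaussian initialisation (std 0.01, zero biases); epoch
        shuffles are re-seeded per epoch from the same seed.

    Attributes
    ----------
    layers_ : list of (weights, bias) pairs
    classes_ : ndarray
    """

    def __init__(
        self,
        hidden_units: int | None = None,
        learning_rate: float = 0.1,
        batch_size: int = 50,
        n_epochs: int = 200,
        random_state: int | None = None,
        dtype: str = "float64",
    ):
        self.hidden_units = hidden_units
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.n_epochs = n_epochs
        self.random_state = random_state
        self.dtype = dtype

    def fit(self, X, y):
        config = NetTrainConfig(
            learning_rate=self.learning_rate,
            batch_size=self.batch_size,
            epochs=self.n_epochs,
        )
        X, y = check_X_y(X, y)
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        if len(self.classes_) < 2:
            raise ValueError("need at least two classes")
        n, d = X.shape
        n_classes = len(self.classes_)
        seed = 0 if self.random_state is None else int(self.random_state)
        rng = np.random.default_rng(seed)
        if self.hidden_units is None:
            shapes = [(d, n_classes)]
        else:
            if self.hidden_units <= 0:
                raise ValueError("hidden_units must be positive or None")
            shapes = [(d, self.hidden_units), (self.hidden_units, n_classes)]
        dt = np.dtype(self.dtype)
        X = X.astype(dt, copy=False)
        params = NetParams(
            [
                ((0.01 * rng.standard_normal(s)).astype(dt), np.zeros(s[1], dtype=dt))
                for s in shapes
            ]
        )
        eta = config.learning_rate
        for epoch in range(config.epochs):
            order = np.random.default_rng([seed, epoch]).permutation(n)
            for start in range(0, n, config.batch_size):
                idx = order[start : start + config.batch_size]
                grads = backprop_gradients(params, X[idx], y_idx[idx])
                for (W, b), (gW, gb) in zip(params.layers, grads.layers):
                    W -= eta * gW
                    b -= eta * gb
        self.layers_ = params.layers
        self.n_features_in_ = d
        return self

    def params_(self) -> NetParams:
        check_is_fitted(self, "layers_")
        return NetParams(self.layers_)

    def predict_proba(self, X):
        check_is_fitted(self, "layers_")
        return forward(self.params_(), check_array(X))

    def predict(self, X):
        proba = self.predict_proba(X)
        # ties broken toward the higher class index
        rev = np.argmax(proba[:, ::-1], axis=1)
        return self.classes_[proba.shape[1] - 1 - rev]


def fit(train, architecture, config: NetTrainConfig):
    """Train a baseline on a labelled dataset.

    ``architecture`` is ``"LR"`` or ``("MLP", n_hidden)``; returns the
    fitted :class:`NetParams`.
    """
    if architecture == "LR":
        hidden = None
    elif isinstance(architecture, tuple) and architecture[0] == "MLP":
        hidden = int(architecture[1])
    else:
        raise ValueError("architecture must be 'LR' or ('MLP', n_hidden)")
    clf = SGDNetClassifier(
        hidden_units=hidden,
        learning_rate=config.learning_rate,
        batch_size=config.batch_size,
        n_epochs=config.epochs,
        random_state=config.seed,
    )
    clf.fit(train.X, train.y)
    return clf.params_()


def predict(params: NetParams, X: np.ndarray) -> np.ndarray:
    """Argmax of the forward pass; ties go to the higher class index."""
    proba = forward(params, X)
    rev = np.argmax(proba[:, ::-1], axis=1)
    return proba.shape[1] - 1 - rev
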