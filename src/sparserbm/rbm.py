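"""Bernoulli restricted Boltzmann machine with a joint feature+label visible layer.

The model is a bipartite energy-based network: ``m`` visible units ``v`` and
``n`` hidden units ``h`` with no intra-layer connections, energy

    H(v, h) = - sum_ij w_ij h_i v_j - sum_j b_j v_j - sum_i c_i h_i.

Bipartiteness makes both conditionals factorial and logistic
(``p(h_i=1|v) = sigma(W v + c)_i`` and symmetrically for the visibles),
which is what makes block Gibbs sampling and contrastive-divergence
training cheap.

Training follows the Hebbian-like contrastive rule

    dw_ij = eta * ( <v_j h_i>_data - <v_j h_i>_recon ),

the difference between data-clamped and reconstruction correlations of the
two units the weight connects.  Both terms are products of unit activities,
so a visible unit that is zero in both phases contributes nothing to its
weights: the rule learns only from co-active units.  Two estimators of the
reconstruction term are provided: CD-tau (restart the chain at every data
batch) and persistent CD (fantasy chains that survive across updates).

For classification the label is appended to the visible layer (one unit for
two classes, a one-hot group otherwise) and the RBM is trained on the joint
distribution of features and label.  Prediction clamps the feature units and
either runs Gibbs sweeps over label and hidden units or evaluates the exact
label posterior from free energies of the label completions.

Numerics: conditionals use ``scipy.special.expit`` and the free energy uses
``log1p``-based softplus, so nothing overflows for any finite weights.
Real-valued (centred) features are clamped as-is in the positive phase; the
Bernoulli structure only enters when the negative phase recomputes visible
units, where mean-field probabilities are used instead of binary samples to
reduce reconstruction noise.  Hidden units are sampled to drive the chains,
but correlation statistics use their probabilities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

__all__ = [
    "RBMParams",
    "RBMTrainConfig",
    "GibbsChainState",
    "energy",
    "hidden_conditional",
    "visible_conditional",
    "sample_bernoulli",
    "free_energy",
    "phase_statistics",
    "cd_update",
    "pcd_update",
    "RBMClassifier",
    "fit_classifier",
    "predict",
]


def _as_float(x) -> np.ndarray:
    arr = np.asarray(x)
    return arr if arr.dtype.kind == "f" else arr.astype(float)


@dataclass
class RBMParams:
    """Weights and biases of the energy function.

    ``weights`` is ``n_hidden x n_visible`` (entry ``w_ij`` links hidden ``i``
    to visible ``j``); the last ``n_label_units`` visible units encode the
    label when the RBM is used as a joint classifier.
    """

    weights: np.ndarray
    visible_bias: np.ndarray
    hidden_bias: np.ndarray
    n_label_units: int = 0

    def __post_init__(self):
        # preserve float32 buffers; promote anything non-float to float64
        self.weights = _as_float(self.weights)
        self.visible_bias = _as_float(self.visible_bias)
        self.hidden_bias = _as_float(self.hidden_bias)
        n_h, n_v = self.weights.shape
        if self.visible_bias.shape != (n_v,):
            raise ValueError("visible_bias length must equal n_visible")
        if self.hidden_bias.shape != (n_h,):
            raise ValueError("hidden_bias length must equal n_hidden")
        for arr in (self.weights, self.visible_bias, self.hidden_bias):
            if not np.all(np.isfinite(arr)):
                raise ValueError("RBM parameters must be finite")
        if not (0 <= self.n_label_units < n_v):
            raise ValueError("need 0 <= n_label_units < n_visible")

    @property
    def n_hidden(self) -> int:
        return self.weights.shape[0]

    @property
    def n_visible(self) -> int:
        return self.weights.shape[1]

    def copy(self) -> "RBMParams":
        return RBMParams(
            self.weights.copy(),
            self.visible_bias.copy(),
            self.hidden_bias.copy(),
            self.n_label_units,
        )


@dataclass(frozen=True)
class RBMTrainConfig:
    """Hyper-parameters of contrastive-divergence training."""

    learning_rate: float = 0.1
    batch_size: int = 50
    epochs: int = 50
    cd_steps: int = 1
    algorithm: str = "pcd"
    visible_mode: str = "mean_field"
    seed: int = 0

    def __post_init__(self):
        if not self.learning_rate > 0:
            raise ValueError("learning_rate must be positive")
        if self.batch_size < 1 or self.cd_steps < 1 or self.epochs < 0:
            raise ValueError("batch_size, cd_steps must be >= 1 and epochs >= 0")
        if self.algorithm not in ("cd", "pcd"):
            raise ValueError("algorithm must be 'cd' or 'pcd'")
        if self.visible_mode not in ("mean_field", "sample"):
            raise ValueError("visible_mode must be 'mean_field' or 'sample'")


@dataclass
class GibbsChainState:
    """Persistent fantasy particles of PCD (one Markov chain per row)."""

    fantasy_visible: np.ndarray
    fantasy_hidden: np.ndarray


def _check_v(params: RBMParams, v: np.ndarray) -> np.ndarray:
    v = _as_float(v)
    if v.shape[-1] != params.n_visible:
        raise ValueError(
            f"visible vector has length {v.shape[-1]}, expected {params.n_visible}"
        )
    return v


def _check_h(params: RBMParams, h: np.ndarray) -> np.ndarray:
    h = _as_float(h)
    if h.shape[-1] != params.n_hidden:
        raise ValueError(
            f"hidden vector has length {h.shape[-1]}, expected {params.n_hidden}"
        )
    return h


def energy(params: RBMParams, v: np.ndarray, h: np.ndarray) -> float:
    """Joint energy H(v, h) of one configuration."""
    v = _check_v(params, v)
    h = _check_h(params, h)
    return float(
        -h @ params.weights @ v - params.visible_bias @ v - params.hidden_bias @ h
    )


def hidden_conditional(params: RBMParams, v: np.ndarray) -> np.ndarray:
    """p(h_i = 1 | v) = sigma(W v + c), elementwise; accepts a batch of rows."""
    v = _check_v(params, v)
    return expit(v @ params.weights.T + params.hidden_bias)


def visible_conditional(params: RBMParams, h: np.ndarray) -> np.ndarray:
    """p(v_j = 1 | h) = sigma(W^T h + b), elementwise; accepts a batch of rows."""
    h = _check_h(params, h)
    return expit(h @ params.weights + params.visible_bias)


def sample_bernoulli(p: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Independent Bernoulli draws with success probabilities ``p``."""
    p = _as_float(p)
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("probabilities must lie in [0, 1]")
    return (rng.random(p.shape) < p).astype(p.dtype)


def free_energy(params: RBMParams, v: np.ndarray) -> np.ndarray | float:
    """F(v) = -b.v - sum_i softplus(c_i + (W v)_i), with P(v) proportional to exp(-F).

    The hidden layer is summed out analytically; evaluation is overflow-safe
    for any finite parameters.
    """
    v = _check_v(params, v)
    act = v @ params.weights.T + params.hidden_bias
    softplus = np.where(act > 0, act, 0.0) + np.log1p(np.exp(-np.abs(act)))
    out = -(v @ params.visible_bias) - softplus.sum(axis=-1)
    return float(out) if np.ndim(out) == 0 else out


def phase_statistics(h: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Batch-averaged pairwise correlations <v_j h_i> as an n_hidden x n_visible table.

    This is the only quantity the contrastive weight rule looks at: the
    update to ``w_ij`` depends on units ``i`` and ``j`` alone, and any
    visible unit at zero contributes a zero column.
    """
    h = np.atleast_2d(np.asarray(h, dtype=float))
    v = np.atleast_2d(np.asarray(v, dtype=float))
    if h.shape[0] != v.shape[0]:
        raise ValueError("hidden and visible batches must have equal row counts")
    return h.T @ v / h.shape[0]


def _gibbs_steps(params, v_start, tau, rng, binary_visible: bool = False):
    """Run ``tau`` alternating block-Gibbs steps from ``v_start``.

    Hidden units are sampled binary to drive the chain; visible units are
    set to their mean-field probabilities (default) or sampled binary when
    ``binary_visible``.  Returns the final visible state, the last binary
    hidden sample and the hidden probabilities at the final visible state.
    """
    v = v_start
    h = None
    for _ in range(tau):
        ph = hidden_conditional(params, v)
        h = sample_bernoulli(ph, rng)
        v = visible_conditional(params, h)
        if binary_visible:
            v = sample_bernoulli(v, rng)
    ph_end = hidden_conditional(params, v)
    return v, h, ph_end


def _cd_gradients(params, v0, v_start, config, rng):
    """Positive statistics from the clamped batch, negative from a chain
    started at ``v_start``; returns (dW, db, dc, v_end, h_end)."""
    v0 = np.atleast_2d(_check_v(params, v0))
    if v0.shape[0] == 0:
        raise ValueError("empty batch")
    ph0 = hidden_conditional(params, v0)
    v_end, h_end, ph_end = _gibbs_steps(
        params, v_start, config.cd_steps, rng,
        binary_visible=config.visible_mode == "sample",
    )
    eta = config.learning_rate
    dW = eta * (phase_statistics(ph0, v0) - phase_statistics(ph_end, v_end))
    db = eta * (v0.mean(axis=0) - v_end.mean(axis=0))
    dc = eta * (ph0.mean(axis=0) - ph_end.mean(axis=0))
    return dW, db, dc, v_end, h_end


def cd_update(
    params: RBMParams,
    batch: np.ndarray,
    config: RBMTrainConfig,
    rng: np.random.Generator,
) -> RBMParams:
    """One CD-tau parameter update from a data batch; returns new parameters."""
    batch = np.atleast_2d(_check_v(params, batch))
    dW, db, dc, _, _ = _cd_gradients(params, batch, batch, config, rng)
    return RBMParams(
        params.weights + dW,
        params.visible_bias + db,
        params.hidden_bias + dc,
        params.n_label_units,
    )


def pcd_update(
    params: RBMParams,
    batch: np.ndarray,
    chains: GibbsChainState,
    config: RBMTrainConfig,
    rng: np.random.Generator,
) -> tuple[RBMParams, GibbsChainState]:
    """One persistent-CD update: the negative chain resumes from ``chains``
    instead of restarting at the data.  Returns new parameters and the
    advanced chains."""
    batch = np.atleast_2d(_check_v(params, batch))
    fv = np.atleast_2d(_check_v(params, chains.fantasy_visible))
    dW, db, dc, v_end, h_end = _cd_gradients(params, batch, fv, config, rng)
    new = RBMParams(
        params.weights + dW,
        params.visible_bias + db,
        params.hidden_bias + dc,
        params.n_label_units,
    )
    return new, GibbsChainState(v_end, h_end)


# ---------------------------------------------------------------------------
# joint classifier


def _posterior_exact(params: RBMParams, X: np.ndarray) -> np.ndarray:
    """Exact label posterior p(class | features) from free energies of each
    label completion; returns an (n_samples, n_classes) table."""
    L = params.n_label_units
    if L == 0:
        raise ValueError("RBM has no label units")
    d = params.n_visible - L
    X = np.atleast_2d(np.asarray(X, dtype=params.weights.dtype))
    if X.shape[1] != d:
        raise ValueError(f"expected {d} features, got {X.shape[1]}")
    n_classes = 2 if L == 1 else L
    F = np.empty((X.shape[0], n_classes))
    for c in range(n_classes):
        lab = np.zeros((X.shape[0], L))
        if L == 1:
            lab[:, 0] = c
        else:
            lab[:, c] = 1.0
        F[:, c] = free_energy(params, np.hstack([X, lab]))
    # p(c|x) = softmax over classes of -F
    F -= F.min(axis=1, keepdims=True)
    p = np.exp(-F)
    return p / p.sum(axis=1, keepdims=True)


def _posterior_gibbs(
    params: RBMParams,
    X: np.ndarray,
    n_gibbs: int,
    burn_in: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Label posterior estimated by block Gibbs sampling with the feature
    units clamped every sweep; label and hidden units are resampled.

    Returns the post-burn-in average of the label-unit conditional
    probabilities (a Rao-Blackwellised estimate of the posterior),
    normalised to an (n_samples, n_classes) table.
    """
    if n_gibbs <= burn_in:
        raise ValueError("n_gibbs must exceed burn_in")
    L = params.n_label_units
    if L == 0:
        raise ValueError("RBM has no label units")
    d = params.n_visible - L
    X = np.atleast_2d(np.asarray(X, dtype=params.weights.dtype))
    if X.shape[1] != d:
        raise ValueError(f"expected {d} features, got {X.shape[1]}")
    W_feat = params.weights[:, :d]
    W_lab = params.weights[:, d:]
    b_lab = params.visible_bias[d:]
    # features are clamped: their contribution to hidden activations is fixed
    base = X @ W_feat.T + params.hidden_bias
    label_state = sample_bernoulli(
        np.full((X.shape[0], L), 0.5, dtype=X.dtype), rng
    )
    acc = np.zeros((X.shape[0], L))
    for sweep in range(n_gibbs):
        ph = expit(base + label_state @ W_lab.T)
        h = sample_bernoulli(ph, rng)
        p_lab = expit(h @ W_lab + b_lab)
        label_state = sample_bernoulli(p_lab, rng)
        if sweep >= burn_in:
            acc += p_lab
    mean_lab = acc / (n_gibbs - burn_in)
    if L == 1:
        return np.column_stack([1.0 - mean_lab[:, 0], mean_lab[:, 0]])
    total = mean_lab.sum(axis=1, keepdims=True)
    return np.where(total > 0, mean_lab / total, 1.0 / L)


class RBMClassifier(ClassifierMixin, BaseEstimator):
    """Joint RBM classifier trained by contrastive divergence.

    The visible layer concatenates the feature units with label units (one
    unit for two classes, a one-hot group otherwise); training models the
    joint distribution of features and label with CD or persistent CD, and
    prediction clamps the features and reads out the label.

    Parameters
    ----------
    n_hidden : int
        Number of hidden units.
    learning_rate : float
        Step size of the contrastive updates.
    batch_size : int
        Mini-batch size; PCD also maintains this many fantasy chains.
    n_epochs : int
        Passes over the training set.  Zero returns the initialisation.
    cd_steps : int
        Gibbs steps per update (the tau of CD-tau).
    algorithm : {'pcd', 'cd'}
        Negative-phase estimator.
    predict_mode : {'gibbs', 'exact'}
        Label readout: Gibbs sampling with clamped features, or the exact
        free-energy posterior.
    n_gibbs, burn_in : int
        Sweeps and discarded initial sweeps of the Gibbs readout.
    random_state : int or None
        Seed for initialisation, batch order, chain noise and readout noise.

    Attributes
    ----------
    weights_ : ndarray of shape (n_hidden, n_features + n_label_units)
    visible_bias_, hidden_bias_ : ndarray
    n_label_units_ : int
    classes_ : ndarray
    """

    def __init__(
        self,
        n_hidden: int = 500,
        learning_rate: float = 0.1,
        batch_size: int = 50,
        n_epochs: int = 50,
        cd_steps: int = 1,
        algorithm: str = "pcd",
        visible_mode: str = "mean_field",
        predict_mode: str = "gibbs",
        n_gibbs: int = 100,
        burn_in: int = 50,
        random_state: int | None = None,
        init_std: float = 0.01,
        dtype: str = "float64",
    ):
        self.n_hidden = n_hidden
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.n_epochs = n_epochs
        self.cd_steps = cd_steps
        self.algorithm = algorithm
        self.visible_mode = visible_mode
        self.predict_mode = predict_mode
        self.n_gibbs = n_gibbs
        self.burn_in = burn_in
        self.random_state = random_state
        self.init_std = init_std
        self.dtype = dtype

    # -- training ----------------------------------------------------------

    def fit(self, X, y):
        if self.n_hidden <= 0:
            raise ValueError("n_hidden must be positive")
        config = RBMTrainConfig(
            learning_rate=self.learning_rate,
            batch_size=self.batch_size,
            epochs=self.n_epochs,
            cd_steps=self.cd_steps,
            algorithm=self.algorithm,
            visible_mode=self.visible_mode,
        )
        X, y = check_X_y(X, y)
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        if len(self.classes_) < 2:
            raise ValueError("need at least two classes")
        L = 1 if len(self.classes_) == 2 else len(self.classes_)
        if L == 1:
            labels = y_idx[:, None].astype(float)
        else:
            labels = np.eye(L)[y_idx]
        dt = np.dtype(self.dtype)
        V = np.hstack([X, labels]).astype(dt)
        n, n_visible = V.shape

        rng = np.random.default_rng(self.random_state)
        params = RBMParams(
            (self.init_std * rng.standard_normal((self.n_hidden, n_visible))).astype(dt),
            np.zeros(n_visible, dtype=dt),
            np.zeros(self.n_hidden, dtype=dt),
            n_label_units=L,
        )
        chains = None
        for _ in range(config.epochs):
            order = rng.permutation(n)
            for start in range(0, n, config.batch_size):
                batch = V[order[start : start + config.batch_size]]
                if config.algorithm == "cd":
                    start_v = batch
                else:
                    if chains is None:
                        chains = GibbsChainState(batch.copy(), None)
                    start_v = chains.fantasy_visible
                dW, db, dc, v_end, h_end = _cd_gradients(
                    params, batch, start_v, config, rng
                )
                params.weights += dW
                params.visible_bias += db
                params.hidden_bias += dc
                if config.algorithm == "pcd":
                    chains = GibbsChainState(v_end, h_end)

        self.weights_ = params.weights
        self.visible_bias_ = params.visible_bias
        self.hidden_bias_ = params.hidden_bias
        self.n_label_units_ = L
        self.n_features_in_ = X.shape[1]
        return self

    def params_(self) -> RBMParams:
        """Fitted parameters bundled as an :class:`RBMParams`."""
        check_is_fitted(self, "weights_")
        return RBMParams(
            self.weights_, self.visible_bias_, self.hidden_bias_, self.n_label_units_
        )

    # -- prediction --------------------------------------------------------

    def predict_proba(self, X):
        check_is_fitted(self, "weights_")
        X = check_array(X)
        if self.predict_mode == "exact":
            return _posterior_exact(self.params_(), X)
        if self.predict_mode != "gibbs":
            raise ValueError("predict_mode must be 'gibbs' or 'exact'")
        rng = np.random.default_rng(
            np.random.SeedSequence(
                entropy=0 if self.random_state is None else self.random_state,
                spawn_key=(2, self._predict_counter()),
            )
        )
        return _posterior_gibbs(self.params_(), X, self.n_gibbs, self.burn_in, rng)

    def _predict_counter(self) -> int:
        # every predict call consumes a fresh, deterministic noise stream
        self._n_predicts = getattr(self, "_n_predicts", 0) + 1
        return self._n_predicts

    def predict(self, X):
        proba = self.predict_proba(X)
        # ties broken toward the higher class index
        rev = np.argmax(proba[:, ::-1], axis=1)
        idx = proba.shape[1] - 1 - rev
        return self.classes_[idx]


# ---------------------------------------------------------------------------
# functional wrappers


def fit_classifier(train, n_hidden: int, config: RBMTrainConfig) -> RBMParams:
    """Train a joint RBM classifier on a labelled dataset; returns its parameters."""
    clf = RBMClassifier(
        n_hidden=n_hidden,
        learning_rate=config.learning_rate,
        batch_size=config.batch_size,
        n_epochs=config.epochs,
        cd_steps=config.cd_steps,
        algorithm=config.algorithm,
        random_state=config.seed,
    )
    clf.fit(train.X, train.y)
    return clf.params_()


def predict(
    params: RBMParams,
    X: np.ndarray,
    mode: str = "gibbs",
    n_gibbs: int = 100,
    burn_in: int = 50,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Predict binary labels for clamped features with a fitted RBM."""
    if mode == "exact":
        proba = _posterior_exact(params, X)
    elif mode == "gibbs":
        if rng is None:
            rng = np.random.default_rng(0)
        proba = _posterior_gibbs(params, X, n_gibbs, burn_in, rng)
    else:
        raise ValueError("mode must be 'gibbs' or 'exact'")
    rev = np.argmax(proba[:, ::-1], axis=1)
    return proba.shape[1] - 1 - rev
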