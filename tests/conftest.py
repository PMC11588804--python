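"""Shared fixtures and independent brute-force oracles.

The oracles here never call the package's vectorised code paths: energies
are triple loops over indices and distributions are exhaustive enumerations
of all binary configurations, so they can serve as ground truth for the
analytic conditionals, the free energy and the label posterior.
"""

import itertools

import numpy as np
import pytest

from sparserbm.rbm import RBMParams


def oracle_energy(W, b, c, v, h) -> float:
    """Triple-loop energy evaluation, independent of the package's matmuls."""
    total = 0.0
    n_h, n_v = W.shape
    for i in range(n_h):
        for j in range(n_v):
            total -= W[i, j] * h[i] * v[j]
    for j in range(n_v):
        total -= b[j] * v[j]
    for i in range(n_h):
        total -= c[i] * h[i]
    return total


def all_states(n: int) -> np.ndarray:
    return np.array(list(itertools.product((0.0, 1.0), repeat=n)))


def oracle_joint(params: RBMParams) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Exhaustive joint distribution over all (v, h) binary configurations.

    Returns (visible states, hidden states, probability matrix p[v, h]).
    """
    V = all_states(params.n_visible)
    H = all_states(params.n_hidden)
    logp = np.array(
        [
            [
                -oracle_energy(
                    params.weights, params.visible_bias, params.hidden_bias, v, h
                )
                for h in H
            ]
            for v in V
        ]
    )
    p = np.exp(logp - logp.max())
    return V, H, p / p.sum()


def oracle_hidden_conditional(params: RBMParams, v: np.ndarray) -> np.ndarray:
    """P(h_i = 1 | v) by enumerating all hidden configurations."""
    H = all_states(params.n_hidden)
    w = np.array(
        [
            np.exp(
                -oracle_energy(
                    params.weights, params.visible_bias, params.hidden_bias, v, h
                )
            )
            for h in H
        ]
    )
    return (H * w[:, None]).sum(axis=0) / w.sum()


def oracle_visible_conditional(params: RBMParams, h: np.ndarray) -> np.ndarray:
    """P(v_j = 1 | h) by enumerating all visible configurations."""
    V = all_states(params.n_visible)
    w = np.array(
        [
            np.exp(
                -oracle_energy(
                    params.weights, params.visible_bias, params.hidden_bias, v, h
                )
            )
            for v in V
        ]
    )
    return (V * w[:, None]).sum(axis=0) / w.sum()


def oracle_label_posterior(params: RBMParams, x: np.ndarray) -> np.ndarray:
    """P(label | features) for a single-label-unit RBM, by enumerating the
    label unit and all hidden configurations with the features clamped."""
    assert params.n_label_units == 1
    H = all_states(params.n_hidden)
    mass = np.empty(2)
    for lab in (0, 1):
        v = np.concatenate([x, [float(lab)]])
        mass[lab] = sum(
            np.exp(
                -oracle_energy(
                    params.weights, params.visible_bias, params.hidden_bias, v, h
                )
            )
            for h in H
        )
    return mass / mass.sum()


def random_params(n_visible, n_hidden, seed, scale=1.0, n_label_units=0) -> RBMParams:
    rng = np.random.default_rng(seed)
    return RBMParams(
        scale * rng.standard_normal((n_hidden, n_visible)),
        scale * rng.standard_normal(n_visible),
        scale * rng.standard_normal(n_hidden),
        n_label_units=n_label_units,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def tiny_params():
    """A 3-visible, 2-hidden RBM small enough for exhaustive enumeration."""
    return random_params(3, 2, seed=7)
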