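"""Synthetic two-class Gaussian datasets with controlled sparsity.

The generative model is a two-class Gaussian mixture designed to probe the
curse of dimensionality: class 0 is centred at the origin, class 1 at a
vector of fives, and both classes share an isotropic covariance whose
variance is ``cov_scale * ||mean1 - mean0||``.  Scaling the variance with
the inter-mean distance keeps the Bayes error roughly comparable across
dimensionalities, so difficulty is controlled by a single knob
(``cov_scale``) plus the sparsification level.

Datasets move through three stages: ``raw`` (fresh Gaussian draws),
``centered`` (each feature shifted to zero mean over the full dataset) and
``sparsified`` (a uniformly random subset of features kept per sample, the
rest set to exactly zero).  The binary helpers (:func:`flip_bits`,
:func:`binarize`, :func:`make_binary_patterns`) support experiments on
sparse binary codes, where the information is carried by which units are
active rather than by real values.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "DatasetSpec",
    "LabeledDataset",
    "generate_gaussian_dataset",
    "center_features",
    "sparsify",
    "train_test_split",
    "flip_bits",
    "binarize",
    "make_binary_patterns",
    "calibrate_cov_scale",
    "save_dataset_csv",
    "load_dataset_csv",
    "save_dataset_npz",
    "load_dataset_npz",
    "read_idx",
]

STAGES = ("raw", "centered", "sparsified")


def _as_float_array(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite values")
    return arr


@dataclass(frozen=True)
class DatasetSpec:
    """Generative parameters of the synthetic two-Gaussian problem.

    Parameters
    ----------
    n_samples : int
        Total number of samples; the first half carries label 0.
    n_features : int
        Dimensionality ``d`` of the feature space.
    mean0, mean1 : array-like of shape (n_features,), optional
        Class means.  Defaults: all zeros (class 0) and all fives (class 1).
    cov_scale : float
        Scale factor applied to ``||mean1 - mean0||`` to obtain the shared
        per-feature variance.  Must be positive.
    sparsity : float
        Fraction ``s`` of features zeroed per sample during sparsification,
        ``0 <= s < 1``.
    train_fraction : float
        Fraction of samples assigned to the training split.
    seed : int
        Seed for all random draws derived from this spec.
    """

    n_samples: int = 2000
    n_features: int = 5000
    mean0: np.ndarray | None = None
    mean1: np.ndarray | None = None
    cov_scale: float = 4.0
    sparsity: float = 0.95
    train_fraction: float = 0.8
    seed: int = 0

    def __post_init__(self):
        if self.n_samples < 2:
            raise ValueError("n_samples must be at least 2")
        if self.n_features < 1:
            raise ValueError("n_features must be positive")
        if not self.cov_scale > 0:
            raise ValueError("cov_scale must be positive")
        if not (0.0 <= self.sparsity < 1.0):
            raise ValueError("sparsity must lie in [0, 1)")
        if not (0.0 < self.train_fraction < 1.0):
            raise ValueError("train_fraction must lie in (0, 1)")
        if self.keep_count < 1:
            raise ValueError("sparsity leaves no features: round((1-s)*d) < 1")
        m0, m1 = self.class_means()
        if m0.shape != (self.n_features,) or m1.shape != (self.n_features,):
            raise ValueError("class means must have length n_features")
        if np.array_equal(m0, m1):
            raise ValueError("class means must differ (zero separation)")

    def class_means(self) -> tuple[np.ndarray, np.ndarray]:
        m0 = (
            np.zeros(self.n_features)
            if self.mean0 is None
            else _as_float_array(self.mean0, "mean0")
        )
        m1 = (
            np.full(self.n_features, 5.0)
            if self.mean1 is None
            else _as_float_array(self.mean1, "mean1")
        )
        return m0, m1

    @property
    def feature_variance(self) -> float:
        """Shared per-feature variance: ``cov_scale * ||mean1 - mean0||``."""
        m0, m1 = self.class_means()
        return float(self.cov_scale * np.linalg.norm(m1 - m0))

    @property
    def keep_count(self) -> int:
        """Number of features kept per sample after sparsification."""
        return int(round((1.0 - self.sparsity) * self.n_features))


@dataclass
class LabeledDataset:
    """Feature matrix plus binary labels, tagged with its processing stage."""

    X: np.ndarray
    y: np.ndarray
    stage: str = "raw"

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y)
        if self.X.ndim != 2:
            raise ValueError("X must be 2-D (n_samples, n_features)")
        if self.y.shape != (self.X.shape[0],):
            raise ValueError("y length must match the number of rows of X")
        if self.stage not in STAGES:
            raise ValueError(f"stage must be one of {STAGES}")

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    def copy(self) -> "LabeledDataset":
        return LabeledDataset(self.X.copy(), self.y.copy(), self.stage)


def generate_gaussian_dataset(spec: DatasetSpec) -> LabeledDataset:
    """Draw the raw two-Gaussian dataset described by ``spec``.

    The first ``floor(n/2)`` rows are class 0 (mean at ``mean0``), the rest
    class 1 (mean at ``mean1``); every feature has the shared variance
    ``cov_scale * ||mean1 - mean0||``.  Deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    m0, m1 = spec.class_means()
    sd = np.sqrt(spec.feature_variance)
    n0 = spec.n_samples // 2
    n1 = spec.n_samples - n0
    X = np.empty((spec.n_samples, spec.n_features))
    X[:n0] = m0 + sd * rng.standard_normal((n0, spec.n_features))
    X[n0:] = m1 + sd * rng.standard_normal((n1, spec.n_features))
    y = np.concatenate([np.zeros(n0, dtype=int), np.ones(n1, dtype=int)])
    return LabeledDataset(X, y, stage="raw")


def center_features(data: LabeledDataset) -> LabeledDataset:
    """Subtract each feature's mean (over the full dataset) from that feature."""
    if data.stage != "raw":
        raise ValueError(f"expected a raw dataset, got stage={data.stage!r}")
    if data.n_samples == 0:
        raise ValueError("cannot center an empty dataset")
    X = data.X - data.X.mean(axis=0, keepdims=True)
    return LabeledDataset(X, data.y.copy(), stage="centered")


def sparsify(data: LabeledDataset, s: float, seed: int) -> LabeledDataset:
    """Keep ``round((1-s)*d)`` uniformly chosen features per row, zero the rest.

    The kept subset is drawn without replacement, independently per row.
    ``s = 0`` keeps every feature (the dataset only changes stage).
    """
    if data.stage != "centered":
        raise ValueError(f"expected a centered dataset, got stage={data.stage!r}")
    if not (0.0 <= s < 1.0):
        raise ValueError("sparsity must lie in [0, 1)")
    d = data.n_features
    k = int(round((1.0 - s) * d))
    if k < 1:
        raise ValueError("sparsity leaves no features per row")
    if k == d:
        return LabeledDataset(data.X.copy(), data.y.copy(), stage="sparsified")
    rng = np.random.default_rng(seed)
    # argsort of iid uniforms -> a uniform random k-subset per row
    order = np.argsort(rng.random(data.X.shape), axis=1)
    mask = np.zeros(data.X.shape, dtype=bool)
    np.put_along_axis(mask, order[:, :k], True, axis=1)
    X = np.where(mask, data.X, 0.0)
    return LabeledDataset(X, data.y.copy(), stage="sparsified")


def train_test_split(
    data: LabeledDataset, train_fraction: float, seed: int
) -> tuple[LabeledDataset, LabeledDataset]:
    """Random permutation split into ``round(n*f)`` train and the rest test."""
    if not (0.0 < train_fraction < 1.0):
        raise ValueError("train_fraction must lie in (0, 1)")
    n = data.n_samples
    n_train = int(round(n * train_fraction))
    if n_train < 1 or n - n_train < 1:
        raise ValueError("split would leave an empty train or test part")
    perm = np.random.default_rng(seed).permutation(n)
    tr, te = perm[:n_train], perm[n_train:]
    train = LabeledDataset(data.X[tr], data.y[tr], data.stage)
    test = LabeledDataset(data.X[te], data.y[te], data.stage)
    return train, test


def flip_bits(table: np.ndarray) -> np.ndarray:
    """Complement a binary table: every entry x -> 1 - x."""
    arr = np.asarray(table)
    if not np.isin(arr, (0, 1)).all():
        raise ValueError("flip_bits requires entries in {0, 1}")
    return (1 - arr).astype(arr.dtype)


def binarize(table: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Threshold a real table to {0, 1}: entry x -> 1 if x > threshold else 0."""
    return (np.asarray(table, dtype=float) > threshold).astype(int)


def make_binary_patterns(
    n_samples: int,
    n_features: int,
    active_bits: int,
    noise: float = 0.05,
    background_rate: float = 0.01,
    seed: int = 0,
) -> LabeledDataset:
    """Two-class sparse binary patterns with class-correlated active bits.

    Each class owns a disjoint prototype set of ``active_bits`` feature
    indices.  A sample activates each of its class's prototype bits with
    probability ``1 - noise`` and each remaining bit with probability
    ``background_rate``, so the discriminative signal lives entirely in
    which units are on — a caricature of a sparse distributed code.
    The first half of the samples carries label 0.
    """
    if 2 * active_bits > n_features:
        raise ValueError("need n_features >= 2 * active_bits for disjoint prototypes")
    rng = np.random.default_rng(seed)
    idx = rng.permutation(n_features)
    proto = {0: idx[:active_bits], 1: idx[active_bits : 2 * active_bits]}
    n0 = n_samples // 2
    y = np.concatenate([np.zeros(n0, dtype=int), np.ones(n_samples - n0, dtype=int)])
    X = (rng.random((n_samples, n_features)) < background_rate).astype(float)
    for c in (0, 1):
        rows = np.flatnonzero(y == c)
        on = rng.random((rows.size, active_bits)) < (1.0 - noise)
        X[np.ix_(rows, proto[c])] = on.astype(float)
    return LabeledDataset(X, y, stage="raw")


def calibrate_cov_scale(
    candidates=(1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 8.0),
    target_test_accuracy: float = 99.0,
    n_features: int = 500,
    n_samples: int = 2000,
    repetitions: int = 3,
    seed: int = 0,
) -> float:
    """Pick the covariance scale whose dense-problem LR test accuracy is
    closest to ``target_test_accuracy``.

    The noise level of the generator is otherwise a free parameter; this
    routine anchors it to the observable behaviour of a logistic-regression
    baseline on the dense (no sparsification) problem, which is the cheapest
    experiment that pins down problem difficulty.
    """
    from .experiments import PipelineConfig, run_pipeline

    best, best_gap = None, np.inf
    for eps in candidates:
        spec = DatasetSpec(
            n_samples=n_samples, n_features=n_features, cov_scale=eps, sparsity=0.0
        )
        cfg = PipelineConfig(
            dataset=spec, models=("LR",), repetitions=repetitions, base_seed=seed
        )
        res = run_pipeline(cfg)
        gap = abs(res.test_accuracy_mean("LR") - target_test_accuracy)
        if gap < best_gap:
            best, best_gap = float(eps), gap
    return best


# ---------------------------------------------------------------------------
# persistence


def save_dataset_csv(data: LabeledDataset, path) -> None:
    """Write a delimited text matrix, one row per sample, label as last column."""
    mat = np.column_stack([data.X, data.y.astype(float)])
    np.savetxt(path, mat, delimiter=",", header=f"stage={data.stage}")


def load_dataset_csv(path) -> LabeledDataset:
    with open(path) as fh:
        header = fh.readline().strip()
    stage = header.split("stage=")[1] if "stage=" in header else "raw"
    mat = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
    return LabeledDataset(mat[:, :-1], mat[:, -1].astype(int), stage=stage)


def save_dataset_npz(data: LabeledDataset, path) -> None:
    """Compact binary container; lossless round-trip of the CSV format."""
    np.savez_compressed(path, X=data.X, y=data.y, stage=np.asarray(data.stage))


def load_dataset_npz(path) -> LabeledDataset:
    with np.load(path, allow_pickle=False) as z:
        return LabeledDataset(z["X"], z["y"], stage=str(z["stage"]))


_IDX_DTYPES = {
    0x08: np.uint8,
    0x09: np.int8,
    0x0B: ">i2",
    0x0C: ">i4",
    0x0D: ">f4",
    0x0E: ">f8",
}


def read_idx(path) -> np.ndarray:
    """Read an IDX-format binary tensor file (magic, dims, row-major payload)."""
    raw = Path(path).read_bytes()
    if len(raw) < 4 or raw[0] != 0 or raw[1] != 0:
        raise ValueError("not an IDX file: bad magic number")
    dtype_code, ndim = raw[2], raw[3]
    if dtype_code not in _IDX_DTYPES:
        raise ValueError(f"unknown IDX dtype code 0x{dtype_code:02x}")
    dims = struct.unpack(f">{ndim}I", raw[4 : 4 + 4 * ndim])
    data = np.frombuffer(raw, dtype=_IDX_DTYPES[dtype_code], offset=4 + 4 * ndim)
    if data.size != int(np.prod(dims)):
        raise ValueError("IDX payload size does not match header dimensions")
    return data.reshape(dims).astype(np.dtype(_IDX_DTYPES[dtype_code]).newbyteorder("="))
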