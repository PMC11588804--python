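"""Repeated-run benchmark pipeline comparing the RBM classifier with backprop nets.

Every experiment repeats one pipeline several times (default 10) with a
seed ladder ``base_seed + r``:

    generate two-Gaussian data -> center -> sparsify -> 80/20 split
    -> fit each requested model -> record train/test accuracy,

then aggregates per-model accuracy means and standard deviations.  Within a
repetition each model consumes an independent sub-stream of randomness, so
adding or removing a model never perturbs the others.  Preset drivers cover
a sparsity sweep at fixed dimensionality, a dimensionality x sparsity grid
reporting the RBM - LR accuracy difference surfaces, and a bit-flip probe
on sparse binary patterns that contrasts how the two learning rules treat
active versus inactive units.
"""

from __future__ import annotations

import logging
import time
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .backprop import SGDNetClassifier, NetTrainConfig
from .datasets import (
    DatasetSpec,
    LabeledDataset,
    center_features,
    flip_bits,
    generate_gaussian_dataset,
    make_binary_patterns,
    sparsify,
    train_test_split,
)
from .rbm import RBMClassifier, RBMTrainConfig

__all__ = [
    "PipelineConfig",
    "ExperimentResult",
    "accuracy",
    "derive_seed",
    "run_pipeline",
    "sparsity_sweep",
    "dim_sparsity_grid",
    "flip_probe",
    "report",
]

logger = logging.getLogger(__name__)

MODELS = ("LR", "MLP", "RBM")
# fixed per-purpose stream ids so seed derivation is stable across versions
_STREAMS = {"sparsify": 1, "split": 2, "LR": 10, "MLP": 11, "RBM": 12}


def derive_seed(base: int, stream: str | int) -> int:
    """Deterministic independent child seed (< 2**31) for a named purpose."""
    key = _STREAMS[stream] if isinstance(stream, str) else int(stream)
    ss = np.random.SeedSequence(entropy=int(base), spawn_key=(key,))
    return int(ss.generate_state(1)[0] % 2**31)


def accuracy(predicted, actual) -> float:
    """Percent agreement between two equal-length label vectors."""
    predicted = np.asarray(predicted)
    actual = np.asarray(actual)
    if predicted.shape != actual.shape:
        raise ValueError("predicted and actual must have equal lengths")
    if predicted.size == 0:
        raise ValueError("cannot score empty label vectors")
    return 100.0 * float(np.mean(predicted == actual))


@dataclass(frozen=True)
class PipelineConfig:
    """Everything one repeated-run experiment needs."""

    dataset: DatasetSpec = field(default_factory=DatasetSpec)
    models: tuple[str, ...] = ("LR", "RBM")
    rbm: RBMTrainConfig = field(default_factory=RBMTrainConfig)
    net: NetTrainConfig = field(default_factory=NetTrainConfig)
    n_hidden: int = 500
    repetitions: int = 10
    base_seed: int = 0
    predict_mode: str = "gibbs"
    n_gibbs: int = 100
    burn_in: int = 50
    # backprop fits run in single precision for throughput; the RBM stays in
    # double precision, where its large clamped activations are stable
    net_dtype: str = "float32"

    def __post_init__(self):
        if self.repetitions < 1:
            raise ValueError("repetitions must be >= 1")
        if self.n_hidden < 1:
            raise ValueError("n_hidden must be positive")
        unknown = set(self.models) - set(MODELS)
        if unknown or not self.models:
            raise ValueError(f"models must be a non-empty subset of {MODELS}")

    def to_dict(self) -> dict:
        d = asdict(self)
        for k in ("mean0", "mean1"):
            if d["dataset"][k] is not None:
                d["dataset"][k] = np.asarray(d["dataset"][k]).tolist()
        d["models"] = list(self.models)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "dataset" in d:
            d["dataset"] = DatasetSpec(**d["dataset"])
        if "rbm" in d:
            d["rbm"] = RBMTrainConfig(**d["rbm"])
        if "net" in d:
            d["net"] = NetTrainConfig(**d["net"])
        if "models" in d:
            d["models"] = tuple(d["models"])
        return cls(**d)


@dataclass
class ExperimentResult:
    """Per-model accuracies (percent, 2 decimals) over the repetitions."""

    train: dict[str, list[float]]
    test: dict[str, list[float]]
    n_features: int
    sparsity: float
    config: dict

    def _check(self, model: str):
        if model not in self.train:
            raise KeyError(f"no results recorded for model {model!r}")

    def train_accuracy_mean(self, model: str) -> float:
        self._check(model)
        return float(np.mean(self.train[model]))

    def train_accuracy_std(self, model: str) -> float:
        self._check(model)
        return float(np.std(self.train[model]))

    def test_accuracy_mean(self, model: str) -> float:
        self._check(model)
        return float(np.mean(self.test[model]))

    def test_accuracy_std(self, model: str) -> float:
        self._check(model)
        return float(np.std(self.test[model]))

    @property
    def models(self) -> tuple[str, ...]:
        return tuple(self.train)

    def summary(self) -> str:
        lines = [
            f"d={self.n_features}  sparsity={self.sparsity:.2f}  "
            f"repetitions={len(next(iter(self.train.values())))}"
        ]
        for m in self.models:
            lines.append(
                f"  {m:>3}: train {self.train_accuracy_mean(m):6.2f} "
                f"± {self.train_accuracy_std(m):5.2f}   "
                f"test {self.test_accuracy_mean(m):6.2f} "
                f"± {self.test_accuracy_std(m):5.2f}"
            )
        return "\n".join(lines)


def _make_model(name: str, config: PipelineConfig, seed: int):
    if name == "LR":
        return SGDNetClassifier(
            hidden_units=None,
            learning_rate=config.net.learning_rate,
            batch_size=config.net.batch_size,
            n_epochs=config.net.epochs,
            random_state=seed,
            dtype=config.net_dtype,
        )
    if name == "MLP":
        return SGDNetClassifier(
            hidden_units=config.n_hidden,
            learning_rate=config.net.learning_rate,
            batch_size=config.net.batch_size,
            n_epochs=config.net.epochs,
            random_state=seed,
            dtype=config.net_dtype,
        )
    if name == "RBM":
        return RBMClassifier(
            n_hidden=config.n_hidden,
            learning_rate=config.rbm.learning_rate,
            batch_size=config.rbm.batch_size,
            n_epochs=config.rbm.epochs,
            cd_steps=config.rbm.cd_steps,
            algorithm=config.rbm.algorithm,
            predict_mode=config.predict_mode,
            n_gibbs=config.n_gibbs,
            burn_in=config.burn_in,
            random_state=seed,
        )
    raise ValueError(f"unknown model {name!r}")


def _one_repetition(config: PipelineConfig, rep_seed: int):
    spec = replace(config.dataset, seed=rep_seed)
    t0 = time.perf_counter()
    data = generate_gaussian_dataset(spec)
    data = center_features(data)
    data = sparsify(data, spec.sparsity, derive_seed(rep_seed, "sparsify"))
    train, test = train_test_split(
        data, spec.train_fraction, derive_seed(rep_seed, "split")
    )
    logger.info("seed %d: generated data in %.2fs", rep_seed, time.perf_counter() - t0)
    out = {}
    for name in config.models:
        t0 = time.perf_counter()
        model = _make_model(name, config, derive_seed(rep_seed, name))
        model.fit(train.X, train.y)
        t_fit = time.perf_counter() - t0
        t0 = time.perf_counter()
        tr = round(accuracy(model.predict(train.X), train.y), 2)
        te = round(accuracy(model.predict(test.X), test.y), 2)
        logger.info(
            "seed %d %s: fit %.2fs eval %.2fs train %.2f test %.2f",
            rep_seed, name, t_fit, time.perf_counter() - t0, tr, te,
        )
        out[name] = (tr, te)
    return out


def run_pipeline(config: PipelineConfig) -> ExperimentResult:
    """Run the full pipeline ``repetitions`` times and aggregate accuracies."""
    train: dict[str, list[float]] = {m: [] for m in config.models}
    test: dict[str, list[float]] = {m: [] for m in config.models}
    for r in range(config.repetitions):
        rep_seed = config.base_seed + r
        try:
            rep = _one_repetition(config, rep_seed)
        except Exception:
            logger.exception("repetition %d (seed %d) failed", r, rep_seed)
            raise
        for m, (tr, te) in rep.items():
            train[m].append(tr)
            test[m].append(te)
    return ExperimentResult(
        train=train,
        test=test,
        n_features=config.dataset.n_features,
        sparsity=config.dataset.sparsity,
        config=config.to_dict(),
    )


def sparsity_sweep(config: PipelineConfig, sparsities) -> list[ExperimentResult]:
    """One :func:`run_pipeline` per sparsity, everything else held fixed."""
    sparsities = list(sparsities)
    if not sparsities:
        raise ValueError("sparsities must be non-empty")
    results = []
    for s in sparsities:
        cfg = replace(config, dataset=replace(config.dataset, sparsity=float(s)))
        results.append(run_pipeline(cfg))
    return results


def dim_sparsity_grid(config: PipelineConfig, dims, sparsities) -> dict:
    """Cartesian product of dimensionalities and sparsities.

    Returns the grid of :class:`ExperimentResult` plus the RBM - LR train
    and test accuracy-difference surfaces (rows indexed by dimensionality,
    columns by sparsity) when both models were run.
    """
    dims = [int(d) for d in dims]
    sparsities = [float(s) for s in sparsities]
    if not dims or not sparsities:
        raise ValueError("dims and sparsities must be non-empty")
    grid = []
    for d in dims:
        row = []
        for s in sparsities:
            cfg = replace(
                config, dataset=replace(config.dataset, n_features=d, sparsity=s)
            )
            row.append(run_pipeline(cfg))
        grid.append(row)
    out = {"dims": dims, "sparsities": sparsities, "results": grid}
    if {"RBM", "LR"} <= set(config.models):
        out["train_diff"] = np.array(
            [
                [r.train_accuracy_mean("RBM") - r.train_accuracy_mean("LR") for r in row]
                for row in grid
            ]
        )
        out["test_diff"] = np.array(
            [
                [r.test_accuracy_mean("RBM") - r.test_accuracy_mean("LR") for r in row]
                for row in grid
            ]
        )
    return out


def flip_probe(
    n_samples: int = 1000,
    n_features: int = 256,
    active_bits: int = 26,
    noise: float = 0.1,
    background_rate: float = 0.02,
    n_hidden: int = 64,
    epochs: int = 30,
    net_epochs: int = 100,
    repetitions: int = 3,
    base_seed: int = 0,
) -> dict:
    """Train LR and the RBM on sparse binary patterns and on their bit-flipped
    complement; returns mean test accuracies per model and encoding.

    The two encodings carry identical information (the flip is an involution),
    so any error-driven learner should score the same on both.  The contrastive
    rule only learns correlations between active units, so flipping — which
    turns the informative minority of ones into zeros and lights up the
    background — removes exactly the statistics it relies on.
    """
    accs = {("LR", e): [] for e in ("original", "flipped")}
    accs.update({("RBM", e): [] for e in ("original", "flipped")})
    for r in range(repetitions):
        seed = base_seed + r
        data = make_binary_patterns(
            n_samples, n_features, active_bits,
            noise=noise, background_rate=background_rate, seed=seed,
        )
        train, test = train_test_split(data, 0.8, derive_seed(seed, "split"))
        for encoding in ("original", "flipped"):
            if encoding == "flipped":
                Xtr, Xte = flip_bits(train.X), flip_bits(test.X)
            else:
                Xtr, Xte = train.X, test.X
            lr = SGDNetClassifier(
                hidden_units=None, n_epochs=net_epochs,
                random_state=derive_seed(seed, "LR"),
            ).fit(Xtr, train.y)
            rbm = RBMClassifier(
                n_hidden=n_hidden, n_epochs=epochs,
                random_state=derive_seed(seed, "RBM"),
            ).fit(Xtr, train.y)
            accs[("LR", encoding)].append(accuracy(lr.predict(Xte), test.y))
            accs[("RBM", encoding)].append(accuracy(rbm.predict(Xte), test.y))
    return {
        model: {
            enc: float(np.mean(accs[(model, enc)])) for enc in ("original", "flipped")
        }
        for model in ("LR", "RBM")
    }


def _tidy_frame(results) -> pd.DataFrame:
    if isinstance(results, ExperimentResult):
        results = [results]
    if not results:
        raise ValueError("no results to report")
    rows = []
    for res in results:
        for m in res.models:
            for r, (tr, te) in enumerate(zip(res.train[m], res.test[m])):
                rows.append((m, res.n_features, res.sparsity, str(r), tr, te))
            rows.append(
                (m, res.n_features, res.sparsity, "mean",
                 res.train_accuracy_mean(m), res.test_accuracy_mean(m))
            )
            rows.append(
                (m, res.n_features, res.sparsity, "std",
                 res.train_accuracy_std(m), res.test_accuracy_std(m))
            )
    return pd.DataFrame(
        rows, columns=["model", "d", "s", "repetition", "train_acc", "test_acc"]
    )


def report(results, out_dir, plots: bool = False) -> pd.DataFrame:
    """Write a tidy CSV (per-repetition rows plus mean/std aggregate rows),
    print a summary, and optionally emit accuracy-vs-sparsity plots."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    frame = _tidy_frame(results)
    frame.to_csv(out_dir / "results.csv", index=False)
    if isinstance(results, ExperimentResult):
        results = [results]
    with open(out_dir / "summary.txt", "w") as fh:
        for res in results:
            fh.write(res.summary() + "\n")
    if plots:
        _plot_sweep(results, out_dir / "accuracy_vs_sparsity.png")
    return frame


def _plot_sweep(results, path):
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    xs = [r.sparsity * 100 for r in results]
    for m in results[0].models:
        ax.plot(xs, [r.train_accuracy_mean(m) for r in results], "--o", label=f"{m} train")
        ax.plot(xs, [r.test_accuracy_mean(m) for r in results], "-o", label=f"{m} test")
    ax.set_xlabel("sparsity (%)")
    ax.set_ylabel("accuracy (%)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
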