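"""Lossless parameter persistence for RBM and backprop-network parameters.

Both parameter types share one self-describing NPZ container: a ``kind``
tag, the arrays, and an optional config echo stored as a JSON string.
"""

from __future__ import annotations

import json

import numpy as np

from .backprop import NetParams
from .rbm import RBMParams

__all__ = ["save_params", "load_params"]


def save_params(params, path, config: dict | None = None) -> None:
    """Write :class:`RBMParams` or :class:`NetParams` to an NPZ container."""
    meta = json.dumps(config) if config is not None else ""
    if isinstance(params, RBMParams):
        np.savez_compressed(
            path,
            kind="rbm",
            weights=params.weights,
            visible_bias=params.visible_bias,
            hidden_bias=params.hidden_bias,
            n_label_units=params.n_label_units,
            config=meta,
        )
    elif isinstance(params, NetParams):
        arrays = {}
        for k, (W, b) in enumerate(params.layers):
            arrays[f"W{k}"] = W
            arrays[f"b{k}"] = b
        np.savez_compressed(
            path, kind="net", n_layers=len(params.layers), config=meta, **arrays
        )
    else:
        raise TypeError(f"cannot serialize {type(params).__name__}")


def load_params(path):
    """Read a container written by :func:`save_params`.

    Returns ``(params, config_dict_or_None)``.
    """
    with np.load(path, allow_pickle=False) as z:
        kind = str(z["kind"])
        meta = str(z["config"])
        config = json.loads(meta) if meta else None
        if kind == "rbm":
            params = RBMParams(
                z["weights"],
                z["visible_bias"],
                z["hidden_bias"],
                int(z["n_label_units"]),
            )
        elif kind == "net":
            n = int(z["n_layers"])
            params = NetParams([(z[f"W{k}"], z[f"b{k}"]) for k in range(n)])
        else:
            raise ValueError(f"unknown container kind {kind!r}")
    return params, config
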