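"""Greedy layer-wise deep belief network pretraining."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .rbm import RBMParams, train_rbm
from .training import TrainConfig

__all__ = ["DBNStack", "dbn_pretrain"]


@dataclass
class DBNStack:
    """A stack of RBMs whose layer dimensions chain (hiddenₖ = visibleₖ₊₁)."""

    layers: list[RBMParams]
    layer_dims: list[int]
    error_traces: list[list[float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        dims = [self.layers[0].W.shape[0]] + [l.W.shape[1] for l in self.layers]
        if dims != list(self.layer_dims):
            raise ValueError(f"layer dims {dims} do not chain to {self.layer_dims}")

    def transform(self, data: np.ndarray) -> np.ndarray:
        """Deterministic upward pass: hidden probabilities layer by layer."""
        out = data
        for layer in self.layers:
            out = layer.hidden_probs(out)
        return out


def dbn_pretrain(dims: list[int], data: np.ndarray, config: TrainConfig,
                 rng: np.random.Generator,
                 first_visible_kind: str = "gaussian") -> DBNStack:
    """Train each RBM on the hidden activations of the layer below.

    The first layer defaults to Gaussian visible units (real-valued,
    standardized input); deeper layers are Bernoulli–Bernoulli over hidden
    probabilities.
    """
    if data.shape[1] != dims[0]:
        raise ValueError(f"data has {data.shape[1]} columns, expected {dims[0]}")
    layers: list[RBMParams] = []
    traces: list[list[float]] = []
    current = data
    for k in range(len(dims) - 1):
        kind = first_visible_kind if k == 0 else "bernoulli"
        rbm = RBMParams.initialize(dims[k], dims[k + 1], rng, visible_kind=kind)
        traces.append(train_rbm(rbm, current, config, rng,
                                epochs=config.pretrain_epochs))
        layers.append(rbm)
        current = rbm.hidden_probs(current)
    return DBNStack(layers=layers, layer_dims=list(dims), error_traces=traces)
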