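"""Stage 2: the fold classifier over fragment vectors.

Layer stack (defaults match the published hyperparameter table):

* COV1 — 10 one-dimensional filters, kernel 10, stride 1, leaky-ReLU;
* MP1  — max-pool width 10, stride 1 (overlapping, as printed);
* ST   — stacking layer: the 10 channel outputs become the 10 rows of a 2-D map;
* COV2 — 100 two-dimensional 10×10 filters spanning the full stack height;
* MP2  — max-pool 5 wide, stride 5; the pool *height* is clipped to the map
  height (1 after COV2) and the width is clipped when the map is narrower
  than 5;
* FC1, FC2 — fully-connected width 100, leaky-ReLU, dropout in training;
* softmax over the fold classes.

For the default 100-long fragment vector the shape pipeline is
100 → 91×10 → 82×10 → 10×82 → 1×73×100 → 1×14×100 → 1400 → 100 → 100 → folds.
All convolutions are 'valid' (no padding).  The minimum input length is 28
(COV2 needs at least 10 columns after MP1).
"""

from __future__ import annotations

import logging

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from sklearn.model_selection import train_test_split

from .ops import (cross_entropy, dropout_mask, leaky_relu, leaky_relu_grad,
                  softmax_rows)
from .training import TrainConfig, TrainingError, supervised_fit

logger = logging.getLogger(__name__)

__all__ = ["FoldCNN", "DEFAULT_CNN_ARCH", "cnn_forward", "train_fold_cnn"]

DEFAULT_CNN_ARCH = {
    "n_input": 100,
    "n_folds": 4,
    "conv1_filters": 10,
    "conv1_kernel": 10,
    "pool1_width": 10,
    "pool1_stride": 1,
    "conv2_filters": 100,
    "conv2_kernel": 10,
    "pool2_width": 5,
    "pool2_stride": 5,
    "fc_dims": [100, 100],
    "leaky_slope": 0.01,
}


def _pool1d(x: np.ndarray, width: int, stride: int, axis: int):
    """Max-pool along ``axis``; returns pooled values and flat argmax indices."""
    win = sliding_window_view(x, width, axis=axis)
    sel = [slice(None)] * win.ndim
    sel[axis] = slice(None, None, stride)
    win = win[tuple(sel)]
    pooled = win.max(axis=-1)
    arg = win.argmax(axis=-1)
    return pooled, arg


class FoldCNN:
    """1D CNN over a fragment vector; parameters live in a named dict."""

    def __init__(self, arch: dict | None = None,
                 rng: np.random.Generator | None = None,
                 zero_init: bool = False) -> None:
        self.arch = {**DEFAULT_CNN_ARCH, **(arch or {})}
        self.shapes = self._shape_trace(self.arch["n_input"])
        rng = rng or np.random.default_rng(0)
        self.params: dict[str, np.ndarray] = {}
        self._build(rng, zero_init)

    # -- shape arithmetic ---------------------------------------------------

    def _shape_trace(self, n: int) -> dict:
        """Deterministic layer-output shapes for an input of length ``n``."""
        a = self.arch
        len1 = n - a["conv1_kernel"] + 1
        if len1 < a["pool1_width"]:
            raise ValueError(f"input length {n} too short for COV1+MP1")
        len1p = (len1 - a["pool1_width"]) // a["pool1_stride"] + 1
        if len1p < a["conv2_kernel"]:
            raise ValueError(
                f"input length {n} too short: COV2 needs >= "
                f"{a['conv2_kernel']} columns after MP1, got {len1p} "
                f"(minimum input length is "
                f"{a['conv2_kernel'] + a['conv1_kernel'] + a['pool1_width'] - 2})")
        len2 = len1p - a["conv2_kernel"] + 1
        p2w = min(a["pool2_width"], len2)  # clip pool width to map width
        len2p = (len2 - p2w) // a["pool2_stride"] + 1
        flat = len2p * a["conv2_filters"]
        return {
            "conv1": (len1, a["conv1_filters"]),
            "pool1": (len1p, a["conv1_filters"]),
            "stack": (a["conv1_filters"], len1p),
            "conv2": (1, len2, a["conv2_filters"]),
            "pool2": (1, len2p, a["conv2_filters"]),
            "flatten": flat,
            "pool2_width_effective": p2w,
        }

    def _build(self, rng: np.random.Generator, zero_init: bool) -> None:
        a = self.arch

        def init(shape, fan_in):
            if zero_init:
                return np.zeros(shape)
            return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)

        self.params["conv1/W"] = init(
            (a["conv1_filters"], a["conv1_kernel"]), a["conv1_kernel"])
        self.params["conv1/b"] = np.zeros(a["conv1_filters"])
        fan2 = a["conv1_filters"] * a["conv2_kernel"]
        self.params["conv2/W"] = init(
            (a["conv2_filters"], a["conv1_filters"], a["conv2_kernel"]), fan2)
        self.params["conv2/b"] = np.zeros(a["conv2_filters"])
        prev = self.shapes["flatten"]
        for i, width in enumerate(a["fc_dims"]):
            self.params[f"fc{i}/W"] = init((prev, width), prev)
            self.params[f"fc{i}/b"] = np.zeros(width)
            prev = width
        self.params["out/W"] = init((prev, a["n_folds"]), prev)
        self.params["out/b"] = np.zeros(a["n_folds"])

    @property
    def n_folds(self) -> int:
        return self.arch["n_folds"]

    # -- forward ------------------------------------------------------------

    def _forward(self, X: np.ndarray, train: bool = False,
                 rng: np.random.Generator | None = None, dropout: float = 0.0):
        a = self.arch
        slope = a["leaky_slope"]
        X = np.atleast_2d(X)
        if X.shape[1] != a["n_input"]:
            raise ValueError(
                f"input length {X.shape[1]} != configured {a['n_input']}")
        cache: dict = {"X": X}
        # COV1: B×L → B×len1×F1
        xw = sliding_window_view(X, a["conv1_kernel"], axis=1)
        pre1 = np.einsum("blk,fk->blf", xw, self.params["conv1/W"]) \
            + self.params["conv1/b"]
        act1 = leaky_relu(pre1, slope)
        cache["pre1"] = pre1
        # MP1 along positions, per channel
        pool1, arg1 = _pool1d(act1, a["pool1_width"], a["pool1_stride"], axis=1)
        cache["arg1"] = arg1
        cache["act1_shape"] = act1.shape
        # ST: B×len1p×F1 → B×F1×len1p
        stack = pool1.transpose(0, 2, 1)
        # COV2: full-height 2D filters → B×len2×F2
        sw = sliding_window_view(stack, a["conv2_kernel"], axis=2)  # B×F1×len2×k
        pre2 = np.einsum("bclk,fck->blf", sw, self.params["conv2/W"]) \
            + self.params["conv2/b"]
        act2 = leaky_relu(pre2, slope)
        cache["pre2"] = pre2
        # MP2 along positions (height is already 1)
        p2w = self.shapes["pool2_width_effective"]
        pool2, arg2 = _pool1d(act2, p2w, a["pool2_stride"], axis=1)
        cache["arg2"] = arg2
        cache["act2_shape"] = act2.shape
        h = pool2.reshape(len(X), -1)
        for i in range(len(a["fc_dims"])):
            pre = h @ self.params[f"fc{i}/W"] + self.params[f"fc{i}/b"]
            act = leaky_relu(pre, slope)
            mask = None
            if train and dropout > 0:
                mask = dropout_mask(rng, act.shape, dropout)
                act = act * mask
            cache[f"fc{i}"] = (h, pre, mask)
            h = act
        cache["head_in"] = h
        logits = h @ self.params["out/W"] + self.params["out/b"]
        return softmax_rows(logits), cache

    # -- backward -----------------------------------------------------------

    def _unpool_grad(self, grad, arg, in_shape, width, stride, axis):
        """Scatter pooled gradients back to argmax positions (overlap-safe)."""
        out = np.zeros(in_shape)
        idx = np.indices(grad.shape)
        pos = idx[axis] * stride + arg
        index = list(idx)
        index[axis] = pos
        np.add.at(out, tuple(index), grad)
        return out

    def loss_and_grads(self, X: np.ndarray, y: np.ndarray,
                       rng: np.random.Generator, dropout: float):
        a = self.arch
        slope = a["leaky_slope"]
        probs, cache = self._forward(X, train=True, rng=rng, dropout=dropout)
        n = len(y)
        loss = cross_entropy(probs, y)
        delta = probs.copy()
        delta[np.arange(n), y] -= 1.0
        delta /= n
        grads: dict[str, np.ndarray] = {}
        grads["out/W"] = cache["head_in"].T @ delta
        grads["out/b"] = delta.sum(axis=0)
        delta = delta @ self.params["out/W"].T
        for i in reversed(range(len(a["fc_dims"]))):
            h, pre, mask = cache[f"fc{i}"]
            if mask is not None:
                delta = delta * mask
            delta = delta * leaky_relu_grad(pre, slope)
            grads[f"fc{i}/W"] = h.T @ delta
            grads[f"fc{i}/b"] = delta.sum(axis=0)
            delta = delta @ self.params[f"fc{i}/W"].T
        # back through flatten → MP2 → COV2
        d_pool2 = delta.reshape(len(X), -1, a["conv2_filters"])
        p2w = self.shapes["pool2_width_effective"]
        d_act2 = self._unpool_grad(d_pool2, cache["arg2"], cache["act2_shape"],
                                   p2w, a["pool2_stride"], axis=1)
        d_pre2 = d_act2 * leaky_relu_grad(cache["pre2"], slope)
        # reconstruct COV2 input windows
        pool1 = leaky_relu(cache["pre1"], slope)
        pool1, _ = _pool1d(pool1, a["pool1_width"], a["pool1_stride"], axis=1)
        stack = pool1.transpose(0, 2, 1)
        sw = sliding_window_view(stack, a["conv2_kernel"], axis=2)
        grads["conv2/W"] = np.einsum("blf,bclk->fck", d_pre2, sw)
        grads["conv2/b"] = d_pre2.sum(axis=(0, 1))
        d_stack = np.zeros_like(stack)
        W2 = self.params["conv2/W"]
        for t in range(d_pre2.shape[1]):
            # d_stack[:, :, t:t+k] += Σ_f d_pre2[:, t, f] · W2[f]
            d_stack[:, :, t:t + a["conv2_kernel"]] += np.einsum(
                "bf,fck->bck", d_pre2[:, t, :], W2)
        d_pool1 = d_stack.transpose(0, 2, 1)
        d_act1 = self._unpool_grad(d_pool1, cache["arg1"], cache["act1_shape"],
                                   a["pool1_width"], a["pool1_stride"], axis=1)
        d_pre1 = d_act1 * leaky_relu_grad(cache["pre1"], slope)
        xw = sliding_window_view(cache["X"], a["conv1_kernel"], axis=1)
        grads["conv1/W"] = np.einsum("blf,blk->fk", d_pre1, xw)
        grads["conv1/b"] = d_pre1.sum(axis=(0, 1))
        return loss, grads

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        probs, _ = self._forward(np.atleast_2d(X), train=False)
        return probs

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.predict_proba(X).argmax(axis=1)

    # -- persistence --------------------------------------------------------

    def config_dict(self) -> dict:
        return {"arch": self.arch}

    def to_arrays(self) -> dict[str, np.ndarray]:
        return {f"param:{k}".replace("/", "|"): v for k, v in self.params.items()}

    @classmethod
    def from_arrays(cls, config: dict, arrays: dict) -> "FoldCNN":
        model = cls(arch=config["arch"], zero_init=True)
        for key, arr in arrays.items():
            name = key.split(":", 1)[1].replace("|", "/")
            if name not in model.params:
                raise ValueError(f"unexpected checkpoint array {name!r}")
            if model.params[name].shape != arr.shape:
                raise ValueError(
                    f"shape mismatch for {name!r}: expected "
                    f"{model.params[name].shape}, found {arr.shape}")
            model.params[name] = np.asarray(arr, dtype=np.float64)
        return model


def cnn_forward(model: FoldCNN, v: np.ndarray) -> np.ndarray:
    """Fold-probability vector for one fragment vector."""
    return model.predict_proba(np.asarray(v)[None, :])[0]


def train_fold_cnn(vectors: np.ndarray, fold_labels: np.ndarray,
                   config: TrainConfig, arch: dict | None = None):
    """Cross-entropy training of the fold CNN with early stopping.

    Returns ``(model, history)`` with the best-validation parameters.
    """
    y = np.asarray(fold_labels)
    classes = np.unique(y)
    if len(classes) < 2:
        raise TrainingError("training requires at least 2 folds")
    arch = {**DEFAULT_CNN_ARCH, **(arch or {})}
    arch["n_input"] = int(np.asarray(vectors).shape[1])
    arch["n_folds"] = int(len(classes))
    rng = np.random.default_rng(config.seed)
    model = FoldCNN(arch=arch, rng=rng)
    X_tr, X_val, y_tr, y_val = train_test_split(
        np.asarray(vectors), y, test_size=config.val_fraction, stratify=y,
        random_state=config.seed)
    history = supervised_fit(model, X_tr, y_tr, X_val, y_val, config, rng)
    return model, history
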