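"""Stage 1: the multimodal fragment-class classifier.

Three feature groups — sequence composition (77), physicochemical (82) and
evolutionary (1600) — each pass through their own DBN-pretrained dense stack;
the top representations are concatenated, fused by a jointly pretrained RBM
layer, and classified by two fully-connected hidden layers (width 1000 by
default) and a softmax over the fragment classes (100 by default).

Pretraining uses logistic units under contrastive divergence; the fine-tuned
feed-forward network applies leaky-ReLU activations throughout, with
inverted dropout after every hidden layer during training only.
"""

from __future__ import annotations

import logging

import numpy as np
from sklearn.model_selection import train_test_split

from .dbn import dbn_pretrain
from .ops import dropout_mask, leaky_relu, leaky_relu_grad, softmax_rows, cross_entropy
from .rbm import RBMParams, train_rbm
from .training import TrainConfig, TrainingError, supervised_fit

logger = logging.getLogger(__name__)

__all__ = ["FragmentPredictor", "DEFAULT_ARCH", "DEFAULT_SPANS",
           "multimodal_forward", "train_fragment_predictor"]

MODALITY_ORDER = ("sequence", "physicochemical", "evolutionary")

DEFAULT_ARCH = {
    "modality_dims": {
        "sequence": [77, 256, 128],
        "physicochemical": [82, 256, 128],
        "evolutionary": [1600, 512, 256],
    },
    "fusion_dim": 512,
    "head_dims": [1000, 1000],
    "n_classes": 100,
    "leaky_slope": 0.01,
}

#: Column spans of the three feature groups in the 1759-wide fragment vector.
DEFAULT_SPANS = {"sequence": (0, 77), "physicochemical": (77, 159),
                 "evolutionary": (159, 1759)}


class FragmentPredictor:
    """Multimodal DBN-initialized classifier over fragment classes."""

    def __init__(self, arch: dict | None = None, spans: dict | None = None,
                 rng: np.random.Generator | None = None,
                 zero_init: bool = False) -> None:
        self.arch = {**DEFAULT_ARCH, **(arch or {})}
        self.spans = {k: tuple(v) for k, v in (spans or DEFAULT_SPANS).items()}
        missing = set(MODALITY_ORDER) - set(self.spans)
        if missing:
            raise ValueError(f"missing feature-group spans: {sorted(missing)}")
        for mod in MODALITY_ORDER:
            lo, hi = self.spans[mod]
            if hi - lo != self.arch["modality_dims"][mod][0]:
                raise ValueError(
                    f"span of {mod!r} is {hi - lo} wide, architecture expects "
                    f"{self.arch['modality_dims'][mod][0]}")
        rng = rng or np.random.default_rng(0)
        self.params: dict[str, np.ndarray] = {}
        self.norms: dict[str, np.ndarray] = {}
        self._build(rng, zero_init)

    # -- construction -------------------------------------------------------

    def _dense_specs(self):
        """Yield (name, n_in, n_out) for every dense layer in forward order."""
        for mod in MODALITY_ORDER:
            dims = self.arch["modality_dims"][mod]
            for i in range(len(dims) - 1):
                yield f"{mod}/{i}", dims[i], dims[i + 1]
        concat = sum(self.arch["modality_dims"][m][-1] for m in MODALITY_ORDER)
        yield "fusion", concat, self.arch["fusion_dim"]
        prev = self.arch["fusion_dim"]
        for i, width in enumerate(self.arch["head_dims"]):
            yield f"head/{i}", prev, width
            prev = width
        yield "out", prev, self.arch["n_classes"]

    def _build(self, rng: np.random.Generator, zero_init: bool) -> None:
        for name, nin, nout in self._dense_specs():
            if zero_init:
                W = np.zeros((nin, nout))
            else:
                W = rng.normal(0.0, np.sqrt(2.0 / nin), size=(nin, nout))
            self.params[f"{name}/W"] = W
            self.params[f"{name}/b"] = np.zeros(nout)
        for mod in MODALITY_ORDER:
            dim = self.arch["modality_dims"][mod][0]
            self.norms[f"{mod}/mu"] = np.zeros(dim)
            self.norms[f"{mod}/sd"] = np.ones(dim)

    @property
    def n_classes(self) -> int:
        return self.arch["n_classes"]

    # -- forward / backward -------------------------------------------------

    def _split(self, X: np.ndarray) -> dict[str, np.ndarray]:
        out = {}
        for mod in MODALITY_ORDER:
            lo, hi = self.spans[mod]
            out[mod] = (X[:, lo:hi] - self.norms[f"{mod}/mu"]) \
                / self.norms[f"{mod}/sd"]
        return out

    def _forward(self, X: np.ndarray, train: bool = False,
                 rng: np.random.Generator | None = None, dropout: float = 0.0):
        slope = self.arch["leaky_slope"]
        parts = self._split(X)
        cache = {"dense": {}}
        outs = []
        for mod in MODALITY_ORDER:
            x = parts[mod]
            dims = self.arch["modality_dims"][mod]
            for i in range(len(dims) - 1):
                x = self._dense_fwd(f"{mod}/{i}", x, slope, train, rng,
                                    dropout, cache)
            outs.append(x)
        concat = np.hstack(outs)
        x = self._dense_fwd("fusion", concat, slope, train, rng, dropout, cache)
        for i in range(len(self.arch["head_dims"])):
            x = self._dense_fwd(f"head/{i}", x, slope, train, rng, dropout, cache)
        logits = x @ self.params["out/W"] + self.params["out/b"]
        cache["dense"]["out"] = (x, None, None)
        probs = softmax_rows(logits)
        return probs, cache

    def _dense_fwd(self, name, x, slope, train, rng, dropout, cache):
        pre = x @ self.params[f"{name}/W"] + self.params[f"{name}/b"]
        act = leaky_relu(pre, slope)
        mask = None
        if train and dropout > 0:
            mask = dropout_mask(rng, act.shape, dropout)
            act = act * mask
        cache["dense"][name] = (x, pre, mask)
        return act

    def _dense_bwd(self, name, delta, cache, grads, slope):
        x, pre, mask = cache["dense"][name]
        if mask is not None:
            delta = delta * mask
        if pre is not None:
            delta = delta * leaky_relu_grad(pre, slope)
        grads[f"{name}/W"] = x.T @ delta
        grads[f"{name}/b"] = delta.sum(axis=0)
        return delta @ self.params[f"{name}/W"].T

    def loss_and_grads(self, X: np.ndarray, y: np.ndarray,
                       rng: np.random.Generator, dropout: float):
        probs, cache = self._forward(X, train=True, rng=rng, dropout=dropout)
        n = len(y)
        loss = cross_entropy(probs, y)
        delta = probs.copy()
        delta[np.arange(n), y] -= 1.0
        delta /= n
        grads: dict[str, np.ndarray] = {}
        slope = self.arch["leaky_slope"]
        h, _, _ = cache["dense"]["out"]
        grads["out/W"] = h.T @ delta
        grads["out/b"] = delta.sum(axis=0)
        delta = delta @ self.params["out/W"].T
        for i in reversed(range(len(self.arch["head_dims"]))):
            delta = self._dense_bwd(f"head/{i}", delta, cache, grads, slope)
        delta = self._dense_bwd("fusion", delta, cache, grads, slope)
        offset = 0
        for mod in MODALITY_ORDER:
            width = self.arch["modality_dims"][mod][-1]
            d = delta[:, offset:offset + width]
            offset += width
            dims = self.arch["modality_dims"][mod]
            for i in reversed(range(len(dims) - 1)):
                d = self._dense_bwd(f"{mod}/{i}", d, cache, grads, slope)
        return loss, grads

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Deterministic inference (dropout disabled)."""
        probs, _ = self._forward(np.atleast_2d(X), train=False)
        return probs

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.predict_proba(X).argmax(axis=1)

    # -- persistence --------------------------------------------------------

    def config_dict(self) -> dict:
        return {"arch": self.arch,
                "spans": {k: list(v) for k, v in self.spans.items()}}

    def to_arrays(self) -> dict[str, np.ndarray]:
        out = {f"param:{k}".replace("/", "|"): v for k, v in self.params.items()}
        out.update({f"norm:{k}".replace("/", "|"): v
                    for k, v in self.norms.items()})
        return out

    @classmethod
    def from_arrays(cls, config: dict, arrays: dict) -> "FragmentPredictor":
        model = cls(arch=config["arch"], spans=config["spans"], zero_init=True)
        for key, arr in arrays.items():
            kind, name = key.split(":", 1)
            name = name.replace("|", "/")
            target = model.params if kind == "param" else model.norms
            if name not in target:
                raise ValueError(f"unexpected checkpoint array {name!r}")
            if target[name].shape != arr.shape:
                raise ValueError(
                    f"shape mismatch for {name!r}: expected "
                    f"{target[name].shape}, found {arr.shape}")
            target[name] = np.asarray(arr, dtype=np.float64)
        return model


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------

def multimodal_forward(model: FragmentPredictor, features) -> np.ndarray:
    """Softmax fragment-class distribution for one FragmentFeatureSet."""
    for mod in MODALITY_ORDER:
        if mod not in features.group_spans:
            raise ValueError(f"feature set is missing the {mod!r} group")
    vec = features.concatenated()
    return model.predict_proba(vec[None, :])[0]


def train_fragment_predictor(X: np.ndarray, y: np.ndarray, config: TrainConfig,
                             arch: dict | None = None,
                             spans: dict | None = None,
                             pretrain: bool = True):
    """Pretrain the per-modality DBNs and fusion RBM, then fine-tune end to end.

    Returns ``(model, history)`` where the model holds the parameters of the
    best validation epoch.
    """
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise TrainingError("training requires at least 2 classes")
    if counts.max() != counts.min():
        logger.warning("unbalanced classes: counts range %d..%d",
                       counts.min(), counts.max())
    rng = np.random.default_rng(config.seed)
    model = FragmentPredictor(arch=arch, spans=spans, rng=rng)
    X_tr, X_val, y_tr, y_val = train_test_split(
        X, y, test_size=config.val_fraction, stratify=y,
        random_state=config.seed)
    # per-modality standardization from training statistics
    for mod in MODALITY_ORDER:
        lo, hi = model.spans[mod]
        block = X_tr[:, lo:hi]
        model.norms[f"{mod}/mu"] = block.mean(axis=0)
        model.norms[f"{mod}/sd"] = np.maximum(block.std(axis=0), 1e-8)
    if pretrain:
        tops = []
        for mod in MODALITY_ORDER:
            lo, hi = model.spans[mod]
            std = (X_tr[:, lo:hi] - model.norms[f"{mod}/mu"]) \
                / model.norms[f"{mod}/sd"]
            dims = model.arch["modality_dims"][mod]
            stack = dbn_pretrain(dims, std, config, rng)
            for i, layer in enumerate(stack.layers):
                model.params[f"{mod}/{i}/W"] = layer.W
                model.params[f"{mod}/{i}/b"] = layer.b
            tops.append(stack.transform(std))
        joint = np.hstack(tops)
        fusion = RBMParams.initialize(joint.shape[1], model.arch["fusion_dim"],
                                      rng, visible_kind="bernoulli")
        train_rbm(fusion, joint, config, rng, epochs=config.pretrain_epochs)
        model.params["fusion/W"] = fusion.W
        model.params["fusion/b"] = fusion.b
    history = supervised_fit(model, X_tr, y_tr, X_val, y_val, config, rng)
    return model, history
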