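"""Restricted Boltzmann machines with contrastive-divergence training.

Two unit families are supported for the visible layer:

* ``bernoulli`` — binary units, energy  E(v,h) = −aᵀv − bᵀh − vᵀWh;
* ``gaussian`` — unit-variance linear units for real-valued (standardized)
  inputs, energy  E(v,h) = ‖v−a‖²/2 − bᵀh − vᵀWh.

Hidden units are always logistic.  Training follows CD-k: the positive
statistics use the data, the negative statistics a k-step Gibbs chain started
at the data, and the resulting stochastic gradient is applied through Adam.

For small Bernoulli machines :func:`exact_log_likelihood` and
:func:`exact_gradient` evaluate the true likelihood and its gradient by
enumerating the visible state space (hidden units are marginalized
analytically through the free energy), which is the correctness anchor for
the CD code path.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .ops import Adam, sigmoid
from .training import TrainConfig, TrainingError

__all__ = ["RBMParams", "rbm_cd_update", "train_rbm",
           "exact_log_likelihood", "exact_gradient"]


@dataclass
class RBMParams:
    W: np.ndarray                       # n_visible × n_hidden
    a: np.ndarray                       # visible bias
    b: np.ndarray                       # hidden bias
    visible_kind: str = "bernoulli"     # or "gaussian"

    def __post_init__(self) -> None:
        nv, nh = self.W.shape
        if self.a.shape != (nv,) or self.b.shape != (nh,):
            raise ValueError("inconsistent RBM parameter shapes")
        if self.visible_kind not in ("bernoulli", "gaussian"):
            raise ValueError(f"unknown visible_kind {self.visible_kind!r}")

    @classmethod
    def initialize(cls, n_visible: int, n_hidden: int,
                   rng: np.random.Generator,
                   visible_kind: str = "bernoulli",
                   scale: float = 0.01) -> "RBMParams":
        return cls(W=rng.normal(0.0, scale, size=(n_visible, n_hidden)),
                   a=np.zeros(n_visible), b=np.zeros(n_hidden),
                   visible_kind=visible_kind)

    # -- conditionals -------------------------------------------------------

    def hidden_probs(self, v: np.ndarray) -> np.ndarray:
        return sigmoid(v @ self.W + self.b)

    def visible_mean(self, h: np.ndarray) -> np.ndarray:
        act = h @ self.W.T + self.a
        return act if self.visible_kind == "gaussian" else sigmoid(act)


def _cd_statistics(params: RBMParams, batch: np.ndarray, k: int,
                   rng: np.random.Generator):
    """Positive/negative sufficient statistics of a CD-k chain + recon error."""
    v0 = batch
    p0 = params.hidden_probs(v0)
    h = (rng.random(p0.shape) < p0).astype(float)
    vk = v0
    for _ in range(k):
        vmean = params.visible_mean(h)
        if params.visible_kind == "gaussian":
            vk = vmean  # mean-field reconstruction for linear units
        else:
            vk = (rng.random(vmean.shape) < vmean).astype(float)
        pk = params.hidden_probs(vk)
        h = (rng.random(pk.shape) < pk).astype(float)
    pk = params.hidden_probs(vk)
    n = len(batch)
    grads = {
        "W": (v0.T @ p0 - vk.T @ pk) / n,
        "a": (v0 - vk).mean(axis=0),
        "b": (p0 - pk).mean(axis=0),
    }
    recon = float(((v0 - params.visible_mean(p0)) ** 2).mean())
    return grads, recon


def rbm_cd_update(params: RBMParams, batch: np.ndarray, config: TrainConfig,
                  rng: np.random.Generator,
                  optimizer: Adam | None = None) -> tuple[RBMParams, float]:
    """One CD-k gradient ascent step through the Adam rule.

    Returns the (in-place updated) parameters and the mean squared
    reconstruction error of the batch.
    """
    if batch.shape[1] != params.W.shape[0]:
        raise ValueError(
            f"batch has {batch.shape[1]} columns, RBM expects {params.W.shape[0]}")
    grads, recon = _cd_statistics(params, batch, config.cd_steps, rng)
    opt = optimizer or Adam(lr=config.learning_rate)
    tensors = {"W": params.W, "a": params.a, "b": params.b}
    opt.step(tensors, {k: -g for k, g in grads.items()})  # ascent
    if any(not np.all(np.isfinite(t)) for t in tensors.values()):
        raise TrainingError("non-finite RBM parameters after update "
                            "(learning rate may be too high)")
    return params, recon


def train_rbm(params: RBMParams, data: np.ndarray, config: TrainConfig,
              rng: np.random.Generator, epochs: int) -> list[float]:
    """Mini-batch CD training; returns the per-epoch reconstruction-error trace."""
    opt = Adam(lr=config.learning_rate)
    n = len(data)
    bs = min(config.batch_size, n)
    trace = []
    for _ in range(epochs):
        order = rng.permutation(n)
        errs = []
        for start in range(0, n, bs):
            batch = data[order[start:start + bs]]
            _, err = rbm_cd_update(params, batch, config, rng, opt)
            errs.append(err)
        trace.append(float(np.mean(errs)))
    return trace


# ---------------------------------------------------------------------------
# exact likelihood machinery (small Bernoulli machines only)
# ---------------------------------------------------------------------------

def _free_energy(params: RBMParams, v: np.ndarray) -> np.ndarray:
    """F(v) = −aᵀv − Σ_j softplus(b_j + (vᵀW)_j), rows of v."""
    act = v @ params.W + params.b
    return -(v @ params.a) - np.logaddexp(0.0, act).sum(axis=1)


def _enumerate_visible(n_visible: int) -> np.ndarray:
    return np.array(list(itertools.product([0.0, 1.0], repeat=n_visible)))


def exact_log_likelihood(params: RBMParams, data: np.ndarray) -> float:
    """Mean log-likelihood by enumerating all visible states (Bernoulli only)."""
    if params.visible_kind != "bernoulli":
        raise ValueError("exact likelihood requires Bernoulli visible units")
    states = _enumerate_visible(params.W.shape[0])
    log_z = float(np.logaddexp.reduce(-_free_energy(params, states)))
    return float((-_free_energy(params, data)).mean() - log_z)


def exact_gradient(params: RBMParams, data: np.ndarray) -> dict[str, np.ndarray]:
    """Exact gradient of the mean log-likelihood w.r.t. (W, a, b).

    The model expectation is computed over the enumerated visible states,
    with hidden units marginalized analytically via p(h|v).
    """
    if params.visible_kind != "bernoulli":
        raise ValueError("exact gradient requires Bernoulli visible units")
    states = _enumerate_visible(params.W.shape[0])
    logp = -_free_energy(params, states)
    logp -= np.logaddexp.reduce(logp)
    pv = np.exp(logp)                       # p(v) over all states
    ph_states = params.hidden_probs(states)
    ph_data = params.hidden_probs(data)
    model_W = states.T @ (pv[:, None] * ph_states)
    model_a = pv @ states
    model_b = pv @ ph_states
    n = len(data)
    return {
        "W": data.T @ ph_data / n - model_W,
        "a": data.mean(axis=0) - model_a,
        "b": ph_data.mean(axis=0) - model_b,
    }
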