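"""Four 400-dimensional summaries of a position-specific scoring matrix.

All blocks flatten a 20×20 residue-pair matrix row-major:

* **P-PSSM** — per-residue-type row averages of the sigmoid-transformed
  profile (rows of residue types absent from the query are zero).
* **PSSM-DC** — dipeptide composition: averaged products of transformed
  values at adjacent positions.
* **Bi-gram PSSM** — bigram products of the softmax row-stochastic profile,
  summed (not averaged) over adjacent positions; the grand total equals L−1.
* **ED-PSSM** — evolutionary difference: averaged squared differences of
  transformed values at positions a lag ``d`` apart.

PSSM-DC and Bi-gram PSSM deliberately use different input normalizations
(sigmoid vs softmax) so the two blocks carry non-duplicated information.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit, softmax

from .alphabet import encode
from .fragment_features import FeatureBlock
from .io_formats import PSSMProfile

__all__ = [
    "TransformedProfile",
    "transform_pssm",
    "p_pssm",
    "pssm_dc",
    "bigram_pssm",
    "ed_pssm",
    "evolutionary_group_features",
]


@dataclass(frozen=True)
class TransformedProfile:
    """Sigmoid-squashed profile: every entry = 1/(1+exp(−score)) ∈ (0,1)."""

    values: np.ndarray
    source: PSSMProfile


def transform_pssm(p: PSSMProfile) -> TransformedProfile:
    return TransformedProfile(values=expit(p.scores), source=p)


def p_pssm(t: TransformedProfile) -> FeatureBlock:
    """Row (a, ·) = mean transformed row over query positions of residue a."""
    codes = encode(t.source.sequence.residues)
    out = np.zeros((20, 20))
    counts = np.bincount(codes, minlength=20).astype(float)
    np.add.at(out, codes, t.values)
    np.divide(out, counts[:, None], out=out, where=counts[:, None] > 0)
    return FeatureBlock("p_pssm", out.ravel(), 400)


def pssm_dc(t: TransformedProfile) -> FeatureBlock:
    """Entry (a, b) = mean over k of t[k,a]·t[k+1,b]."""
    v = t.values
    if v.shape[0] < 2:
        raise ValueError("pssm_dc requires profile length >= 2")
    out = v[:-1].T @ v[1:] / (v.shape[0] - 1)
    return FeatureBlock("pssm_dc", out.ravel(), 400)


def bigram_pssm(p: PSSMProfile) -> FeatureBlock:
    """Entry (a, b) = Σ_k n[k,a]·n[k+1,b] with n the softmax-normalized profile."""
    if p.scores.shape[0] < 2:
        raise ValueError("bigram_pssm requires profile length >= 2")
    n = softmax(p.scores, axis=1)
    out = n[:-1].T @ n[1:]
    return FeatureBlock("bigram_pssm", out.ravel(), 400)


def ed_pssm(t: TransformedProfile, d: int = 1) -> FeatureBlock:
    """Entry (a, b) = mean over k of (t[k,a] − t[k+d,b])²."""
    v = t.values
    L = v.shape[0]
    if d < 1:
        raise ValueError("lag d must be >= 1")
    if L <= d:
        raise ValueError(f"ed_pssm requires profile length > d (L={L}, d={d})")
    x, y = v[:L - d], v[d:]
    m = L - d
    # expand (x_ka − y_kb)²: column means of squares plus the cross term
    out = ((x ** 2).mean(axis=0)[:, None] + (y ** 2).mean(axis=0)[None, :]
           - 2.0 * (x.T @ y) / m)
    out = np.maximum(out, 0.0)  # guard tiny negative round-off
    return FeatureBlock("ed_pssm", out.ravel(), 400)


def evolutionary_group_features(p: PSSMProfile, d: int = 1) -> list[FeatureBlock]:
    """The four PSSM blocks in fixed order (total 1600 values)."""
    t = transform_pssm(p)
    return [p_pssm(t), pssm_dc(t), bigram_pssm(p), ed_pssm(t, d=d)]
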