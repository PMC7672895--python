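"""Synthetic fragment libraries and fold datasets for desk-scale experiments.

The generator emulates the two structural premises of the method:

* a **fragment class** is a recurring 4–20 residue pattern — modelled as a
  class consensus sequence plus per-position categorical noise, where
  ``motif_strength`` is the probability mass on the consensus residue
  (0 = uniform residues, 1 = every sample equals the consensus);
* a **fold** is a characteristic mixture of fragment-class usage — modelled
  by concatenating fragments drawn from a per-fold mixture until a target
  sequence length is reached.

Profiles are synthesized from BLOSUM62: row k is the substitution-matrix row
of residue k plus rounded Gaussian noise, which keeps the integer ASCII
dialect exact.  Every generator is a pure function of (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio.Align import substitution_matrices

from .alphabet import PSSM_COLUMN_ORDER
from .io_formats import (AminoAcidSequence, FragmentLibrary, FragmentRecord,
                         PSSMProfile)

__all__ = [
    "SyntheticLibrarySpec", "SyntheticFoldSpec",
    "make_fragment_library", "synth_pssm", "make_fold_dataset",
    "distinct_mixtures",
]

_blosum62_rows: np.ndarray | None = None


def _blosum62() -> np.ndarray:
    """20×20 BLOSUM62 log-odds in the fixed residue column order."""
    global _blosum62_rows
    if _blosum62_rows is None:
        mat = substitution_matrices.load("BLOSUM62")
        idx = [mat.alphabet.index(aa) for aa in PSSM_COLUMN_ORDER]
        _blosum62_rows = np.asarray(mat)[np.ix_(idx, idx)].astype(np.float64)
    return _blosum62_rows


@dataclass(frozen=True)
class SyntheticLibrarySpec:
    """Study conditions for a synthetic fragment library."""

    n_classes: int = 10
    samples_per_class: int = 100
    length_range: tuple[int, int] = (4, 20)
    motif_strength: float = 0.9
    pssm_noise: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        if not 0.0 <= self.motif_strength <= 1.0:
            raise ValueError("motif_strength must be in [0, 1]")
        lo, hi = self.length_range
        if not 4 <= lo <= hi <= 20:
            raise ValueError("length_range must sit inside [4, 20]")


@dataclass(frozen=True)
class SyntheticFoldSpec:
    """Study conditions for a synthetic fold dataset."""

    n_folds: int
    fragment_mixtures: tuple
    seqs_per_fold: int = 50
    seq_length_range: tuple[int, int] = (30, 50)
    pssm_noise: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        mixes = np.asarray(self.fragment_mixtures, dtype=float)
        if mixes.shape[0] != self.n_folds:
            raise ValueError("one mixture per fold required")
        if not np.allclose(mixes.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("each fragment mixture must sum to 1")

    @property
    def mixtures(self) -> np.ndarray:
        return np.asarray(self.fragment_mixtures, dtype=float)


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------

def synth_pssm(seq: AminoAcidSequence, noise: float = 1.0,
               seed: int = 0) -> PSSMProfile:
    """BLOSUM62 rows of the sequence plus rounded Gaussian noise (integer scores)."""
    if noise < 0:
        raise ValueError("noise must be >= 0")
    rng = np.random.default_rng(seed)
    lut = _blosum62()
    codes = [PSSM_COLUMN_ORDER.index(aa) for aa in seq.residues]
    scores = lut[codes].copy()
    if noise > 0:
        scores += np.rint(rng.normal(0.0, noise, size=scores.shape))
    return PSSMProfile(sequence=seq, scores=scores)


def make_fragment_library(spec: SyntheticLibrarySpec) -> FragmentLibrary:
    """Sample a labelled fragment library with class-specific sequence signal."""
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.length_range
    records: list[FragmentRecord] = []
    off = (1.0 - spec.motif_strength) / 19.0
    for cls in range(spec.n_classes):
        length = int(rng.integers(lo, hi + 1))
        consensus = rng.integers(0, 20, size=length)
        for s in range(spec.samples_per_class):
            probs = np.full((length, 20), off)
            probs[np.arange(length), consensus] = spec.motif_strength
            codes = np.array([rng.choice(20, p=p) for p in probs])
            residues = "".join(PSSM_COLUMN_ORDER[c] for c in codes)
            seq = AminoAcidSequence(id=f"c{cls:03d}_s{s:04d}", residues=residues)
            profile = synth_pssm(seq, noise=spec.pssm_noise,
                                 seed=int(rng.integers(0, 2**31 - 1)))
            records.append(FragmentRecord(sequence=seq, class_label=cls,
                                          profile=profile))
    return FragmentLibrary(records=records, n_classes=spec.n_classes)


def distinct_mixtures(n_folds: int, n_classes: int,
                      concentration: float = 0.8) -> np.ndarray:
    """Well-separated per-fold mixtures: each fold puts ``concentration`` of
    its mass on a disjoint block of fragment classes, the rest uniform."""
    if n_classes < n_folds:
        raise ValueError("need at least one fragment class per fold")
    mixes = np.full((n_folds, n_classes), (1.0 - concentration) / n_classes)
    block = n_classes // n_folds
    for f in range(n_folds):
        lo = f * block
        hi = n_classes if f == n_folds - 1 else lo + block
        mixes[f, lo:hi] += concentration / (hi - lo)
    return mixes / mixes.sum(axis=1, keepdims=True)


def make_fold_dataset(spec: SyntheticFoldSpec, library: FragmentLibrary,
                      return_usage: bool = False):
    """Concatenate library fragments drawn from each fold's mixture.

    Returns a list of (AminoAcidSequence, PSSMProfile, fold_label); with
    ``return_usage`` also an n_folds×n_classes count matrix of the fragment
    classes actually drawn, for checking empirical usage against the mixture.
    """
    mixes = spec.mixtures
    if mixes.shape[1] != library.n_classes:
        raise ValueError(
            f"mixtures cover {mixes.shape[1]} classes, library has "
            f"{library.n_classes}")
    by_class: dict[int, list] = {}
    for rec in library.records:
        by_class.setdefault(rec.class_label, []).append(rec)
    for cls in range(library.n_classes):
        if mixes[:, cls].max() > 0 and cls not in by_class:
            raise ValueError(f"mixture references empty class {cls}")
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.seq_length_range
    out = []
    usage = np.zeros((spec.n_folds, library.n_classes), dtype=np.int64)
    for fold in range(spec.n_folds):
        for s in range(spec.seqs_per_fold):
            target = int(rng.integers(lo, hi + 1))
            parts: list[str] = []
            total = 0
            while total < target:
                cls = int(rng.choice(library.n_classes, p=mixes[fold]))
                frag = by_class[cls][int(rng.integers(0, len(by_class[cls])))]
                parts.append(frag.sequence.residues)
                total += len(frag.sequence)
                usage[fold, cls] += 1
            residues = "".join(parts)[:target]
            seq = AminoAcidSequence(id=f"f{fold:02d}_s{s:04d}",
                                    residues=residues)
            profile = synth_pssm(seq, noise=spec.pssm_noise,
                                 seed=int(rng.integers(0, 2**31 - 1)))
            out.append((seq, profile, fold))
    if return_usage:
        return out, usage
    return out
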