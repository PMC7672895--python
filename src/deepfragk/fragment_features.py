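"""Sequence-composition and physicochemical feature blocks for fragments.

Each fragment (4–20 residues) is described by six fixed-dimension blocks:

====================================  ====
functional-group frequencies           10
information entropy (residue, dipep)    2
residue position distribution          20
functional-group transitions           45
pseudo amino acid composition          40
wavelet statistics of property profiles 42
====================================  ====

The ten functional groups are standard side-chain chemistry classes
(glycine; small aliphatic A/V/L/I; hydroxyl S/T; cysteine; methionine;
proline; aromatic F/W/Y; amide N/Q; acidic D/E; basic K/R/H).  Ten groups
give C(10,2)=45 unordered transition pairs.

Property scales are published residue tables (Kyte–Doolittle hydropathy,
Hopp–Woods hydrophilicity, Bhaskaran–Ponnuswamy flexibility, Rose mean
accessible surface area, classic side-chain masses), swappable via the
``PropertyScale`` type.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pywt

from .alphabet import PSSM_COLUMN_ORDER, STANDARD_AA, encode
from .io_formats import AminoAcidSequence

logger = logging.getLogger(__name__)

__all__ = [
    "GroupPartition",
    "PropertyScale",
    "FeatureBlock",
    "FragmentFeatureSet",
    "DEFAULT_PARTITION",
    "HYDROPHOBICITY",
    "HYDROPHILICITY",
    "FLEXIBILITY",
    "MEAN_ASA",
    "SIDE_CHAIN_MASS",
    "DWT_SCALES",
    "functional_group_frequencies",
    "sequence_entropy",
    "residue_distribution",
    "group_transitions",
    "pseaac",
    "property_profile",
    "dwt_features",
    "sequence_group_features",
    "physchem_group_features",
]


# ---------------------------------------------------------------------------
# types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GroupPartition:
    """An ordered partition of the 20 residues into 10 disjoint groups."""

    groups: tuple[frozenset, ...]
    names: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.groups) != 10 or len(self.names) != 10:
            raise ValueError("exactly 10 groups required")
        union = set().union(*self.groups)
        if union != set(STANDARD_AA):
            raise ValueError("groups must cover the 20-letter alphabet exactly")
        if sum(len(g) for g in self.groups) != 20:
            raise ValueError("groups must be pairwise disjoint")

    def code_of(self) -> np.ndarray:
        """residue column index -> group index (length-20 lookup)."""
        lut = np.empty(20, dtype=np.int64)
        for gi, grp in enumerate(self.groups):
            for aa in grp:
                lut[PSSM_COLUMN_ORDER.index(aa)] = gi
        return lut


@dataclass(frozen=True)
class PropertyScale:
    """A named residue -> real value table."""

    name: str
    values: dict

    def __post_init__(self) -> None:
        if set(self.values) != set(STANDARD_AA):
            raise ValueError(f"scale {self.name!r} must cover all 20 residues")

    def as_array(self) -> np.ndarray:
        """Values ordered by the fixed PSSM column order."""
        return np.array([self.values[aa] for aa in PSSM_COLUMN_ORDER], dtype=float)

    def standardized(self) -> np.ndarray:
        """Zero-mean unit-variance version over the 20 residues (population sd)."""
        arr = self.as_array()
        return (arr - arr.mean()) / arr.std()


@dataclass(frozen=True)
class FeatureBlock:
    name: str
    values: np.ndarray
    dim: int

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=np.float64)
        object.__setattr__(self, "values", vals)
        if vals.shape != (self.dim,):
            raise ValueError(f"block {self.name!r}: got shape {vals.shape}, "
                             f"expected ({self.dim},)")
        if not np.all(np.isfinite(vals)):
            raise ValueError(f"block {self.name!r}: non-finite values")


@dataclass
class FragmentFeatureSet:
    """The block-addressable feature representation of one fragment."""

    fragment_id: str
    blocks: list[FeatureBlock]
    group_spans: dict = field(default_factory=dict)

    def concatenated(self) -> np.ndarray:
        return np.concatenate([b.values for b in self.blocks])

    def group(self, name: str) -> np.ndarray:
        lo, hi = self.group_spans[name]
        return self.concatenated()[lo:hi]


# ---------------------------------------------------------------------------
# embedded tables
# ---------------------------------------------------------------------------

DEFAULT_PARTITION = GroupPartition(
    groups=tuple(frozenset(g) for g in
                 ("G", "AVLI", "ST", "C", "M", "P", "FWY", "NQ", "DE", "KRH")),
    names=("glycine", "aliphatic", "hydroxyl", "cysteine", "methionine",
           "proline", "aromatic", "amide", "acidic", "basic"),
)

#: Kyte & Doolittle hydropathy index.
HYDROPHOBICITY = PropertyScale("hydrophobicity_kyte_doolittle", {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5, "Q": -3.5, "E": -3.5,
    "G": -0.4, "H": -3.2, "I": 4.5, "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8,
    "P": -1.6, "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2})

#: Hopp & Woods hydrophilicity.
HYDROPHILICITY = PropertyScale("hydrophilicity_hopp_woods", {
    "A": -0.5, "R": 3.0, "N": 0.2, "D": 3.0, "C": -1.0, "Q": 0.2, "E": 3.0,
    "G": 0.0, "H": -0.5, "I": -1.8, "L": -1.8, "K": 3.0, "M": -1.3, "F": -2.5,
    "P": 0.0, "S": 0.3, "T": -0.4, "W": -3.4, "Y": -2.3, "V": -1.5})

#: Bhaskaran & Ponnuswamy average flexibility.
FLEXIBILITY = PropertyScale("flexibility_bhaskaran_ponnuswamy", {
    "A": 0.357, "R": 0.529, "N": 0.463, "D": 0.511, "C": 0.346, "Q": 0.493,
    "E": 0.497, "G": 0.544, "H": 0.323, "I": 0.462, "L": 0.365, "K": 0.466,
    "M": 0.295, "F": 0.314, "P": 0.509, "S": 0.507, "T": 0.444, "W": 0.305,
    "Y": 0.420, "V": 0.386})

#: Rose et al. mean accessible surface area (Å²) in the standard state.
MEAN_ASA = PropertyScale("mean_asa_rose", {
    "A": 118.1, "R": 256.0, "N": 165.5, "D": 158.7, "C": 146.1, "Q": 193.2,
    "E": 186.2, "G": 88.1, "H": 202.5, "I": 181.0, "L": 193.1, "K": 225.8,
    "M": 203.4, "F": 222.8, "P": 146.8, "S": 129.8, "T": 152.5, "W": 266.3,
    "Y": 236.8, "V": 164.5})

#: Classic integer side-chain masses (Da) used in sequence-order correlation.
SIDE_CHAIN_MASS = PropertyScale("side_chain_mass", {
    "G": 1.0, "A": 15.0, "S": 31.0, "P": 42.0, "V": 43.0, "T": 45.0, "C": 47.0,
    "L": 57.0, "I": 57.0, "N": 58.0, "D": 59.0, "Q": 72.0, "K": 72.0,
    "E": 73.0, "M": 75.0, "H": 81.0, "F": 91.0, "R": 100.0, "Y": 107.0,
    "W": 130.0})

#: The three profiles summarized by the wavelet block.
DWT_SCALES = (HYDROPHOBICITY, FLEXIBILITY, MEAN_ASA)

#: Properties entering the PseAAC sequence-order correlation.
_PSEAAC_SCALES = (HYDROPHOBICITY, HYDROPHILICITY, SIDE_CHAIN_MASS)

_DWT_RESAMPLE_LEN = 32
_DWT_LEVELS = 3


# ---------------------------------------------------------------------------
# sequence-composition blocks
# ---------------------------------------------------------------------------

def functional_group_frequencies(seq: AminoAcidSequence,
                                 partition: GroupPartition = DEFAULT_PARTITION,
                                 ) -> FeatureBlock:
    """Fraction of residues falling in each of the 10 functional groups."""
    codes = encode(seq.residues)
    groups = partition.code_of()[codes]
    freq = np.bincount(groups, minlength=10) / len(codes)
    return FeatureBlock("group_frequencies", freq, 10)


def _entropy_bits(counts: np.ndarray) -> float:
    total = counts.sum()
    p = counts[counts > 0] / total
    return float(-(p * np.log2(p)).sum())


def sequence_entropy(seq: AminoAcidSequence) -> FeatureBlock:
    """Shannon entropy (bits) of residue and overlapping-dipeptide frequencies."""
    codes = encode(seq.residues)
    if len(codes) < 2:
        raise ValueError("sequence_entropy requires length >= 2")
    res_counts = np.bincount(codes, minlength=20)
    dipep = codes[:-1] * 20 + codes[1:]
    dipep_counts = np.bincount(dipep, minlength=400)
    return FeatureBlock(
        "entropy", [_entropy_bits(res_counts), _entropy_bits(dipep_counts)], 2)


def residue_distribution(seq: AminoAcidSequence) -> FeatureBlock:
    """Mean relative position i/L of each residue type; 0 when absent."""
    codes = encode(seq.residues)
    L = len(codes)
    sums = np.zeros(20)
    counts = np.zeros(20)
    np.add.at(sums, codes, (np.arange(1, L + 1)) / L)
    np.add.at(counts, codes, 1.0)
    out = np.divide(sums, counts, out=np.zeros(20), where=counts > 0)
    return FeatureBlock("residue_distribution", out, 20)


_PAIR_INDEX = {}
_k = 0
for _g in range(10):
    for _h in range(_g + 1, 10):
        _PAIR_INDEX[(_g, _h)] = _k
        _k += 1


def group_transitions(seq: AminoAcidSequence,
                      partition: GroupPartition = DEFAULT_PARTITION) -> FeatureBlock:
    """Adjacent-pair frequencies between distinct functional groups (45 pairs)."""
    codes = encode(seq.residues)
    if len(codes) < 2:
        raise ValueError("group_transitions requires length >= 2")
    groups = partition.code_of()[codes]
    out = np.zeros(45)
    for g, h in zip(groups[:-1], groups[1:]):
        if g != h:
            out[_PAIR_INDEX[(min(g, h), max(g, h))]] += 1.0
    return FeatureBlock("group_transitions", out / (len(codes) - 1), 45)


# ---------------------------------------------------------------------------
# physicochemical blocks
# ---------------------------------------------------------------------------

def pseaac(seq: AminoAcidSequence, lam: int = 19, w: float = 0.05) -> FeatureBlock:
    """Classic type-1 pseudo amino acid composition, zero-padded to 40 entries.

    Entries 1–20 are normalized residue frequencies; entries 20+k are the
    weighted sequence-order correlation factors θ_k, k = 1..min(lam, L−1).
    θ_k averages the mean squared difference of three standardized property
    values (hydropathy, hydrophilicity, side-chain mass) between residues k
    apart.  All 40 entries share the denominator Σf + w·Σθ, so the populated
    prefix sums to 1.
    """
    codes = encode(seq.residues)
    L = len(codes)
    if L < 2:
        raise ValueError("pseaac requires length >= 2")
    if w <= 0:
        raise ValueError("w must be positive")
    if lam < 1:
        raise ValueError("lam must be >= 1")
    if lam > 19:
        logger.warning("pseaac: lam=%d clipped to 19 (fragments are <= 20 residues)",
                       lam)
        lam = 19
    props = np.stack([s.standardized() for s in _PSEAAC_SCALES])  # 3×20
    vals = props[:, codes]  # 3×L
    k_max = min(lam, L - 1)
    thetas = np.zeros(20)
    for k in range(1, k_max + 1):
        diff = vals[:, :-k] - vals[:, k:]
        thetas[k - 1] = np.mean(diff ** 2, axis=0).mean()
    freqs = np.bincount(codes, minlength=20) / L
    denom = freqs.sum() + w * thetas.sum()
    out = np.zeros(40)
    out[:20] = freqs / denom
    out[20:] = w * thetas / denom
    return FeatureBlock("pseaac", out, 40)


def property_profile(seq: AminoAcidSequence, scale: PropertyScale) -> np.ndarray:
    """Per-position lookup of a property scale along the sequence."""
    return scale.as_array()[encode(seq.residues)]


def _dwt_stats(profile: np.ndarray) -> np.ndarray:
    x = np.asarray(profile, dtype=np.float64)
    pos = np.linspace(0.0, 1.0, len(x))
    grid = np.linspace(0.0, 1.0, _DWT_RESAMPLE_LEN)
    resampled = np.interp(grid, pos, x)
    coeffs = pywt.wavedec(resampled, "haar", level=_DWT_LEVELS,
                          mode="periodization")  # A3, D3, D2, D1
    stats = []
    for band in coeffs:
        stats.extend((band.mean(), band.std(), band.max()))
    flat = np.concatenate(coeffs)
    energy = float((flat ** 2).sum())
    sq = flat ** 2
    if energy > 0:
        p = sq / energy
        p = p[p > 0]
        ent = float(-(p * np.log2(p)).sum())
    else:
        ent = 0.0
    stats.extend((energy, ent))
    return np.array(stats)


def dwt_features(seq: AminoAcidSequence,
                 scales: tuple = DWT_SCALES) -> FeatureBlock:
    """Multi-resolution statistics of three physicochemical profiles (42 values).

    Each profile is linearly resampled to 32 points, decomposed by a 3-level
    orthonormal Haar wavelet transform (sub-bands A3, D3, D2, D1), and
    summarized by {mean, sd, max} per band plus total coefficient energy and
    the Shannon entropy (bits) of the normalized squared coefficients.
    """
    if len(seq) < 4:
        raise ValueError("dwt_features requires length >= 4")
    if len(scales) != 3:
        raise ValueError("exactly 3 property scales expected")
    parts = [_dwt_stats(property_profile(seq, s)) for s in scales]
    return FeatureBlock("dwt", np.concatenate(parts), 42)


# ---------------------------------------------------------------------------
# group concatenations
# ---------------------------------------------------------------------------

def sequence_group_features(seq: AminoAcidSequence,
                            partition: GroupPartition = DEFAULT_PARTITION,
                            ) -> list[FeatureBlock]:
    """The four sequence-composition blocks in fixed order (total 77 values)."""
    return [
        functional_group_frequencies(seq, partition),
        sequence_entropy(seq),
        residue_distribution(seq),
        group_transitions(seq, partition),
    ]


def physchem_group_features(seq: AminoAcidSequence, lam: int = 19,
                            w: float = 0.05) -> list[FeatureBlock]:
    """The two physicochemical blocks in fixed order (total 82 values)."""
    return [pseaac(seq, lam=lam, w=w), dwt_features(seq)]
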