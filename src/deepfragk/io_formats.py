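"""File formats: FASTA, PSI-BLAST ASCII PSSMs, fragment libraries, features, checkpoints.

The PSSM dialect is the one produced by ``psiblast -out_ascii_pssm``: a couple
of header lines, one line per query position carrying the position index, the
query residue, 20 integer log-odds columns and 20 weighted-percentage columns
(plus two per-line trailing statistics), then an optional footer.  Only the
log-odds block is retained; columns are re-mapped to the package-wide order
declared in :mod:`deepfragk.alphabet`.

Fragment libraries are stored as an inspectable directory: one multi-record
FASTA, one PSSM file per fragment, and a tab-separated manifest.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import h5py
import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .alphabet import AA_SET, AA_TO_COL, PSSM_COLUMN_ORDER

logger = logging.getLogger(__name__)

__all__ = [
    "AminoAcidSequence",
    "PSSMProfile",
    "FragmentRecord",
    "FragmentLibrary",
    "FormatError",
    "CheckpointError",
    "read_fasta",
    "write_fasta",
    "read_pssm_ascii",
    "write_pssm_ascii",
    "excise_profile",
    "save_library",
    "load_library",
    "write_feature_matrix",
    "read_feature_matrix",
    "save_checkpoint",
    "load_checkpoint",
]


class FormatError(ValueError):
    """A file does not follow the expected layout."""


class CheckpointError(ValueError):
    """A checkpoint cannot be restored (version or shape mismatch)."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AminoAcidSequence:
    """A sanitized protein sequence over the 20 standard residues."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        if len(self.residues) < 1:
            raise ValueError(f"sequence {self.id!r} is empty")
        bad = set(self.residues) - AA_SET
        if bad:
            raise ValueError(
                f"sequence {self.id!r} contains non-standard residues {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class PSSMProfile:
    """Per-position log-odds profile aligned to a query sequence.

    ``scores`` is L×20 with columns in :data:`~deepfragk.alphabet.PSSM_COLUMN_ORDER`.
    """

    sequence: AminoAcidSequence
    scores: np.ndarray

    def __post_init__(self) -> None:
        scores = np.asarray(self.scores, dtype=np.float64)
        object.__setattr__(self, "scores", scores)
        if scores.ndim != 2 or scores.shape[1] != 20:
            raise ValueError(f"scores must be L×20, got {scores.shape}")
        if scores.shape[0] != len(self.sequence):
            raise ValueError(
                f"profile rows ({scores.shape[0]}) != sequence length "
                f"({len(self.sequence)}) for {self.sequence.id!r}"
            )


@dataclass(frozen=True)
class FragmentRecord:
    """A labelled library fragment (4–20 residues) with its profile."""

    sequence: AminoAcidSequence
    class_label: int
    profile: PSSMProfile

    def __post_init__(self) -> None:
        if not 4 <= len(self.sequence) <= 20:
            raise ValueError(
                f"fragment {self.sequence.id!r} has length {len(self.sequence)}, "
                "expected 4..20"
            )
        if self.profile.sequence.residues != self.sequence.residues:
            raise ValueError(f"profile/sequence mismatch for {self.sequence.id!r}")


@dataclass
class FragmentLibrary:
    """A set of labelled fragments defining the fragment-class vocabulary."""

    records: list[FragmentRecord]
    n_classes: int
    class_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.class_names:
            self.class_names = [f"class_{i}" for i in range(self.n_classes)]
        if len(self.class_names) != self.n_classes:
            raise ValueError("class_names length must equal n_classes")
        seen = set()
        for rec in self.records:
            if not 0 <= rec.class_label < self.n_classes:
                raise ValueError(
                    f"class label {rec.class_label} out of range [0, {self.n_classes})"
                )
            seen.add(rec.class_label)
        missing = set(range(self.n_classes)) - seen
        if missing:
            raise ValueError(f"classes with no records: {sorted(missing)}")

    def __len__(self) -> int:
        return len(self.records)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def _sanitize(raw: str) -> tuple[str, int]:
    kept = [c for c in raw.upper() if c in AA_SET]
    return "".join(kept), len(raw) - len(kept)


def read_fasta(path: str | Path, strict: bool = False) -> list[AminoAcidSequence]:
    """Read a multi-record FASTA, sanitizing to the 20-letter alphabet.

    Characters outside the standard alphabet (X/B/Z/U/O, gaps, ...) are
    removed and counted per record.  A record left empty after sanitization is
    a record-level error: logged and skipped by default, raised if ``strict``.
    """
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    out: list[AminoAcidSequence] = []
    empty_ids: list[str] = []
    for rec in records:
        residues, removed = _sanitize(str(rec.seq))
        if removed:
            logger.info("%s: removed %d non-standard characters from %r",
                        path.name, removed, rec.id)
        if not residues:
            logger.error("%s: record %r empty after sanitization", path.name, rec.id)
            empty_ids.append(rec.id)
            continue
        out.append(AminoAcidSequence(id=rec.id, residues=residues))
    if strict and empty_ids:
        raise FormatError(f"{path}: records empty after sanitization: {empty_ids}")
    return out


def write_fasta(seqs: Iterable[AminoAcidSequence], path: str | Path) -> None:
    records = [SeqRecord(Seq(s.residues), id=s.id, description="") for s in seqs]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# PSI-BLAST ASCII PSSM
# ---------------------------------------------------------------------------

def _find_header_order(line: str) -> list[str] | None:
    tokens = line.split()
    if len(tokens) < 20:
        return None
    head = tokens[:20]
    if all(t in AA_SET and len(t) == 1 for t in head) and len(set(head)) == 20:
        return head
    return None


def read_pssm_ascii(path: str | Path, seq_id: str | None = None) -> PSSMProfile:
    """Parse a PSI-BLAST ASCII PSSM into a profile in the fixed column order.

    Only the 20 log-odds columns are kept; the weighted-percentage block and
    any footer are discarded.  Rows whose query residue is non-standard are
    dropped with a warning (the sequence position is removed too).
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    order: list[str] | None = None
    rows: list[list[float]] = []
    letters: list[str] = []
    in_matrix = False
    for line in lines:
        if order is None:
            order = _find_header_order(line)
            continue
        tokens = line.split()
        if len(tokens) < 2:
            if in_matrix:
                break  # footer reached
            continue
        try:
            int(tokens[0])
        except ValueError:
            if in_matrix:
                break
            continue
        residue = tokens[1].upper()
        fields = tokens[2:]
        numeric: list[float] = []
        for t in fields:
            try:
                numeric.append(float(t))
            except ValueError:
                break
        # 40 score fields required; up to 2 trailing per-line statistics allowed
        if len(numeric) not in (40, 41, 42):
            raise FormatError(
                f"{path}: position {tokens[0]} has {len(numeric)} numeric fields, "
                "expected 40 score fields (+ up to 2 trailing)"
            )
        in_matrix = True
        if residue not in AA_SET:
            logger.warning("%s: dropping row %s with non-standard residue %r",
                           path.name, tokens[0], residue)
            continue
        rows.append(numeric[:20])
        letters.append(residue)
    if order is None:
        raise FormatError(f"{path}: no PSSM column-header line found")
    if not rows:
        raise FormatError(f"{path}: no matrix rows found")
    raw = np.asarray(rows, dtype=np.float64)
    # re-map file column order to the fixed internal order
    perm = [order.index(aa) for aa in PSSM_COLUMN_ORDER]
    scores = raw[:, perm]
    seq = AminoAcidSequence(id=seq_id or path.stem, residues="".join(letters))
    return PSSMProfile(sequence=seq, scores=scores)


def write_pssm_ascii(profile: PSSMProfile, path: str | Path) -> None:
    """Write a profile in the PSI-BLAST ASCII dialect (fixed column order)."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("\n")
        fh.write("Last position-specific scoring matrix computed, weighted observed "
                 "percentages rounded down\n")
        fh.write("     " + "  ".join(PSSM_COLUMN_ORDER) + "   "
                 + "   ".join(PSSM_COLUMN_ORDER) + "\n")
        scores = profile.scores
        # weighted percentages: softmax of the row, rounded — informational only
        exp = np.exp(scores - scores.max(axis=1, keepdims=True))
        pct = np.rint(100 * exp / exp.sum(axis=1, keepdims=True)).astype(int)
        for i, aa in enumerate(profile.sequence.residues):
            svals = " ".join(f"{int(round(v)):4d}" if float(v).is_integer()
                             else f"{v:6.2f}" for v in scores[i])
            pvals = " ".join(f"{p:4d}" for p in pct[i])
            fh.write(f"{i + 1:5d} {aa} {svals}  {pvals}  0.00 0.00\n")
        fh.write("\n")
        fh.write("                      K         Lambda\n")


def excise_profile(profile: PSSMProfile, start: int, length: int,
                   fragment_id: str | None = None) -> PSSMProfile:
    """Slice a fragment profile out of a whole-protein profile (rows [start, start+length))."""
    if start < 0 or start + length > len(profile.sequence):
        raise ValueError(
            f"window [{start}, {start + length}) outside profile of length "
            f"{len(profile.sequence)}"
        )
    sub = profile.sequence.residues[start:start + length]
    seq = AminoAcidSequence(
        id=fragment_id or f"{profile.sequence.id}_{start}_{length}", residues=sub)
    return PSSMProfile(sequence=seq, scores=profile.scores[start:start + length])


# ---------------------------------------------------------------------------
# fragment-library store (FASTA + per-record PSSM + TSV manifest)
# ---------------------------------------------------------------------------

def save_library(library: FragmentLibrary, out_dir: str | Path) -> None:
    out_dir = Path(out_dir)
    (out_dir / "pssm").mkdir(parents=True, exist_ok=True)
    write_fasta((rec.sequence for rec in library.records),
                out_dir / "fragments.fasta")
    with (out_dir / "manifest.tsv").open("w") as fh:
        fh.write("id\tclass_label\tclass_name\tpssm_path\n")
        for rec in library.records:
            rel = f"pssm/{rec.sequence.id}.pssm"
            write_pssm_ascii(rec.profile, out_dir / rel)
            fh.write(f"{rec.sequence.id}\t{rec.class_label}\t"
                     f"{library.class_names[rec.class_label]}\t{rel}\n")


def load_library(in_dir: str | Path) -> FragmentLibrary:
    in_dir = Path(in_dir)
    seqs = {s.id: s for s in read_fasta(in_dir / "fragments.fasta")}
    records: list[FragmentRecord] = []
    class_names: dict[int, str] = {}
    manifest = (in_dir / "manifest.tsv").read_text().splitlines()
    if not manifest or manifest[0].split("\t")[:2] != ["id", "class_label"]:
        raise FormatError(f"{in_dir}/manifest.tsv: bad or missing header")
    for line in manifest[1:]:
        if not line.strip():
            continue
        rec_id, label_s, class_name, rel = line.split("\t")
        label = int(label_s)
        class_names[label] = class_name
        profile = read_pssm_ascii(in_dir / rel, seq_id=rec_id)
        records.append(FragmentRecord(sequence=seqs[rec_id], class_label=label,
                                      profile=profile))
    n_classes = max(class_names) + 1
    names = [class_names.get(i, f"class_{i}") for i in range(n_classes)]
    return FragmentLibrary(records=records, n_classes=n_classes, class_names=names)


# ---------------------------------------------------------------------------
# feature matrices (HDF5)
# ---------------------------------------------------------------------------

def write_feature_matrix(features: Sequence, path: str | Path) -> None:
    """Write FragmentFeatureSets as one rectangular matrix with a block-layout header.

    All records must share the same block layout; the paired reader restores
    values bitwise.
    """
    path = Path(path)
    if features:
        layout = [(b.name, b.dim) for b in features[0].blocks]
        for fs in features[1:]:
            if [(b.name, b.dim) for b in fs.blocks] != layout:
                raise ValueError(
                    f"inconsistent block layout in record {fs.fragment_id!r}")
        matrix = np.stack([fs.concatenated() for fs in features])
        ids = [fs.fragment_id for fs in features]
        spans = features[0].group_spans
    else:
        layout, matrix, ids, spans = [], np.zeros((0, 0)), [], {}
    with h5py.File(path, "w") as h5:
        h5.create_dataset("features", data=matrix)
        h5.create_dataset("fragment_ids", data=np.array(ids, dtype="S"))
        h5.attrs["block_names"] = json.dumps([n for n, _ in layout])
        h5.attrs["block_dims"] = json.dumps([d for _, d in layout])
        h5.attrs["group_spans"] = json.dumps(
            {k: [int(v[0]), int(v[1])] for k, v in spans.items()})


def read_feature_matrix(path: str | Path):
    """Read back (matrix, fragment_ids, block_layout, group_spans)."""
    with h5py.File(path, "r") as h5:
        matrix = h5["features"][...]
        ids = [s.decode() for s in h5["fragment_ids"][...]]
        names = json.loads(h5.attrs["block_names"])
        dims = json.loads(h5.attrs["block_dims"])
        spans = {k: tuple(v) for k, v in json.loads(h5.attrs["group_spans"]).items()}
    return matrix, ids, list(zip(names, dims)), spans


# ---------------------------------------------------------------------------
# model checkpoints (HDF5)
# ---------------------------------------------------------------------------

_CHECKPOINT_VERSION = 1


def save_checkpoint(model, path: str | Path, name: str = "model") -> None:
    """Save a FragmentPredictor or FoldCNN (or both, under distinct names)."""
    path = Path(path)
    mode = "a" if path.exists() else "w"
    with h5py.File(path, mode) as h5:
        if name in h5:
            del h5[name]
        grp = h5.create_group(name)
        grp.attrs["version"] = _CHECKPOINT_VERSION
        grp.attrs["model_type"] = type(model).__name__
        grp.attrs["config"] = json.dumps(model.config_dict())
        for key, arr in model.to_arrays().items():
            grp.create_dataset(key, data=arr)


def load_checkpoint(path: str | Path, name: str = "model",
                    expect_config: dict | None = None):
    """Restore a model; forward outputs are bit-identical to the saved model."""
    from .neural.fold_cnn import FoldCNN
    from .neural.fragment_predictor import FragmentPredictor

    registry = {"FragmentPredictor": FragmentPredictor, "FoldCNN": FoldCNN}
    with h5py.File(path, "r") as h5:
        if name not in h5:
            raise CheckpointError(f"{path}: no model group {name!r}")
        grp = h5[name]
        if grp.attrs["version"] != _CHECKPOINT_VERSION:
            raise CheckpointError(
                f"{path}: checkpoint version {grp.attrs['version']} != "
                f"{_CHECKPOINT_VERSION}")
        model_type = grp.attrs["model_type"]
        config = json.loads(grp.attrs["config"])
        arrays = {key: grp[key][...] for key in grp.keys()}
    if expect_config:
        for key, val in expect_config.items():
            if config.get(key) != val:
                raise CheckpointError(
                    f"{path}: config mismatch for {key!r}: expected {val}, "
                    f"found {config.get(key)}")
    cls = registry[model_type]
    try:
        return cls.from_arrays(config, arrays)
    except ValueError as exc:
        raise CheckpointError(f"{path}: {exc}") from exc
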