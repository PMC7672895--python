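"""End-to-end orchestration of the two-stage fold recognizer.

A query sequence is segmented into every sliding window of 4–20 residues;
each window is featurized (1759 values in three groups) and scored by the
stage-1 fragment classifier; the per-window softmax outputs are aggregated
into a fixed-length fragment vector; the stage-2 CNN maps that vector to
fold probabilities.

Coordinates are 0-based half-open internally and 1-based inclusive in
user-facing tables.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .evolutionary_features import evolutionary_group_features
from .fragment_features import (DEFAULT_PARTITION, FragmentFeatureSet,
                                physchem_group_features,
                                sequence_group_features)
from .io_formats import (AminoAcidSequence, FragmentLibrary, PSSMProfile,
                         excise_profile, load_library, read_fasta,
                         read_pssm_ascii, save_checkpoint, load_checkpoint,
                         write_fasta, write_pssm_ascii)
from .neural.fold_cnn import FoldCNN, train_fold_cnn
from .neural.fragment_predictor import (DEFAULT_SPANS, FragmentPredictor,
                                        train_fragment_predictor)
from .neural.training import TrainConfig

logger = logging.getLogger(__name__)

__all__ = [
    "FragmentWindow", "FragmentVector", "FoldPrediction",
    "segment_sequence", "featurize_window", "featurize_fragments",
    "build_fragment_vector", "predict_fold",
    "save_fold_dataset", "load_fold_dataset",
    "run_train", "run_predict",
]

MIN_WINDOW, MAX_WINDOW = 4, 20

#: Total feature width: 77 sequence + 82 physicochemical + 1600 evolutionary.
FEATURE_DIM = DEFAULT_SPANS["evolutionary"][1]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FragmentWindow:
    """One sliding-window fragment of a parent sequence."""

    parent_id: str
    start: int                    # 0-based inclusive
    length: int
    sequence: AminoAcidSequence
    profile_slice: PSSMProfile

    def __post_init__(self) -> None:
        if not MIN_WINDOW <= self.length <= MAX_WINDOW:
            raise ValueError(f"window length {self.length} outside "
                             f"[{MIN_WINDOW}, {MAX_WINDOW}]")


@dataclass
class FragmentVector:
    """Aggregated per-sequence fragment-class usage vector."""

    parent_id: str
    values: np.ndarray
    n_windows: int
    mode: str = "soft"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if (self.values < 0).any():
            raise ValueError("fragment vector must be non-negative")


@dataclass
class FoldPrediction:
    parent_id: str
    fold_probs: np.ndarray
    top_fold: int
    fragment_vector: FragmentVector


# ---------------------------------------------------------------------------
# segmentation & featurization
# ---------------------------------------------------------------------------

def segment_sequence(seq: AminoAcidSequence, profile: PSSMProfile,
                     min_len: int = MIN_WINDOW,
                     max_len: int = MAX_WINDOW) -> list[FragmentWindow]:
    """All windows of every length in [min_len, max_len] at stride 1.

    Windows are ordered lexicographically by (length, start); the total count
    is Σ_k max(0, L−k+1).
    """
    L = len(seq)
    if L < min_len:
        raise ValueError(
            f"sequence {seq.id!r} too short: {L} < minimum window {min_len}")
    Lp = len(profile.sequence)
    if Lp > L:
        raise ValueError(f"profile not aligned to sequence {seq.id!r}")
    if Lp < L:
        # profile shorter than the sanitized sequence: windows without
        # profile rows are dropped rather than zero-filled
        logger.warning("%s: profile covers %d of %d residues; windows beyond "
                       "position %d dropped", seq.id, Lp, L, Lp)
        L = Lp
        if L < min_len:
            raise ValueError(
                f"sequence {seq.id!r} too short after profile truncation")
    windows = []
    for k in range(min_len, max_len + 1):
        for start in range(0, L - k + 1):
            windows.append(FragmentWindow(
                parent_id=seq.id, start=start, length=k,
                sequence=AminoAcidSequence(
                    id=f"{seq.id}:{start + 1}-{start + k}",
                    residues=seq.residues[start:start + k]),
                profile_slice=excise_profile(profile, start, k),
            ))
    return windows


def featurize_window(window: FragmentWindow,
                     partition=DEFAULT_PARTITION, lam: int = 19,
                     w: float = 0.05, ed_lag: int = 1) -> FragmentFeatureSet:
    """All ten feature blocks of one fragment (concatenated length 1759)."""
    blocks = (sequence_group_features(window.sequence, partition)
              + physchem_group_features(window.sequence, lam=lam, w=w)
              + evolutionary_group_features(window.profile_slice, d=ed_lag))
    return FragmentFeatureSet(
        fragment_id=window.sequence.id, blocks=blocks,
        group_spans=dict(DEFAULT_SPANS))


def featurize_fragments(windows, **kwargs) -> np.ndarray:
    """Feature matrix (n × 1759) for a list of windows or fragment records."""
    rows = []
    for item in windows:
        if not isinstance(item, FragmentWindow):
            item = FragmentWindow(parent_id=item.sequence.id, start=0,
                                  length=len(item.sequence),
                                  sequence=item.sequence,
                                  profile_slice=item.profile)
        rows.append(featurize_window(item, **kwargs).concatenated())
    return np.asarray(rows)


# ---------------------------------------------------------------------------
# aggregation & prediction
# ---------------------------------------------------------------------------

def build_fragment_vector(windows: list[FragmentWindow],
                          predictor: FragmentPredictor,
                          mode: str = "soft",
                          features: np.ndarray | None = None,
                          min_max_prob: float = 0.0) -> FragmentVector:
    """Aggregate per-window softmax outputs into one fragment vector.

    ``soft`` (default): mean of the window softmax distributions (sums to 1).
    ``hard``: normalized histogram of per-window argmax classes.
    ``min_max_prob`` optionally discards low-confidence windows (those whose
    top class probability falls below the threshold) before aggregating;
    it is off (0.0) by default.
    """
    if not windows:
        raise ValueError("cannot build a fragment vector from zero windows")
    if mode not in ("soft", "hard"):
        raise ValueError(f"unknown aggregation mode {mode!r}")
    if features is None:
        features = featurize_fragments(windows)
    probs = predictor.predict_proba(features)
    if min_max_prob > 0.0:
        keep = probs.max(axis=1) >= min_max_prob
        if not keep.any():
            raise ValueError(
                f"no window reaches min_max_prob={min_max_prob}")
        probs = probs[keep]
        windows = [w for w, k in zip(windows, keep) if k]
    if mode == "soft":
        values = probs.mean(axis=0)
    else:
        counts = np.bincount(probs.argmax(axis=1),
                             minlength=predictor.n_classes)
        values = counts / counts.sum()
    return FragmentVector(parent_id=windows[0].parent_id, values=values,
                          n_windows=len(windows), mode=mode)


def predict_fold(seq: AminoAcidSequence, profile: PSSMProfile,
                 stage1: FragmentPredictor, stage2: FoldCNN,
                 mode: str = "soft", min_len: int = MIN_WINDOW,
                 max_len: int = MAX_WINDOW) -> FoldPrediction:
    """Run the full two-stage pipeline on one sequence (deterministic)."""
    if stage2.arch["n_input"] != stage1.n_classes:
        raise ValueError(
            f"stage-2 input length {stage2.arch['n_input']} != stage-1 "
            f"classes {stage1.n_classes}")
    windows = segment_sequence(seq, profile, min_len, max_len)
    fvec = build_fragment_vector(windows, stage1, mode=mode)
    fold_probs = stage2.predict_proba(fvec.values[None, :])[0]
    # ties broken toward the lowest fold index (argmax convention)
    return FoldPrediction(parent_id=seq.id, fold_probs=fold_probs,
                          top_fold=int(fold_probs.argmax()),
                          fragment_vector=fvec)


# ---------------------------------------------------------------------------
# fold-dataset store (FASTA + per-sequence PSSM + labels.tsv)
# ---------------------------------------------------------------------------

def save_fold_dataset(dataset, out_dir: str | Path) -> None:
    """``dataset`` is a list of (AminoAcidSequence, PSSMProfile, fold_label)."""
    out_dir = Path(out_dir)
    (out_dir / "pssm").mkdir(parents=True, exist_ok=True)
    write_fasta((seq for seq, _, _ in dataset), out_dir / "sequences.fasta")
    with (out_dir / "labels.tsv").open("w") as fh:
        fh.write("id\tfold_label\tpssm_path\n")
        for seq, profile, label in dataset:
            rel = f"pssm/{seq.id}.pssm"
            write_pssm_ascii(profile, out_dir / rel)
            fh.write(f"{seq.id}\t{label}\t{rel}\n")


def load_fold_dataset(in_dir: str | Path):
    in_dir = Path(in_dir)
    seqs = {s.id: s for s in read_fasta(in_dir / "sequences.fasta")}
    out = []
    lines = (in_dir / "labels.tsv").read_text().splitlines()
    for line in lines[1:]:
        if not line.strip():
            continue
        seq_id, label, rel = line.split("\t")
        profile = read_pssm_ascii(in_dir / rel, seq_id=seq_id)
        out.append((seqs[seq_id], profile, int(label)))
    return out


# ---------------------------------------------------------------------------
# config-driven runners
# ---------------------------------------------------------------------------

_REQUIRED_TRAIN_KEYS = ("library_dir", "folds_dir", "out_dir")
_REQUIRED_PREDICT_KEYS = ("checkpoint", "fasta", "pssm_dir", "out_dir")


def _load_config(config) -> dict:
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    if not isinstance(config, dict):
        raise ValueError("config must be a mapping")
    return config


def _validate(config: dict, required) -> None:
    missing = [k for k in required if k not in config]
    if missing:
        raise ValueError(f"config missing required fields: {missing}")


def _train_config(config: dict, section: str) -> TrainConfig:
    base = dict(config.get("train", {}))
    base.update(config.get(section, {}).get("train", {}))
    base.setdefault("seed", config.get("seed", 0))
    return TrainConfig(**base)


def run_train(config) -> dict:
    """Train both stages from on-disk data; write checkpoints and reports.

    Returns a summary dict with history and artifact paths.
    """
    config = _load_config(config)
    _validate(config, _REQUIRED_TRAIN_KEYS)
    out_dir = Path(config["out_dir"])
    out_dir.mkdir(parents=True, exist_ok=True)
    library = load_library(config["library_dir"])
    logger.info("featurizing %d library fragments", len(library))
    X = featurize_fragments(library.records)
    y = np.array([rec.class_label for rec in library.records])
    cfg1 = _train_config(config, "stage1")
    stage1, hist1 = train_fragment_predictor(
        X, y, cfg1, arch=config.get("stage1", {}).get("arch"))
    dataset = load_fold_dataset(config["folds_dir"])
    vectors, fold_labels = [], []
    mode = config.get("aggregate", "soft")
    for seq, profile, label in dataset:
        windows = segment_sequence(seq, profile)
        vectors.append(build_fragment_vector(windows, stage1, mode=mode).values)
        fold_labels.append(label)
    cfg2 = _train_config(config, "stage2")
    stage2, hist2 = train_fold_cnn(np.asarray(vectors), np.asarray(fold_labels),
                                   cfg2, arch=config.get("stage2", {}).get("arch"))
    ckpt = out_dir / "checkpoints.h5"
    if ckpt.exists():
        ckpt.unlink()
    save_checkpoint(stage1, ckpt, name="stage1")
    save_checkpoint(stage2, ckpt, name="stage2")
    for name, hist in (("stage1", hist1), ("stage2", hist2)):
        with (out_dir / f"history_{name}.tsv").open("w") as fh:
            fh.write("epoch\ttrain_loss\tval_loss\n")
            for i, (tr, vl) in enumerate(zip(hist["train_loss"],
                                             hist["val_loss"])):
                fh.write(f"{i}\t{tr:.6f}\t{vl:.6f}\n")
    return {"checkpoint": str(ckpt), "stage1_history": hist1,
            "stage2_history": hist2}


def run_predict(config) -> Path:
    """Predict folds for a FASTA + PSSM directory; write a TSV table."""
    config = _load_config(config)
    _validate(config, _REQUIRED_PREDICT_KEYS)
    ckpt = Path(config["checkpoint"])
    if not ckpt.exists():
        raise FileNotFoundError(f"checkpoint not found: {ckpt}")
    stage1 = load_checkpoint(ckpt, name="stage1")
    stage2 = load_checkpoint(ckpt, name="stage2")
    out_dir = Path(config["out_dir"])
    out_dir.mkdir(parents=True, exist_ok=True)
    seqs = read_fasta(config["fasta"])
    mode = config.get("aggregate", "soft")
    out_path = out_dir / "predictions.tsv"
    n_folds = stage2.n_folds
    with out_path.open("w") as fh:
        headers = ["id", "top_fold", "n_windows"] \
            + [f"p_fold_{i}" for i in range(n_folds)]
        fh.write("\t".join(headers) + "\n")
        for seq in seqs:
            profile = read_pssm_ascii(Path(config["pssm_dir"]) / f"{seq.id}.pssm",
                                      seq_id=seq.id)
            pred = predict_fold(seq, profile, stage1, stage2, mode=mode)
            probs = "\t".join(f"{p:.6f}" for p in pred.fold_probs)
            fh.write(f"{seq.id}\t{pred.top_fold}\t"
                     f"{pred.fragment_vector.n_windows}\t{probs}\n")
    return out_path
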