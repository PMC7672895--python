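"""Desk-scale benchmark experiments on synthetic data.

These are the package's standard verification experiments: parameter
recovery for the stage-1 fragment classifier (with a label-shuffled negative
control) and end-to-end fold recovery through the full two-stage pipeline.
They run on one CPU in minutes by using reduced layer widths and a reduced
training profile (larger learning rate, smaller batches) appropriate to the
small synthetic datasets; the data-generating conditions themselves
(motif strength 0.9, 100 samples per fragment class) are fixed.
"""

from __future__ import annotations

import numpy as np
from sklearn.model_selection import train_test_split

from .neural.fold_cnn import train_fold_cnn
from .neural.fragment_predictor import train_fragment_predictor
from .neural.training import TrainConfig
from .pipeline import build_fragment_vector, featurize_fragments, segment_sequence
from .synthetic_data import (SyntheticFoldSpec, SyntheticLibrarySpec,
                             distinct_mixtures, make_fold_dataset,
                             make_fragment_library)

__all__ = ["REDUCED_STAGE1_ARCH", "reduced_train_config",
           "stage1_recovery", "fold_recovery"]

#: Reduced layer widths for desk-scale runs (full-scale defaults are in
#: :mod:`deepfragk.neural.fragment_predictor`).
REDUCED_STAGE1_ARCH = {
    "modality_dims": {"sequence": [77, 32], "physicochemical": [82, 32],
                      "evolutionary": [1600, 64]},
    "fusion_dim": 64,
    "head_dims": [64, 64],
}


def reduced_train_config(seed: int, **overrides) -> TrainConfig:
    """Training profile matched to thousand-sample synthetic datasets."""
    base = dict(learning_rate=1e-3, batch_size=100, dropout=0.2,
                max_epochs=120, patience=8, pretrain_epochs=3, seed=seed)
    base.update(overrides)
    return TrainConfig(**base)


def stage1_recovery(seed: int = 0, n_classes: int = 10,
                    samples_per_class: int = 100,
                    motif_strength: float = 0.9,
                    n_shuffles: int = 5) -> dict:
    """Train the fragment classifier on a well-separated synthetic library.

    Returns held-out accuracy, and the mean accuracy of the same protocol on
    ``n_shuffles`` independently label-shuffled copies of the dataset — a
    permutation control that should sit at the class prior.  Labels are
    shuffled *before* the train/test split so the held-out labels are
    independent of the features; shuffling only the training labels leaves a
    consistent ~1/k correctly-labelled subset a flexible model can exploit,
    biasing the control above chance.  The mean over shuffles is the stable
    statistic.
    """
    spec = SyntheticLibrarySpec(n_classes=n_classes,
                                samples_per_class=samples_per_class,
                                motif_strength=motif_strength, seed=seed)
    library = make_fragment_library(spec)
    X = featurize_fragments(library.records)
    y = np.array([rec.class_label for rec in library.records])
    arch = {**REDUCED_STAGE1_ARCH, "n_classes": n_classes}
    cfg = reduced_train_config(seed)
    X_tr, X_te, y_tr, y_te = train_test_split(
        X, y, test_size=0.2, stratify=y, random_state=seed)
    model, history = train_fragment_predictor(X_tr, y_tr, cfg, arch=arch)
    out = {
        "accuracy": float((model.predict(X_te) == y_te).mean()),
        "n_test": int(len(y_te)),
        "n_train": int(len(y_tr)),
        "epochs": len(history["train_loss"]),
        "model": model,
        "library": library,
    }
    if n_shuffles:
        rng = np.random.default_rng(seed + 1)
        accs = []
        for _ in range(n_shuffles):
            y_shuf = rng.permutation(y)
            Xs_tr, Xs_te, ys_tr, ys_te = train_test_split(
                X, y_shuf, test_size=0.2, stratify=y_shuf,
                random_state=int(rng.integers(0, 2**31 - 1)))
            shuf_model, _ = train_fragment_predictor(Xs_tr, ys_tr, cfg,
                                                     arch=arch)
            accs.append(float((shuf_model.predict(Xs_te) == ys_te).mean()))
        out["shuffled_accuracy"] = float(np.mean(accs))
        out["shuffled_accuracies"] = accs
    return out


def fold_recovery(seed: int = 0, n_fragment_classes: int = 32,
                  samples_per_class: int = 50, n_folds: int = 4,
                  seqs_per_fold: int = 40,
                  seq_length_range: tuple[int, int] = (40, 56)) -> dict:
    """End-to-end two-stage recovery of synthetic folds.

    Folds are defined by distinct fragment-class mixtures; the stage-2 CNN
    needs a fragment vector of at least 28 entries, hence the 32-class
    library.  Returns held-out fold accuracy and the trained models.
    """
    lib_spec = SyntheticLibrarySpec(n_classes=n_fragment_classes,
                                    samples_per_class=samples_per_class,
                                    seed=seed)
    library = make_fragment_library(lib_spec)
    X = featurize_fragments(library.records)
    y = np.array([rec.class_label for rec in library.records])
    cfg1 = reduced_train_config(seed)
    arch = {**REDUCED_STAGE1_ARCH, "n_classes": n_fragment_classes}
    stage1, _ = train_fragment_predictor(X, y, cfg1, arch=arch)

    fold_spec = SyntheticFoldSpec(
        n_folds=n_folds,
        fragment_mixtures=tuple(map(tuple, distinct_mixtures(
            n_folds, n_fragment_classes))),
        seqs_per_fold=seqs_per_fold, seq_length_range=seq_length_range,
        seed=seed + 1)
    dataset = make_fold_dataset(fold_spec, library)
    vectors = []
    labels = []
    for seq, profile, label in dataset:
        windows = segment_sequence(seq, profile)
        vectors.append(build_fragment_vector(windows, stage1).values)
        labels.append(label)
    vectors = np.asarray(vectors)
    labels = np.asarray(labels)
    V_tr, V_te, y_tr, y_te = train_test_split(
        vectors, labels, test_size=0.25, stratify=labels, random_state=seed)
    cfg2 = reduced_train_config(seed, batch_size=32, max_epochs=200, patience=15)
    stage2, history = train_fold_cnn(V_tr, y_tr, cfg2)
    return {
        "accuracy": float((stage2.predict(V_te) == y_te).mean()),
        "n_test": int(len(y_te)),
        "n_train": int(len(y_tr)),
        "epochs": len(history["train_loss"]),
        "stage1": stage1,
        "stage2": stage2,
        "library": library,
        "dataset": dataset,
    }
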