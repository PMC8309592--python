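"""Training and Monte-Carlo cross-validation of the epoch decoder.

The decoder reads min-max-normalized, proximity-reordered 1-s epochs
and predicts the VDEP class.  Validation follows the non-exhaustive
scheme: k independent stratified random 90/10 train/validation splits,
one freshly initialised model per split, with ROC-AUC, accuracy (0.5
threshold) and PR-AUC computed on each held-out 10%.  Splits are drawn
at the epoch level by default, so epochs of one participant can land on
both sides; ``group_by`` enables leakage-free subject- or video-wise
splitting.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import accuracy_score, average_precision_score, roc_auc_score
from sklearn.model_selection import GroupShuffleSplit, StratifiedShuffleSplit

from .config import ModelConfig
from .etp import EpochSet
from .layout import ChannelLayout, proximity_layout, spatial_reorder
from .nn import CNNClassifier

__all__ = ["CVResult", "evaluate", "train_once", "crossval", "decoder_inputs"]

#: class mapped to the positive (sigmoid = 1) decoder output
POSITIVE_CLASS = 2


class DecoderError(ValueError):
    """Raised on decoder-contract violations."""


@dataclass
class CVResult:
    """Per-fold and mean validation metrics for one design principle."""

    vdep: str
    folds: pd.DataFrame  # fold, auc, accuracy, pr_auc
    seed: int
    config: ModelConfig | None = None

    @property
    def means(self) -> dict[str, float]:
        return {m: float(self.folds[m].mean()) for m in ("auc", "accuracy", "pr_auc")}

    def to_frame(self) -> pd.DataFrame:
        mean_row = pd.DataFrame([{"fold": "mean", **self.means}])
        return pd.concat([self.folds, mean_row], ignore_index=True)


def evaluate(scores: np.ndarray, labels: np.ndarray) -> tuple[float, float, float]:
    """(ROC-AUC, accuracy at 0.5, PR-AUC) for binary labels."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise DecoderError("evaluation requires both classes in the labels")
    auc = float(roc_auc_score(labels, scores))
    acc = float(accuracy_score(labels, scores >= 0.5))
    pr = float(average_precision_score(labels, scores))
    return auc, acc, pr


def decoder_inputs(es: EpochSet, layout: ChannelLayout | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Reorder channels and shape an epoch set for the CNN.

    Returns (X, y): X is (n, fs, 32, 1) in [0, 1], y is 1 for the
    positive class and 0 otherwise.
    """
    if not es.normalized:
        raise DecoderError("decoder inputs must be normalized to [0, 1]")
    layout = layout if layout is not None else proximity_layout()
    es = spatial_reorder(es, layout)
    X = es.data[..., None].astype(np.float32)
    y = (es.labels == POSITIVE_CLASS).astype(np.int64)
    return X, y


def train_once(X_train: np.ndarray, y_train: np.ndarray,
               X_val: np.ndarray, y_val: np.ndarray,
               cfg: ModelConfig) -> tuple[CNNClassifier, dict[str, float]]:
    """Fit one fresh model and score the validation split."""
    for arr, name in ((X_train, "train"), (X_val, "val")):
        if arr.min() < 0 or arr.max() > 1:
            raise DecoderError(f"{name} inputs must lie in [0, 1] (normalize first)")
    if len(np.unique(y_train)) < 2:
        raise DecoderError("training labels contain a single class")
    model = CNNClassifier(cfg, input_shape=X_train.shape[1:3])
    model.fit(X_train, y_train, X_val, y_val)
    scores = model.predict_proba(X_val)
    auc, acc, pr = evaluate(scores, y_val)
    return model, {"auc": auc, "accuracy": acc, "pr_auc": pr}


def crossval(X: np.ndarray, y: np.ndarray, cfg: ModelConfig, k: int = 10,
             seed: int = 0, val_fraction: float = 0.1,
             groups: np.ndarray | None = None, vdep: str = "") -> CVResult:
    """Non-exhaustive k-fold Monte-Carlo cross-validation.

    Each of the k rounds draws an independent stratified random
    train/validation split (90/10 by default) and trains a fresh model;
    ``groups`` switches to group-wise splitting so that all epochs of a
    group stay on one side.
    """
    if k < 2:
        raise DecoderError("k must be >= 2")
    counts = np.bincount(y, minlength=2)
    if counts.min() < 10:
        raise DecoderError("need at least 10 epochs per class for 90/10 splitting")
    if groups is not None:
        splitter = GroupShuffleSplit(n_splits=k, test_size=val_fraction, random_state=seed)
        split_iter = splitter.split(X, y, groups)
    else:
        splitter = StratifiedShuffleSplit(n_splits=k, test_size=val_fraction, random_state=seed)
        split_iter = splitter.split(X, y)
    rows = []
    fold_seeds = np.random.SeedSequence(seed).generate_state(k) % (2**31)
    for fold, (tr, va) in enumerate(split_iter):
        fold_cfg = cfg.replace(seed=int(fold_seeds[fold]))
        _, metrics = train_once(X[tr], y[tr], X[va], y[va], fold_cfg)
        rows.append({"fold": fold, **metrics})
    return CVResult(vdep=vdep, folds=pd.DataFrame(rows), seed=seed, config=cfg)
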