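"""Extraction-transformation process: tagged seconds -> 1-s EEG epochs.

Steps, per class interval and participant: skip the 3-s pre-trial
baseline, drop the 8 peripheral channels, trim half a second from each
interval end, and cut the remainder into contiguous non-overlapping
1-s windows.  An interval of L whole seconds therefore yields
floor(L - 1) epochs per participant, each a (fs x 32) matrix.  Epoch
metadata records the video second in which the window starts.

Min-max normalization to [0, 1] (over the whole epoch matrix by
default) is applied only on the decoder path; band-power statistics
consume raw amplitudes.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotations import IntervalSet
from .synthetic import RecordingSet

__all__ = ["Epoch", "EpochSet", "map_second_to_samples", "extract_epochs",
           "normalize_epoch", "normalize_epochs"]

log = logging.getLogger(__name__)

META_COLUMNS = ["participant", "video", "second", "vdep", "cls"]


class EpochError(ValueError):
    """Raised on epoch-contract violations."""


@dataclass
class Epoch:
    """One second of one participant's EEG: (fs samples x 32 channels)."""

    data: np.ndarray
    participant: int
    video: int
    second: int
    vdep: str
    cls: int
    normalized: bool = False


@dataclass
class EpochSet:
    """Stacked epochs (n, fs, 32) with aligned metadata rows."""

    data: np.ndarray
    meta: pd.DataFrame
    fs: int
    vdep: str
    normalized: bool = False
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.data) != len(self.meta):
            raise EpochError("metadata rows must match epoch count")

    def __len__(self) -> int:
        return len(self.data)

    def select(self, mask: np.ndarray) -> "EpochSet":
        return EpochSet(self.data[mask], self.meta.loc[mask].reset_index(drop=True),
                        self.fs, self.vdep, self.normalized, dict(self.provenance))

    @property
    def labels(self) -> np.ndarray:
        return self.meta["cls"].to_numpy()


def map_second_to_samples(second: int, fs: int = 128, baseline_s: int = 3,
                          tagged_duration_s: int = 60) -> tuple[int, int]:
    """Half-open sample range of one tagged video second within a trial."""
    if not (0 <= second < tagged_duration_s):
        raise EpochError(f"second {second} outside [0, {tagged_duration_s})")
    start = (second + baseline_s) * fs
    return start, start + fs


def extract_epochs(rec: RecordingSet, iv: IntervalSet) -> EpochSet:
    """Cut 1-s epochs for every participant from every class interval.

    Epoch k of an interval [s0, s1) covers video time
    [s0 + 0.5 + k, s0 + 1.5 + k) and is attributed to second s0 + k.
    Intervals referencing trials missing from the recordings are
    skipped with a warning.
    """
    fs, n_eeg = rec.fs, 32
    half = fs // 2
    chunks: list[np.ndarray] = []
    meta_rows: list[tuple[int, int, int, str, int]] = []
    for r in iv.intervals.itertuples():
        if r.video >= rec.n_trials:
            log.warning("interval references trial %d absent from recordings; skipped", r.video)
            continue
        n_ep = max(r.end - r.start - 1, 0)  # floor(L - 1)
        for k in range(n_ep):
            second = r.start + k
            lo, _ = map_second_to_samples(second, fs, rec.baseline_s)
            lo += half
            seg = rec.data[:, r.video, :n_eeg, lo : lo + fs]  # (participants, 32, fs)
            chunks.append(np.swapaxes(seg, 1, 2))
            for p in range(rec.n_participants):
                meta_rows.append((p, r.video, second, iv.vdep, r.cls))
    if chunks:
        data = np.concatenate(chunks, axis=0).astype(np.float32, copy=False)
    else:
        data = np.empty((0, fs, n_eeg), dtype=np.float32)
    meta = pd.DataFrame(meta_rows, columns=META_COLUMNS)
    return EpochSet(data=data, meta=meta, fs=fs, vdep=iv.vdep)


def _minmax(x: np.ndarray, axis=None) -> np.ndarray:
    lo = x.min(axis=axis, keepdims=True)
    hi = x.max(axis=axis, keepdims=True)
    span = hi - lo
    degenerate = span == 0
    if np.any(degenerate):
        log.warning("degenerate (constant) epoch encountered; returning zeros")
    out = np.where(degenerate, 0.0, (x - lo) / np.where(degenerate, 1.0, span))
    return out


def normalize_epoch(e: Epoch, per_channel: bool = False) -> Epoch:
    """Min-max map an epoch to [0, 1]; constant epochs become zeros."""
    if e.normalized:
        raise EpochError("epoch already normalized")
    axis = 0 if per_channel else None
    return Epoch(_minmax(e.data, axis=axis), e.participant, e.video, e.second,
                 e.vdep, e.cls, normalized=True)


def normalize_epochs(es: EpochSet, per_channel: bool = False) -> EpochSet:
    """Vectorized min-max normalization of a whole epoch set."""
    if es.normalized:
        raise EpochError("epoch set already normalized")
    axis = (1,) if per_channel else (1, 2)
    out = _minmax(es.data.astype(np.float64), axis=axis).astype(np.float32)
    return EpochSet(out, es.meta.copy(), es.fs, es.vdep, normalized=True,
                    provenance=dict(es.provenance))
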