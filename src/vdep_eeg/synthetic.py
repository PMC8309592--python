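"""Synthetic DEAP-shaped recordings and two-expert annotations.

The generator produces (a) a latent per-second class timeline for each
of the four visual design elements/principles (VDEPs) of every tagged
video, (b) multi-participant EEG-like recordings in the 40-trial x
40-channel x 8064-sample layout whose per-band oscillation amplitudes
depend on the latent classes, and (c) two simulated expert annotators
with configurable accuracy and "unclear" rates.

The signal model for one EEG channel-second is

    x(t) = pink_noise(t) + sum_b  A_b * sin(2 pi f_b t + phi_b)

with ``A_b = base_amplitudes[b] * prod_v gain(class_v, b)`` over the
four VDEPs active that second and ``f_b`` the band's geometric-centre
frequency rounded to the nearest integer Hz (bin-aligned for 1-s
windows).  The oscillator phase is drawn once per (channel, trial,
band) and stays coherent across the trial, so every extracted epoch
contains pure in-band tones; the pink-noise background is generated in
independent half-second blocks aligned with the epoch grid, so no two
epochs share noise.  The 3-s pre-trial baseline and the untagged
filler trials carry the base amplitudes only (no class effect);
peripheral channels are white noise.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import BAND_NAMES, UNCLEAR, VDEPS, ConfigError, SimConfig

__all__ = [
    "VDEPTruth",
    "RecordingSet",
    "band_center_frequencies",
    "make_truth",
    "make_recordings",
    "make_expert_tags",
]

# geometric centre of the default band edges, rounded to the nearest
# DFT bin of a 1-s window at 128 Hz
_BAND_CENTER_HZ = {"delta": 2.0, "theta": 6.0, "alpha": 10.0, "beta": 20.0, "gamma": 37.0}


def band_center_frequencies() -> dict[str, float]:
    """Oscillator frequency used for each band (Hz)."""
    return dict(_BAND_CENTER_HZ)


@dataclass
class VDEPTruth:
    """Latent ground-truth class per (video, second, vdep).

    ``table`` has columns video, second, vdep, cls with cls in {1, 2};
    seconds are 0-based indices into the tagged portion of each video.
    """

    table: pd.DataFrame
    n_videos: int
    duration_s: int

    def class_array(self) -> np.ndarray:
        """(n_vdeps, n_videos, duration_s) integer class array."""
        arr = np.empty((len(VDEPS), self.n_videos, self.duration_s), dtype=np.int8)
        piv = self.table.pivot_table(index=["vdep", "video"], columns="second", values="cls")
        for vi, vdep in enumerate(VDEPS):
            arr[vi] = piv.loc[vdep].to_numpy()
        return arr


@dataclass
class RecordingSet:
    """Per-participant trial x channel x sample arrays plus metadata."""

    data: np.ndarray  # (n_participants, n_trials, n_channels_total, n_samples)
    fs: int
    channel_names: list[str]
    baseline_s: int
    n_tagged: int  # first n_tagged trials correspond to annotated videos

    def __post_init__(self) -> None:
        if self.data.ndim != 4:
            raise ValueError("recording data must be 4-D")

    @property
    def n_participants(self) -> int:
        return self.data.shape[0]

    @property
    def n_trials(self) -> int:
        return self.data.shape[1]


def _rng(cfg: SimConfig, stream: int) -> np.random.Generator:
    # independent deterministic substreams per generator product
    return np.random.default_rng(np.random.SeedSequence(cfg.seed, spawn_key=(stream,)))


def make_truth(cfg: SimConfig) -> VDEPTruth:
    """Draw latent per-second classes with geometric run lengths.

    Classes alternate between consecutive runs so that every run is
    maximal; run lengths are Geometric(1/mean_run_s) on {1, 2, ...},
    giving contiguous same-class intervals with the configured mean.
    """
    rng = _rng(cfg, 0)
    dur = cfg.tagged_duration_s
    p = 1.0 / cfg.mean_run_s
    rows: list[tuple[int, int, str, int]] = []
    for video in range(cfg.n_videos):
        for vdep in VDEPS:
            cls = int(rng.integers(1, 3))
            second = 0
            while second < dur:
                run = int(rng.geometric(p))
                for s in range(second, min(second + run, dur)):
                    rows.append((video, s, vdep, cls))
                second += run
                cls = 3 - cls
    table = pd.DataFrame(rows, columns=["video", "second", "vdep", "cls"])
    return VDEPTruth(table=table, n_videos=cfg.n_videos, duration_s=dur)


def _pink_noise(rng: np.random.Generator, shape: tuple[int, ...], n: int,
                fs: int, exponent: float, std: float) -> np.ndarray:
    """Independent 1/f^exponent noise segments of ``n`` samples each.

    ``shape`` indexes segments; the returned array has shape
    ``shape + (n,)`` and per-sample variance ``std**2``.  Segments are
    mutually independent.
    """
    nf = n // 2 + 1
    f = np.arange(nf, dtype=float) * fs / n  # physical frequency per bin
    spec = np.zeros(nf)
    spec[1:] = f[1:] ** (-exponent / 2.0)
    # scale so the synthesized samples have the requested variance
    var_unit = (2.0 * np.sum(spec[1:-1] ** 2) + spec[-1] ** 2) / n**2
    scale = std / math.sqrt(var_unit) if var_unit > 0 else 0.0
    re = rng.standard_normal(shape + (nf,))
    im = rng.standard_normal(shape + (nf,))
    coef = (re + 1j * im) / math.sqrt(2.0)
    coef[..., 0] = 0.0
    coef[..., -1] = re[..., -1]  # Nyquist bin is real
    coef *= scale * spec
    return np.fft.irfft(coef, n=n, axis=-1)


def _gain_table(cfg: SimConfig, truth: VDEPTruth) -> np.ndarray:
    """(n_videos, duration_s, n_bands) product of class gains over VDEPs."""
    cls_arr = truth.class_array()  # (V, videos, seconds)
    gains = np.ones((cfg.n_videos, truth.duration_s, len(BAND_NAMES)))
    for vi, vdep in enumerate(VDEPS):
        if vdep not in cfg.gain_vdeps:
            continue
        for bi, band in enumerate(BAND_NAMES):
            g1, g2 = cfg.gain(1, band), cfg.gain(2, band)
            gains[..., bi] *= np.where(cls_arr[vi] == 1, g1, g2)
    return gains


def make_recordings(cfg: SimConfig, truth: VDEPTruth) -> RecordingSet:
    """Synthesize the full recording set for all participants.

    Tagged trials get class-dependent oscillation amplitudes from
    ``truth``; filler trials and the pre-trial baseline get base
    amplitudes; peripheral channels get white noise.
    """
    if truth.n_videos != cfg.n_videos or truth.duration_s != cfg.tagged_duration_s:
        raise ConfigError("truth does not match the simulation geometry")
    from .layout import DEAP_CHANNELS  # cyclic-import safe: module constant

    rng = _rng(cfg, 1)
    n_p, n_t = cfg.n_participants, cfg.n_trials
    n_eeg, n_ch = cfg.n_channels_eeg, cfg.n_channels_total
    fs, dur = cfg.fs, cfg.trial_duration_s
    data = np.empty((n_p, n_t, n_ch, dur * fs), dtype=np.float32)

    freqs = np.array([_BAND_CENTER_HZ[b] for b in BAND_NAMES])
    base = np.array([float(cfg.base_amplitudes.get(b, 1.0)) for b in BAND_NAMES])
    gains = _gain_table(cfg, truth)  # (videos, tagged seconds, bands)
    # amplitude per (trial, second-of-trial, band): baseline + tagged seconds
    amp = np.tile(base, (n_t, dur, 1))
    amp[: cfg.n_videos, cfg.baseline_s :, :] = gains * base

    # oscillator phase is coherent across a trial (one draw per channel and
    # band); the integer-Hz tones then contain a whole number of cycles in
    # any 1-s window, so extracted epochs see pure in-band tones with the
    # per-second amplitude dictated by the latent classes
    # noise comes in independent half-second blocks aligned with the
    # half-second epoch grid, so no two extracted epochs share noise
    half = fs // 2
    t_full = np.arange(dur * fs) / fs
    for p in range(n_p):
        for trial in range(n_t):
            noise = _pink_noise(rng, (n_eeg, dur * 2), half, fs,
                                cfg.noise_exponent, cfg.noise_std)
            phases = rng.uniform(0, 2 * np.pi, size=(n_eeg, len(BAND_NAMES)))
            tones = np.sin(2 * np.pi * freqs[None, :, None] * t_full + phases[..., None])
            amp_t = np.repeat(amp[trial], fs, axis=0).T  # (bands, dur*fs)
            seg = noise.reshape(n_eeg, dur * fs) + (tones * amp_t[None]).sum(axis=1)
            data[p, trial, :n_eeg] = seg
            data[p, trial, n_eeg:] = rng.standard_normal((n_ch - n_eeg, dur * fs)) * cfg.noise_std
    names = list(DEAP_CHANNELS) + [f"peripheral{i}" for i in range(1, n_ch - n_eeg + 1)]
    return RecordingSet(data=data, fs=fs, channel_names=names,
                        baseline_s=cfg.baseline_s, n_tagged=cfg.n_videos)


def expected_keep_probability(cfg: SimConfig) -> float:
    """Closed-form probability that a tagged second survives resolution.

    Each expert independently reports "unclear" with probability u,
    otherwise the true class with probability a and the wrong class
    with probability 1-a.  A second is kept iff both experts report the
    same non-unclear label, hence P(keep) = (1-u)^2 (a^2 + (1-a)^2).
    """
    u, a = cfg.annot_unclear, cfg.annot_agreement
    return (1 - u) ** 2 * (a**2 + (1 - a) ** 2)


def make_expert_tags(cfg: SimConfig, truth: VDEPTruth) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate the two annotators over the latent truth.

    Returns two tag tables with columns video, second, vdep, label where
    label is 1, 2 or UNCLEAR (0).
    """
    out = []
    for expert, stream in ((1, 2), (2, 3)):
        rng = _rng(cfg, stream)
        base = truth.table.copy()
        n = len(base)
        u = rng.random(n) < cfg.annot_unclear
        correct = rng.random(n) < cfg.annot_agreement
        label = np.where(correct, base["cls"], 3 - base["cls"])
        label = np.where(u, UNCLEAR, label)
        base["label"] = label.astype(np.int64)
        out.append(base.drop(columns="cls"))
    return out[0], out[1]
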