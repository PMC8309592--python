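"""Configuration objects shared across the pipeline.

All tunables live here: simulation conditions, EEG frequency-band
definitions, decoder hyper-parameters and the pipeline-level bundle.
Every object validates itself on construction and raises
:class:`ConfigError` on inconsistent settings.
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

VDEPS = ("colour", "balance", "movement", "light")

#: human-readable class names per visual design element/principle
CLASS_NAMES: dict[str, tuple[str, str]] = {
    "colour": ("cold", "warm"),
    "balance": ("asymmetrical", "symmetrical"),
    "movement": ("fast", "slow"),
    "light": ("bright", "dark"),
}

BAND_NAMES = ("delta", "theta", "alpha", "beta", "gamma")

#: integer label used for an "unclear" expert tag in in-memory tables
UNCLEAR = 0


class ConfigError(ValueError):
    """Raised when a configuration object is internally inconsistent."""


@dataclass(frozen=True)
class BandDefinition:
    """Half-open frequency band [lo, hi) in Hz."""

    name: str
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not (0 < self.lo < self.hi):
            raise ConfigError(f"band {self.name}: need 0 < lo < hi, got [{self.lo}, {self.hi})")


def default_bands() -> list[BandDefinition]:
    """Conventional band edges, truncated at 45 Hz (the upstream low-pass)."""
    return [
        BandDefinition("delta", 1.0, 4.0),
        BandDefinition("theta", 4.0, 8.0),
        BandDefinition("alpha", 8.0, 13.0),
        BandDefinition("beta", 13.0, 30.0),
        BandDefinition("gamma", 30.0, 45.0),
    ]


def _default_band_gains() -> dict[int, dict[str, float]]:
    # modest alpha-amplitude contrast between the two classes of every
    # design principle; the null (no effect) is gains == 1 everywhere
    return {1: {"alpha": 1.5}, 2: {}}


def _default_base_amplitudes() -> dict[str, float]:
    return {b: 1.0 for b in BAND_NAMES}


@dataclass
class SimConfig:
    """Conditions for the synthetic DEAP-shaped study.

    Defaults mirror the source dataset geometry: 32 participants, 40
    one-minute trials of which 26 are tagged videos, 63 s per trial at
    128 Hz (3-s pre-trial baseline), 40 channels of which the first 32
    are EEG.
    """

    n_participants: int = 32
    n_videos: int = 26
    n_trials: int = 40
    trial_duration_s: int = 63
    baseline_s: int = 3
    fs: int = 128
    n_channels_eeg: int = 32
    n_channels_total: int = 40
    mean_run_s: float = 5.0
    band_gains: Mapping[int, Mapping[str, float]] = field(default_factory=_default_band_gains)
    gain_vdeps: Sequence[str] = VDEPS
    base_amplitudes: Mapping[str, float] = field(default_factory=_default_base_amplitudes)
    noise_std: float = 1.0
    noise_exponent: float = 1.0
    annot_agreement: float = 0.9
    annot_unclear: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_videos > self.n_trials:
            raise ConfigError("n_videos cannot exceed n_trials")
        if self.trial_duration_s <= self.baseline_s:
            raise ConfigError("trial_duration_s must exceed baseline_s")
        if self.mean_run_s < 1.0:
            raise ConfigError("mean_run_s must be >= 1 second")
        for p, name in ((self.annot_agreement, "annot_agreement"), (self.annot_unclear, "annot_unclear")):
            if not (0.0 <= p <= 1.0):
                raise ConfigError(f"{name} must lie in [0, 1], got {p}")
        if set(self.band_gains) - {1, 2}:
            raise ConfigError(f"band_gains class keys must be 1/2, got {sorted(self.band_gains)}")
        for cls, gains in self.band_gains.items():
            for band, g in gains.items():
                if band not in BAND_NAMES:
                    raise ConfigError(f"band_gains[{cls}] references unknown band {band!r}")
                if g < 0:
                    raise ConfigError(f"band_gains[{cls}][{band}] must be >= 0")
        if set(self.gain_vdeps) - set(VDEPS):
            raise ConfigError(f"gain_vdeps must be a subset of {VDEPS}")
        for band in self.base_amplitudes:
            if band not in BAND_NAMES:
                raise ConfigError(f"base_amplitudes references unknown band {band!r}")
        if self.noise_std < 0:
            raise ConfigError("noise_std must be >= 0")

    @property
    def n_samples(self) -> int:
        return self.trial_duration_s * self.fs

    @property
    def tagged_duration_s(self) -> int:
        """Seconds of video that carry annotations (baseline excluded)."""
        return self.trial_duration_s - self.baseline_s

    def gain(self, cls: int, band: str) -> float:
        return float(self.band_gains.get(cls, {}).get(band, 1.0))


@dataclass
class ModelConfig:
    """Hyper-parameters of the convolutional decoder.

    The architecture is a small image-style CNN: ``conv_filters`` 3x3
    convolution blocks (ReLU + 2x2 max-pool each), one dense hidden
    layer, one sigmoid output unit; binary cross-entropy loss, Adam.
    """

    conv_filters: Sequence[int] = (16, 32)
    kernel_size: int = 3
    dense_units: int = 64
    learning_rate: float = 1e-3
    batch_size: int = 64
    max_epochs: int = 30
    patience: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.conv_filters) < 1:
            raise ConfigError("need at least one convolution block")
        if self.kernel_size % 2 != 1:
            raise ConfigError("kernel_size must be odd (same-padding)")
        if self.max_epochs < 1 or self.patience < 0:
            raise ConfigError("max_epochs >= 1 and patience >= 0 required")

    def replace(self, **kw) -> "ModelConfig":
        d = asdict(self)
        d.update(kw)
        return ModelConfig(**d)
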