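"""FFT band filtering and per-epoch mean band power.

Band filtering zeroes every DFT coefficient whose frequency lies
outside [lo, hi) (DC and Nyquist are always zeroed) and inverts the
transform.  The mean band power of an epoch is the time-average of the
squared band-filtered signal, averaged over the 32 EEG channels; by
Parseval's identity this equals ``2/N^2 * sum_{k in band} |X_k|^2``,
which is how the vectorized table builder computes it.

An optional rectified-amplitude variant (mean absolute value of the
filtered signal) is provided for sensitivity analyses.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .config import BAND_NAMES, BandDefinition, ConfigError, default_bands
from .etp import EpochSet

__all__ = ["band_filter", "band_mask", "mean_band_power", "band_power_table",
           "export_band_table", "read_band_table"]


class SpectralError(ValueError):
    """Raised on spectral-contract violations."""


def band_mask(n: int, fs: float, band: BandDefinition) -> np.ndarray:
    """Boolean rfft-bin mask: lo <= f < hi, DC and Nyquist excluded."""
    if band.hi > fs / 2:
        raise ConfigError(f"band {band.name} [{band.lo}, {band.hi}) exceeds Nyquist {fs / 2}")
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    mask = (freqs >= band.lo) & (freqs < band.hi)
    mask[0] = False
    if n % 2 == 0:
        mask[-1] = False
    return mask


def band_filter(signal: np.ndarray, band: BandDefinition, fs: float) -> np.ndarray:
    """Keep only the band's DFT coefficients and invert the transform.

    Works along the last axis; the output is real.
    """
    n = signal.shape[-1]
    coef = np.fft.rfft(signal, axis=-1)
    coef[..., ~band_mask(n, fs, band)] = 0.0
    return np.fft.irfft(coef, n=n, axis=-1)


def _band_powers_from_fft(coef: np.ndarray, n: int, fs: float,
                          bands: list[BandDefinition]) -> np.ndarray:
    """Per-band mean power along the transformed axis (Parseval)."""
    # coef: (..., n_bins); returns (..., n_bands)
    p = (np.abs(coef) ** 2).real
    out = np.empty(coef.shape[:-1] + (len(bands),))
    for bi, band in enumerate(bands):
        m = band_mask(n, fs, band)
        out[..., bi] = 2.0 * p[..., m].sum(axis=-1) / n**2
    return out


def mean_band_power(data: np.ndarray, fs: float,
                    bands: list[BandDefinition] | None = None,
                    rectified: bool = False) -> dict[str, float]:
    """Mean band power of one (time x channel) epoch matrix.

    Per band: mean over time of the squared band-filtered samples, then
    the unweighted mean over channels.  ``rectified=True`` substitutes
    the mean absolute filtered amplitude for the squared mean.
    """
    bands = bands if bands is not None else default_bands()
    x = np.asarray(data, dtype=np.float64)
    if x.ndim != 2:
        raise SpectralError("epoch data must be 2-D (time x channel)")
    n = x.shape[0]
    if rectified:
        vals = [float(np.abs(band_filter(x.T, b, fs)).mean()) for b in bands]
    else:
        coef = np.fft.rfft(x, axis=0)
        vals = _band_powers_from_fft(coef.T, n, fs, bands).mean(axis=0)
        vals = [float(v) for v in vals]
    return dict(zip([b.name for b in bands], vals))


def band_power_table(es: EpochSet, bands: list[BandDefinition] | None = None,
                     rectified: bool = False) -> pd.DataFrame:
    """Flat per-epoch table: metadata + one power column per band.

    The statistics path requires raw amplitudes, so normalized epoch
    sets are rejected.
    """
    if es.normalized:
        raise SpectralError("band power must be computed on un-normalized epochs")
    bands = bands if bands is not None else default_bands()
    x = es.data.astype(np.float64)  # (n, time, ch)
    if rectified:
        powers = np.stack(
            [np.abs(band_filter(np.swapaxes(x, 1, 2), b, es.fs)).mean(axis=(1, 2)) for b in bands],
            axis=1,
        )
    else:
        coef = np.fft.rfft(x, axis=1)  # (n, bins, ch)
        per_ch = _band_powers_from_fft(np.swapaxes(coef, 1, 2), x.shape[1], es.fs, bands)
        powers = per_ch.mean(axis=1)  # average over channels
    table = es.meta.copy()
    for bi, b in enumerate(bands):
        table[b.name] = powers[:, bi]
    return table


def export_band_table(table: pd.DataFrame, path) -> None:
    """Write the band-power spreadsheet (CSV, one row per epoch)."""
    if table.empty:
        raise SpectralError("refusing to export an empty band table")
    if table["vdep"].nunique() != 1:
        raise SpectralError("band table must contain a single vdep")
    missing = [b for b in BAND_NAMES if b not in table.columns]
    if missing:
        raise SpectralError(f"band table missing columns {missing}")
    table.to_csv(path, index=False)


def read_band_table(path) -> pd.DataFrame:
    return pd.read_csv(path)
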