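"""Scalp-proximity channel re-ordering for the decoder input.

The 32 EEG channels of the source dataset are stored hemisphere-by-
hemisphere, so physically adjacent electrodes can sit far apart in the
matrix.  The default layout re-orders the columns along a short path
over the scalp (greedy nearest-neighbour walk with 2-opt refinement on
the montage coordinates), which places scalp neighbours in
neighbouring matrix columns — the property 2-D convolutions exploit.
A serpentine row-scan alternative is provided, and the montage
coordinates (Biosemi-32, the cap used for the recordings) support
auditing the adjacency of any ordering.
"""
from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .etp import EpochSet

__all__ = ["DEAP_CHANNELS", "ChannelLayout", "proximity_layout", "serpentine_layout",
           "identity_layout", "spatial_reorder", "mean_adjacent_distance"]

#: EEG channel order of the source recordings (Geneva convention)
DEAP_CHANNELS = [
    "Fp1", "AF3", "F3", "F7", "FC5", "FC1", "C3", "T7",
    "CP5", "CP1", "P3", "P7", "PO3", "O1", "Oz", "Pz",
    "Fp2", "AF4", "Fz", "F4", "F8", "FC6", "FC2", "Cz",
    "C4", "T8", "CP6", "CP2", "P4", "P8", "PO4", "O2",
]

# anterior -> posterior electrode rows of the 32-channel 10-20 cap,
# each listed left -> right
_ROWS = [
    ["Fp1", "Fp2"],
    ["AF3", "AF4"],
    ["F7", "F3", "Fz", "F4", "F8"],
    ["FC5", "FC1", "FC2", "FC6"],
    ["T7", "C3", "Cz", "C4", "T8"],
    ["CP5", "CP1", "CP2", "CP6"],
    ["P7", "P3", "Pz", "P4", "P8"],
    ["PO3", "PO4"],
    ["O1", "Oz", "O2"],
]


class LayoutError(ValueError):
    """Raised on invalid channel layouts."""


@dataclass(frozen=True)
class ChannelLayout:
    """Column permutation: new column j reads source column perm[j]."""

    permutation: tuple[int, ...]
    names: tuple[str, ...]

    def __post_init__(self) -> None:
        if sorted(self.permutation) != list(range(32)):
            raise LayoutError("permutation must be a bijection on the 32 EEG channels")

    def inverse(self) -> "ChannelLayout":
        inv = tuple(int(i) for i in np.argsort(self.permutation))
        return ChannelLayout(inv, tuple(self.names[i] for i in inv))


def _layout_from_names(names: list[str]) -> ChannelLayout:
    perm = tuple(DEAP_CHANNELS.index(n) for n in names)
    return ChannelLayout(permutation=perm, names=tuple(names))


def identity_layout() -> ChannelLayout:
    return ChannelLayout(tuple(range(32)), tuple(DEAP_CHANNELS))


def serpentine_layout() -> ChannelLayout:
    """Alternating-direction row scan of the electrode grid."""
    names: list[str] = []
    for i, row in enumerate(_ROWS):
        names.extend(row if i % 2 == 0 else row[::-1])
    return _layout_from_names(names)


@lru_cache(maxsize=1)
def proximity_layout() -> ChannelLayout:
    """Default decoder ordering: a short scalp path through all channels.

    Greedy nearest-neighbour walk over the montage coordinates starting
    at Fp1, refined by 2-opt until no reversal shortens the path.
    Deterministic, and substantially shorter (mean adjacent distance)
    than the storage order of the source dataset.
    """
    coords = montage_coords()
    names = list(DEAP_CHANNELS)
    pts = np.stack([coords[n] for n in names])
    n = len(names)
    # greedy walk
    order = [names.index("Fp1")]
    left = set(range(n)) - set(order)
    while left:
        cur = pts[order[-1]]
        nxt = min(left, key=lambda i: float(np.linalg.norm(pts[i] - cur)))
        order.append(nxt)
        left.remove(nxt)
    # 2-opt refinement of the open path
    def seg(i, j):
        return float(np.linalg.norm(pts[i] - pts[j]))

    improved = True
    while improved:
        improved = False
        for i in range(n - 2):
            for j in range(i + 2, n):
                a, b = order[i], order[i + 1]
                c = order[j]
                d = order[j + 1] if j + 1 < n else None
                old = seg(a, b) + (seg(c, d) if d is not None else 0.0)
                new = seg(a, c) + (seg(b, d) if d is not None else 0.0)
                if new < old - 1e-12:
                    order[i + 1 : j + 1] = order[i + 1 : j + 1][::-1]
                    improved = True
    return _layout_from_names([names[i] for i in order])


@lru_cache(maxsize=1)
def montage_coords() -> dict[str, np.ndarray]:
    """2-D scalp-plane coordinates (metres) per channel name."""
    import mne

    montage = mne.channels.make_standard_montage("biosemi32")
    pos = montage.get_positions()["ch_pos"]
    return {name: np.asarray(pos[name][:2]) for name in DEAP_CHANNELS}


def mean_adjacent_distance(layout: ChannelLayout) -> float:
    """Mean scalp distance between consecutive matrix columns."""
    coords = montage_coords()
    pts = np.stack([coords[n] for n in layout.names])
    return float(np.linalg.norm(np.diff(pts, axis=0), axis=1).mean())


def spatial_reorder(es: EpochSet, layout: ChannelLayout) -> EpochSet:
    """Permute the channel columns of every epoch; metadata unchanged."""
    if es.data.shape[-1] != 32:
        raise LayoutError(f"expected 32 channels, got {es.data.shape[-1]}")
    perm = np.asarray(layout.permutation)
    return EpochSet(es.data[..., perm], es.meta.copy(), es.fs, es.vdep,
                    es.normalized, dict(es.provenance))
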