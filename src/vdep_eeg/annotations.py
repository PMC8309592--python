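"""Two-expert tag resolution, class intervals, counts and balancing.

An expert tag table has one row per (video, second, vdep, expert) with
``label`` in {1, 2, UNCLEAR}.  Resolution keeps a second only when both
experts gave the same non-unclear label; every discarded second is kept
on the side with its reason ("unclear" when either expert was unsure,
"disagreement" otherwise).  Class intervals are maximal runs of
consecutive same-class seconds within one video; discarded seconds
break runs.  Balancing sub-samples the larger class down to n_v, the
size of the smaller class, uniformly without replacement.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import UNCLEAR, VDEPS

__all__ = [
    "ResolvedTimeline",
    "IntervalSet",
    "resolve_tags",
    "build_intervals",
    "count_classes",
    "balance_seconds",
]

KEY = ["video", "second", "vdep"]


class AnnotationError(ValueError):
    """Raised on malformed or mismatched annotation inputs."""


@dataclass
class ResolvedTimeline:
    """Consensus per-second classes plus the discarded remainder."""

    records: pd.DataFrame  # video, second, vdep, cls
    discarded: pd.DataFrame  # video, second, vdep, reason

    @property
    def n_total(self) -> int:
        return len(self.records) + len(self.discarded)

    def for_vdep(self, vdep: str) -> pd.DataFrame:
        return self.records[self.records["vdep"] == vdep]


@dataclass
class IntervalSet:
    """Maximal same-class second runs for one design principle."""

    vdep: str
    intervals: pd.DataFrame  # video, start, end (half-open seconds), cls

    def explode_seconds(self) -> pd.DataFrame:
        """Inverse of interval building: one row per covered second."""
        rows = [
            (r.video, s, self.vdep, r.cls)
            for r in self.intervals.itertuples()
            for s in range(r.start, r.end)
        ]
        return pd.DataFrame(rows, columns=["video", "second", "vdep", "cls"])


def resolve_tags(a: pd.DataFrame, b: pd.DataFrame) -> ResolvedTimeline:
    """Merge the two experts' tags into a consensus timeline."""
    merged = a.merge(b, on=KEY, how="outer", suffixes=("_a", "_b"), indicator=True)
    if (merged["_merge"] != "both").any():
        bad = merged.loc[merged["_merge"] != "both", KEY].head()
        raise AnnotationError(f"experts cover different (video, second, vdep) keys, e.g.\n{bad}")
    la, lb = merged["label_a"].to_numpy(), merged["label_b"].to_numpy()
    unclear = (la == UNCLEAR) | (lb == UNCLEAR)
    keep = ~unclear & (la == lb)
    records = merged.loc[keep, KEY].copy()
    records["cls"] = la[keep].astype(np.int64)
    discarded = merged.loc[~keep, KEY].copy()
    discarded["reason"] = np.where(unclear[~keep], "unclear", "disagreement")
    return ResolvedTimeline(records.reset_index(drop=True), discarded.reset_index(drop=True))


def build_intervals(t: ResolvedTimeline, vdep: str) -> IntervalSet:
    """Run-length encode the resolved seconds of one design principle."""
    if vdep not in VDEPS:
        raise AnnotationError(f"unknown vdep {vdep!r}")
    sub = t.for_vdep(vdep).sort_values(["video", "second"])
    rows: list[tuple[int, int, int, int]] = []
    for video, grp in sub.groupby("video", sort=True):
        secs = grp["second"].to_numpy()
        clss = grp["cls"].to_numpy()
        if len(secs) == 0:
            continue
        start = 0
        for i in range(1, len(secs) + 1):
            boundary = i == len(secs) or secs[i] != secs[i - 1] + 1 or clss[i] != clss[i - 1]
            if boundary:
                rows.append((int(video), int(secs[start]), int(secs[i - 1]) + 1, int(clss[start])))
                start = i
    df = pd.DataFrame(rows, columns=["video", "start", "end", "cls"])
    return IntervalSet(vdep=vdep, intervals=df)


def count_classes(t: ResolvedTimeline) -> pd.DataFrame:
    """Per-vdep second counts: the Table-1-style summary.

    Columns: vdep, n_class1, n_class2, n_unclear, n_disagreement,
    n_discarded, n_v.  Conservation: n_class1 + n_class2 + n_discarded
    equals the number of tagged seconds for that vdep.
    """
    rows = []
    for vdep in VDEPS:
        kept = t.for_vdep(vdep)
        disc = t.discarded[t.discarded["vdep"] == vdep]
        n1 = int((kept["cls"] == 1).sum())
        n2 = int((kept["cls"] == 2).sum())
        nu = int((disc["reason"] == "unclear").sum())
        nd = int((disc["reason"] == "disagreement").sum())
        rows.append((vdep, n1, n2, nu, nd, nu + nd, min(n1, n2)))
    return pd.DataFrame(
        rows,
        columns=["vdep", "n_class1", "n_class2", "n_unclear", "n_disagreement", "n_discarded", "n_v"],
    )


def balance_seconds(t: ResolvedTimeline, vdep: str, seed: int) -> ResolvedTimeline:
    """Sub-sample the larger class of one vdep down to n_v seconds.

    Returns a timeline containing only the selected seconds of ``vdep``
    (the discard side is passed through unchanged).
    """
    sub = t.for_vdep(vdep)
    by_cls = {c: sub[sub["cls"] == c] for c in (1, 2)}
    for c, grp in by_cls.items():
        if len(grp) == 0:
            raise AnnotationError(f"cannot balance {vdep!r}: class {c} has no seconds")
    n_v = min(len(by_cls[1]), len(by_cls[2]))
    rng = np.random.default_rng(seed)
    parts = []
    for c in (1, 2):
        grp = by_cls[c]
        if len(grp) > n_v:
            idx = rng.choice(len(grp), size=n_v, replace=False)
            grp = grp.iloc[np.sort(idx)]
        parts.append(grp)
    kept = pd.concat(parts).sort_values(["video", "second"]).reset_index(drop=True)
    disc = t.discarded[t.discarded["vdep"] == vdep].reset_index(drop=True)
    return ResolvedTimeline(records=kept, discarded=disc)
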