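"""On-disk formats: NPY recordings + JSON sidecar, annotation CSVs,
epoch containers and summary tables.

Recordings are stored one ``sXX.npy`` per participant (trials x
channels x samples) with a ``recordings.json`` sidecar holding the
sampling rate, channel names, baseline length and tagged-trial count.
Annotations are plain CSV with columns video_id, second, vdep,
expert_id, label where label is "1", "2" or "unclear".
"""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .config import UNCLEAR
from .etp import EpochSet
from .synthetic import RecordingSet

__all__ = [
    "write_recordings", "read_recordings",
    "write_tags", "read_tags",
    "write_epochs", "read_epochs",
]


def write_recordings(rec: RecordingSet, out_dir: str | Path) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for p in range(rec.n_participants):
        np.save(out / f"s{p + 1:02d}.npy", rec.data[p])
    sidecar = {
        "fs": rec.fs,
        "channel_names": rec.channel_names,
        "baseline_s": rec.baseline_s,
        "n_tagged": rec.n_tagged,
        "n_participants": rec.n_participants,
        "shape_per_participant": list(rec.data.shape[1:]),
    }
    (out / "recordings.json").write_text(json.dumps(sidecar, indent=2))
    return out


def read_recordings(in_dir: str | Path) -> RecordingSet:
    src = Path(in_dir)
    meta = json.loads((src / "recordings.json").read_text())
    arrays = [np.load(src / f"s{p + 1:02d}.npy") for p in range(meta["n_participants"])]
    return RecordingSet(
        data=np.stack(arrays),
        fs=meta["fs"],
        channel_names=meta["channel_names"],
        baseline_s=meta["baseline_s"],
        n_tagged=meta["n_tagged"],
    )


def write_tags(tags_by_expert: dict[int, pd.DataFrame], path: str | Path) -> Path:
    """Write the two experts' tags in the annotation CSV schema."""
    frames = []
    for expert_id, df in tags_by_expert.items():
        out = df.rename(columns={"video": "video_id"}).copy()
        out["expert_id"] = expert_id
        out["label"] = out["label"].map(lambda v: "unclear" if v == UNCLEAR else str(int(v)))
        frames.append(out[["video_id", "second", "vdep", "expert_id", "label"]])
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
    return Path(path)


def read_tags(path: str | Path) -> dict[int, pd.DataFrame]:
    raw = pd.read_csv(path, dtype={"label": str})
    raw["label"] = raw["label"].map(lambda v: UNCLEAR if v == "unclear" else int(v))
    out = {}
    for expert_id, grp in raw.groupby("expert_id"):
        df = grp.rename(columns={"video_id": "video"})
        out[int(expert_id)] = df[["video", "second", "vdep", "label"]].reset_index(drop=True)
    return out


def write_epochs(es: EpochSet, out_dir: str | Path) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    np.save(out / "epochs.npy", es.data)
    meta = es.meta.copy()
    meta.insert(0, "epoch_id", np.arange(len(meta)))
    meta.to_csv(out / "epochs_meta.csv", index=False)
    (out / "epochs.json").write_text(json.dumps({
        "fs": es.fs, "vdep": es.vdep, "normalized": es.normalized,
        "provenance": es.provenance,
    }, indent=2))
    return out


def read_epochs(in_dir: str | Path) -> EpochSet:
    src = Path(in_dir)
    info = json.loads((src / "epochs.json").read_text())
    meta = pd.read_csv(src / "epochs_meta.csv").drop(columns=["epoch_id"])
    return EpochSet(
        data=np.load(src / "epochs.npy"),
        meta=meta,
        fs=info["fs"],
        vdep=info["vdep"],
        normalized=info["normalized"],
        provenance=info.get("provenance", {}),
    )
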