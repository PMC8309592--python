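"""End-to-end orchestration: simulate -> resolve -> extract -> bands ->
statistics -> decoder, once per requested design principle.

Every stage derives its own seed from the global one, persists its
artifacts under the output directory, and the final report carries the
configuration hash so any artifact can be traced to the exact settings
that produced it.  A failing design principle is logged and skipped;
the others still run.
"""
from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .annotations import ResolvedTimeline, balance_seconds, build_intervals, count_classes, resolve_tags
from .config import BandDefinition, ConfigError, ModelConfig, SimConfig, VDEPS, default_bands
from .decoder import CVResult, crossval, decoder_inputs
from .etp import extract_epochs, normalize_epochs
from .io import write_epochs, write_recordings, write_tags
from .spectral import band_power_table, export_band_table
from .stats import StatsReport, compare_vdep_bands, violin_data
from .synthetic import make_expert_tags, make_recordings, make_truth

log = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "RunReport", "run_pipeline", "balance_epoch_set"]


@dataclass
class PipelineConfig:
    sim: SimConfig = field(default_factory=SimConfig)
    bands: list[BandDefinition] = field(default_factory=default_bands)
    alpha: float = 0.05
    holm: bool = False
    model: ModelConfig = field(default_factory=ModelConfig)
    k: int = 10
    vdeps: list[str] = field(default_factory=lambda: list(VDEPS))
    balance_stage: str = "epochs"  # or "tags"
    group_split: str | None = None  # None | "participant" | "video"
    seed: int = 0
    out_dir: str = "vdep_run"

    def __post_init__(self) -> None:
        if not self.vdeps:
            raise ConfigError("vdep list must not be empty")
        unknown = set(self.vdeps) - set(VDEPS)
        if unknown:
            raise ConfigError(f"unknown vdeps {sorted(unknown)}")
        if self.balance_stage not in ("epochs", "tags"):
            raise ConfigError("balance_stage must be 'epochs' or 'tags'")
        if self.group_split not in (None, "participant", "video"):
            raise ConfigError("group_split must be None, 'participant' or 'video'")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        kw = dict(raw)
        if "sim" in kw:
            sim = dict(kw["sim"])
            if "band_gains" in sim:
                sim["band_gains"] = {int(c): dict(g) for c, g in sim["band_gains"].items()}
            kw["sim"] = SimConfig(**sim)
        if "model" in kw:
            kw["model"] = ModelConfig(**kw["model"])
        if "bands" in kw:
            kw["bands"] = [BandDefinition(**b) for b in kw["bands"]]
        return cls(**kw)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["sim"]["band_gains"] = {int(c): dict(g) for c, g in self.sim.band_gains.items()}
        d["sim"]["gain_vdeps"] = list(self.sim.gain_vdeps)  # YAML-safe
        d["model"]["conv_filters"] = list(self.model.conv_filters)
        return d

    def config_hash(self) -> str:
        """Hash of the scientific settings (output paths excluded)."""
        d = self.to_dict()
        d.pop("out_dir")
        blob = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class RunReport:
    config_hash: str
    version: str
    counts: pd.DataFrame
    stats: dict[str, StatsReport]
    cv: dict[str, CVResult]
    failures: dict[str, str]
    timings_s: dict[str, float]

    def to_dict(self) -> dict:
        return {
            "config_hash": self.config_hash,
            "version": self.version,
            "counts": self.counts.to_dict(orient="records"),
            "stats": {v: r.table.to_dict(orient="records") for v, r in self.stats.items()},
            "cv": {v: r.to_frame().to_dict(orient="records") for v, r in self.cv.items()},
            "failures": self.failures,
            "timings_s": {k: round(t, 3) for k, t in self.timings_s.items()},
        }

    def report_hash(self) -> str:
        """Hash of the scientific content (wall-clock timings excluded)."""
        d = self.to_dict()
        d.pop("timings_s")
        blob = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()

    def to_markdown(self) -> str:
        lines = [f"# Pipeline report (config {self.config_hash}, v{self.version})", ""]
        lines += ["## Second counts per design principle", self.counts.to_markdown(index=False), ""]
        for vdep, rep in self.stats.items():
            lines += [f"## {vdep}: band statistics", rep.table.to_markdown(index=False), ""]
        for vdep, cv in self.cv.items():
            lines += [f"## {vdep}: decoder cross-validation", cv.to_frame().to_markdown(index=False), ""]
        if self.failures:
            lines += ["## Failures"] + [f"- {v}: {msg}" for v, msg in self.failures.items()]
        return "\n".join(lines)


def balance_epoch_set(es, timeline: ResolvedTimeline, vdep: str, seed: int):
    """Balance classes over epoch-yielding seconds, then filter epochs.

    Seconds that survived trimming are balanced to n_v per class; the
    epoch set is restricted to the selected seconds, so the final epoch
    counts are exactly balanced (n_participants x n_v per class).
    """
    yielding = es.meta[["video", "second", "cls"]].drop_duplicates()
    yielding = yielding.assign(vdep=vdep)[["video", "second", "vdep", "cls"]]
    tl = ResolvedTimeline(records=yielding.reset_index(drop=True),
                          discarded=timeline.discarded[timeline.discarded["vdep"] == vdep])
    balanced = balance_seconds(tl, vdep, seed)
    key = pd.MultiIndex.from_frame(balanced.records[["video", "second"]])
    mask = pd.MultiIndex.from_frame(es.meta[["video", "second"]]).isin(key)
    return es.select(np.asarray(mask))


def run_pipeline(cfg: PipelineConfig) -> RunReport:
    """Execute every stage for every requested design principle."""
    t0 = time.perf_counter()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = np.random.SeedSequence(cfg.seed).generate_state(8) % (2**31)
    sim = SimConfig(**{**asdict(cfg.sim), "seed": int(seeds[0]),
                       "band_gains": {int(c): dict(g) for c, g in cfg.sim.band_gains.items()}})
    timings: dict[str, float] = {}

    truth = make_truth(sim)
    rec = make_recordings(sim, truth)
    tags_a, tags_b = make_expert_tags(sim, truth)
    write_recordings(rec, out / "recordings")
    write_tags({1: tags_a, 2: tags_b}, out / "annotations.csv")
    timings["simulate"] = time.perf_counter() - t0

    timeline = resolve_tags(tags_a, tags_b)
    counts = count_classes(timeline)
    counts.to_csv(out / "class_counts.csv", index=False)

    stats_reports: dict[str, StatsReport] = {}
    cv_results: dict[str, CVResult] = {}
    failures: dict[str, str] = {}
    for i, vdep in enumerate(cfg.vdeps):
        tv = time.perf_counter()
        try:
            vdir = out / vdep
            vdir.mkdir(exist_ok=True)
            seed_v = int(seeds[1] + i)
            tl = timeline
            if cfg.balance_stage == "tags":
                tl = balance_seconds(timeline, vdep, seed_v)
            intervals = build_intervals(tl, vdep)
            es = extract_epochs(rec, intervals)
            if cfg.balance_stage == "epochs":
                es = balance_epoch_set(es, timeline, vdep, seed_v)
            es.provenance.update(config_hash=cfg.config_hash(), seed=cfg.seed)
            write_epochs(es, vdir / "epochs")

            table = band_power_table(es, cfg.bands)
            export_band_table(table, vdir / "band_power.csv")
            violin_data(table, [b.name for b in cfg.bands]).to_csv(vdir / "violin.csv", index=False)
            rep = compare_vdep_bands(table, vdep, alpha=cfg.alpha, holm=cfg.holm,
                                     bands=[b.name for b in cfg.bands])
            rep.to_csv(vdir / "stats.csv")
            stats_reports[vdep] = rep

            X, y = decoder_inputs(normalize_epochs(es))
            groups = (es.meta[cfg.group_split].to_numpy() if cfg.group_split else None)
            cv = crossval(X, y, cfg.model, k=cfg.k, seed=int(seeds[2] + i),
                          groups=groups, vdep=vdep)
            cv.to_frame().to_csv(vdir / "cv_metrics.csv", index=False)
            cv_results[vdep] = cv
        except Exception as exc:  # noqa: BLE001 - stage isolation is the contract
            log.exception("pipeline failed for %s", vdep)
            failures[vdep] = f"{type(exc).__name__}: {exc}"
        timings[vdep] = time.perf_counter() - tv

    report = RunReport(config_hash=cfg.config_hash(), version=__version__,
                       counts=counts, stats=stats_reports, cv=cv_results,
                       failures=failures, timings_s=timings)
    (out / "report.json").write_text(json.dumps(report.to_dict(), indent=2, default=str))
    (out / "report.md").write_text(report.to_markdown())
    return report
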