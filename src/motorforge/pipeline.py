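"""Pipeline orchestration: run the analysis stages from a single config.

The config is a TOML file with per-stage tables.  Stages run in dependency
order; a failure inside one stage is recorded as a warning and does not
corrupt the outputs of the others.  All randomness flows through one seed
recorded in the report, so a run is reproducible bit for bit.
"""

from __future__ import annotations

import dataclasses
import json
import tomllib
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any, Optional

import numpy as np

from . import __version__
from . import io as mfio
from .force_stats import StallSummary, summarize_stalls
from .force_velocity import FVParams, force_velocity_curve
from .motility import MotilityParams, summarize_motility
from .stall_analysis import StallCriteria, detect_stalls, downsample
from .synthetic_data import (MotorTrapParams, mutant_motor_params,
                             simulate_trap_trace, wt_motor_params)


class PipelineConfigError(ValueError):
    pass


class PipelineDataError(RuntimeError):
    pass


PRESETS = {
    "wt": (wt_motor_params, StallCriteria.wt_preset),
    "mutant": (mutant_motor_params, StallCriteria.mutant_preset),
}


@dataclass
class PipelineConfig:
    output_dir: Path
    seed: int = 0
    constructs: dict[str, dict[str, Any]] = field(default_factory=dict)
    n_traces: int = 50
    fv: dict[str, Any] = field(default_factory=dict)
    tracks_file: Optional[Path] = None
    stages: tuple[str, ...] = ("simulate", "stalls", "compare")

    def __post_init__(self) -> None:
        if not self.constructs:
            self.constructs = {"wt": {"preset": "wt"},
                               "mutant": {"preset": "mutant"}}

    @classmethod
    def from_toml(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        if not path.exists():
            raise PipelineConfigError(f"config file not found: {path}")
        with path.open("rb") as fh:
            raw = tomllib.load(fh)
        try:
            out = Path(raw["output_dir"])
        except KeyError as exc:
            raise PipelineConfigError("config missing output_dir") from exc
        cfg = cls(output_dir=out,
                  seed=int(raw.get("seed", 0)),
                  constructs=raw.get("constructs", {}),
                  n_traces=int(raw.get("n_traces", 50)),
                  fv=raw.get("fv", {}),
                  stages=tuple(raw.get("stages",
                                       ("simulate", "stalls", "compare"))))
        if "tracks_file" in raw:
            cfg.tracks_file = Path(raw["tracks_file"])
            if not cfg.tracks_file.exists():
                raise PipelineConfigError(
                    f"tracks file not found: {cfg.tracks_file}")
        for label, spec in cfg.constructs.items():
            preset = spec.get("preset", label)
            if preset not in PRESETS:
                raise PipelineConfigError(f"unknown preset {preset!r} for "
                                          f"construct {label!r}")
        return cfg


@dataclass
class ConstructComparison:
    reduction: float
    reduction_sem: float
    stall_time_ratio: float


def compare_constructs(summary_a: StallSummary, summary_b: StallSummary
                       ) -> ConstructComparison:
    """Fractional stall-force reduction (A - B) / A with propagated SEM."""
    ma, mb = summary_a.mean_stall_force, summary_b.mean_stall_force
    if ma == 0:
        raise PipelineDataError("zero mean stall force in reference summary")
    reduction = (ma - mb) / ma
    # first-order propagation of the two SEMs through (ma - mb)/ma
    sem = float(np.hypot(summary_b.sem / ma,
                         summary_a.sem * mb / ma ** 2))
    ratio = (summary_b.mean_stall_time / summary_a.mean_stall_time
             if summary_a.mean_stall_time > 0 else float("nan"))
    return ConstructComparison(reduction=float(reduction), reduction_sem=sem,
                               stall_time_ratio=float(ratio))


@dataclass
class RunReport:
    version: str
    seed: int
    config: dict[str, Any]
    stall_summaries: dict[str, dict[str, Any]] = field(default_factory=dict)
    comparison: Optional[dict[str, Any]] = None
    fv_curves: dict[str, dict[str, Any]] = field(default_factory=dict)
    motility: list[dict[str, Any]] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunReport":
        return cls(**json.loads(text))


def _simulate_construct(label: str, spec: dict[str, Any], n_traces: int,
                        seed: int):
    preset = spec.get("preset", label)
    param_fn, _ = PRESETS[preset]
    overrides = {k: v for k, v in spec.items() if k != "preset"}
    # derive per-trace seeds from the run seed; keep below 2**31
    label_tag = zlib.crc32(label.encode()) % 9973
    base = (seed * 100003 + label_tag) % (2 ** 31 - 100000)
    return [simulate_trap_trace(param_fn(seed=base + i, **overrides))
            for i in range(n_traces)]


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute the configured stages and write outputs under output_dir."""
    out = config.output_dir
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport(version=__version__, seed=config.seed,
                       config={"n_traces": config.n_traces,
                               "stages": list(config.stages),
                               "constructs": config.constructs})

    traces: dict[str, list] = {}
    if "simulate" in config.stages:
        for label, spec in config.constructs.items():
            traces[label] = _simulate_construct(label, spec, config.n_traces,
                                                config.seed)
            tdir = out / f"traces_{label}"
            tdir.mkdir(exist_ok=True)
            for i, tr in enumerate(traces[label]):
                mfio.write_trace(tdir / f"trace_{i:04d}.txt", tr)

    summaries: dict[str, StallSummary] = {}
    if "stalls" in config.stages:
        for label, spec in config.constructs.items():
            try:
                _, crit_fn = PRESETS[spec.get("preset", label)]
                criteria = crit_fn()
                events = []
                for tr in traces.get(label, []):
                    low = downsample(tr, criteria.analysis_rate)
                    events.extend(detect_stalls(low, criteria))
                summary = summarize_stalls(events, construct=label)
                summaries[label] = summary
                report.stall_summaries[label] = asdict(summary)
            except Exception as exc:  # isolate stage failures
                report.warnings.append(f"stalls[{label}]: {exc}")

    if "compare" in config.stages and len(summaries) >= 2:
        labels = list(summaries)
        cmp = compare_constructs(summaries[labels[0]], summaries[labels[1]])
        report.comparison = {"a": labels[0], "b": labels[1], **asdict(cmp)}

    if "fv" in config.stages:
        for label in config.constructs:
            try:
                params = FVParams(**config.fv)
                curve = force_velocity_curve(traces.get(label, []), params)
                report.fv_curves[label] = {
                    "bin_centers": curve.bin_centers.tolist(),
                    "mean_velocity": curve.mean_velocity.tolist(),
                    "sem": curve.sem.tolist(),
                    "n_events": curve.n_events.tolist()}
            except Exception as exc:
                report.warnings.append(f"fv[{label}]: {exc}")

    if "motility" in config.stages and config.tracks_file is not None:
        try:
            tracks = mfio.read_tracks(config.tracks_file)
            for s in summarize_motility(tracks, MotilityParams()):
                report.motility.append(asdict(s))
        except Exception as exc:
            report.warnings.append(f"motility: {exc}")

    (out / "report.json").write_text(report.to_json())
    return report
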