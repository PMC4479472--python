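"""End-to-end run orchestration with on-disk artifacts.

A run takes either real input files (accel/depth/events CSVs per animal)
or a simulation config, executes segment -> detect -> match -> metrics ->
optimize through :class:`apcdetect.model.CaptureValidation`, and writes
every intermediate table plus a summary into a run directory.  Outputs are
deterministic given the seeds; every CSV carries the config hash in a
header comment so runs can be tied to their configuration.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .detector import DetectorParams, detect
from .dives import DiveParams, dives_to_frame
from .matching import match_dive, records_to_frame
from .model import CaptureValidation, Deployment
from .optimize import generic_params, grid_results_to_frame, split_summary
from .synthetic import SimConfig, generate_deployment, write_deployment

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage (and dive)."""


@dataclass(frozen=True)
class RunConfig:
    """One validation run: real inputs XOR a simulated cohort."""

    output_dir: str
    inputs: tuple[dict, ...] = ()  # dicts: animal_id, accel, depth, events (paths)
    sim: SimConfig | None = None
    n_animals: int = 4
    axes: tuple[str, ...] = ("surge",)
    split_seed: int = 0
    tie_window: float = 2.0
    dive_params: DiveParams = field(default_factory=DiveParams)
    detector: DetectorParams = field(default_factory=DetectorParams)

    def __post_init__(self) -> None:
        if bool(self.inputs) == (self.sim is not None):
            raise ValueError("provide exactly one of input files or a simulation config")

    def hash(self) -> str:
        def default(o):
            if dataclasses.is_dataclass(o):
                return dataclasses.asdict(o)
            raise TypeError(type(o).__name__)

        fields = dataclasses.asdict(self)
        fields.pop("output_dir")  # hash identifies the analysis, not where it lands
        payload = json.dumps(fields, sort_keys=True, default=default)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _write_csv(frame: pd.DataFrame, path: Path, config_hash: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# config_hash: {config_hash}\n")
        frame.to_csv(fh, index=False)


def run_pipeline(config: RunConfig) -> Path:
    """Execute a full run; returns the run directory."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config.hash()
    logger.info("run %s -> %s", chash, out)

    def stage(name, fn, *args, dive_id=None, **kw):
        try:
            return fn(*args, **kw)
        except Exception as exc:
            where = f"stage '{name}'" + (f", dive {dive_id}" if dive_id is not None else "")
            raise PipelineError(f"{where}: {exc}") from exc

    deployments: list[Deployment] = []
    if config.sim is not None:
        for k in range(config.n_animals):
            cfg = SimConfig(**{**config.sim.__dict__, "seed": config.sim.seed * 1000 + k})
            accel, depth, truth = stage("simulate", generate_deployment, cfg)
            ddir = out / f"A{k + 1}"
            stage("simulate-write", write_deployment, accel, depth, truth, ddir)
            deployments.append(stage("load", Deployment.from_files, f"A{k + 1}", ddir / "accel.csv", ddir / "depth.csv", ddir / "events.csv"))
    else:
        for spec in config.inputs:
            deployments.append(
                stage("load", Deployment.from_files, spec["animal_id"], spec["accel"], spec["depth"], spec["events"])
            )

    model = stage(
        "segment",
        CaptureValidation,
        deployments,
        axes=config.axes,
        dive_params=config.dive_params,
        detector=config.detector,
    )
    for dep in deployments:
        _write_csv(dives_to_frame(dep.dives).assign(animal=dep.animal_id), out / f"dives_{dep.animal_id}.csv", chash)

    results = stage("optimize", model.fit, seed=config.split_seed, tie_window=config.tie_window)

    # per-animal detections and match records under the generic parameters
    rec_frames, det_frames = [], []
    for dep in deployments:
        for ax in config.axes:
            params = generic_params(ax, config.detector)
            detections = stage("detect", detect, dep.accel, dep.depth_hi, dep.dives, params,
                               config.dive_params.surface_exclusion_depth)
            det_frames.append(
                pd.DataFrame(
                    [
                        {
                            "animal": dep.animal_id,
                            "axis": d.axis,
                            "dive_id": d.dive_id,
                            "t_first_peak_s": d.t_first_peak,
                            "duration_s": d.duration,
                            "n_peaks": d.n_peaks,
                            "integral_area": d.integral_area,
                        }
                        for d in detections
                    ]
                )
            )
            by_dive: dict[int, list] = {}
            for d in detections:
                by_dive.setdefault(d.dive_id, []).append(d)
            for dive in dep.dives:
                records, _ = stage(
                    "match",
                    match_dive,
                    by_dive.get(dive.dive_id, []),
                    dep.events_per_dive.get(dive.dive_id, []),
                    dive.dive_id,
                    dive_id=dive.dive_id,
                )
                frame = records_to_frame(records)
                frame.insert(0, "axis", ax)
                frame.insert(0, "animal", dep.animal_id)
                rec_frames.append(frame)

    _write_csv(pd.concat(det_frames, ignore_index=True), out / "detections_generic.csv", chash)
    _write_csv(pd.concat(rec_frames, ignore_index=True), out / "match_records_generic.csv", chash)
    _write_csv(grid_results_to_frame(results.grid_results), out / "grid_results.csv", chash)
    _write_csv(results.summary_frame(), out / "summary.csv", chash)
    if len(results.foraging["table"]):
        _write_csv(results.foraging["table"], out / "foraging_dives.csv", chash)

    chosen = {
        ax: {
            a: {"variance_threshold": p.variance_threshold, "min_interval_s": p.min_interval}
            for a, p in results.animal_params[ax].items()
        }
        for ax in config.axes
    }
    manifest = {
        "config_hash": chash,
        "split_seed": config.split_seed,
        "axes": list(config.axes),
        "splits": {a: split_summary(s) for a, s in results.splits.items()},
        "animal_specific_params": chosen,
        "foraging": {k: v for k, v in results.foraging.items() if k != "table"},
    }
    (out / "run_manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    (out / "summary.txt").write_text(results.summary() + "\n")
    return out
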