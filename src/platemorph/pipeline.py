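"""Pipeline orchestration: segment -> measure -> (spreading | migrate) -> validate.

A run is described by a YAML config (see :class:`RunConfig`).  Every
output directory receives a ``run.log`` echoing the full configuration,
its SHA-256 hash and the seed, plus per-stage platelet counts and
exclusion reasons, so a rerun with an identical config reproduces all
deterministic outputs bit-for-bit.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import dynamics, io, migration, morphometry, segmentation, stats
from .types import ParameterError, ShapeRecord

log = logging.getLogger(__name__)

_VALID_STAGES = ("segment", "measure", "spreading", "migrate", "validate")


@dataclass
class RunConfig:
    """Validated description of one pipeline run."""

    input_path: str
    output_dir: str
    stages: list[str]
    pixel_size: float | None = None
    frame_interval: float | None = None
    seed: int = 0
    model_path: str | None = None
    truth_path: str | None = None
    min_area: float = 0.0
    gate_px: float = migration.GATE_PX
    filo_min_length: float = morphometry.FILO_MIN_LENGTH_UM
    filo_min_tip_curvature: float = morphometry.FILO_MIN_TIP_CURVATURE_UM
    idle_threshold: float = dynamics.IDLE_THRESHOLD
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(_VALID_STAGES)
        if unknown:
            raise ParameterError(f"unknown stages: {sorted(unknown)}")
        if not self.stages:
            raise ParameterError("no stages selected")
        if "spreading" in self.stages and "migrate" in self.stages:
            raise ParameterError("select either spreading or migrate, not both")
        if ("spreading" in self.stages or "migrate" in self.stages) \
                and self.frame_interval is None:
            raise ParameterError(
                "frame_interval is required for spreading/migration runs"
            )
        if self.frame_interval is not None and self.frame_interval <= 0:
            raise ParameterError("frame_interval must be positive")
        if self.pixel_size is not None and self.pixel_size <= 0:
            raise ParameterError("pixel_size must be positive")
        if "segment" in self.stages and self.model_path is None:
            raise ParameterError("segment stage requires model_path")
        if "validate" in self.stages and self.truth_path is None:
            raise ParameterError("validate stage requires truth_path")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if not isinstance(raw, dict):
            raise ParameterError(f"{path} does not contain a mapping")
        known = {f for f in cls.__dataclass_fields__ if f != "extra"}
        kwargs = {k: v for k, v in raw.items() if k in known}
        kwargs["extra"] = {k: v for k, v in raw.items() if k not in known}
        return cls(**kwargs)

    def config_hash(self) -> str:
        canonical = json.dumps(self.__dict__, sort_keys=True, default=str)
        return hashlib.sha256(canonical.encode()).hexdigest()[:16]


def run_pipeline(cfg: RunConfig) -> dict[str, Path]:
    """Execute the selected stages in order; returns output paths."""
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines = [
        f"config_hash: {cfg.config_hash()}",
        f"seed: {cfg.seed}",
        "config: " + json.dumps(cfg.__dict__, sort_keys=True, default=str),
    ]
    outputs: dict[str, Path] = {}

    try:
        masks = None
        if "segment" in cfg.stages:
            images = io.read_image_stack(cfg.input_path, pixel_size=cfg.pixel_size)
            model = segmentation.TrainedModel.load(cfg.model_path)
            masks = [segmentation.predict(model, img) for img in images]
            mask_path = out / "masks.tif"
            io.write_mask_stack(mask_path, masks)
            outputs["masks"] = mask_path
            log_lines.append(f"segment: {len(masks)} frames")
        else:
            masks = io.read_mask_stack(cfg.input_path, pixel_size=cfg.pixel_size)
            log_lines.append(f"input: {len(masks)} mask frames")

        records = []
        if "measure" in cfg.stages or "spreading" in cfg.stages:
            for f, mask in enumerate(masks):
                recs = morphometry.measure_mask(
                    mask, frame_index=f, min_area=cfg.min_area,
                    filo_min_length=cfg.filo_min_length,
                    filo_min_tip_curvature=cfg.filo_min_tip_curvature,
                )
                records.extend(recs)
            shape_path = out / "shapes.csv"
            io.write_records_csv(shape_path, records)
            outputs["shapes"] = shape_path
            log_lines.append(f"measure: {len(records)} platelet-frames")

        if "spreading" in cfg.stages:
            rows = []
            frame = io.records_to_frame(records)
            for pid, sub in frame.groupby("platelet_id"):
                recs = [
                    ShapeRecord(
                        platelet_id=int(r.platelet_id),
                        frame_index=int(r.frame_index),
                        centroid=(r.x_um, r.y_um), area=r.area_um2,
                        perimeter=r.perimeter_um, circularity=r.circularity,
                        aspect_ratio=r.aspect_ratio,
                        n_filopodia=int(r.n_filopodia),
                    )
                    for r in sub.itertuples()
                ]
                trace = dynamics.SpreadingTrace(int(pid), cfg.frame_interval, recs)
                m = dynamics.spreading_metrics(trace, threshold=cfg.idle_threshold)
                rows.append({
                    "platelet_id": m.platelet_id,
                    "adhesion_frame": m.adhesion_frame,
                    "idle_time_s": m.idle_time_s,
                    "rate_um2_per_min": m.rate_um2_per_min,
                    "status": m.status.value,
                })
            spread_path = out / "spreading.csv"
            pd.DataFrame(rows).to_csv(spread_path, index=False)
            outputs["spreading"] = spread_path
            log_lines.append(f"spreading: {len(rows)} platelets")

        if "migrate" in cfg.stages:
            tracks = migration.link_tracks(masks, gate=cfg.gate_px,
                                           frame_interval=cfg.frame_interval)
            track_rows, metric_rows = [], []
            for tr in tracks:
                for f, (x, y) in enumerate(tr.positions):
                    track_rows.append({"platelet_id": tr.platelet_id, "frame": f,
                                       "x_um": x, "y_um": y,
                                       "complete": tr.complete})
                if tr.complete:
                    metric_rows.append({
                        "platelet_id": tr.platelet_id,
                        "velocity_um_min": migration.migration_velocity(tr),
                        "straightness": migration.straightness(tr),
                        "mean_cos_theta": migration.directional_change(
                            tr, cfg.frame_interval),
                    })
            tracks_path = out / "tracks.csv"
            metrics_path = out / "migration.csv"
            pd.DataFrame(track_rows).to_csv(tracks_path, index=False)
            pd.DataFrame(metric_rows).to_csv(metrics_path, index=False)
            outputs["tracks"] = tracks_path
            outputs["migration"] = metrics_path
            n_excl = sum(1 for t in tracks if not t.complete)
            log_lines.append(
                f"migrate: {len(tracks)} tracks, {n_excl} incomplete (excluded)"
            )

        if "validate" in cfg.stages:
            truth = io.read_mask_stack(cfg.truth_path, pixel_size=cfg.pixel_size)
            if len(truth) != len(masks):
                raise ParameterError("truth and prediction frame counts differ")
            tp = fp = fn = 0
            for p, t in zip(masks, truth):
                conf = stats.pixel_confusion(p, t)
                tp, fp, fn = tp + conf.tp, fp + conf.fp, fn + conf.fn
            conf = stats.PixelConfusion(tp, fp, fn)
            report = {
                "config_hash": cfg.config_hash(),
                "seed": cfg.seed,
                "pixel_confusion": {
                    "tp": conf.tp, "fp": conf.fp, "fn": conf.fn,
                    "fractions": conf.fractions, "iou": conf.iou,
                },
            }
            val_path = out / "validation.json"
            io.write_json(val_path, report)
            outputs["validation"] = val_path
            log_lines.append(f"validate: iou={conf.iou:.4f}")
    except Exception as exc:
        log_lines.append(f"FAILED: {exc}")
        (out / "run.log").write_text("\n".join(log_lines) + "\n")
        raise

    (out / "run.log").write_text("\n".join(log_lines) + "\n")
    outputs["log"] = out / "run.log"
    return outputs
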