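"""One-call orchestration of the full plate analysis and the simulator.

``run_analysis`` executes load -> background subtraction -> temporal sum
projection -> smoothing -> blob detection -> ROIs -> per-colony radius
series, logistic growth fit, intensity trace and expression rate (and
optional strain classification), writing ``colonies.csv``,
``timeseries.csv`` and ``classifications.csv`` to the output directory.
Every step is reachable through the underlying module functions with
identical results; these entry points only wire them together and
persist tables. The analysis path contains no randomness, so reruns with
an identical config produce byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from colonylapse import classify, detect, expression, growth, simulate, stack

logger = logging.getLogger(__name__)

__all__ = [
    "AnalysisConfig",
    "run_analysis",
    "run_simulate",
    "fit_signatures_from_plates",
]


@dataclass(frozen=True)
class AnalysisConfig:
    """All parameters of one analysis run, serializable as JSON."""

    input_dir: str
    out_dir: str
    pattern: str = "*.png"
    frame_interval_h: float | None = None
    timestamps_file: str | None = None
    background_method: str = "first_frame_median"
    sigma_smooth: float = 2.0
    min_sigma: float = 3.0
    max_sigma: float = 30.0
    n_scales: int = 10
    threshold: float | None = None
    threshold_rel: float = 0.05
    roi_scale: float = 3.0
    radius_threshold: float = 4.0
    smoothing_factor: float | None = None
    classification_reference: str = "endpoint"
    signatures_file: str | None = None

    def __post_init__(self) -> None:
        if not 0 < self.min_sigma < self.max_sigma:
            raise ValueError("require 0 < min_sigma < max_sigma")
        if self.n_scales < 2:
            raise ValueError("n_scales must be >= 2")
        if self.roi_scale <= 0 or self.sigma_smooth < 0 or self.threshold_rel < 0:
            raise ValueError("roi_scale, sigma_smooth and threshold_rel must be valid")
        if self.classification_reference not in ("endpoint", "time_sum"):
            raise ValueError("classification_reference must be 'endpoint' or 'time_sum'")

    @classmethod
    def from_json(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = json.load(fh)
        unknown = set(raw) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2)


def _analyze_stack(
    lapse: stack.Timelapse, config: AnalysisConfig
) -> tuple[list, list, list, list]:
    """Shared detection + per-colony analysis; returns (blobs, rois, fits,
    per-colony records)."""
    corrected = stack.subtract_background(lapse, method=config.background_method)
    projection = detect.temporal_sum_projection(corrected)
    smoothed = detect.smooth_projection(projection, config.sigma_smooth)
    blobs = detect.detect_colonies(
        smoothed,
        min_sigma=config.min_sigma,
        max_sigma=config.max_sigma,
        n_scales=config.n_scales,
        threshold=config.threshold,
        threshold_rel=config.threshold_rel,
    )
    rois = detect.make_rois(blobs, config.roi_scale, corrected.image_shape)

    records = []
    for blob, roi in zip(blobs, rois):
        trace = growth.radius_series(
            corrected, roi, threshold=config.radius_threshold
        )
        fit = growth.fit_growth_model(trace)
        itrace = expression.intensity_series(corrected, roi, fit, blob.center_rc)
        strace = expression.smooth_trace(itrace, config.smoothing_factor)
        ok = np.isfinite(itrace.mean_F)
        kf = np.full(corrected.n_frames, np.nan)
        inside = ok & (corrected.times >= strace.t_range[0]) & (
            corrected.times <= strace.t_range[1]
        )
        if inside.any():
            kf[inside] = expression.expression_rate(
                strace, fit, corrected.times[inside]
            ).KF
        records.append((blob, roi, trace, fit, itrace, kf, corrected))
    return blobs, rois, [r[3] for r in records], records


def run_analysis(config: AnalysisConfig) -> dict[str, Path]:
    """Run the full pipeline and write the CSV bundle; returns output paths."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    logger.info("analysis config: %s", dataclasses.asdict(config))

    lapse = stack.load_timelapse(
        config.input_dir,
        pattern=config.pattern,
        frame_interval_h=config.frame_interval_h,
        timestamps_file=config.timestamps_file,
    )
    blobs, rois, fits, records = _analyze_stack(lapse, config)

    colonies = pd.DataFrame(
        {
            "colony_id": [b.id for b in blobs],
            "row": [b.center_rc[0] for b in blobs],
            "col": [b.center_rc[1] for b in blobs],
            "sigma": [b.sigma for b in blobs],
            "response": [b.response for b in blobs],
            "half_width": [r.half_width for r in rois],
            "Amax": [f.Amax for f in fits],
            "mu_max": [f.mu_max for f in fits],
            "t0": [f.t0 for f in fits],
            "residual_rms": [f.residual_rms for f in fits],
            "n_points_used": [f.n_points_used for f in fits],
        }
    )

    rows = []
    for blob, roi, trace, fit, itrace, kf, corrected in records:
        mu = growth.growth_rate_curve(fit, corrected.times)
        area_fit = np.asarray(fit.area(corrected.times))
        for i, t in enumerate(corrected.times):
            rows.append(
                {
                    "colony_id": blob.id,
                    "time_h": t,
                    "radius_px": trace.radius_px[i],
                    "area_px2": trace.area_px2[i],
                    "area_fit_px2": area_fit[i],
                    "mu_h": mu[i],
                    "mean_F": itrace.mean_F[i],
                    "KF": kf[i],
                }
            )
    timeseries = pd.DataFrame(rows)

    paths = {
        "colonies": out_dir / "colonies.csv",
        "timeseries": out_dir / "timeseries.csv",
    }
    colonies.to_csv(paths["colonies"], index=False)
    timeseries.to_csv(paths["timeseries"], index=False)

    if config.signatures_file is not None:
        signatures = classify.load_signatures(config.signatures_file)
        corrected = records[0][6] if records else None
        totals = [
            classify.channel_totals(
                rec[6], rec[1], rec[3], rec[0].center_rc,
                reference=config.classification_reference,
            )
            for rec in records
        ]
        results = classify.classify_colonies(totals, signatures)
        classifications = pd.DataFrame(
            {
                "colony_id": [r.colony_id for r in results],
                "label": [r.assigned_label for r in results],
                "angular_distance_rad": [r.angular_distance for r in results],
                "runner_up_margin_rad": [r.runner_up_margin for r in results],
            }
        )
        paths["classifications"] = out_dir / "classifications.csv"
        classifications.to_csv(paths["classifications"], index=False)

    config.to_json(out_dir / "config.json")
    logger.info("analysis complete: %d colonies -> %s", len(blobs), out_dir)
    return paths


def run_simulate(spec_file: str | Path, out: str | Path) -> Path:
    """Render a plate described by a PlateSpec JSON file to *out*."""
    spec = simulate.PlateSpec.from_json(spec_file)
    logger.info("simulating plate with seed %d -> %s", spec.seed, out)
    return simulate.write_plate(spec, out)


def fit_signatures_from_plates(
    input_dirs: list[str | Path],
    labels: list[str],
    out_file: str | Path,
    config: AnalysisConfig | None = None,
    frame_interval_h: float = 0.5,
    pattern: str = "*.png",
) -> list[classify.ProteinSignature]:
    """Fit one protein signature per single-strain plate and save them.

    Each input directory holds one plate of colonies of a single strain;
    the full analysis runs per plate and the (R, G) totals of its
    colonies define that strain's characteristic line.
    """
    if len(input_dirs) != len(labels):
        raise ValueError("need exactly one label per input directory")
    signatures = []
    for directory, label in zip(input_dirs, labels):
        cfg = config or AnalysisConfig(
            input_dir=str(directory),
            out_dir=str(directory),
            frame_interval_h=frame_interval_h,
            pattern=pattern,
        )
        lapse = stack.load_timelapse(
            directory, pattern=cfg.pattern,
            frame_interval_h=cfg.frame_interval_h,
            timestamps_file=cfg.timestamps_file,
        )
        _, _, _, records = _analyze_stack(lapse, cfg)
        totals = [
            classify.channel_totals(
                rec[6], rec[1], rec[3], rec[0].center_rc,
                reference=cfg.classification_reference,
            )
            for rec in records
        ]
        signatures.append(classify.fit_signature(totals, label))
    classify.save_signatures(signatures, out_file)
    return signatures
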