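"""End-to-end orchestration: simulate/load -> detect -> quantify -> compare.

A single config describes the conditions of a phototoxicity experiment
(label, dose in J/cm², wavelength, and either a synthetic scenario or
video+mask files per FOV).  The pipeline produces per-FOV rounding curves
and peaks, population curves, activity traces, condition-level event
statistics against the designated control, and a reproducibility manifest
with config snapshot, seeds, and output hashes.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .activity import activity_trace, cumulative_activity_at, normalize_per_replica, DEFAULT_REPORT_TIME
from .detection import count_nuclei, masks_to_detections
from .io_formats import read_label_masks, read_video, write_table
from .preprocess import preprocess_for_activity
from .quantify import (
    events_from_table,
    population_curves,
    rounding_curve,
    transition_fraction,
)
from .stats import ks_two_sided
from .synthetic import SyntheticScenario, render_video
from .io_formats import read_table

logger = logging.getLogger("phototox")

__all__ = ["run_pipeline"]


def _sha256(path: Path) -> str:
    digest = hashlib.sha256()
    digest.update(path.read_bytes())
    return digest.hexdigest()


def _scenario_for(condition: dict, config: dict, fov: int, cond_index: int) -> SyntheticScenario:
    base = dict(config.get("scenario", {}))
    base.update(condition.get("scenario", {}))
    if "field_shape" in base:
        base["field_shape"] = tuple(base["field_shape"])
    seed0 = int(config.get("seed", 0))
    scenario = SyntheticScenario(**base)
    # one stream per FOV, derived from the run seed, the condition and the FOV index
    fov_seed = (seed0 * 100003 + cond_index * 9973 + fov) % (2**31)
    return replace(scenario, seed=fov_seed, identifier=f"{condition['label']}_fov{fov}")


def _analyse_fov(
    condition: dict,
    config: dict,
    fov: int,
    compute_activity: bool,
    cond_index: int = 0,
) -> dict:
    """Run one FOV end to end and return its measurements."""
    report_time = float(config.get("report_time_min", DEFAULT_REPORT_TIME))
    if "fovs" in condition:  # pre-acquired video + mask files
        entry = condition["fovs"][fov]
        video = read_video(
            entry["video"],
            pixel_size=config["pixel_size"],
            frame_interval=config["frame_interval"],
        )
        masks = read_label_masks(
            entry["masks"], pixel_size=entry.get("mask_pixel_size", config["pixel_size"])
        )
        nuclei = count_nuclei(int(entry["nuclei"])) if "nuclei" in entry else count_nuclei(masks)
        events = events_from_table(read_table(entry["events"])) if "events" in entry else []
        frame_interval = float(config["frame_interval"])
        n_frames = masks.n_frames
        origin = 0.0
    else:  # synthetic scenario
        scenario = _scenario_for(condition, config, fov, cond_index)
        video, truth = render_video(scenario, with_video=compute_activity)
        masks = truth.masks
        nuclei = count_nuclei(truth.nuclei_count)
        events = truth.events
        frame_interval = scenario.frame_interval
        n_frames = scenario.n_frames
        origin = 0.0

    detections = masks_to_detections(masks, frame_interval, origin_time=origin)
    curve = rounding_curve(detections, nuclei, frame_interval, origin_time=origin, n_frames=n_frames)
    populations = population_curves(detections)

    row = {
        "condition": condition["label"],
        "fov": fov,
        "replica": condition.get("replica", 1),
        "dose_j_cm2": condition.get("dose_j_cm2", float("nan")),
        "wavelength_nm": condition.get("wavelength_nm", float("nan")),
        "n_nuclei": nuclei.count,
        "peak_time_min": curve.peak_time if curve.peak_time is not None else float("nan"),
        "max_fraction": float(curve.fraction.max()) if len(curve.fraction) else float("nan"),
    }
    if compute_activity and video is not None:
        pre = preprocess_for_activity(video)
        trace = activity_trace(pre)
        row["cumulative_activity"] = cumulative_activity_at(trace, min(report_time, trace.times[-1]))
    return {
        "summary": row,
        "curve": curve,
        "populations": populations,
        "events": events,
    }


def run_pipeline(config: dict, out_dir: str | Path) -> dict:
    """Run every condition of a pipeline config and write result tables.

    Returns the manifest dictionary (also written to ``manifest.json``).
    Raises with the offending stage and condition on any failure.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    conditions = config.get("conditions", [])
    if not conditions:
        raise ValueError("config lists no conditions")
    control_label = config.get("control", "control")
    labels = [c["label"] for c in conditions]
    if control_label not in labels:
        raise ValueError(f"control condition {control_label!r} missing from conditions {labels}")
    compute_activity = bool(config.get("activity", True))
    by_time = float(config.get("transition_by_time_min", 50.0))

    timings: dict[str, float] = {}
    summaries: list[dict] = []
    pooled_events: dict[str, list] = {}
    for cond_index, condition in enumerate(conditions):
        label = condition["label"]
        n_fovs = int(condition.get("n_fovs", len(condition.get("fovs", [])) or 1))
        start = time.monotonic()
        pooled_events[label] = []
        for fov in range(n_fovs):
            try:
                result = _analyse_fov(condition, config, fov, compute_activity, cond_index)
            except Exception as exc:  # noqa: BLE001 - re-raise with stage context
                raise RuntimeError(
                    f"stage 'analyse_fov' failed for condition {label!r}, FOV {fov}: {exc}"
                ) from exc
            summaries.append(result["summary"])
            pooled_events[label].extend(result["events"])
            result["curve"].to_frame().to_csv(
                out_dir / f"curve_{label}_fov{fov}.csv", index=False
            )
        timings[label] = time.monotonic() - start
        logger.info("condition %s: %d FOVs in %.1f s", label, n_fovs, timings[label])

    summary = pd.DataFrame(summaries)
    if compute_activity and "cumulative_activity" in summary:
        summary = normalize_per_replica(summary, control_label=control_label)
    write_table(summary, out_dir / "summary.csv")

    comparisons = []
    control_starts = np.array([e.t_round_start for e in pooled_events[control_label]])
    for label in labels:
        if label == control_label:
            continue
        if len(pooled_events[label]) == 0 or len(control_starts) == 0:
            continue
        sample = np.array([e.t_round_start for e in pooled_events[label]])
        ks = ks_two_sided(control_starts, sample)
        comparisons.append(
            {
                "condition": label,
                "vs": control_label,
                "ks_statistic": ks.ks_statistic,
                "p_value": ks.p_value,
                "stars": ks.significance_stars,
                "n_control": ks.n1,
                "n_condition": ks.n2,
            }
        )
    comparisons = pd.DataFrame(
        comparisons,
        columns=["condition", "vs", "ks_statistic", "p_value", "stars", "n_control", "n_condition"],
    )
    write_table(comparisons, out_dir / "comparisons.csv")

    transitions = pd.DataFrame(
        [
            {
                "condition": label,
                "n_events": len(events),
                "transition_fraction": transition_fraction(events, by_time) if events else float("nan"),
                "by_time_min": by_time,
            }
            for label, events in pooled_events.items()
        ]
    )
    write_table(transitions, out_dir / "transitions.csv")

    outputs = sorted(p for p in out_dir.glob("*.csv"))
    manifest = {
        "version": __version__,
        "config": config,
        "seed": int(config.get("seed", 0)),
        "stage_seconds": timings,
        "outputs": {p.name: _sha256(p) for p in outputs},
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest
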