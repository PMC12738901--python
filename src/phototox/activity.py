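"""Population-level cellular activity from frame differencing.

The activity at time t is the mean over pixels of the squared difference
between consecutive preprocessed frames,

    activity(t) = mean((eIm(t) - eIm(t-1))**2),

where eIm is the normalised, contrast-enhanced, smoothed image.  Cumulative
activity is the running sum of activity over time; the frame-0 term, which
has no predecessor, is defined as 0.  The conventional reporting point for
cumulative activity is T = 420 min (7 h post exposure).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .preprocess import PreprocessedVideo

__all__ = [
    "ActivityTrace",
    "frame_activity",
    "activity_trace",
    "cumulative_activity_at",
    "normalize_per_replica",
    "DEFAULT_REPORT_TIME",
]

DEFAULT_REPORT_TIME = 420.0  # minutes (7 h)


@dataclass
class ActivityTrace:
    """Per-step activity values and their cumulative aggregation.

    ``times[i]`` is the acquisition time (minutes) of the *later* frame of
    pair i, i.e. t = 1..T-1 mapped through the frame interval and origin.
    """

    times: np.ndarray
    activity: np.ndarray
    cumulative: np.ndarray
    identifier: str = ""
    normalization: str = "none"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.activity = np.asarray(self.activity, dtype=float)
        self.cumulative = np.asarray(self.cumulative, dtype=float)
        if not (len(self.times) == len(self.activity) == len(self.cumulative)):
            raise ValueError("times, activity and cumulative must align")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_min": self.times,
                "activity": self.activity,
                "cumulative": self.cumulative,
            }
        )


def frame_activity(a: np.ndarray, b: np.ndarray) -> float:
    """Mean squared per-pixel difference between two preprocessed frames."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError(f"frame shapes differ: {a.shape} vs {b.shape}")
    diff = a - b
    return float(np.mean(diff * diff))


def activity_trace(video: PreprocessedVideo) -> ActivityTrace:
    """Activity for every consecutive frame pair plus its prefix sum."""
    if video.n_frames < 2:
        raise ValueError("activity needs at least 2 frames")
    frames = np.asarray(video.frames, dtype=np.float64)
    diffs = frames[1:] - frames[:-1]
    activity = np.mean(diffs * diffs, axis=(1, 2))
    times = video.times[1:]
    return ActivityTrace(
        times=times,
        activity=activity,
        cumulative=np.cumsum(activity),
        identifier=video.identifier,
    )


def cumulative_activity_at(trace: ActivityTrace, T_minutes: float = DEFAULT_REPORT_TIME) -> float:
    """Cumulative activity at the last entry with time <= ``T_minutes``."""
    if len(trace.times) == 0:
        raise ValueError("empty trace")
    if T_minutes < trace.times[0]:
        raise ValueError(
            f"report time {T_minutes} min precedes first trace entry at {trace.times[0]} min"
        )
    idx = int(np.searchsorted(trace.times, T_minutes, side="right")) - 1
    return float(trace.cumulative[idx])


def normalize_per_replica(
    values: pd.DataFrame,
    control_label: str = "control",
    value_column: str = "cumulative_activity",
    condition_column: str = "condition",
    replica_column: str = "replica",
) -> pd.DataFrame:
    """Scale cumulative activities within each replica by its control mean.

    Each replica's values are divided by the mean of that replica's control
    condition, so the control maps to mean 1 and exposed conditions become
    fold-type values comparable across replicas of different raw scale.
    """
    out = values.copy()
    controls = (
        out.loc[out[condition_column] == control_label]
        .groupby(replica_column)[value_column]
        .mean()
    )
    missing = sorted(set(out[replica_column]) - set(controls.index))
    if missing:
        raise ValueError(f"replicas without a {control_label!r} group: {missing}")
    if (controls == 0).any():
        raise ValueError("control mean is zero in at least one replica")
    out[value_column + "_normalized"] = (
        out[value_column] / out[replica_column].map(controls).astype(float)
    )
    return out
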