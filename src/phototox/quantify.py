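"""Headline measurements from round-cell detections.

* C(t): fraction of cells detected as round at each time point, i.e.
  detections per frame divided by a nuclei count frozen at frame 0.
* t_p: the earliest time at which C(t) attains its maximum (phototoxicity
  manifests as rightward peak shifts, so the earliest maximum is the
  conservative estimator).
* mother/daughter population curves from the 18 µm size split.
* division / arrest event classification: a cell that rounds but fails to
  produce two daughters by the end of the observation window is arrested.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
import pandas as pd

from .detection import NucleiCount

__all__ = [
    "RoundingCurve",
    "CellEvent",
    "rounding_curve",
    "peak_time",
    "population_curves",
    "classify_event",
    "transition_fraction",
    "events_to_table",
    "events_from_table",
    "NO_PEAK_FLOOR",
]

NO_PEAK_FLOOR = 0.01


@dataclass
class RoundingCurve:
    """C(t) for one FOV plus its peak.

    ``peak_time`` is None when the curve never rises above the no-peak
    floor (at very high doses the characteristic rounding peak all but
    disappears).
    """

    times: np.ndarray
    fraction: np.ndarray
    n_nuclei: int
    peak_time: float | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.fraction = np.asarray(self.fraction, dtype=float)
        if len(self.times) != len(self.fraction):
            raise ValueError("times and fraction must align")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_min": self.times, "fraction": self.fraction})


@dataclass
class CellEvent:
    """One tracked rounding event and its outcome."""

    event_id: str
    t_round_start: float
    t_division: float | None
    outcome: str  # 'divided' | 'arrested'
    division_duration: float | None = None


def rounding_curve(
    detections: pd.DataFrame,
    nuclei: NucleiCount,
    frame_interval: float,
    origin_time: float = 0.0,
    n_frames: int | None = None,
    no_peak_floor: float = NO_PEAK_FLOOR,
) -> RoundingCurve:
    """C(t) = detections per frame / nuclei count (frozen at frame 0).

    Frames without detections contribute 0.  ``n_frames`` extends the curve
    to the full video length; when omitted it is inferred from the last
    frame present in the table.
    """
    if nuclei.count <= 0:
        raise ValueError("nuclei count must be positive to form C(t)")
    if n_frames is None:
        n_frames = int(detections["frame_index"].max()) + 1 if len(detections) else 1
    counts = np.zeros(n_frames, dtype=float)
    if len(detections):
        by_frame = detections.groupby("frame_index").size()
        idx = by_frame.index.to_numpy(dtype=int)
        in_range = idx < n_frames
        counts[idx[in_range]] = by_frame.to_numpy(dtype=float)[in_range]
    fraction = counts / nuclei.count
    if fraction.max() > 1:
        warnings.warn(
            "C(t) exceeds 1: more round detections than nuclei in at least one frame"
        )
    times = origin_time + np.arange(n_frames) * frame_interval
    curve = RoundingCurve(times=times, fraction=fraction, n_nuclei=nuclei.count)
    curve.peak_time = peak_time(curve, no_peak_floor)
    return curve


def peak_time(curve: RoundingCurve, no_peak_floor: float = NO_PEAK_FLOOR) -> float | None:
    """Earliest time achieving max C(t); None when the max is below the floor."""
    if len(curve.fraction) == 0:
        return None
    peak = curve.fraction.max()
    if peak < no_peak_floor:
        return None
    return float(curve.times[int(np.argmax(curve.fraction))])


def population_curves(detections: pd.DataFrame) -> pd.DataFrame:
    """Per-frame mother/daughter counts and mean diameter."""
    if len(detections) == 0:
        return pd.DataFrame(
            columns=["frame_index", "time_min", "n_mother", "n_daughter", "mean_diameter_um"]
        )
    grouped = detections.groupby(["frame_index", "time_min"])
    out = grouped.agg(
        n_mother=("size_class", lambda s: int((s == "mother").sum())),
        n_daughter=("size_class", lambda s: int((s == "daughter").sum())),
        mean_diameter_um=("diameter_um", "mean"),
    ).reset_index()
    return out


def classify_event(
    event_id: str,
    t_round_start: float,
    t_division: float | None,
    t_end: float,
) -> CellEvent:
    """Divided when two daughters appear by ``t_end``; arrested otherwise."""
    if t_division is not None and not np.isnan(t_division):
        if t_division < t_round_start:
            raise ValueError(
                f"division at {t_division} min precedes rounding at {t_round_start} min"
            )
        if t_division <= t_end:
            return CellEvent(
                event_id=str(event_id),
                t_round_start=float(t_round_start),
                t_division=float(t_division),
                outcome="divided",
                division_duration=float(t_division - t_round_start),
            )
    return CellEvent(
        event_id=str(event_id),
        t_round_start=float(t_round_start),
        t_division=None,
        outcome="arrested",
    )


def transition_fraction(events: list[CellEvent], by_time: float = 50.0) -> float:
    """Fraction of all events that divided no later than ``by_time`` minutes."""
    if not events:
        raise ValueError("no events to summarise")
    n = sum(
        1
        for e in events
        if e.outcome == "divided" and e.t_division is not None and e.t_division <= by_time
    )
    return n / len(events)


def events_to_table(events: list[CellEvent], t_end: float) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "event_id": [e.event_id for e in events],
            "t_round_start_min": [e.t_round_start for e in events],
            "t_division_min": [e.t_division for e in events],
            "t_end_min": [t_end] * len(events),
        }
    )


def events_from_table(table: pd.DataFrame) -> list[CellEvent]:
    """Build events from the annotation CSV schema.

    Columns: event_id, t_round_start_min, t_division_min (blank when the
    cell never divided), t_end_min.
    """
    events = []
    for row in table.itertuples(index=False):
        t_div = getattr(row, "t_division_min")
        t_div = None if pd.isna(t_div) else float(t_div)
        events.append(
            classify_event(
                str(getattr(row, "event_id")),
                float(getattr(row, "t_round_start_min")),
                t_div,
                float(getattr(row, "t_end_min")),
            )
        )
    return events
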