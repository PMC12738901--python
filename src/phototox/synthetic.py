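"""Synthetic brightfield-like time-lapses with known ground truth.

The generator emulates a field of adherent cells released from a G2/M
synchronisation block: each cell rounds up for mitosis around a
population-level event-time law (default Normal with mode 50 min and
sd 10 min), stays round for a fixed division time (default 30 min),
then splits into two smaller daughters that remain detectably round for a
short respreading window.  Photodamage surrogates are an extra delay added
to all event times and a per-cell arrest probability (arrested cells round
and never divide).  Rounded cells are rendered with the halo contrast they
show in defocused brightfield: a bright ring around a dark interior, on a
mid-grey background with a static low-contrast texture for spread cells,
an illumination gradient, optional temporal drift, and Gaussian sensor
noise.

Event-time anchoring
--------------------
The configured mode is the time at which the *population occupancy* of
round cells (the quantity C(t) measures) peaks.  Because a cell is
detectable over a window (mother rounding plus daughter respreading), the
occupancy peak lags the round-start law; the generator therefore computes
the lag of the occupancy kernel against the event law numerically and
anchors sampled round-start times so that the occupancy peak lands on the
configured mode.  With the default phase structure this also places the
median division time at the mode, matching a synchronised population in
which about half the cells have produced resolvable daughters by the
nominal peak time.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .detection import NucleiCount
from .io_formats import LabelMaskStack, VideoStack, write_label_masks, write_table, write_video
from .quantify import CellEvent, classify_event, events_to_table

__all__ = [
    "SyntheticScenario",
    "GroundTruth",
    "sample_events",
    "render_video",
    "render_viability_frame",
    "occupancy_peak_offset",
    "expected_transition_fraction",
    "write_scenario_outputs",
]


@dataclass
class SyntheticScenario:
    """Parameters of one synthetic FOV; defaults emulate the control condition."""

    n_cells: int = 126
    field_shape: tuple[int, int] = (512, 512)
    pixel_size: float = 0.55          # µm
    frame_interval: float = 4.0       # min
    duration: float = 480.0           # min (8 h)
    rounding_time_mode: float = 50.0  # min, peak of round-cell occupancy
    rounding_time_sd: float = 10.0    # min
    rounding_time_law: str = "normal"  # or "gamma" for skewed, high-dose-like
    rounding_duration: float = 30.0   # min round-start -> division
    daughter_round_duration: float = 12.0  # min daughters stay detectably round
    arrest_prob: float = 0.0
    extra_delay: float = 0.0          # min, photodamage surrogate
    mother_diameter: float = 20.0     # µm
    daughter_diameter: float = 15.0   # µm
    illumination_gradient: float = 0.1   # relative amplitude across the field
    drift_factor: float = 1.0         # end-of-video brightness multiplier
    noise_sd: float = 0.01            # Gaussian sensor noise, intensity units
    background: float = 0.45
    adherent_contrast: float = 0.04
    ring_intensity: float = 0.85
    center_intensity: float = 0.25
    seed: int = 0
    identifier: str = "synthetic"

    def __post_init__(self) -> None:
        if not 0 <= self.arrest_prob <= 1:
            raise ValueError("arrest_prob must be in [0, 1]")
        if not (self.mother_diameter > 0 and self.daughter_diameter > 0):
            raise ValueError("diameters must be positive")
        if self.daughter_diameter >= self.mother_diameter:
            raise ValueError("daughter diameter must be below mother diameter")
        if self.rounding_time_law not in ("normal", "gamma"):
            raise ValueError(f"unknown event-time law {self.rounding_time_law!r}")

    @property
    def n_frames(self) -> int:
        return int(round(self.duration / self.frame_interval)) + 1

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval


@dataclass
class GroundTruth:
    """Everything the analysis should recover from one synthetic FOV."""

    masks: LabelMaskStack
    nuclei_count: int
    events: list[CellEvent]
    schedule: pd.DataFrame
    scenario: SyntheticScenario = None


def _event_law(scenario: SyntheticScenario):
    """Frozen scipy distribution whose mode/sd match the scenario."""
    mode, sd = scenario.rounding_time_mode, scenario.rounding_time_sd
    if scenario.rounding_time_law == "normal":
        return stats.norm(loc=mode, scale=sd)
    # gamma parameterised by mode and sd: mode=(k-1)*theta, var=k*theta**2
    theta = (-mode + np.sqrt(mode**2 + 4 * sd**2)) / 2.0
    k = mode / theta + 1.0
    return stats.gamma(k, scale=theta)


def occupancy_peak_offset(scenario: SyntheticScenario, step: float = 0.05) -> float:
    """Lag of the round-cell occupancy peak behind the event-law mode.

    The occupancy of round cells is the convolution of the round-start law
    with the visibility kernel w(s) = 1 during mother rounding and 2 during
    the daughter respreading window.  Computed on a fine grid; the returned
    offset is subtracted from sampled event times so the occupancy peak
    lands on the configured mode.
    """
    law = _event_law(scenario)
    w = np.concatenate(
        [
            np.ones(max(1, int(round(scenario.rounding_duration / step)))),
            2.0 * np.ones(int(round(scenario.daughter_round_duration / step))),
        ]
    )
    lo = scenario.rounding_time_mode - 8 * scenario.rounding_time_sd
    hi = scenario.rounding_time_mode + 8 * scenario.rounding_time_sd
    x = np.arange(lo, hi, step)
    pdf = law.pdf(x)
    occupancy = np.convolve(pdf, w) * step
    t_peak = lo + np.argmax(occupancy) * step
    return float(t_peak - scenario.rounding_time_mode)


def sample_events(scenario: SyntheticScenario) -> pd.DataFrame:
    """Per-cell event schedule, fully determined by the scenario seed.

    Columns: cell_id, t_round_start, t_division (NaN when arrested),
    t_daughters_end, arrested.  Round starts are the anchored event-law
    samples (see module docstring) shifted by ``extra_delay`` and truncated
    at 0 by resampling.
    """
    rng = np.random.default_rng([scenario.seed, 0])
    law = _event_law(scenario)
    offset = occupancy_peak_offset(scenario)
    n = scenario.n_cells

    starts = np.empty(n)
    filled = 0
    while filled < n:
        draw = law.rvs(size=n - filled, random_state=rng)
        r = draw + scenario.extra_delay - offset
        r = r[r >= 0]
        starts[filled : filled + len(r)] = r
        filled += len(r)

    arrested = rng.random(n) < scenario.arrest_prob
    t_division = starts + scenario.rounding_duration
    t_division[arrested] = np.nan
    t_daughters_end = t_division + scenario.daughter_round_duration
    return pd.DataFrame(
        {
            "cell_id": np.arange(n),
            "t_round_start": starts,
            "t_division": t_division,
            "t_daughters_end": t_daughters_end,
            "arrested": arrested,
        }
    )


def _grid_positions(scenario: SyntheticScenario, rng: np.random.Generator) -> np.ndarray:
    """Jittered grid placement; raises when cells cannot fit without overlap."""
    h, w = scenario.field_shape
    n = scenario.n_cells
    k = int(np.ceil(np.sqrt(n)))
    pitch_r, pitch_c = h / k, w / k
    mother_px = scenario.mother_diameter / scenario.pixel_size
    if min(pitch_r, pitch_c) < mother_px + 2:
        raise ValueError(
            f"cannot place {n} non-overlapping cells of {scenario.mother_diameter} µm "
            f"in a {h}x{w} px field at {scenario.pixel_size} µm/px"
        )
    jitter = min(3.0, (min(pitch_r, pitch_c) - mother_px) / 2.0 - 1.0)
    jitter = max(0.0, jitter)
    sites = [( (i + 0.5) * pitch_r, (j + 0.5) * pitch_c) for i in range(k) for j in range(k)]
    chosen = rng.permutation(len(sites))[:n]
    pos = np.array([sites[i] for i in chosen])
    pos += rng.uniform(-jitter, jitter, size=pos.shape)
    return pos


def _adherent_stamp(size: int, contrast: float, rng: np.random.Generator) -> np.ndarray:
    """Static low-contrast irregular texture for one spread cell."""
    noise = ndimage.gaussian_filter(rng.standard_normal((size, size)), 3.0)
    rr, cc = np.mgrid[:size, :size]
    r = np.hypot(rr - (size - 1) / 2, cc - (size - 1) / 2)
    envelope = np.clip(1.0 - r / (size / 2.0), 0.0, 1.0)
    peak = np.abs(noise).max()
    if peak > 0:
        noise = noise / peak
    return contrast * noise * envelope


def _stamp_disc(
    scene: np.ndarray | None,
    mask: np.ndarray | None,
    center: tuple[float, float],
    radius_px: float,
    ring_value: float,
    center_value: float,
    label: int,
) -> None:
    """Draw a bright-ring / dark-interior disc and (optionally) its mask label."""
    h, w = mask.shape if mask is not None else scene.shape
    r0 = int(np.floor(center[0] - radius_px - 1))
    c0 = int(np.floor(center[1] - radius_px - 1))
    r1 = int(np.ceil(center[0] + radius_px + 2))
    c1 = int(np.ceil(center[1] + radius_px + 2))
    r0, c0 = max(r0, 0), max(c0, 0)
    r1, c1 = min(r1, h), min(c1, w)
    rr, cc = np.mgrid[r0:r1, c0:c1]
    dist = np.hypot(rr - center[0], cc - center[1])
    inside = dist <= radius_px
    if scene is not None:
        interior = dist <= 0.6 * radius_px
        region = scene[r0:r1, c0:c1]
        region[inside] = ring_value
        region[interior] = center_value
    if mask is not None:
        mask[r0:r1, c0:c1][inside] = label


def render_video(
    scenario: SyntheticScenario,
    schedule: pd.DataFrame | None = None,
    with_video: bool = True,
) -> tuple[VideoStack | None, GroundTruth]:
    """Render the brightfield stack and its ground truth.

    ``with_video=False`` skips the intensity rendering and produces masks,
    events and schedule only (cheap path for detection-free analyses).
    Masks mark round cells only: the mother disc during its rounding
    window, then the two daughter discs until they respread.
    """
    if schedule is None:
        schedule = sample_events(scenario)
    rng_place = np.random.default_rng([scenario.seed, 1])
    rng_noise = np.random.default_rng([scenario.seed, 2])

    h, w = scenario.field_shape
    n = scenario.n_cells
    positions = _grid_positions(scenario, rng_place)
    angles = rng_place.uniform(0, np.pi, size=n)
    mother_r = scenario.mother_diameter / 2.0 / scenario.pixel_size
    daughter_r = scenario.daughter_diameter / 2.0 / scenario.pixel_size

    stamp_size = int(2 * mother_r * 1.3) | 1
    stamps = [
        _adherent_stamp(stamp_size, scenario.adherent_contrast, rng_place)
        for _ in range(n)
    ]

    rows = np.linspace(0, 1, h)[:, None]
    cols = np.linspace(0, 1, w)[None, :]
    gradient = 1.0 + scenario.illumination_gradient * ((rows - 0.5) + (cols - 0.5))

    times = scenario.times
    t_end = times[-1] if len(times) > 1 else 1.0
    frames = np.empty((len(times), h, w), dtype=np.float32) if with_video else None
    masks = np.zeros((len(times), h, w), dtype=np.int32)

    starts = schedule["t_round_start"].to_numpy()
    divisions = schedule["t_division"].to_numpy()
    daughters_end = schedule["t_daughters_end"].to_numpy()
    arrested = schedule["arrested"].to_numpy()

    half = stamp_size // 2
    for k, t in enumerate(times):
        scene = np.full((h, w), scenario.background, dtype=np.float64) if with_video else None
        mask = masks[k]
        round_mother = (t >= starts) & (arrested | (t < divisions))
        in_daughters = (~arrested) & (t >= divisions) & (t < daughters_end)
        if with_video:
            flat = ~(round_mother | in_daughters)
            for i in np.nonzero(flat)[0]:
                r0 = int(round(positions[i, 0])) - half
                c0 = int(round(positions[i, 1])) - half
                rs, cs = max(r0, 0), max(c0, 0)
                re, ce = min(r0 + stamp_size, h), min(c0 + stamp_size, w)
                scene[rs:re, cs:ce] += stamps[i][rs - r0 : re - r0, cs - c0 : ce - c0]
        for i in np.nonzero(round_mother)[0]:
            _stamp_disc(
                scene,
                mask,
                tuple(positions[i]),
                mother_r,
                scenario.ring_intensity,
                scenario.center_intensity,
                int(i) + 1,
            )
        for i in np.nonzero(in_daughters)[0]:
            offset = daughter_r * np.array([np.cos(angles[i]), np.sin(angles[i])])
            for d, sign in enumerate((1.0, -1.0)):
                _stamp_disc(
                    scene,
                    mask,
                    tuple(positions[i] + sign * offset),
                    daughter_r,
                    scenario.ring_intensity,
                    scenario.center_intensity,
                    n + 2 * int(i) + 1 + d,
                )
        if with_video:
            drift = 1.0 + (scenario.drift_factor - 1.0) * (t / t_end)
            frame = scene * gradient * drift
            if scenario.noise_sd > 0:
                frame = frame + rng_noise.normal(0.0, scenario.noise_sd, size=frame.shape)
            frames[k] = np.clip(frame, 0.0, None)

    events = [
        classify_event(
            f"cell_{int(row.cell_id)}",
            float(row.t_round_start),
            None if np.isnan(row.t_division) else float(row.t_division),
            float(scenario.duration),
        )
        for row in schedule.itertuples(index=False)
    ]
    truth = GroundTruth(
        masks=LabelMaskStack(masks=masks, pixel_size=scenario.pixel_size),
        nuclei_count=n,
        events=events,
        schedule=schedule,
        scenario=scenario,
    )
    video = None
    if with_video:
        video = VideoStack(
            frames=frames,
            pixel_size=scenario.pixel_size,
            frame_interval=scenario.frame_interval,
            origin_time=0.0,
            identifier=scenario.identifier,
        )
    return video, truth



def expected_transition_fraction(scenario: SyntheticScenario, by_time: float = 50.0) -> float:
    """Analytic fraction of cells divided by ``by_time`` under the scenario law.

    (1 - arrest_prob) * P(division time <= by_time), ignoring the
    negligible truncation of event times at 0.
    """
    law = _event_law(scenario)
    offset = occupancy_peak_offset(scenario)
    threshold = by_time - scenario.extra_delay + offset - scenario.rounding_duration
    return float((1.0 - scenario.arrest_prob) * law.cdf(threshold))


def render_viability_frame(
    n_total: int,
    positive_fraction: float,
    shape: tuple[int, int] = (512, 512),
    seed: int = 0,
    noise_sd: float = 0.01,
    nucleus_sigma_px: float = 3.0,
) -> tuple[np.ndarray, int]:
    """Synthetic viability-dye fluorescence frame plus the true positive count.

    Dye-positive nuclei are bright Gaussian blobs, negatives are dim;
    exactly round(n_total * positive_fraction) nuclei are positive.
    """
    if not 0 <= positive_fraction <= 1:
        raise ValueError("positive_fraction must be in [0, 1]")
    rng = np.random.default_rng([seed, 3])
    h, w = shape
    k = int(np.ceil(np.sqrt(n_total))) if n_total else 1
    if min(h / k, w / k) < 6 * nucleus_sigma_px:
        raise ValueError("field too small for the requested nucleus count")
    frame = np.full(shape, 0.02, dtype=np.float64)
    n_positive = int(round(n_total * positive_fraction))
    which_positive = np.zeros(n_total, dtype=bool)
    which_positive[rng.permutation(n_total)[:n_positive]] = True
    sites = [((i + 0.5) * h / k, (j + 0.5) * w / k) for i in range(k) for j in range(k)]
    chosen = rng.permutation(len(sites))[:n_total]
    span = int(4 * nucleus_sigma_px)
    for idx, site_idx in enumerate(chosen):
        cr, cc = sites[site_idx]
        cr += rng.uniform(-2, 2)
        cc += rng.uniform(-2, 2)
        amplitude = 0.8 if which_positive[idx] else 0.03
        r0, c0 = max(int(cr) - span, 0), max(int(cc) - span, 0)
        r1, c1 = min(int(cr) + span + 1, h), min(int(cc) + span + 1, w)
        rr, ccg = np.mgrid[r0:r1, c0:c1]
        frame[r0:r1, c0:c1] += amplitude * np.exp(
            -((rr - cr) ** 2 + (ccg - cc) ** 2) / (2 * nucleus_sigma_px**2)
        )
    if noise_sd > 0:
        frame += rng.normal(0.0, noise_sd, size=frame.shape)
    return np.clip(frame, 0.0, None).astype(np.float32), n_positive


def write_scenario_outputs(
    scenario: SyntheticScenario, out_dir: str | Path, with_video: bool = True
) -> dict:
    """Render a scenario and write video.tif, masks.tif, events.csv, truth.json."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    video, truth = render_video(scenario, with_video=with_video)
    paths = {}
    if video is not None:
        write_video(video, out_dir / "video.tif")
        paths["video"] = str(out_dir / "video.tif")
    write_label_masks(truth.masks, out_dir / "masks.tif")
    paths["masks"] = str(out_dir / "masks.tif")
    write_table(events_to_table(truth.events, scenario.duration), out_dir / "events.csv")
    paths["events"] = str(out_dir / "events.csv")
    meta = {
        "scenario": {k: (list(v) if isinstance(v, tuple) else v) for k, v in asdict(scenario).items()},
        "nuclei_count": truth.nuclei_count,
        "n_frames": scenario.n_frames,
    }
    with open(out_dir / "truth.json", "w") as fh:
        json.dump(meta, fh, indent=2)
    paths["truth"] = str(out_dir / "truth.json")
    return paths
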