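"""Reading and writing of on-disk artifacts: videos, label masks, tables, configs.

All calibration (pixel size, frame interval) is carried explicitly on the
in-memory containers; nothing downstream ever touches a file or guesses a
calibration.  Axis order is (time, row, column), 0-based, origin at the
top-left corner, and pixels are assumed square (isotropic).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml

__all__ = [
    "VideoStack",
    "LabelMaskStack",
    "read_video",
    "write_video",
    "read_label_masks",
    "write_label_masks",
    "read_table",
    "write_table",
    "load_config",
]


def _check_isotropic(pixel_size: float | Sequence[float]) -> float:
    """Return a scalar pixel size in µm, rejecting anisotropic input."""
    if np.ndim(pixel_size) > 0:
        values = np.asarray(pixel_size, dtype=float)
        if values.size == 0:
            raise ValueError("pixel_size must not be empty")
        if not np.allclose(values, values.flat[0]):
            raise ValueError(
                f"anisotropic pixel size {values.tolist()} not supported; "
                "pixels must be square"
            )
        pixel_size = float(values.flat[0])
    pixel_size = float(pixel_size)
    if not pixel_size > 0:
        raise ValueError(f"pixel_size must be positive, got {pixel_size}")
    return pixel_size


@dataclass
class VideoStack:
    """A single-FOV time-lapse with spatial and temporal calibration.

    Parameters
    ----------
    frames
        Intensity array of shape (time, height, width), non-negative,
        arbitrary scale (raw camera counts or floats).
    pixel_size
        Isotropic pixel size in µm.
    frame_interval
        Minutes between consecutive frames.
    origin_time
        Minutes of frame 0 relative to synchronisation release.
    identifier
        Free-text FOV / condition label.
    """

    frames: np.ndarray
    pixel_size: float
    frame_interval: float
    origin_time: float = 0.0
    identifier: str = ""

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError(
                f"frames must be 3-D (time, height, width), got ndim={self.frames.ndim}"
            )
        self.pixel_size = _check_isotropic(self.pixel_size)
        self.frame_interval = float(self.frame_interval)
        if not self.frame_interval > 0:
            raise ValueError("frame_interval must be positive")
        self.origin_time = float(self.origin_time)

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.frames.shape

    @property
    def times(self) -> np.ndarray:
        """Acquisition time of every frame in minutes."""
        return self.origin_time + np.arange(self.n_frames) * self.frame_interval


@dataclass
class LabelMaskStack:
    """Per-frame instance label masks aligned to a :class:`VideoStack`.

    Background is 0; instance labels are positive integers unique within a
    frame but carry no identity across frames.  The mask grid may have a
    different pixel size than the video when detection ran on a resampled
    grid; all physical quantities are derived from the mask's own
    calibration.
    """

    masks: np.ndarray
    pixel_size: float

    def __post_init__(self) -> None:
        self.masks = np.asarray(self.masks)
        if self.masks.ndim != 3:
            raise ValueError("masks must be 3-D (time, height, width)")
        if not np.issubdtype(self.masks.dtype, np.integer):
            raise ValueError(
                f"label masks must be integer-valued, got dtype {self.masks.dtype}"
            )
        if self.masks.size and self.masks.min() < 0:
            raise ValueError("label masks must not contain negative labels")
        self.pixel_size = _check_isotropic(self.pixel_size)

    @property
    def n_frames(self) -> int:
        return self.masks.shape[0]

    def n_instances(self, frame_index: int) -> int:
        """Number of distinct positive labels in one frame."""
        labels = np.unique(self.masks[frame_index])
        return int((labels > 0).sum())


def read_video(
    path: str | Path,
    pixel_size: float,
    frame_interval: float,
    origin_time: float = 0.0,
    identifier: str | None = None,
) -> VideoStack:
    """Read a multi-page TIFF time-lapse, attaching the supplied calibration.

    Intensities are preserved bit-exact.  A single-page TIFF is accepted
    (e.g. a viability still) and yields a stack with one frame.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    frames = tifffile.imread(path)
    if frames.ndim == 2:
        frames = frames[None]
    if frames.ndim != 3:
        raise ValueError(f"expected a (multi-)page 2-D TIFF, got shape {frames.shape}")
    return VideoStack(
        frames=frames,
        pixel_size=pixel_size,
        frame_interval=frame_interval,
        origin_time=origin_time,
        identifier=identifier if identifier is not None else path.stem,
    )


def write_video(video: VideoStack, path: str | Path) -> None:
    """Write a :class:`VideoStack` as a multi-page TIFF (lossless)."""
    tifffile.imwrite(Path(path), video.frames)


def read_label_masks(path: str | Path, pixel_size: float) -> LabelMaskStack:
    """Read an integer-label multi-page TIFF; labels preserved exactly."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    masks = tifffile.imread(path)
    if masks.ndim == 2:
        masks = masks[None]
    if not np.issubdtype(masks.dtype, np.integer):
        raise ValueError(
            f"label mask TIFF must be integer-valued, got dtype {masks.dtype}"
        )
    return LabelMaskStack(masks=masks, pixel_size=pixel_size)


def write_label_masks(masks: LabelMaskStack, path: str | Path) -> None:
    tifffile.imwrite(Path(path), masks.masks)


def write_table(rows: pd.DataFrame, path: str | Path) -> None:
    """Write tabular records as CSV with header and stable column order."""
    rows.to_csv(Path(path), index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(Path(path))


def load_config(path: str | Path) -> dict:
    """Load a YAML (or JSON, a YAML subset) configuration file."""
    with open(path) as fh:
        config = yaml.safe_load(fh)
    if not isinstance(config, dict):
        raise ValueError(f"config at {path} must be a mapping")
    return config
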