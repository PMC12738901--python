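"""Intensity normalisation and contrast enhancement ahead of activity analysis.

The chain applied before frame differencing is, in order:

1. per-frame min-max normalisation to [0, 1];
2. per-frame bleach / illumination correction (subtract a wide Gaussian
   low-pass of the frame);
3. whole-video min-max normalisation (global min/max over all frames, so
   that temporal differences stay comparable);
4. per-frame CLAHE (kernel 25 px, clip limit 0.01, 256 bins);
5. per-frame Gaussian smoothing with sigma = 1 px.

Every step is deterministic and recorded in the provenance list of the
returned :class:`PreprocessedVideo`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import exposure, transform

from .io_formats import VideoStack

__all__ = [
    "PreprocessedVideo",
    "normalize_minmax",
    "bleach_correct",
    "enhance_contrast_clahe",
    "smooth_gaussian",
    "preprocess_for_activity",
    "resample_to_pixel_size",
]

CLAHE_KERNEL = 25
CLAHE_CLIP = 0.01
CLAHE_BINS = 256
SMOOTH_SIGMA = 1.0


@dataclass
class PreprocessedVideo:
    """Video after the full normalisation chain, values in [0, 1]."""

    frames: np.ndarray
    pixel_size: float
    frame_interval: float
    origin_time: float = 0.0
    identifier: str = ""
    provenance: list = field(default_factory=list)

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def times(self) -> np.ndarray:
        return self.origin_time + np.arange(self.n_frames) * self.frame_interval


def normalize_minmax(frames: np.ndarray, scope: str = "per-frame") -> np.ndarray:
    """Min-max projection to [0, 1].

    ``scope='per-frame'`` rescales each frame by its own extrema;
    ``scope='whole-video'`` uses the global min/max over the full array.
    A constant input (zero range) maps to all zeros.
    """
    frames = np.asarray(frames, dtype=np.float64)
    if frames.size == 0:
        raise ValueError("cannot normalise an empty array")
    if scope == "whole-video" or frames.ndim == 2:
        lo, hi = frames.min(), frames.max()
        if hi > lo:
            return (frames - lo) / (hi - lo)
        return np.zeros_like(frames)
    if scope != "per-frame":
        raise ValueError(f"unknown scope {scope!r}")
    lo = frames.min(axis=(-2, -1), keepdims=True)
    hi = frames.max(axis=(-2, -1), keepdims=True)
    span = hi - lo
    out = np.zeros_like(frames)
    np.divide(frames - lo, span, out=out, where=span > 0)
    return out


def _wide_gaussian(frame: np.ndarray, sigma: float) -> np.ndarray:
    """Gaussian low-pass; for very wide kernels filter at reduced resolution.

    For sigma above ~8 px the frame is downscaled, filtered with an
    equivalent small sigma and upscaled again, which is numerically close
    to the direct filter for the smooth illumination fields this estimates
    and far cheaper.
    """
    if sigma <= 8:
        return ndimage.gaussian_filter(frame, sigma, mode="nearest")
    factor = sigma / 8.0
    small_shape = (
        max(4, int(round(frame.shape[0] / factor))),
        max(4, int(round(frame.shape[1] / factor))),
    )
    small = transform.resize(
        frame, small_shape, order=1, mode="edge", anti_aliasing=True,
        preserve_range=True,
    )
    realized_factor = frame.shape[0] / small_shape[0]
    small = ndimage.gaussian_filter(small, sigma / realized_factor, mode="nearest")
    return transform.resize(
        small, frame.shape, order=1, mode="edge", preserve_range=True
    )


def bleach_correct(frame: np.ndarray, sigma: float) -> np.ndarray:
    """Subtract a wide Gaussian low-pass (the illumination estimate).

    The output may be negative; the subsequent whole-video min-max step
    rescales it back into [0, 1].
    """
    if not sigma > 0:
        raise ValueError("sigma must be positive")
    frame = np.asarray(frame, dtype=np.float64)
    return frame - _wide_gaussian(frame, sigma)


def enhance_contrast_clahe(
    frame: np.ndarray,
    kernel: int = CLAHE_KERNEL,
    clip: float = CLAHE_CLIP,
    bins: int = CLAHE_BINS,
) -> np.ndarray:
    """Contrast-limited adaptive histogram equalisation on a [0, 1] frame."""
    frame = np.asarray(frame, dtype=np.float64)
    if frame.min() < 0 or frame.max() > 1:
        raise ValueError("CLAHE input must lie within [0, 1]")
    if frame.max() == frame.min():
        return frame.copy()
    out = exposure.equalize_adapthist(
        frame, kernel_size=kernel, clip_limit=clip, nbins=bins
    )
    return np.clip(out, 0.0, 1.0)


def smooth_gaussian(frame: np.ndarray, sigma: float = SMOOTH_SIGMA) -> np.ndarray:
    """Gaussian smoothing; ``sigma=0`` is the identity."""
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    frame = np.asarray(frame, dtype=np.float64)
    if sigma == 0:
        return frame.copy()
    return ndimage.gaussian_filter(frame, sigma, mode="nearest")


def preprocess_for_activity(
    video: VideoStack, sigma_bleach: float | None = None
) -> PreprocessedVideo:
    """Apply the full normalisation chain ahead of frame differencing.

    ``sigma_bleach`` defaults to min(height, width)/4: the low-pass must
    capture the illumination field, which is far larger than a ~20 µm cell.
    """
    if video.n_frames < 2:
        raise ValueError("temporal analysis needs at least 2 frames")
    if sigma_bleach is None:
        sigma_bleach = min(video.frames.shape[1:]) / 4.0

    provenance: list = []
    frames = normalize_minmax(video.frames, scope="per-frame")
    provenance.append(("normalize_minmax", {"scope": "per-frame"}))

    frames = np.stack([bleach_correct(f, sigma_bleach) for f in frames])
    provenance.append(("bleach_correct", {"sigma": float(sigma_bleach)}))

    frames = normalize_minmax(frames, scope="whole-video")
    provenance.append(("normalize_minmax", {"scope": "whole-video"}))

    frames = np.stack(
        [
            enhance_contrast_clahe(f, CLAHE_KERNEL, CLAHE_CLIP, CLAHE_BINS)
            for f in frames
        ]
    )
    provenance.append(
        ("enhance_contrast_clahe", {"kernel": CLAHE_KERNEL, "clip": CLAHE_CLIP, "bins": CLAHE_BINS})
    )

    frames = np.stack([smooth_gaussian(f, SMOOTH_SIGMA) for f in frames])
    frames = np.clip(frames, 0.0, 1.0)
    provenance.append(("smooth_gaussian", {"sigma": SMOOTH_SIGMA}))

    return PreprocessedVideo(
        frames=frames,
        pixel_size=video.pixel_size,
        frame_interval=video.frame_interval,
        origin_time=video.origin_time,
        identifier=video.identifier,
        provenance=provenance,
    )


def resample_to_pixel_size(video: VideoStack, target: float) -> VideoStack:
    """Bilinear downsampling to a coarser grid (e.g. for detection).

    The integer output shape is round(extent/target) per axis, and the
    realized pixel size is recomputed from that shape; it lies within 1%
    of the requested target.  Upsampling requests are rejected.
    """
    if not target > 0:
        raise ValueError("target pixel size must be positive")
    if target < video.pixel_size:
        raise ValueError(
            f"upsampling not supported: target {target} µm < source {video.pixel_size} µm"
        )
    if target == video.pixel_size:
        return VideoStack(
            frames=video.frames.copy(),
            pixel_size=video.pixel_size,
            frame_interval=video.frame_interval,
            origin_time=video.origin_time,
            identifier=video.identifier,
        )
    t, h, w = video.frames.shape
    out_h = max(1, int(round(h * video.pixel_size / target)))
    out_w = max(1, int(round(w * video.pixel_size / target)))
    frames = np.stack(
        [
            transform.resize(
                f.astype(np.float64), (out_h, out_w), order=1, mode="edge",
                anti_aliasing=True, preserve_range=True,
            )
            for f in video.frames
        ]
    )
    realized = float(np.mean([h * video.pixel_size / out_h, w * video.pixel_size / out_w]))
    return VideoStack(
        frames=frames,
        pixel_size=realized,
        frame_interval=video.frame_interval,
        origin_time=video.origin_time,
        identifier=video.identifier,
    )
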