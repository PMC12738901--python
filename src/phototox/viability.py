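"""Dead/apoptotic-cell fraction from a nuclear viability-dye channel.

Dye-positive nuclei are segmented by a global Otsu threshold followed by a
watershed on the distance transform to split touching nuclei; the
viability fraction is the positive count divided by the total-cell
denominator (fixed at frame 0, consistent with C(t); a per-frame
denominator is available through :func:`viability_series`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np
from scipy import ndimage
from skimage import feature, filters, measure, segmentation

from .detection import NucleiCount

__all__ = ["ViabilityResult", "segment_positive_nuclei", "viability_fraction", "viability_series"]

DEFAULT_MIN_AREA_PX = 10


@dataclass
class ViabilityResult:
    """Dye-positive count, denominator and their ratio."""

    n_positive: int
    n_total: int
    fraction: float


def segment_positive_nuclei(
    frame: np.ndarray,
    min_area_px: int = DEFAULT_MIN_AREA_PX,
    min_separation_px: int = 5,
) -> np.ndarray:
    """Instance mask of dye-positive nuclei in one fluorescence frame.

    Otsu threshold -> binary mask -> distance-transform watershed (seeds
    are local maxima at least ``min_separation_px`` apart, roughly half
    the expected nucleus diameter) -> components below ``min_area_px``
    dropped as noise specks.  A constant frame yields an empty mask with
    a warning.
    """
    frame = np.asarray(frame, dtype=np.float64)
    if frame.ndim != 2:
        raise ValueError("expected a single-channel 2-D frame")
    out = np.zeros(frame.shape, dtype=np.int32)
    if frame.max() == frame.min():
        warnings.warn("constant frame: no Otsu split possible, returning empty mask")
        return out
    # Otsu with a robust noise floor: on a signal-free frame Otsu merely
    # bisects the noise, so require the threshold to also clear the
    # background level by six robust standard deviations
    median = np.median(frame)
    robust_sd = 1.4826 * np.median(np.abs(frame - median))
    threshold = max(filters.threshold_otsu(frame), median + 6.0 * robust_sd)
    binary = frame > threshold
    if not binary.any():
        return out
    distance = ndimage.distance_transform_edt(binary)
    peaks = feature.peak_local_max(
        distance, min_distance=max(1, int(min_separation_px)), labels=binary,
        exclude_border=False,
    )
    if len(peaks) == 0:
        return out
    markers = np.zeros(frame.shape, dtype=np.int32)
    markers[tuple(peaks.T)] = np.arange(1, len(peaks) + 1)
    labels = segmentation.watershed(-distance, markers, mask=binary)
    next_label = 1
    for prop in measure.regionprops(labels):
        if prop.area < min_area_px:
            continue
        out[labels == prop.label] = next_label
        next_label += 1
    return out


def viability_fraction(positive_mask: np.ndarray, nuclei: NucleiCount) -> ViabilityResult:
    """Positive-instance count over the total-cell denominator."""
    if nuclei.count <= 0:
        raise ValueError("total cell count must be positive")
    labels = np.unique(np.asarray(positive_mask))
    n_positive = int((labels > 0).sum())
    return ViabilityResult(
        n_positive=n_positive,
        n_total=nuclei.count,
        fraction=n_positive / nuclei.count,
    )


def viability_series(
    frames: np.ndarray,
    nuclei: NucleiCount,
    min_area_px: int = DEFAULT_MIN_AREA_PX,
) -> list[ViabilityResult]:
    """Per-frame viability fractions for a fluorescence video."""
    return [
        viability_fraction(segment_positive_nuclei(f, min_area_px=min_area_px), nuclei)
        for f in np.asarray(frames)
    ]
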