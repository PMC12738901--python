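"""Per-frame round-cell detections and the total-cell denominator.

The primary contract is mask-in / detections-out: instance label masks from
an external detector (e.g. a trained star-convex segmentation model) are
converted to a tabular form with physical areas and diameters.  A built-in
classical blob detector closes the loop on synthetic imagery where round
cells appear as bright rings with dark interiors; it is a fixture-level
device and makes no claim about real microscope data.

Cell size S (pixel count of the mask) maps to an equivalent-circle
diameter via S = pi * R**2, D = 2 R.  Detections with D > 18 µm are
classed as mother cells, the rest as daughters.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import filters, measure, morphology, segmentation

from .io_formats import LabelMaskStack

__all__ = [
    "NucleiCount",
    "SIZE_THRESHOLD_UM",
    "DETECTION_COLUMNS",
    "area_to_diameter",
    "diameter_to_area",
    "classify_size",
    "masks_to_detections",
    "detect_round_cells_classical",
    "match_detections",
    "count_nuclei",
]

SIZE_THRESHOLD_UM = 18.0

DETECTION_COLUMNS = [
    "frame_index",
    "time_min",
    "instance_label",
    "area_px",
    "area_um2",
    "diameter_um",
    "centroid_row",
    "centroid_col",
    "size_class",
]


@dataclass
class NucleiCount:
    """Total number of cells in the FOV, fixed for the whole video."""

    count: int
    source: str = "external-mask"

    def __post_init__(self) -> None:
        self.count = int(self.count)
        if self.count < 0:
            raise ValueError("nuclei count must be non-negative")


def area_to_diameter(area_um2: np.ndarray | float) -> np.ndarray | float:
    """Equivalent-circle diameter D = 2*sqrt(S/pi) in µm."""
    return 2.0 * np.sqrt(np.asarray(area_um2, dtype=float) / np.pi)


def diameter_to_area(diameter_um: np.ndarray | float) -> np.ndarray | float:
    """Inverse of :func:`area_to_diameter`: S = pi*(D/2)**2."""
    return np.pi * (np.asarray(diameter_um, dtype=float) / 2.0) ** 2


def classify_size(diameter_um: float, threshold_um: float = SIZE_THRESHOLD_UM) -> str:
    """'mother' for diameters strictly above the threshold, else 'daughter'."""
    return "mother" if diameter_um > threshold_um else "daughter"


def masks_to_detections(
    masks: LabelMaskStack,
    frame_interval: float,
    origin_time: float = 0.0,
    size_threshold_um: float = SIZE_THRESHOLD_UM,
) -> pd.DataFrame:
    """One row per instance per frame, with physical area and diameter.

    Areas use the mask's own pixel calibration:
    area_um2 = area_px * pixel_size**2.  Zero-pixel labels cannot occur in
    a label image and instances touching the border are kept.
    """
    ps2 = masks.pixel_size**2
    records: list[dict] = []
    for frame_index in range(masks.n_frames):
        frame = masks.masks[frame_index]
        if frame.max() == 0:
            continue
        time_min = origin_time + frame_index * frame_interval
        for prop in measure.regionprops(frame):
            area_px = int(prop.area)
            if area_px < 1:  # pragma: no cover - defensive
                warnings.warn(f"skipping zero-pixel label {prop.label}")
                continue
            area_um2 = area_px * ps2
            diameter = float(area_to_diameter(area_um2))
            records.append(
                {
                    "frame_index": frame_index,
                    "time_min": time_min,
                    "instance_label": int(prop.label),
                    "area_px": area_px,
                    "area_um2": area_um2,
                    "diameter_um": diameter,
                    "centroid_row": float(prop.centroid[0]),
                    "centroid_col": float(prop.centroid[1]),
                    "size_class": classify_size(diameter, size_threshold_um),
                }
            )
    return pd.DataFrame(records, columns=DETECTION_COLUMNS)


def detect_round_cells_classical(
    frame: np.ndarray,
    pixel_size: float,
    diameter_range: tuple[float, float] = (10.0, 25.0),
    circularity_min: float = 0.8,
) -> np.ndarray:
    """Segment bright-ring round cells in one preprocessed [0, 1] frame.

    Bright ring pixels are thresholded (Otsu), the enclosed dark interiors
    filled, touching cells split by a watershed on the distance transform,
    and components kept only if their circularity 4*pi*A/P**2 reaches
    ``circularity_min`` and their equivalent diameter lies within
    ``diameter_range`` (µm).  Returns an int32 instance label mask.
    """
    lo_d, hi_d = diameter_range
    if not (lo_d > 0 and hi_d > lo_d):
        raise ValueError(f"empty or invalid diameter range {diameter_range}")
    frame = np.asarray(frame, dtype=np.float64)
    out = np.zeros(frame.shape, dtype=np.int32)
    if frame.max() - frame.min() < 1e-3:
        return out

    binary = frame > filters.threshold_otsu(frame)
    binary = ndimage.binary_fill_holes(binary)
    min_area_px = int(diameter_to_area(lo_d) / pixel_size**2 * 0.25)
    binary = ndimage.binary_opening(binary, iterations=1)
    # split touching round cells on the distance transform; markers are
    # h-maxima so that only maxima separated by a genuinely deep saddle
    # (two abutting discs) split, while the flat EDT ridge of an elongated
    # blob stays a single marker and fails the circularity test downstream
    distance = ndimage.distance_transform_edt(binary)
    h = max(1.0, 0.15 * (lo_d / 2.0) / pixel_size)
    maxima = morphology.h_maxima(distance, h)
    markers, n_markers = ndimage.label(maxima)
    if n_markers == 0:
        return out
    labels = segmentation.watershed(-distance, markers, mask=binary)

    next_label = 1
    for prop in measure.regionprops(labels):
        if prop.area < max(min_area_px, 4):
            continue
        diameter = float(area_to_diameter(prop.area * pixel_size**2))
        if not (lo_d <= diameter <= hi_d):
            continue
        perimeter = prop.perimeter
        if perimeter == 0:
            continue
        circularity = 4.0 * np.pi * prop.area / perimeter**2
        if circularity < circularity_min:
            continue
        out[labels == prop.label] = next_label
        next_label += 1
    return out


def match_detections(
    truth_mask: np.ndarray,
    predicted_mask: np.ndarray,
    max_dist_px: float = 5.0,
) -> tuple[int, int, int]:
    """Greedy centroid matching of predicted to ground-truth instances.

    Returns (true positives, false positives, false negatives); each truth
    instance matches at most one prediction within ``max_dist_px``.
    """
    truth_centroids = np.array(
        [p.centroid for p in measure.regionprops(np.asarray(truth_mask))]
    ).reshape(-1, 2)
    pred_centroids = np.array(
        [p.centroid for p in measure.regionprops(np.asarray(predicted_mask))]
    ).reshape(-1, 2)
    n_truth, n_pred = len(truth_centroids), len(pred_centroids)
    if n_truth == 0 or n_pred == 0:
        return 0, n_pred, n_truth
    dists = np.linalg.norm(
        truth_centroids[:, None, :] - pred_centroids[None, :, :], axis=-1
    )
    tp = 0
    used_pred: set[int] = set()
    for t_idx in np.argsort(dists.min(axis=1)):
        order = np.argsort(dists[t_idx])
        for p_idx in order:
            if dists[t_idx, p_idx] > max_dist_px:
                break
            if p_idx not in used_pred:
                used_pred.add(int(p_idx))
                tp += 1
                break
    return tp, n_pred - tp, n_truth - tp


def count_nuclei(source: LabelMaskStack | int) -> NucleiCount:
    """Total-cell denominator from the first-frame nuclei mask.

    Accepts either a label mask stack (distinct positive labels in frame 0)
    or an integer ground-truth count from the synthetic generator.
    """
    if isinstance(source, LabelMaskStack):
        return NucleiCount(count=source.n_instances(0), source="external-mask")
    if isinstance(source, (int, np.integer)):
        return NucleiCount(count=int(source), source="ground-truth")
    raise TypeError("count_nuclei needs a LabelMaskStack or an integer count")
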