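"""Illumination-dose bookkeeping in J/cm².

The areal light dose is power x time / illuminated area:

* widefield: the full field of view (e.g. 0.014 cm²) is illuminated for
  the exposure time, so dose = n_repeats * P * t_exposure / A_FOV;
* point scanning: each pixel receives the beam for the dwell time, so the
  per-pixel dose = P * t_dwell / A_pixel (the conventional per-pixel
  number; a whole-frame average is a separate derived report).

Powers are as measured at the sample; no transmission modelling.
Internal values are exact; rounding to display precision happens only at
the reporting layer.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "IlluminationRegime",
    "areal_dose",
    "duration_for_dose",
    "pixel_area_from_dimension",
    "percent_of_max",
    "regime_from_dict",
]


@dataclass
class IlluminationRegime:
    """A widefield exposure or a scanning dwell regime.

    Parameters
    ----------
    mode
        'widefield' or 'scanning'.
    power_w
        Power at the sample in watts.
    duration_s
        Exposure time (widefield) or per-pixel dwell time (scanning), s.
    area_cm2
        Illuminated area: FOV for widefield, single-pixel area for scanning.
    n_repeats
        Number of identical exposure events.
    max_power_w
        Optional system maximum, for percent-of-max reporting.
    """

    mode: str
    power_w: float
    duration_s: float
    area_cm2: float
    n_repeats: int = 1
    max_power_w: float | None = None
    label: str = ""

    def __post_init__(self) -> None:
        if self.mode not in ("widefield", "scanning"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.power_w < 0:
            raise ValueError("power must be non-negative")
        if self.duration_s < 0:
            raise ValueError("duration must be non-negative")
        if not self.area_cm2 > 0:
            raise ValueError("area must be positive")
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be at least 1")


def areal_dose(regime: IlluminationRegime) -> float:
    """Areal dose in J/cm²: n_repeats * power * duration / area."""
    return regime.n_repeats * regime.power_w * regime.duration_s / regime.area_cm2


def duration_for_dose(target_j_cm2: float, power_w: float, area_cm2: float) -> float:
    """Exposure/dwell time in s delivering ``target_j_cm2`` (inverse of dose)."""
    if not power_w > 0:
        raise ValueError("power must be positive to invert the dose")
    if not area_cm2 > 0:
        raise ValueError("area must be positive")
    if target_j_cm2 < 0:
        raise ValueError("target dose must be non-negative")
    return target_j_cm2 * area_cm2 / power_w


def pixel_area_from_dimension(side_um: float) -> tuple[float, float]:
    """(µm², cm²) of a square scan pixel of the given side length.

    1 µm² = 1e-8 cm².  A zero side is accepted but flagged degenerate by
    returning zeros (such a regime cannot be dosed).
    """
    if side_um < 0:
        raise ValueError("pixel side must be non-negative")
    um2 = side_um**2
    return um2, um2 * 1e-8


def percent_of_max(power_w: float, max_power_w: float) -> float:
    """100 * power / max, rounded to one decimal for reporting."""
    if not max_power_w > 0:
        raise ValueError("maximum power must be positive")
    return round(100.0 * power_w / max_power_w, 1)


def regime_from_dict(spec: dict) -> IlluminationRegime:
    """Build a regime from a YAML/JSON mapping.

    Scanning regimes may give ``pixel_um`` instead of ``area_cm2``; powers
    may be given in mW (``power_mw`` / ``max_power_mw``) and dwell times in
    µs (``dwell_us``).
    """
    spec = dict(spec)
    if "power_mw" in spec:
        spec["power_w"] = spec.pop("power_mw") * 1e-3
    if "max_power_mw" in spec:
        spec["max_power_w"] = spec.pop("max_power_mw") * 1e-3
    if "dwell_us" in spec:
        spec["duration_s"] = spec.pop("dwell_us") * 1e-6
    if "pixel_um" in spec:
        _, spec["area_cm2"] = pixel_area_from_dimension(spec.pop("pixel_um"))
    allowed = {
        "mode", "power_w", "duration_s", "area_cm2", "n_repeats", "max_power_w", "label",
    }
    unknown = set(spec) - allowed
    if unknown:
        raise ValueError(f"unknown regime keys: {sorted(unknown)}")
    return IlluminationRegime(**spec)
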