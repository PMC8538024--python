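"""Geometric eyelid metrology: calibration, MRD1/MRD2/LF, grading.

Distances are vertical (y-axis) pixel distances at the reflex x-column,
converted to mm by the fiducial-derived scale and read off in clinical
0.25-mm increments.  Conventions:

* MRD1 in an eye whose reflex is occluded by a ptotic lid is recorded as 0.
* Ground-truth / rater MRD1 is clamped at 0; model predictions are never
  clamped here.
* Quantization rounds half away from zero onto the 0.25-mm grid.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np

__all__ = [
    "MeasurementRecord",
    "mm_per_pixel",
    "quantize_mm",
    "measure_mrd1",
    "measure_mrd2",
    "measure_lf",
    "consensus",
    "grade_ptosis",
    "PTOSIS_GRADES",
]

QUANT_STEP_MM = 0.25


@dataclass(frozen=True)
class MeasurementRecord:
    """One eye's measurements in mm, from one source."""

    eye_id: str
    mrd1_mm: float | None = None
    mrd2_mm: float | None = None
    lf_mm: float | None = None
    source: str = "ground_truth"    # ground_truth | rater | model
    rater_id: str | None = None
    quantized: bool = False

    def __post_init__(self):
        if self.source not in ("ground_truth", "rater", "model"):
            raise ValueError(f"unknown source {self.source!r}")
        if self.source in ("ground_truth", "rater") and self.mrd1_mm is not None:
            if self.mrd1_mm < 0:
                raise ValueError("ground-truth/rater MRD1 must be clamped at 0")
        if self.quantized:
            for v in (self.mrd1_mm, self.mrd2_mm, self.lf_mm):
                if v is not None and abs(v / QUANT_STEP_MM - round(v / QUANT_STEP_MM)) > 1e-9:
                    raise ValueError(f"{v} is not a multiple of {QUANT_STEP_MM} mm")


def mm_per_pixel(fiducial_corners) -> float:
    """Scale factor from the 20x20-mm square fiducial.

    Returns 20 mm divided by the mean of the four side lengths in px.
    Corners must form a convex quadrilateral (in order).
    """
    corners = np.asarray(fiducial_corners, dtype=np.float64)
    if corners.shape != (4, 2):
        raise ValueError("need exactly 4 (x, y) corners")
    sides = np.roll(corners, -1, axis=0) - corners
    lengths = np.hypot(sides[:, 0], sides[:, 1])
    if np.any(lengths < 1e-9):
        raise ValueError("degenerate fiducial: coincident corners")
    # convexity: consistent sign of consecutive 2-d cross products
    nxt = np.roll(sides, -1, axis=0)
    cross = sides[:, 0] * nxt[:, 1] - sides[:, 1] * nxt[:, 0]
    if np.any(np.abs(cross) < 1e-9) or not (np.all(cross > 0) or np.all(cross < 0)):
        raise ValueError("degenerate fiducial: corners not a convex quadrilateral")
    return 20.0 / float(lengths.mean())


def quantize_mm(value_mm: float, step: float = QUANT_STEP_MM) -> float:
    """Round half away from zero onto the clinical ``step``-mm grid."""
    return float(np.sign(value_mm) * np.floor(abs(value_mm) / step + 0.5) * step)


def _vertical_mm(y_far: float, y_near: float, scale: float) -> float:
    return (y_far - y_near) * scale


def measure_mrd1(annotation, scale: float, *, quantize: bool = True) -> float:
    """MRD1: reflex center to upper lid margin, mm.

    Returns 0 when the annotation carries no reflex (ptotic convention).
    """
    if annotation.upper_margin_px is None:
        raise ValueError("annotation has no upper lid margin")
    if annotation.reflex_px is None:
        return 0.0
    raw = _vertical_mm(annotation.reflex_px[1], annotation.upper_margin_px[1], scale)
    raw = max(raw, 0.0)
    return quantize_mm(raw) if quantize else raw


def measure_mrd2(annotation, scale: float, *, quantize: bool = True) -> float:
    """MRD2: lower lid margin to reflex center, mm."""
    if annotation.lower_margin_px is None:
        raise ValueError("annotation has no lower lid margin")
    if annotation.reflex_px is None:
        raise ValueError("cannot measure MRD2 without a visible reflex")
    raw = _vertical_mm(annotation.lower_margin_px[1], annotation.reflex_px[1], scale)
    return quantize_mm(raw) if quantize else raw


def measure_lf(up_annotation, down_annotation, scale: float, *,
               quantize: bool = True) -> float:
    """Levator function: upper-lid travel from down-gaze to up-gaze, mm.

    Both annotations must be in a common reference frame.  A non-positive
    travel is physiologically inconsistent and triggers a warning.
    """
    if up_annotation is None or down_annotation is None:
        from .normalize import MergeExclusion
        raise MergeExclusion("missing a gaze annotation for levator function")
    raw = _vertical_mm(down_annotation.upper_margin_px[1],
                       up_annotation.upper_margin_px[1], scale)
    if raw <= 0:
        warnings.warn(f"levator travel {raw:.2f} mm is below the physiologic range",
                      stacklevel=2)
    return quantize_mm(raw) if quantize else raw


def consensus(rater_a: MeasurementRecord, rater_b: MeasurementRecord) -> MeasurementRecord:
    """Gold standard: the mean of two raters' values, not re-quantized."""
    if rater_a.eye_id != rater_b.eye_id:
        raise ValueError("consensus requires the same eye")

    def _mean(a, b, name):
        if (a is None) != (b is None):
            raise ValueError(f"both raters must provide {name}")
        return None if a is None else (a + b) / 2.0

    return MeasurementRecord(
        eye_id=rater_a.eye_id,
        mrd1_mm=_mean(rater_a.mrd1_mm, rater_b.mrd1_mm, "mrd1_mm"),
        mrd2_mm=_mean(rater_a.mrd2_mm, rater_b.mrd2_mm, "mrd2_mm"),
        lf_mm=_mean(rater_a.lf_mm, rater_b.lf_mm, "lf_mm"),
        source="ground_truth",
        quantized=False,
    )


PTOSIS_GRADES = ("none", "mild", "moderate", "severe")


def grade_ptosis(mrd1_mm: float) -> str:
    """Ptosis grade from MRD1 (half-open, lower-inclusive bins).

    severe [0, 2), moderate [2, 3), mild [3, 4), none >= 4 mm.
    """
    if mrd1_mm < 0:
        raise ValueError(f"MRD1 must be non-negative, got {mrd1_mm}")
    if mrd1_mm < 2:
        return "severe"
    if mrd1_mm < 3:
        return "moderate"
    if mrd1_mm < 4:
        return "mild"
    return "none"
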