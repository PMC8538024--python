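"""Photograph normalization: reflex-centered crops and up/down-gaze merging.

A "normalized eye photograph" is a square crop of side ``min(H, W) / 4``
centered on the corneal light reflex, resized to 256x256 with bilinear
interpolation.  For levator-function models the up-gaze and down-gaze crops
of the same eye are merged into a single 2:1 image (up above down, aligned on
the reflex x-coordinate) before the resize.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from PIL import Image

__all__ = [
    "NormalizedPatch",
    "MergeExclusion",
    "crop_primary",
    "merge_gazes",
    "resize_patch",
    "PATCH_SIZE",
]

PATCH_SIZE = 256
MIN_CROP_SIDE = 32


class MergeExclusion(Exception):
    """Up/down-gaze photographs could not be merged; the eye is excluded."""


@dataclass(frozen=True)
class NormalizedPatch:
    pixels: np.ndarray              # (256, 256, 3) uint8
    origin_px: tuple[int, int]      # crop top-left in the source image
    source_gaze: str                # "primary" | "merged"
    eye_id: str = ""

    def __post_init__(self):
        if self.pixels.shape[:2] != (PATCH_SIZE, PATCH_SIZE):
            raise ValueError(f"patch must be {PATCH_SIZE}x{PATCH_SIZE}, got {self.pixels.shape}")


def crop_side(image_shape: tuple[int, ...]) -> int:
    """Square crop side: floor of a quarter of the smaller image dimension."""
    return min(image_shape[0], image_shape[1]) // 4


def crop_primary(image: np.ndarray, reflex: tuple[float, float]
                 ) -> tuple[np.ndarray, tuple[int, int]]:
    """Square crop of side ``min(H, W) // 4`` centered on the reflex.

    When the square would exceed the image boundary it is shifted inward
    (never padded) so all returned pixels are real content.  Returns the crop
    and its top-left origin in the source frame.
    """
    h, w = image.shape[:2]
    s = crop_side(image.shape)
    if s < MIN_CROP_SIDE:
        raise ValueError(f"image too small: crop side {s} < {MIN_CROP_SIDE}")
    rx, ry = reflex
    if not (0 <= rx <= w - 1 and 0 <= ry <= h - 1):
        raise ValueError(f"reflex {reflex} outside image bounds {(h, w)}")
    x0 = int(np.clip(int(round(rx)) - s // 2, 0, w - s))
    y0 = int(np.clip(int(round(ry)) - s // 2, 0, h - s))
    return image[y0:y0 + s, x0:x0 + s].copy(), (x0, y0)


def merge_gazes(up_crop: np.ndarray | None, down_crop: np.ndarray | None) -> np.ndarray:
    """Vertically concatenate reflex-centered up- and down-gaze crops.

    Up-gaze on top, down-gaze below; both crops are already centered on their
    own reflex so the reflex x-columns coincide.  A missing crop raises
    :class:`MergeExclusion` (the "not well merged" bookkeeping signal).
    """
    if up_crop is None or down_crop is None:
        missing = "up" if up_crop is None else "down"
        raise MergeExclusion(f"{missing}-gaze crop unavailable")
    if up_crop.shape != down_crop.shape:
        raise ValueError(f"crop shape mismatch: {up_crop.shape} vs {down_crop.shape}")
    return np.concatenate([up_crop, down_crop], axis=0)


def resize_patch(crop: np.ndarray, *, source_gaze: str = "primary",
                 origin_px: tuple[int, int] = (0, 0), eye_id: str = "") -> NormalizedPatch:
    """Bilinear resample of a square or 2:1 crop to 256x256.

    Merged (2:1) images are squashed to the same square input size, accepting
    the aspect distortion.  A crop already at 256x256 passes through
    bit-identically.
    """
    if crop.size == 0:
        raise ValueError("empty input raster")
    h, w = crop.shape[:2]
    if h not in (w, 2 * w):
        raise ValueError(f"expected square or 2:1 crop, got {crop.shape}")
    if (h, w) == (PATCH_SIZE, PATCH_SIZE):
        pixels = crop.copy()
    else:
        pixels = np.asarray(
            Image.fromarray(crop).resize((PATCH_SIZE, PATCH_SIZE), Image.BILINEAR))
    return NormalizedPatch(pixels=pixels, origin_px=tuple(origin_px),
                           source_gaze=source_gaze, eye_id=eye_id)
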