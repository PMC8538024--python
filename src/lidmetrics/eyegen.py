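"""Synthetic periocular photograph generator with exact geometric ground truth.

Real clinical photographs for eyelid metrology are rarely shareable, so every
stage of the measurement pipeline is validated against rendered scenes whose
geometry is known analytically: a bright compact corneal light reflex, smooth
upper/lower lid margin arcs, an iris/pupil/sclera region, an optional
20x20-mm square fiducial, and (for up-/down-gaze pairs) a lid excursion of
exactly ``lf_mm`` between the two gazes.

Coordinate convention: 0-based pixels, x rightward, y downward, coordinates
refer to pixel centers.

Geometry
--------
Lid margins are parabolic arcs through three control points (apex at the
reflex x-column, canthi at the fissure corners).  For a scene in primary gaze
the upper apex sits ``mrd1_mm`` above the reflex center and the lower apex
``mrd2_mm`` below it.  Across gazes the globe (and reflex) rotates and the
upper lid travels exactly ``lf_mm`` from up-gaze to down-gaze:

=========  ========================  =================================
gaze       reflex y (rel. primary)   upper apex y (rel. gaze reflex)
=========  ========================  =================================
primary    0                         -mrd1
up         -0.15 * lf                -(mrd1 + 0.30 * lf)
down       +0.70 * lf                -(mrd1 + 0.15 * lf)
=========  ========================  =================================

so the absolute lid travel is (0.70 + 0.15)*lf + (0.30 - 0.15)*lf = lf, and
the reflex-relative margin offsets visible inside reflex-centered crops
jointly determine lf — which is what lets a patch-based levator-function
regressor learn from merged up/down crops.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .landmarks import LandmarkAnnotation

__all__ = [
    "EyeScene",
    "NoiseConfig",
    "DistributionConfig",
    "TABLE_DEFAULTS",
    "make_eye_scenes",
    "render_eye",
    "generate_dataset",
    "SyntheticDataset",
    "GeometryError",
]

# lid/globe kinematics across gazes (fractions of lf)
GLOBE_UP_SHIFT = 0.15     # globe rotates up by this fraction of lf in up-gaze
GLOBE_DOWN_SHIFT = 0.70   # globe rotates down by this fraction in down-gaze
LID_UP_EXTRA = 0.30       # extra lid elevation above the mrd1 offset in up-gaze
LID_DOWN_EXTRA = 0.15     # residual lid elevation above the reflex in down-gaze


class GeometryError(ValueError):
    """Scene geometry cannot be rendered (e.g. lid curves crossing)."""


@dataclass(frozen=True)
class EyeScene:
    """Parametric description of one synthetic periocular image.

    ``upper_apex_y``/``lower_apex_y`` are the exact lid-margin heights at the
    reflex x-column, in the image frame of this gaze.
    """

    subject_id: str
    side: str                       # "left" | "right"
    gaze: str                       # "primary" | "up" | "down"
    mrd1_mm: float
    mrd2_mm: float
    lf_mm: float
    mm_per_px: float = 0.2
    iris_radius_mm: float = 5.9
    fissure_halfwidth_mm: float = 14.0
    image_size: tuple[int, int] = (512, 512)   # (height, width)
    reflex_center_px: tuple[float, float] = (256.0, 256.0)
    upper_apex_y: float = 0.0
    lower_apex_y: float = 0.0
    fiducial_present: bool = True
    fiducial_origin_px: tuple[float, float] = (10.0, 10.0)

    def __post_init__(self):
        if self.side not in ("left", "right"):
            raise ValueError(f"side must be left|right, got {self.side!r}")
        if self.gaze not in ("primary", "up", "down"):
            raise ValueError(f"gaze must be primary|up|down, got {self.gaze!r}")
        if self.mrd1_mm < 0 or self.mrd2_mm <= 0 or self.lf_mm <= 0:
            raise ValueError("mrd1_mm must be >= 0 and mrd2_mm, lf_mm > 0")
        if self.mm_per_px <= 0:
            raise ValueError("mm_per_px must be positive")

    # -- derived quantities --------------------------------------------
    @property
    def eye_id(self) -> str:
        return f"{self.subject_id}_{self.side}"

    @property
    def image_id(self) -> str:
        return f"{self.subject_id}_{self.side}_{self.gaze}"

    @property
    def reflex_visible(self) -> bool:
        # visible iff the upper margin is strictly above the reflex center
        return self.upper_apex_y < self.reflex_center_px[1]

    @property
    def fiducial_corners_px(self) -> np.ndarray:
        x0, y0 = self.fiducial_origin_px
        side = 20.0 / self.mm_per_px
        return np.array([(x0, y0), (x0 + side, y0),
                         (x0 + side, y0 + side), (x0, y0 + side)])


def make_eye_scenes(subject_id: str, side: str, mrd1_mm: float, mrd2_mm: float,
                    lf_mm: float, *, mm_per_px: float = 0.2,
                    image_size: tuple[int, int] = (512, 512),
                    reflex_xy: tuple[float, float] | None = None,
                    fiducial: bool = True) -> dict[str, EyeScene]:
    """Build the primary/up/down-gaze scene triple for one eye.

    The three scenes share subject geometry; reflex position and lid apexes
    follow the gaze kinematics documented in the module docstring, so the
    up/down upper-apex positions differ by exactly ``lf_mm``.
    """
    h, w = image_size
    if reflex_xy is None:
        reflex_xy = (w / 2.0, h / 2.0)
    rx, ry0 = reflex_xy
    s = mm_per_px
    lf_px = lf_mm / s
    base = dict(subject_id=subject_id, side=side, mrd1_mm=mrd1_mm,
                mrd2_mm=mrd2_mm, lf_mm=lf_mm, mm_per_px=s,
                image_size=image_size, fiducial_present=fiducial)
    scenes = {}
    for gaze, (g_shift, lid_extra) in {
            "primary": (0.0, 0.0),
            "up": (-GLOBE_UP_SHIFT, LID_UP_EXTRA),
            "down": (GLOBE_DOWN_SHIFT, LID_DOWN_EXTRA)}.items():
        ry = ry0 + g_shift * lf_px
        apex_u = ry - (mrd1_mm / s + lid_extra * lf_px)
        apex_l = ry + mrd2_mm / s
        scenes[gaze] = EyeScene(gaze=gaze, reflex_center_px=(rx, ry),
                                upper_apex_y=apex_u, lower_apex_y=apex_l, **base)
    return scenes


@dataclass(frozen=True)
class NoiseConfig:
    """Additive pixel noise + coarse background texture + optional artifacts."""

    pixel_sigma: float = 4.0       # per-pixel Gaussian noise, 8-bit units
    texture_sigma: float = 6.0     # coarse background texture amplitude
    texture_scale: int = 32        # texture cell size, px
    mascara: bool = False          # dark lash band hugging the upper margin
    mascara_width_px: float = 5.0

    @classmethod
    def none(cls) -> "NoiseConfig":
        return cls(pixel_sigma=0.0, texture_sigma=0.0)


# flat colours; photorealism is an explicit non-goal
_SKIN = np.array([204.0, 168.0, 148.0])
_SCLERA = np.array([218.0, 215.0, 210.0])
_IRIS = np.array([92.0, 62.0, 40.0])
_PUPIL = np.array([26.0, 22.0, 22.0])
_MASCARA = np.array([32.0, 26.0, 26.0])
_FIDUCIAL_FILL = np.array([206.0, 206.0, 206.0])

REFLEX_SIGMA_PX = 2.0


def render_eye(scene: EyeScene, noise: NoiseConfig | None = None,
               seed: int = 0) -> tuple[np.ndarray, LandmarkAnnotation]:
    """Render one scene to an 8-bit RGB image plus its exact annotation.

    Deterministic given ``(scene, noise, seed)``.  Raises
    :class:`GeometryError` when the lid curves cross or the fissure leaves
    the image.
    """
    noise = NoiseConfig() if noise is None else noise
    h, w = scene.image_size
    if min(h, w) < 256:
        raise GeometryError(f"image must be at least 256x256, got {scene.image_size}")
    rx, ry = scene.reflex_center_px
    apex_u, apex_l = scene.upper_apex_y, scene.lower_apex_y
    if apex_u > apex_l:
        raise GeometryError(
            f"upper lid apex ({apex_u:.1f}) below lower lid apex ({apex_l:.1f}): curves cross")
    half_w = scene.fissure_halfwidth_mm / scene.mm_per_px
    corner_y = 0.5 * (apex_u + apex_l)
    lo = min(apex_u, corner_y)
    hi = max(apex_l, corner_y)
    if lo < 0 or hi > h - 1 or rx - half_w < 0 or rx + half_w > w - 1:
        raise GeometryError("eye fissure extends outside the image")

    rng = np.random.default_rng(seed)
    img = np.empty((h, w, 3), dtype=np.float64)
    img[:] = _SKIN

    if noise.texture_sigma > 0:
        cells = (h // noise.texture_scale + 2, w // noise.texture_scale + 2)
        coarse = rng.normal(0.0, noise.texture_sigma, cells)
        tex = np.kron(coarse, np.ones((noise.texture_scale, noise.texture_scale)))
        img += tex[:h, :w, None]

    xs = np.arange(w, dtype=np.float64)
    ys = np.arange(h, dtype=np.float64)[:, None]
    dx = xs[None, :] - rx
    # parabolic lid margins through apex and canthi
    cu = (corner_y - apex_u) / half_w ** 2
    cl = (apex_l - corner_y) / half_w ** 2
    upper = apex_u + cu * dx ** 2
    lower = apex_l - cl * dx ** 2
    in_span = np.abs(dx) <= half_w
    fissure = (ys >= upper) & (ys <= lower) & in_span

    img[fissure] = _SCLERA
    r2 = (xs[None, :] - rx) ** 2 + (ys - ry) ** 2
    r_iris = scene.iris_radius_mm / scene.mm_per_px
    iris = fissure & (r2 <= r_iris ** 2)
    img[iris] = _IRIS
    pupil = fissure & (r2 <= (0.38 * r_iris) ** 2)
    img[pupil] = _PUPIL

    if noise.mascara:
        band = (ys < upper) & (ys >= upper - noise.mascara_width_px) & in_span
        img[band] = _MASCARA

    if scene.reflex_visible:
        fx, fy = rx, ry
        g = np.exp(-((xs[None, :] - fx) ** 2 + (ys - fy) ** 2)
                   / (2.0 * REFLEX_SIGMA_PX ** 2))
        g = np.where(fissure, g, 0.0)  # the lid occludes the reflex
        img += (255.0 - img) * g[:, :, None]

    if scene.fiducial_present:
        _draw_fiducial(img, scene)

    if noise.pixel_sigma > 0:
        img += rng.normal(0.0, noise.pixel_sigma, img.shape)

    img = np.clip(img, 0, 255).astype(np.uint8)
    ann = LandmarkAnnotation(
        image_id=scene.image_id,
        reflex_px=(rx, ry) if scene.reflex_visible else None,
        upper_margin_px=(rx, apex_u),
        lower_margin_px=(rx, apex_l),
        source="ground_truth",
    )
    return img, ann


def _draw_fiducial(img: np.ndarray, scene: EyeScene) -> None:
    """20x20-mm square: light fill with a dark border, corners analytic."""
    x0f, y0f = scene.fiducial_origin_px
    side = 20.0 / scene.mm_per_px
    x0, y0 = int(round(x0f)), int(round(y0f))
    x1, y1 = int(round(x0f + side)), int(round(y0f + side))
    img[y0:y1 + 1, x0:x1 + 1] = _FIDUCIAL_FILL
    t = 2  # border thickness
    img[y0:y0 + t, x0:x1 + 1] = 30.0
    img[y1 - t + 1:y1 + 1, x0:x1 + 1] = 30.0
    img[y0:y1 + 1, x0:x0 + t] = 30.0
    img[y0:y1 + 1, x1 - t + 1:x1 + 1] = 30.0


# ---------------------------------------------------------------------------
# dataset generation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TruncatedNormal:
    """Truncated normal sampling spec; sd == 0 degenerates to a constant."""

    mean: float
    sd: float
    low: float
    high: float

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if self.sd == 0:
            return np.full(n, self.mean)
        a = (self.low - self.mean) / self.sd
        b = (self.high - self.mean) / self.sd
        return stats.truncnorm.rvs(a, b, loc=self.mean, scale=self.sd,
                                   size=n, random_state=rng)


@dataclass(frozen=True)
class DistributionConfig:
    """Population distributions for one synthetic cohort.

    Defaults follow the reported clinical summary statistics: MRD1
    2.59 (SD 1.21) mm on [0, 6], MRD2 5.51 (SD 0.83) mm on [1.5, 10], levator
    function 12.1 (SD 2.12) mm on [3.5, 18]; ~3.4% of eyelids are ptotic with
    no visible reflex (MRD1 recorded as 0).
    """

    mrd1: TruncatedNormal = field(default_factory=lambda: TruncatedNormal(2.59, 1.21, 0.0, 6.0))
    mrd2: TruncatedNormal = field(default_factory=lambda: TruncatedNormal(5.51, 0.83, 1.5, 10.0))
    lf: TruncatedNormal = field(default_factory=lambda: TruncatedNormal(12.1, 2.12, 3.5, 18.0))
    p_zero_mrd1: float = 0.034
    mm_per_px: float = 0.2
    image_size: tuple[int, int] = (512, 512)
    reflex_jitter_px: float = 8.0
    noise: NoiseConfig = field(default_factory=NoiseConfig)


TABLE_DEFAULTS = DistributionConfig()

MANIFEST_COLUMNS = [
    "subject_id", "eye_id", "side", "gaze", "image_path",
    "mrd1_mm", "mrd2_mm", "lf_mm", "reflex_x_px", "reflex_y_px",
    "reflex_visible", "mm_per_px",
]


@dataclass
class SyntheticDataset:
    """Manifest plus (optionally in-memory) rendered images and annotations."""

    manifest: pd.DataFrame
    images: dict[str, np.ndarray]
    annotations: dict[str, LandmarkAnnotation]
    scenes: dict[str, EyeScene]


def generate_dataset(n_subjects: int, dist: DistributionConfig | None = None,
                     seed: int = 0, out_dir=None) -> SyntheticDataset:
    """Generate a seeded cohort: 6 images per subject (2 eyes x 3 gazes).

    Ground-truth measurements are recorded in the manifest before any
    quantization.  With ``out_dir`` set, images are written as 8-bit PNG and
    the manifest as CSV; otherwise everything stays in memory.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    dist = TABLE_DEFAULTS if dist is None else dist
    rng = np.random.default_rng(seed)
    h, w = dist.image_size

    rows = []
    images: dict[str, np.ndarray] = {}
    annotations: dict[str, LandmarkAnnotation] = {}
    scenes: dict[str, EyeScene] = {}
    n_eyes = 2 * n_subjects
    mrd1 = dist.mrd1.sample(n_eyes, rng)
    mrd2 = dist.mrd2.sample(n_eyes, rng)
    lf = dist.lf.sample(n_eyes, rng)
    if dist.p_zero_mrd1 > 0:
        mrd1[rng.random(n_eyes) < dist.p_zero_mrd1] = 0.0

    eye_idx = 0
    for si in range(n_subjects):
        subject_id = f"S{si:04d}"
        for side in ("right", "left"):
            jx, jy = rng.uniform(-dist.reflex_jitter_px, dist.reflex_jitter_px, 2)
            triple = make_eye_scenes(
                subject_id, side, float(mrd1[eye_idx]), float(mrd2[eye_idx]),
                float(lf[eye_idx]), mm_per_px=dist.mm_per_px,
                image_size=dist.image_size,
                reflex_xy=(w / 2.0 + jx, h / 2.0 + jy))
            for gaze, scene in triple.items():
                render_seed = int(rng.integers(0, 2 ** 31 - 1))
                img, ann = render_eye(scene, dist.noise, seed=render_seed)
                images[scene.image_id] = img
                annotations[scene.image_id] = ann
                scenes[scene.image_id] = scene
                rows.append({
                    "subject_id": subject_id,
                    "eye_id": scene.eye_id,
                    "side": side,
                    "gaze": gaze,
                    "image_path": f"{scene.image_id}.png",
                    "mrd1_mm": scene.mrd1_mm,
                    "mrd2_mm": scene.mrd2_mm,
                    "lf_mm": scene.lf_mm,
                    "reflex_x_px": scene.reflex_center_px[0],
                    "reflex_y_px": scene.reflex_center_px[1],
                    "reflex_visible": scene.reflex_visible,
                    "mm_per_px": scene.mm_per_px,
                    "upper_margin_y_px": scene.upper_apex_y,
                    "lower_margin_y_px": scene.lower_apex_y,
                })
            eye_idx += 1

    manifest = pd.DataFrame(rows)
    if out_dir is not None:
        from pathlib import Path
        from PIL import Image
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for image_id, img in images.items():
            Image.fromarray(img).save(out / f"{image_id}.png")
        manifest.to_csv(out / "manifest.csv", index=False)
    return SyntheticDataset(manifest, images, annotations, scenes)
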