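"""Corneal light-reflex localization.

Two routes to the same coordinate:

* a deterministic classical detector — top-percentile thresholding followed by
  the intensity-weighted centroid of the brightest compact connected
  component — which serves as the measurement oracle and as a label source
  for unannotated photographs;
* a trained convolutional coordinate-regression network predicting the
  normalized (X, Y) of the reflex, mirroring the lightweight-regressor
  approach used for smartphone photographs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, asdict

import numpy as np
from skimage import measure
from skimage.transform import resize as _sk_resize

from . import nn

log = logging.getLogger(__name__)

__all__ = [
    "LandmarkAnnotation",
    "ReflexDetection",
    "detect_reflex_classical",
    "ReflexRegressor",
    "train_reflex_regressor",
    "locate_reflex",
]


@dataclass(frozen=True)
class LandmarkAnnotation:
    """Reflex coordinate and lid-margin reference points for one image.

    ``reflex_px`` is ``None`` when the reflex is occluded (ptotic lid).
    Margin points are taken at the reflex x-column.
    """

    image_id: str
    reflex_px: tuple[float, float] | None
    upper_margin_px: tuple[float, float]
    lower_margin_px: tuple[float, float]
    source: str = "ground_truth"  # ground_truth | classical | regressor

    def __post_init__(self):
        if self.source not in ("ground_truth", "classical", "regressor"):
            raise ValueError(f"unknown annotation source {self.source!r}")


@dataclass(frozen=True)
class ReflexDetection:
    x: float
    y: float
    confidence: float  # blob compactness in [0, 1]


def _to_gray(image: np.ndarray) -> np.ndarray:
    if image.ndim == 3:
        return image[..., :3] @ np.array([0.299, 0.587, 0.114])
    return image.astype(np.float64)


def detect_reflex_classical(image: np.ndarray, *, percentile: float = 99.5,
                            min_area: int = 3, max_area: int | None = None,
                            min_peak: float = 235.0) -> ReflexDetection | None:
    """Locate the light reflex as the brightest compact bright blob.

    Thresholds at the top ``percentile`` of grayscale intensity, labels the
    connected components whose area lies in ``[min_area, max_area]``, picks
    the one with the highest peak intensity and returns its intensity-weighted
    centroid.  Returns ``None`` ("reflex not found") when no component
    qualifies or the candidate peak is dimmer than ``min_peak`` — the ptotic
    no-reflex case.

    Confidence is the blob's isoperimetric compactness ``4*pi*A / P**2``
    clipped to [0, 1].
    """
    gray = _to_gray(image)
    if max_area is None:
        max_area = max(64, int(gray.size * 0.002))
    thr = np.percentile(gray, percentile)
    mask = gray > thr
    if not mask.any():
        return None
    labels = measure.label(mask, connectivity=2)
    best = None
    best_peak = -np.inf
    for region in measure.regionprops(labels, intensity_image=gray):
        if not (min_area <= region.area <= max_area):
            continue
        peak = region.intensity_max
        if peak > best_peak:
            best_peak, best = peak, region
    if best is None or best_peak < min_peak:
        return None
    rr, cc = best.coords[:, 0], best.coords[:, 1]
    wgt = gray[rr, cc] - thr
    total = wgt.sum()
    if total <= 0:
        return None
    cy = float((rr * wgt).sum() / total)
    cx = float((cc * wgt).sum() / total)
    if best.perimeter > 0:
        conf = float(np.clip(4.0 * np.pi * best.area / best.perimeter ** 2, 0.0, 1.0))
    else:
        conf = 1.0
    return ReflexDetection(cx, cy, conf)


# ---------------------------------------------------------------------------
# coordinate-regression network
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ReflexTrainConfig:
    """Hyperparameters of the reflex coordinate regressor.

    The network is a small convolutional stack ending in a single-channel
    response map and a spatial soft-argmax, so the MSE on normalized
    coordinates trains a blob localizer with sub-cell precision.
    """

    input_size: int = 128       # network input resolution (square, grayscale)
    batch_size: int = 32
    epochs: int = 10
    max_lr: float = 3e-3
    channels: tuple[int, ...] = (8, 16)   # one 2x pool after each
    refine_channels: int = 16             # full-resolution conv before the map

    def config_hash(self) -> str:
        return hashlib.sha256(json.dumps(asdict(self), sort_keys=True).encode()).hexdigest()[:16]


def _build_coord_net(cfg: ReflexTrainConfig, rng: np.random.Generator) -> nn.Sequential:
    layers: list[nn.Layer] = []
    c_in = 1
    for c in cfg.channels:
        layers += [nn.Conv2d(c_in, c, rng), nn.ReLU(), nn.MaxPool2d()]
        c_in = c
    layers += [nn.Conv2d(c_in, cfg.refine_channels, rng), nn.ReLU(),
               nn.Conv2d(cfg.refine_channels, 1, rng, k=1, pad=0),
               nn.SoftArgmax2d()]
    return nn.Sequential(layers)


def _prep_images(images: list[np.ndarray], input_size: int) -> np.ndarray:
    """Grayscale, resize to the network input, scale to [0, 1], NCHW."""
    out = np.empty((len(images), 1, input_size, input_size), dtype=np.float32)
    for i, img in enumerate(images):
        g = _to_gray(img) / 255.0
        if g.shape != (input_size, input_size):
            g = _sk_resize(g, (input_size, input_size), order=1, anti_aliasing=True)
        out[i, 0] = g
    return out


@dataclass
class ReflexRegressor:
    """Trained coordinate-regression model predicting normalized (X, Y)."""

    net: nn.Sequential
    config: ReflexTrainConfig
    train_image_shape: tuple[int, int]  # (height, width) the model was trained on

    def predict(self, image: np.ndarray) -> tuple[float, float]:
        h, w = image.shape[:2]
        if (h, w) != self.train_image_shape:
            log.warning("image size %s differs from training size %s; resizing",
                        (h, w), self.train_image_shape)
        x = _prep_images([image], self.config.input_size)
        ux, uy = self.net.forward(x)[0]
        # denormalize by the *input* image dimensions, clip to its bounds
        px = float(np.clip(ux * w, 0, w - 1))
        py = float(np.clip(uy * h, 0, h - 1))
        return px, py

    # -- checkpoint -----------------------------------------------------
    def save(self, path) -> None:
        meta = {"config": asdict(self.config),
                "config_hash": self.config.config_hash(),
                "train_image_shape": list(self.train_image_shape)}
        state = self.net.state_dict()
        np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
                 **state)

    @classmethod
    def load(cls, path) -> "ReflexRegressor":
        with np.load(path) as data:
            meta = json.loads(bytes(data["__meta__"]).decode())
            cfg_d = meta["config"]
            cfg_d["channels"] = tuple(cfg_d["channels"])
            cfg = ReflexTrainConfig(**cfg_d)
            net = _build_coord_net(cfg, np.random.default_rng(0))
            net.load_state_dict({k: data[k] for k in data.files if k != "__meta__"})
        return cls(net, cfg, tuple(meta["train_image_shape"]))


def train_reflex_regressor(images: list[np.ndarray],
                           coords: np.ndarray,
                           config: ReflexTrainConfig | None = None,
                           seed: int = 0) -> ReflexRegressor:
    """Train the reflex regressor on images with known reflex coordinates.

    ``coords`` holds one (x, y) pixel coordinate per image; targets are
    normalized by image width/height into [0, 1] and fitted with MSE.
    Deterministic given ``seed`` (weight init, batch order, dropout masks).
    """
    config = ReflexTrainConfig() if config is None else config
    coords = np.asarray(coords, dtype=np.float64)
    if len(images) < 50:
        raise ValueError(f"need at least 50 training images, got {len(images)}")
    if coords.shape != (len(images), 2):
        raise ValueError("coords must be (n_images, 2)")
    if not np.isfinite(coords).all():
        raise ValueError("training coordinates contain missing/non-finite values")
    h, w = images[0].shape[:2]
    x = _prep_images(images, config.input_size)
    y = (coords / np.array([w, h])).astype(np.float32)
    rng = np.random.default_rng(seed)
    net = _build_coord_net(config, rng)
    nn.fit_regressor(net, x, y, epochs=config.epochs, batch_size=config.batch_size,
                     max_lr=config.max_lr, seed=int(rng.integers(0, 2 ** 31 - 1)))
    return ReflexRegressor(net, config, (h, w))


def locate_reflex(model: ReflexRegressor, image: np.ndarray) -> tuple[float, float]:
    """Forward pass of the trained regressor, in pixel coordinates."""
    return model.predict(image)
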