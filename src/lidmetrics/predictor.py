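"""MRD1/MRD2/LF regression on normalized eye patches.

Training recipe: normalized 256x256 patches, horizontal-flip and random-
rotation augmentation, minibatches of 32, Adam on an MSE loss with a
one-cycle cosine learning-rate schedule, dropout between 0.25 and 0.5,
5-fold cross-validation, and a final ensemble that averages the fold models'
outputs.  The backbone is a small convolutional regression network sized for
CPU training; capacity is a config knob.

The modelling surface follows the Model/Results idiom:

>>> model = EyelidRegression(patches, targets_mm, target="mrd1")
>>> results = model.fit()
>>> print(results.summary())
>>> results.predict(new_patches)
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage
from sklearn.model_selection import KFold

from . import nn
from .landmarks import _prep_images, _to_gray

log = logging.getLogger(__name__)

__all__ = [
    "TrainConfig",
    "SplitPlan",
    "split_dataset",
    "augment",
    "EyelidRegression",
    "EyelidRegressionResults",
    "EnsembleModel",
    "train_cv",
    "predict",
]

TARGETS = ("mrd1", "mrd2", "lf")


@dataclass(frozen=True)
class TrainConfig:
    """Hyperparameters of one eyelid-regression training run.

    ``input_size`` is the normalized-patch resolution; ``net_input_size`` is
    the (smaller) resolution the backbone actually consumes, a CPU-scale
    concession that trades receptive-field resolution for speed.
    """

    input_size: int = 256
    net_input_size: int = 64
    batch_size: int = 32
    dropout: float = 0.3
    folds: int = 5
    max_epochs: int = 40
    max_lr: float = 3e-3
    rotation_limit_deg: float = 15.0
    hflip_prob: float = 0.5
    channels: tuple[int, ...] = (8, 16, 32)
    hidden: int = 64
    seed: int = 0

    def __post_init__(self):
        if not 0.25 <= self.dropout <= 0.5:
            raise ValueError(f"dropout must lie in [0.25, 0.5], got {self.dropout}")
        if self.folds < 2:
            raise ValueError("need at least 2 folds")
        if self.batch_size < 1 or self.max_epochs < 1:
            raise ValueError("batch_size and max_epochs must be positive")

    def config_hash(self) -> str:
        return hashlib.sha256(json.dumps(asdict(self), sort_keys=True).encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# data splitting
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SplitPlan:
    """Random partition plan: 10% test, then 80/20 train/validation.

    ``unit='subject'`` keeps both eyes of a person in the same partition
    (no left/right leakage); ``unit='eye'`` randomizes individual eyes,
    reproducing photograph-level randomization.
    """

    unit: str = "subject"
    test_fraction: float = 0.10
    val_fraction_within_trainval: float = 0.20

    def __post_init__(self):
        if self.unit not in ("subject", "eye"):
            raise ValueError("unit must be 'subject' or 'eye'")
        if not (0 < self.test_fraction < 1 and 0 <= self.val_fraction_within_trainval < 1):
            raise ValueError("fractions out of range")


def partition_counts(n_units: int, test_fraction: float = 0.10,
                     val_fraction: float = 0.20) -> tuple[int, int, int]:
    """(train, val, test) unit counts under floor arithmetic.

    822 units at 10% test -> 740 train/val and 82 test; 685 -> 617/68;
    a 740-unit train/val pool at 80/20 -> 592 train, 148 validation.
    """
    n_test = int(np.floor(n_units * test_fraction))
    n_trainval = n_units - n_test
    n_val = int(np.floor(n_trainval * val_fraction))
    return n_trainval - n_val, n_val, n_test


def split_dataset(manifest: pd.DataFrame, plan: SplitPlan | None = None,
                  seed: int = 0) -> pd.DataFrame:
    """Assign every manifest row a partition label at the plan's unit level.

    Returns a copy with a ``partition`` column in {train, val, test}.
    Deterministic given ``seed``; no unit lands in two partitions.
    """
    plan = SplitPlan() if plan is None else plan
    if manifest.empty:
        raise ValueError("manifest is empty")
    key = "subject_id" if plan.unit == "subject" else "eye_id"
    units = np.sort(manifest[key].unique())
    if len(units) < 3:
        raise ValueError(f"fewer units ({len(units)}) than partitions")
    rng = np.random.default_rng(seed)
    rng.shuffle(units)
    n_train, n_val, n_test = partition_counts(
        len(units), plan.test_fraction, plan.val_fraction_within_trainval)
    labels = {}
    for u in units[:n_test]:
        labels[u] = "test"
    for u in units[n_test:n_test + n_val]:
        labels[u] = "val"
    for u in units[n_test + n_val:]:
        labels[u] = "train"
    out = manifest.copy()
    out["partition"] = out[key].map(labels)
    return out


# ---------------------------------------------------------------------------
# augmentation
# ---------------------------------------------------------------------------

def augment(patch: np.ndarray, config: TrainConfig,
            rng: np.random.Generator | int = 0) -> np.ndarray:
    """Horizontal flip (w.p. ``hflip_prob``) + uniform random rotation.

    Rotation uses reflection padding and bilinear resampling.  Measurement
    targets are lengths, invariant to both transforms, so labels are
    unchanged.  Deterministic given the generator/seed.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    out = patch.astype(np.float32, copy=True)
    if rng.random() < config.hflip_prob:
        out = out[:, ::-1].copy()
    if config.rotation_limit_deg > 0:
        angle = rng.uniform(-config.rotation_limit_deg, config.rotation_limit_deg)
        out = ndimage.rotate(out, angle, axes=(1, 0), reshape=False,
                             order=1, mode="reflect")
    if np.issubdtype(patch.dtype, np.integer):
        out = np.clip(np.rint(out), 0, 255).astype(patch.dtype)
    return out


def _augment_batch(xb: np.ndarray, rng: np.random.Generator,
                   config: TrainConfig) -> np.ndarray:
    """Batched NCHW version used inside the training loop."""
    out = xb.copy()
    for i in range(len(out)):
        if rng.random() < config.hflip_prob:
            out[i] = out[i, :, :, ::-1]
        if config.rotation_limit_deg > 0:
            angle = rng.uniform(-config.rotation_limit_deg, config.rotation_limit_deg)
            out[i, 0] = ndimage.rotate(out[i, 0], angle, reshape=False,
                                       order=1, mode="reflect")
    return out


# ---------------------------------------------------------------------------
# ensemble model
# ---------------------------------------------------------------------------

def _build_backbone(cfg: TrainConfig, rng: np.random.Generator) -> nn.Sequential:
    layers: list[nn.Layer] = []
    c_in, size = 1, cfg.net_input_size
    for c in cfg.channels:
        layers += [nn.Conv2d(c_in, c, rng), nn.ReLU(), nn.MaxPool2d()]
        c_in, size = c, size // 2
    layers += [nn.Flatten(), nn.Dropout(cfg.dropout),
               nn.Dense(c_in * size * size, cfg.hidden, rng), nn.ReLU(),
               nn.Dense(cfg.hidden, 1, rng)]
    return nn.Sequential(layers)


@dataclass
class _FoldMember:
    net: nn.Sequential
    y_mean: float
    y_std: float

    def predict(self, x: np.ndarray) -> np.ndarray:
        raw = nn.predict_in_batches(self.net, x).ravel()
        return raw * self.y_std + self.y_mean


@dataclass
class EnsembleModel:
    """Cross-validation ensemble: the mean of the fold models' outputs, mm."""

    members: list[_FoldMember]
    target: str
    config: TrainConfig

    @property
    def config_hash(self) -> str:
        return self.config.config_hash()

    def _check(self):
        if len(self.members) != self.config.folds:
            raise ValueError(
                f"ensemble integrity: {len(self.members)} members != {self.config.folds} folds")

    def predict_prepared(self, x: np.ndarray) -> np.ndarray:
        self._check()
        preds = np.stack([m.predict(x) for m in self.members])
        return preds.mean(axis=0)

    def predict(self, patches) -> np.ndarray:
        """Predict mm values for normalized patches (never quantized)."""
        x = _prepare_patches(patches, self.config.net_input_size)
        return self.predict_prepared(x)

    # -- checkpointing --------------------------------------------------
    def save(self, directory) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        index = {"target": self.target, "config": asdict(self.config),
                 "config_hash": self.config_hash, "folds": []}
        for i, m in enumerate(self.members):
            fname = f"fold{i}.npz"
            np.savez(directory / fname, **m.net.state_dict())
            index["folds"].append({"file": fname, "y_mean": m.y_mean, "y_std": m.y_std})
        (directory / "ensemble.json").write_text(json.dumps(index, indent=2))

    @classmethod
    def load(cls, directory) -> "EnsembleModel":
        directory = Path(directory)
        index = json.loads((directory / "ensemble.json").read_text())
        cfg_d = index["config"]
        cfg_d["channels"] = tuple(cfg_d["channels"])
        cfg = TrainConfig(**cfg_d)
        members = []
        for fold in index["folds"]:
            net = _build_backbone(cfg, np.random.default_rng(0))
            with np.load(directory / fold["file"]) as data:
                net.load_state_dict(dict(data))
            members.append(_FoldMember(net, fold["y_mean"], fold["y_std"]))
        return cls(members, index["target"], cfg)


def _prepare_patches(patches, net_input_size: int) -> np.ndarray:
    """Accept NormalizedPatch objects, arrays or lists thereof -> NCHW."""
    from .normalize import NormalizedPatch
    if isinstance(patches, NormalizedPatch):
        patches = [patches]
    elif isinstance(patches, np.ndarray) and patches.ndim == 3:
        patches = [patches]
    imgs = [p.pixels if isinstance(p, NormalizedPatch) else p for p in patches]
    return _prep_images(imgs, net_input_size)


# ---------------------------------------------------------------------------
# model / results
# ---------------------------------------------------------------------------

class EyelidRegression:
    """Eyelid-measurement regression model over normalized patches.

    Parameters
    ----------
    patches : sequence of NormalizedPatch or (H, W, 3) arrays
    targets_mm : per-patch measurement in mm
    target : "mrd1" | "mrd2" | "lf"
    config : TrainConfig
    """

    def __init__(self, patches, targets_mm, target: str = "mrd1",
                 config: TrainConfig | None = None):
        if target not in TARGETS:
            raise ValueError(f"target must be one of {TARGETS}")
        self.config = TrainConfig() if config is None else config
        self.target = target
        self.x = _prepare_patches(patches, self.config.net_input_size)
        self.y = np.asarray(targets_mm, dtype=np.float64).ravel()
        if len(self.x) != len(self.y):
            raise ValueError("patch/target length mismatch")
        if not np.isfinite(self.y).all():
            raise ValueError(f"{target} targets contain missing values")

    @classmethod
    def from_manifest(cls, manifest: pd.DataFrame, patches: dict,
                      target: str = "mrd1", config: TrainConfig | None = None,
                      partition: str | None = None) -> "EyelidRegression":
        """Build from a manifest whose eye_ids key the ``patches`` dict."""
        rows = manifest if partition is None else manifest[manifest["partition"].isin(
            ["train", "val"] if partition == "trainval" else [partition])]
        eye_ids = rows["eye_id"].unique()
        eye_ids = [e for e in eye_ids if e in patches]
        per_eye = rows.drop_duplicates("eye_id").set_index("eye_id")
        y = per_eye.loc[eye_ids, f"{target}_mm"].to_numpy()
        return cls([patches[e] for e in eye_ids], y, target, config)

    def fit(self, verbose: bool = False) -> "EyelidRegressionResults":
        """Train the 5-fold cross-validation ensemble."""
        cfg = self.config
        n = len(self.y)
        if n < cfg.folds:
            raise ValueError(f"need at least {cfg.folds} samples, got {n}")
        kf = KFold(n_splits=cfg.folds, shuffle=True, random_state=cfg.seed)
        master = np.random.default_rng(cfg.seed)
        members, rows = [], []
        for fold, (tr, va) in enumerate(kf.split(self.x)):
            fold_seed = int(master.integers(0, 2 ** 31 - 1))
            rng = np.random.default_rng(fold_seed)
            net = _build_backbone(cfg, rng)
            y_mean = float(self.y[tr].mean())
            y_std = float(self.y[tr].std()) or 1.0
            ytr = ((self.y[tr] - y_mean) / y_std).astype(np.float32)
            try:
                nn.fit_regressor(
                    net, self.x[tr], ytr,
                    epochs=cfg.max_epochs, batch_size=cfg.batch_size,
                    max_lr=cfg.max_lr, seed=fold_seed,
                    augment_fn=lambda xb, r: _augment_batch(xb, r, cfg))
            except FloatingPointError as err:
                raise FloatingPointError(f"fold {fold}: {err}") from err
            member = _FoldMember(net, y_mean, y_std)
            pv = member.predict(self.x[va])
            mae = float(np.abs(pv - self.y[va]).mean())
            mse = float(((pv - self.y[va]) ** 2).mean())
            rows.append({"fold": fold, "n_train": len(tr), "n_val": len(va),
                         "val_mae_mm": mae, "val_mse_mm2": mse})
            members.append(member)
            if verbose:
                log.info("%s fold %d: val MAE %.3f mm", self.target, fold, mae)
        ensemble = EnsembleModel(members, self.target, cfg)
        return EyelidRegressionResults(self, ensemble, pd.DataFrame(rows))


@dataclass
class EyelidRegressionResults:
    """Fitted ensemble plus per-fold validation metrics."""

    model: EyelidRegression
    ensemble: EnsembleModel
    fold_metrics: pd.DataFrame

    def predict(self, patches) -> np.ndarray:
        return self.ensemble.predict(patches)

    def summary(self) -> str:
        fm = self.fold_metrics
        lines = [
            f"Eyelid regression results — target: {self.model.target}",
            f"n = {len(self.model.y)}, folds = {self.ensemble.config.folds}, "
            f"backbone channels = {self.ensemble.config.channels}",
            "-" * 56,
            fm.to_string(index=False,
                         formatters={"val_mae_mm": "{:.3f}".format,
                                     "val_mse_mm2": "{:.3f}".format}),
            "-" * 56,
            f"mean fold validation MAE: {fm['val_mae_mm'].mean():.3f} mm",
        ]
        return "\n".join(lines)


def train_cv(patches, targets_mm, target: str = "mrd1",
             config: TrainConfig | None = None
             ) -> tuple[EnsembleModel, pd.DataFrame]:
    """Functional wrapper: fit the CV ensemble, return it with fold metrics."""
    results = EyelidRegression(patches, targets_mm, target, config).fit()
    return results.ensemble, results.fold_metrics


def predict(model: EnsembleModel, patch) -> float | np.ndarray:
    """Ensemble prediction in mm (mean of member outputs, never quantized)."""
    out = model.predict(patch)
    return float(out[0]) if out.size == 1 else out
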