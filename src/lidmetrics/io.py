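"""Manifest I/O and validation.

The manifest is the dataset's single source of truth: one CSV row per image,
keyed by ``(eye_id, gaze)``, carrying the ground-truth measurements (mm,
pre-quantization), the reflex coordinate and the pixel scale, plus whatever
partition labels or exclusion flags later stages append.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .eyegen import MANIFEST_COLUMNS

__all__ = ["read_manifest", "write_manifest", "validate_manifest", "ManifestError"]


class ManifestError(ValueError):
    pass


def validate_manifest(manifest: pd.DataFrame) -> pd.DataFrame:
    if manifest.empty:
        raise ManifestError("manifest is empty")
    missing = [c for c in MANIFEST_COLUMNS if c not in manifest.columns]
    if missing:
        raise ManifestError(f"manifest missing required columns: {', '.join(missing)}")
    dup = manifest.duplicated(subset=["eye_id", "gaze"])
    if dup.any():
        keys = manifest.loc[dup, ["eye_id", "gaze"]].to_records(index=False).tolist()
        raise ManifestError(f"duplicate eye/gaze rows: {keys[:5]}")
    for col in ("mrd1_mm", "mrd2_mm", "lf_mm", "mm_per_px"):
        if manifest[col].isna().any():
            bad = manifest.loc[manifest[col].isna(), "eye_id"].tolist()
            raise ManifestError(f"missing {col} for eyes {bad[:5]}")
    return manifest


def _canonical_order(manifest: pd.DataFrame) -> pd.DataFrame:
    extras = [c for c in manifest.columns if c not in MANIFEST_COLUMNS]
    return manifest[MANIFEST_COLUMNS + extras]


def read_manifest(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists() or path.stat().st_size == 0:
        raise ManifestError(f"empty or missing manifest file: {path}")
    try:
        manifest = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.EmptyDataError as err:
        raise ManifestError(f"empty manifest file: {path}") from err
    validate_manifest(manifest)
    return _canonical_order(manifest)


def write_manifest(manifest: pd.DataFrame, path) -> None:
    validate_manifest(manifest)
    # %.17g keeps the write-read round trip exact for float64 columns
    _canonical_order(manifest).to_csv(path, index=False, float_format="%.17g")
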