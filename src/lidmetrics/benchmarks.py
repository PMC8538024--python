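"""Self-contained verification benchmarks.

Each function recomputes, from scratch, one of the quantities used to verify
the package: cohort-partition arithmetic, the internal consistency of the
published Bland-Altman confidence intervals and limits of agreement, ICC
oracle equivalence, limits-of-agreement coverage, the generator/metrology
geometry round trip, reflex localization accuracy, and end-to-end MRD1
parameter recovery on synthetic data.

The published summary numbers used as *inputs* here (sample sizes, bias CIs,
demographic counts) are the values printed in the clinical study this
pipeline mirrors; everything else is computed by running the package.
"""

from __future__ import annotations

import numpy as np

from . import eyegen, evalstats, landmarks, metrology, normalize, pipeline, predictor

# ---------------------------------------------------------------------------
# published inputs (sample sizes, printed CIs, printed counts)
# ---------------------------------------------------------------------------

#: printed 95% CIs of the Bland-Altman bias and test-group sizes per model
PUBLISHED_BIAS_CI = {
    "mrd1": ((-0.1090, 0.1015), 82),
    "mrd2": ((-0.05347, 0.1646), 82),
    "lf": ((-0.3658, 0.2713), 68),
}

#: printed demographic counts: (numerator, denominator) per percentage
PUBLISHED_COUNTS = {
    "women_of_volunteers": (344, 411),
    "males_of_mrd1_eyes": (154, 822),
    "males_of_mrd1_test": (12, 82),
    "males_of_lf_eyes": (122, 685),
}

#: study-conditions cohort for desk-scale synthetic experiments: Table-style
#: measurement distributions at a reduced render resolution (256 px, 0.4
#: mm/px) that preserves the crop's 25.6-mm field of view.
BENCH_DIST = eyegen.DistributionConfig(mm_per_px=0.4, image_size=(256, 256),
                                       reflex_jitter_px=5.0)
REFLEX_DIST = eyegen.DistributionConfig(mm_per_px=0.4, image_size=(256, 256),
                                        reflex_jitter_px=12.0)


def split_arithmetic() -> dict[str, int]:
    """Partition sizes for the published cohort sizes under the 90/10 + 80/20 plan."""
    tr822, va822, te822 = predictor.partition_counts(822)
    tr685, va685, te685 = predictor.partition_counts(685)
    return {
        "trainval_822": tr822 + va822,
        "test_822": te822,
        "trainval_685": tr685 + va685,
        "test_685": te685,
        "train_of_740": tr822,
        "val_of_740": va822,
    }


def bland_altman_consistency() -> dict[str, dict[str, float]]:
    """Invert each published bias CI and rebuild the limits of agreement."""
    out = {}
    for target, (ci, n) in PUBLISHED_BIAS_CI.items():
        bias, sd = evalstats.recover_sd_from_ci(ci, n)
        loa_low = bias - evalstats.LOA_MULTIPLIER * sd
        loa_high = bias + evalstats.LOA_MULTIPLIER * sd
        out[target] = {"bias": bias, "sd_diff": sd,
                       "loa_low": round(loa_low, 2), "loa_high": round(loa_high, 2)}
    return out


def demographic_arithmetic() -> dict[str, float]:
    """Percentages implied by the printed counts, at printed (1-dp) precision."""
    return {name: round(100.0 * num / den, 1)
            for name, (num, den) in PUBLISHED_COUNTS.items()}


def _bruteforce_icc(table: np.ndarray, form: str) -> float:
    """Definitional sums-of-squares oracle, independent of evalstats."""
    x = np.asarray(table, float)
    n, k = x.shape
    grand = x.sum() / (n * k)
    ss_rows = sum(k * (x[i].sum() / k - grand) ** 2 for i in range(n))
    ss_cols = sum(n * (x[:, j].sum() / n - grand) ** 2 for j in range(k))
    ss_tot = sum((x[i, j] - grand) ** 2 for i in range(n) for j in range(k))
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = (ss_tot - ss_rows - ss_cols) / ((n - 1) * (k - 1))
    if form == "agreement":
        return (msr - mse) / (msr + mse + (2.0 / n) * (msc - mse))
    return (msr - mse) / (msr + mse)


def icc_oracle_deviation(seed: int, n_tables: int = 100) -> float:
    """Max |icc - oracle| over random 10x2 tables, both forms."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_tables):
        table = rng.normal(0, 2, (10, 1)) + rng.normal(0, 1, (10, 2))
        table[:, 1] += rng.normal(0, 0.5)
        for form in ("agreement", "consistency"):
            dev = abs(evalstats.icc(table, form) - _bruteforce_icc(table, form))
            worst = max(worst, dev)
    return worst


def loa_coverage(seed: int, n: int = 5000) -> float:
    """Fraction of Gaussian differences inside the computed limits of agreement."""
    rng = np.random.default_rng(seed)
    a = rng.normal(3.0, 1.2, n)
    b = a - rng.normal(0.0, 0.5, n)
    ba = evalstats.bland_altman(a, b)
    d = a - b
    return float(np.mean((d > ba.loa[0]) & (d < ba.loa[1])))


def geometry_roundtrip(seed: int, n_eyes: int = 100) -> dict[str, float]:
    """Measure rendered annotations back into mm and compare with ground truth.

    Returns the worst absolute error (mm, pre-quantization) per quantity and
    the worst deviation of the quantized values from the 0.25-mm grid.
    """
    n_subjects = (n_eyes + 1) // 2
    ds = eyegen.generate_dataset(n_subjects, BENCH_DIST, seed=seed)
    scale = BENCH_DIST.mm_per_px
    err = {"mrd1": 0.0, "mrd2": 0.0, "lf": 0.0}
    grid_dev = 0.0
    count = 0
    for eye_id, group in ds.manifest.groupby("eye_id"):
        rows = {r.gaze: r for r in group.itertuples()}
        ann = {g: ds.annotations[f"{eye_id}_{g}"] for g in rows}
        truth = rows["primary"]
        m1 = metrology.measure_mrd1(ann["primary"], scale, quantize=False)
        err["mrd1"] = max(err["mrd1"], abs(m1 - truth.mrd1_mm))
        if ann["primary"].reflex_px is not None:
            m2 = metrology.measure_mrd2(ann["primary"], scale, quantize=False)
            err["mrd2"] = max(err["mrd2"], abs(m2 - truth.mrd2_mm))
            q2 = metrology.measure_mrd2(ann["primary"], scale)
            grid_dev = max(grid_dev, abs(q2 / 0.25 - round(q2 / 0.25)))
        lf = metrology.measure_lf(ann["up"], ann["down"], scale, quantize=False)
        err["lf"] = max(err["lf"], abs(lf - truth.lf_mm))
        q1 = metrology.measure_mrd1(ann["primary"], scale)
        qlf = metrology.measure_lf(ann["up"], ann["down"], scale)
        for q in (q1, qlf):
            grid_dev = max(grid_dev, abs(q / 0.25 - round(q / 0.25)))
        count += 1
    return {"n_eyes": count, "max_err_mrd1_mm": err["mrd1"],
            "max_err_mrd2_mm": err["mrd2"], "max_err_lf_mm": err["lf"],
            "max_quantization_grid_dev": grid_dev,
            "tolerance_mm": 1.0 * scale}


def _reflex_pool(n_subjects: int, seed: int):
    """Rendered images with a visible reflex, plus their true coordinates."""
    ds = eyegen.generate_dataset(n_subjects, REFLEX_DIST, seed=seed)
    images, coords = [], []
    for image_id, ann in ds.annotations.items():
        if ann.reflex_px is None:
            continue
        images.append(ds.images[image_id])
        coords.append(ann.reflex_px)
    return images, np.asarray(coords)


def classical_detector_error(seed: int, n_renders: int = 100) -> float:
    """Worst localization error (px) of the classical detector, noise-free."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    done = 0
    i = 0
    while done < n_renders:
        i += 1
        mrd1 = float(rng.uniform(1.0, 5.5))
        scene = eyegen.make_eye_scenes(
            f"R{i}", "right", mrd1, float(rng.uniform(3.5, 8.0)),
            float(rng.uniform(8.0, 16.0)), mm_per_px=0.4, image_size=(256, 256),
            reflex_xy=(128 + rng.uniform(-10, 10), 128 + rng.uniform(-10, 10)))["primary"]
        if scene.reflex_center_px[1] - scene.upper_apex_y < 6.0:
            continue
        img, ann = eyegen.render_eye(scene, eyegen.NoiseConfig.none(), seed=i)
        det = landmarks.detect_reflex_classical(img)
        worst = max(worst, float(np.hypot(det.x - ann.reflex_px[0],
                                          det.y - ann.reflex_px[1])))
        done += 1
    return worst


def reflex_regressor_benchmark(seed: int, n_train: int = 600,
                               n_test: int = 100) -> dict[str, float]:
    """Train the coordinate regressor and measure held-out localization error."""
    train_imgs, train_xy = _reflex_pool(n_subjects=(n_train + 5) // 6 + 8, seed=seed)
    test_imgs, test_xy = _reflex_pool(n_subjects=(n_test + 5) // 6 + 6, seed=seed + 1)
    train_imgs, train_xy = train_imgs[:n_train], train_xy[:n_train]
    test_imgs, test_xy = test_imgs[:n_test], test_xy[:n_test]
    model = landmarks.train_reflex_regressor(train_imgs, train_xy, seed=seed)
    errs = [float(np.hypot(*(np.subtract(model.predict(img), xy))))
            for img, xy in zip(test_imgs, test_xy)]
    return {"n_train": len(train_imgs), "n_test": len(test_imgs),
            "median_err_px": float(np.median(errs)),
            "mean_err_px": float(np.mean(errs))}


def mrd1_recovery(seed: int, n_subjects: int = 350,
                  max_epochs: int = 12) -> dict[str, float]:
    """End-to-end MRD1 recovery: simulate, normalize, split, train CV ensemble,
    evaluate held-out MAE and predicted-vs-true correlation."""
    ds = eyegen.generate_dataset(n_subjects, BENCH_DIST, seed=seed)
    primary, _, _ = pipeline.build_patches(ds, ground_truth_reflex=True)
    manifest = predictor.split_dataset(ds.manifest, seed=seed + 1)
    cfg = predictor.TrainConfig(net_input_size=64, max_epochs=max_epochs, seed=seed + 2)
    model = predictor.EyelidRegression.from_manifest(
        manifest, primary, target="mrd1", config=cfg, partition="trainval")
    results = model.fit()
    test = manifest[manifest["partition"] == "test"].drop_duplicates("eye_id")
    eye_ids = [e for e in test["eye_id"] if e in primary]
    actual = test.set_index("eye_id").loc[eye_ids, "mrd1_mm"].to_numpy()
    predicted = results.predict([primary[e] for e in eye_ids])
    report = evalstats.build_report(actual, predicted)
    return {"n_train": int(len(model.y)), "n_test": int(report.n),
            "test_mae_mm": report.mae, "pearson_r": report.pearson_r,
            "mean_fold_val_mae_mm": float(results.fold_metrics["val_mae_mm"].mean())}
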