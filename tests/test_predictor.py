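"""Splits, augmentation, CV training and the ensemble contract."""

import numpy as np
import pandas as pd
import pytest

from lidmetrics import predictor
from lidmetrics.predictor import (EnsembleModel, EyelidRegression, SplitPlan,
                                  TrainConfig, augment, partition_counts,
                                  split_dataset)


def fake_manifest(n_eyes):
    rows = []
    for i in range(n_eyes):
        rows.append({"subject_id": f"S{i // 2}", "eye_id": f"E{i}",
                     "side": "right" if i % 2 else "left", "gaze": "primary",
                     "mrd1_mm": 3.0, "mrd2_mm": 5.0, "lf_mm": 12.0})
    return pd.DataFrame(rows)


class TestSplitArithmetic:
    @pytest.mark.parametrize("n,expected", [
        (822, (592, 148, 82)),
        (685, (494, 123, 68)),
    ])
    def test_partition_counts(self, n, expected):
        assert partition_counts(n) == expected
        train, val, test = expected
        assert train + val == {822: 740, 685: 617}[n]

    def test_740_trainval_splits_592_148(self):
        train, val, _ = partition_counts(822)
        assert (train, val) == (592, 148)

    def test_split_dataset_by_eye(self):
        manifest = fake_manifest(822)
        out = split_dataset(manifest, SplitPlan(unit="eye"), seed=0)
        counts = out["partition"].value_counts()
        assert counts["test"] == 82
        assert counts["train"] + counts["val"] == 740

    def test_no_unit_in_two_partitions(self):
        manifest = fake_manifest(100)
        out = split_dataset(manifest, SplitPlan(unit="subject"), seed=1)
        per_subject = out.groupby("subject_id")["partition"].nunique()
        assert (per_subject == 1).all()

    def test_deterministic_given_seed(self):
        manifest = fake_manifest(60)
        a = split_dataset(manifest, seed=3)
        b = split_dataset(manifest, seed=3)
        assert a["partition"].equals(b["partition"])
        c = split_dataset(manifest, seed=4)
        assert not a["partition"].equals(c["partition"])

    def test_too_few_units(self):
        with pytest.raises(ValueError, match="fewer units"):
            split_dataset(fake_manifest(2), SplitPlan(unit="eye"))


class TestTrainConfig:
    def test_dropout_bounds_enforced(self):
        TrainConfig(dropout=0.25)
        TrainConfig(dropout=0.5)
        with pytest.raises(ValueError, match="dropout"):
            TrainConfig(dropout=0.1)
        with pytest.raises(ValueError, match="dropout"):
            TrainConfig(dropout=0.6)

    def test_defaults_match_recipe(self):
        cfg = TrainConfig()
        assert cfg.batch_size == 32 and cfg.folds == 5 and cfg.input_size == 256


class TestAugment:
    def _patch(self):
        rng = np.random.default_rng(0)
        return (rng.random((64, 64, 3)) * 255).astype(np.uint8)

    def test_pure_flip(self):
        cfg = TrainConfig(hflip_prob=1.0, rotation_limit_deg=0.0)
        p = self._patch()
        assert np.array_equal(augment(p, cfg, 0), p[:, ::-1])

    def test_noop_config_identity(self):
        cfg = TrainConfig(hflip_prob=0.0, rotation_limit_deg=0.0)
        p = self._patch()
        assert np.array_equal(augment(p, cfg, 0), p)

    def test_deterministic_given_seed(self):
        cfg = TrainConfig()
        p = self._patch()
        assert np.array_equal(augment(p, cfg, 7), augment(p, cfg, 7))

    def test_rotation_keeps_shape_and_dtype(self):
        cfg = TrainConfig(hflip_prob=0.0, rotation_limit_deg=15.0)
        p = self._patch()
        out = augment(p, cfg, 1)
        assert out.shape == p.shape and out.dtype == p.dtype


class _StubMember:
    def __init__(self, value):
        self.value = value

    def predict(self, x):
        return np.full(len(x), self.value, dtype=float)


class TestEnsemble:
    def _ensemble(self, values, folds=5):
        cfg = TrainConfig()
        return EnsembleModel([_StubMember(v) for v in values], "mrd1", cfg)

    def test_mean_of_members(self):
        ens = self._ensemble([1, 2, 3, 4, 5])
        assert ens.predict_prepared(np.zeros((1, 1, 8, 8)))[0] == pytest.approx(3.0)

    def test_identical_members_equal_single(self):
        ens = self._ensemble([2.5] * 5)
        assert ens.predict_prepared(np.zeros((2, 1, 8, 8)))[0] == pytest.approx(2.5)

    def test_member_count_integrity(self):
        ens = self._ensemble([1, 2, 3])
        with pytest.raises(ValueError, match="integrity"):
            ens.predict_prepared(np.zeros((1, 1, 8, 8)))

    def test_variance_reduction(self):
        """Averaged outputs never have higher MSE than the member average."""
        rng = np.random.default_rng(0)
        truth = rng.normal(3, 1, 50)
        members = [truth + rng.normal(0, 0.5, 50) for _ in range(5)]
        ens = np.mean(members, axis=0)
        mse_members = [np.mean((m - truth) ** 2) for m in members]
        assert np.mean((ens - truth) ** 2) <= np.mean(mse_members) + 1e-12


@pytest.fixture(scope="module")
def tiny_patches():
    rng = np.random.default_rng(0)
    return [(rng.random((256, 256, 3)) * 255).astype(np.uint8) for _ in range(25)]


class TestTraining:
    def test_constant_target_regression(self, tiny_patches):
        cfg = TrainConfig(net_input_size=32, max_epochs=40, rotation_limit_deg=0.0,
                          hflip_prob=0.0)
        res = EyelidRegression(tiny_patches, [3.0] * 25, "mrd1", cfg).fit()
        for _, row in res.fold_metrics.iterrows():
            assert row["val_mae_mm"] <= 0.1
        preds = res.predict(tiny_patches[:3])
        assert np.allclose(preds, 3.0, atol=0.1)

    def test_fold_sizes_partition_data(self, tiny_patches):
        cfg = TrainConfig(net_input_size=32, max_epochs=1)
        res = EyelidRegression(tiny_patches, [3.0] * 25, "mrd1", cfg).fit()
        assert len(res.fold_metrics) == 5
        assert res.fold_metrics["n_val"].sum() == 25
        assert (res.fold_metrics["n_val"] == 5).all()

    def test_missing_targets_rejected(self, tiny_patches):
        with pytest.raises(ValueError, match="missing"):
            EyelidRegression(tiny_patches, [np.nan] * 25, "mrd1",
                             TrainConfig(net_input_size=32))

    def test_ensemble_checkpoint_roundtrip(self, tiny_patches, tmp_path):
        cfg = TrainConfig(net_input_size=32, max_epochs=1)
        res = EyelidRegression(tiny_patches, [3.0] * 25, "mrd1", cfg).fit()
        res.ensemble.save(tmp_path / "ens")
        loaded = EnsembleModel.load(tmp_path / "ens")
        a = res.ensemble.predict(tiny_patches[0])
        b = loaded.predict(tiny_patches[0])
        assert a == pytest.approx(b)

    def test_summary_mentions_target_and_folds(self, tiny_patches):
        cfg = TrainConfig(net_input_size=32, max_epochs=1)
        res = EyelidRegression(tiny_patches, [3.0] * 25, "mrd1", cfg).fit()
        s = res.summary()
        assert "mrd1" in s and "folds = 5" in s
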