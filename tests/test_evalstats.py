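"""Agreement statistics: error metrics, Pearson, ICC, Bland-Altman, reports."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from lidmetrics.evalstats import (REPORT_ROW_LABELS, MethodAgreement,
                                  bland_altman, build_report, error_metrics,
                                  icc, pearson, recover_sd_from_ci)


def brute_force_icc(table, form):
    """Independent oracle: definitional sums of squares of the two-way layout."""
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


class TestErrorMetrics:
    def test_arithmetic(self):
        assert error_metrics([1, 2], [2, 4]) == (1.5, 2.5)
        assert error_metrics([3], [3.5]) == (0.5, 0.25)

    def test_identity(self):
        assert error_metrics([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == (0.0, 0.0)

    def test_errors(self):
        with pytest.raises(ValueError, match="mismatch"):
            error_metrics([1, 2], [1])
        with pytest.raises(ValueError, match="empty"):
            error_metrics([], [])

    @given(st.lists(st.floats(-10, 10), min_size=1, max_size=30),
           st.data())
    @settings(max_examples=50, derandomize=True)
    def test_nonnegative_and_zero_iff(self, a, data):
        b = data.draw(st.lists(st.floats(-10, 10), min_size=len(a), max_size=len(a)))
        mae, mse = error_metrics(a, b)
        assert mae >= 0 and mse >= 0
        assert (mse == 0) == (mae == 0)


class TestPearson:
    def test_perfect_linear(self):
        a = np.arange(10.0)
        assert pearson(a, 2 * a + 1) == pytest.approx(1.0)
        assert pearson(a, -a) == pytest.approx(-1.0)

    def test_independent_series_near_zero(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(size=1000), rng.normal(size=1000)
        assert abs(pearson(a, b)) < 0.1

    def test_zero_variance_undefined(self):
        with pytest.raises(ValueError, match="zero-variance"):
            pearson([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestICC:
    def test_identical_columns(self):
        a = np.arange(10.0)
        table = np.column_stack([a, a])
        assert icc(table, "agreement") == pytest.approx(1.0)
        assert icc(table, "consistency") == pytest.approx(1.0)

    def test_constant_offset_consistency_one(self):
        a = np.arange(10.0)
        table = np.column_stack([a, a + 1.0])
        assert icc(table, "consistency") == pytest.approx(1.0)
        assert icc(table, "agreement") < 1.0

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            subj = rng.normal(0, 2, (10, 1))
            table = subj + rng.normal(0, 1, (10, 2)) + np.array([[0.0, rng.normal()]])
            for form in ("agreement", "consistency"):
                assert icc(table, form) == pytest.approx(
                    brute_force_icc(table, form), abs=1e-10)

    def test_matches_pingouin_reference(self):
        """Cross-check against the published R-convention implementations."""
        pg = pytest.importorskip("pingouin")
        import pandas as pd
        rng = np.random.default_rng(3)
        table = rng.normal(5, 2, (15, 1)) + rng.normal(0, 1, (15, 2))
        long = pd.DataFrame({
            "subject": np.repeat(np.arange(15), 2),
            "rater": np.tile(["a", "b"], 15),
            "score": table.ravel()})
        res = pg.intraclass_corr(long, targets="subject", raters="rater",
                                 ratings="score").set_index("Type")
        assert icc(table, "agreement") == pytest.approx(res.loc["ICC(A,1)", "ICC"], abs=1e-9)
        assert icc(table, "consistency") == pytest.approx(res.loc["ICC(C,1)", "ICC"], abs=1e-9)

    def test_agreement_never_exceeds_consistency_when_column_effect(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            table = rng.normal(0, 2, (12, 1)) + rng.normal(0, 0.5, (12, 2))
            table[:, 1] += 1.5  # strong method offset -> MSC > MSE
            assert icc(table, "agreement") <= icc(table, "consistency") + 1e-12

    def test_errors(self):
        with pytest.raises(ValueError, match="constant"):
            icc(np.ones((5, 2)))
        with pytest.raises(ValueError, match="missing"):
            icc(np.array([[1.0, np.nan], [2, 2], [3, 3]]))
        with pytest.raises(ValueError, match="n x 2"):
            icc(np.ones((5, 3)))


class TestBlandAltman:
    def test_zero_differences(self):
        a = np.array([1.0, 2.0, 3.0])
        ba = bland_altman(a, a)
        assert ba.bias == 0.0 and ba.sd_diff == 0.0 and ba.loa == (0.0, 0.0)

    def test_simple_arithmetic(self):
        ba = bland_altman([0.0, 1.0, 3.0], [1.0, 1.0, 2.0])
        # d = [-1, 0, 1]: bias 0, sd 1, loa +-1.96
        assert ba.bias == pytest.approx(0.0)
        assert ba.sd_diff == pytest.approx(1.0)
        assert ba.loa == pytest.approx((-1.96, 1.96))
        assert ba.bias_ci[0] < ba.bias < ba.bias_ci[1]

    def test_loa_identity(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(5, 1, 50), rng.normal(5, 1, 50)
        ba = bland_altman(a, b)
        assert ba.loa[0] == pytest.approx(ba.bias - 1.96 * ba.sd_diff)
        assert ba.loa[1] == pytest.approx(ba.bias + 1.96 * ba.sd_diff)

    def test_coverage_converges_to_95_percent(self):
        rng = np.random.default_rng(12345)
        d = rng.normal(0.1, 0.5, 5000)
        ba = bland_altman(d, np.zeros(5000))
        frac = np.mean((d > ba.loa[0]) & (d < ba.loa[1]))
        assert frac == pytest.approx(0.95, abs=0.01)


class TestRecoverSdFromCi:
    def test_midpoint_bias(self):
        bias, _ = recover_sd_from_ci((-0.5, 0.5), 30)
        assert bias == 0.0

    def test_forward_backward_consistency(self):
        rng = np.random.default_rng(2)
        a = rng.normal(4, 1, 82)
        b = a - rng.normal(-0.004, 0.479, 82)
        ba = bland_altman(a, b)
        bias, sd = recover_sd_from_ci(ba.bias_ci, ba.n)
        assert bias == pytest.approx(ba.bias, abs=1e-9)
        assert sd == pytest.approx(ba.sd_diff, abs=1e-9)

    def test_published_ci_inversion(self):
        bias, sd = recover_sd_from_ci((-0.1090, 0.1015), 82)
        assert bias == pytest.approx(-0.00375)
        assert sd == pytest.approx(0.479, abs=0.001)


class TestBuildReport:
    def test_identical_series_guarded(self):
        r = build_report([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert r.mae == 0 and r.mse == 0
        assert r.pearson_r == pytest.approx(1.0)
        assert r.icc_agreement == pytest.approx(1.0)
        assert r.loa == (0.0, 0.0)
        # with no spread at all, every coefficient is guarded instead of NaN
        r2 = build_report([2.0, 2.0, 2.0], [2.0, 2.0, 2.0])
        assert r2.pearson_r is None and r2.icc_agreement == 1.0

    def test_loa_contains_95pct_of_gaussian_differences(self):
        rng = np.random.default_rng(9)
        actual = rng.normal(3, 1.2, 500)
        predicted = actual + rng.normal(0, 0.5, 500)
        r = build_report(actual, predicted)
        d = actual - predicted
        frac = np.mean((d > r.loa[0]) & (d < r.loa[1]))
        assert 0.92 <= frac <= 0.98

    def test_row_labels_match_convention(self):
        rng = np.random.default_rng(0)
        a = rng.normal(3, 1, 50)
        r = build_report(a, a + rng.normal(0, 0.3, 50))
        assert list(r.to_frame().index) == REPORT_ROW_LABELS

    def test_bias_ci_inside_loa(self):
        rng = np.random.default_rng(4)
        a = rng.normal(3, 1, 100)
        r = build_report(a, a + rng.normal(0, 0.4, 100))
        assert r.loa[0] < r.bias_ci[0] < r.bias < r.bias_ci[1] < r.loa[1]

    def test_model_facade(self):
        import pandas as pd
        rng = np.random.default_rng(5)
        frame = pd.DataFrame({"gold": rng.normal(3, 1, 40)})
        frame["pred"] = frame["gold"] + rng.normal(0, 0.3, 40)
        report = MethodAgreement.from_dataframe(frame, "gold", "pred", name="mrd1").fit()
        assert "Bland-Altman" not in report.summary()  # plain text table
        assert "ICC (Agreement)" in report.summary()
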