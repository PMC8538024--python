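"""Method-agreement statistics for eyelid measurements.

Quantifies how well one measurement route (a model, or a second rater) agrees
with a reference: MAE, MSE, Pearson r, two-way single-measure intraclass
correlation (absolute agreement and consistency), and Bland-Altman bias with
a t-based 95% CI and 1.96-SD limits of agreement.

The ICC forms follow the classical two-way mean-squares decomposition with
n subjects (rows) and k = 2 methods (columns):

    ICC(agreement)   = (MSR - MSE) / (MSR + MSE + (2/n) (MSC - MSE))
    ICC(consistency) = (MSR - MSE) / (MSR + MSE)

where MSR, MSC and MSE are the row (subject), column (method) and residual
mean squares.  ``recover_sd_from_ci`` inverts a printed bias CI back to the
SD of differences, which lets published limits of agreement be checked
against published CIs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "AgreementReport",
    "MethodAgreement",
    "error_metrics",
    "pearson",
    "icc",
    "bland_altman",
    "recover_sd_from_ci",
    "build_report",
]

LOA_MULTIPLIER = 1.96

REPORT_ROW_LABELS = [
    "MAE",
    "MSE",
    "Pearson correlation coefficient",
    "ICC (Agreement)",
    "ICC (Consistency)",
]


def _as_series(a, name: str) -> np.ndarray:
    arr = np.asarray(a, dtype=np.float64).ravel()
    if arr.size == 0:
        raise ValueError(f"{name} is empty")
    if not np.isfinite(arr).all():
        raise ValueError(f"{name} contains non-finite values")
    return arr


def error_metrics(actual, predicted) -> tuple[float, float]:
    """Mean absolute error and mean square error of paired series."""
    a = _as_series(actual, "actual")
    p = _as_series(predicted, "predicted")
    if a.size != p.size:
        raise ValueError(f"length mismatch: {a.size} vs {p.size}")
    d = a - p
    return float(np.abs(d).mean()), float((d * d).mean())


def pearson(actual, predicted) -> float:
    """Sample Pearson product-moment correlation."""
    a = _as_series(actual, "actual")
    p = _as_series(predicted, "predicted")
    if a.size != p.size:
        raise ValueError(f"length mismatch: {a.size} vs {p.size}")
    if a.size < 3:
        raise ValueError("need at least 3 pairs")
    if np.std(a) == 0 or np.std(p) == 0:
        raise ValueError("correlation undefined for zero-variance input")
    return float(stats.pearsonr(a, p).statistic)


def two_way_mean_squares(table: np.ndarray) -> tuple[float, float, float]:
    """Row, column and residual mean squares of an n x k two-way layout."""
    x = np.asarray(table, dtype=np.float64)
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((x - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    return float(msr), float(msc), float(mse)


def icc(ratings, form: str = "agreement") -> float:
    """Two-way single-measure ICC of an n x 2 ratings table.

    ``form='agreement'`` (ICC(A,1)) penalizes systematic offsets between the
    two methods; ``form='consistency'`` (ICC(C,1)) does not.
    """
    x = np.asarray(ratings, dtype=np.float64)
    if x.ndim != 2 or x.shape[1] != 2:
        raise ValueError(f"ratings must be n x 2, got {x.shape}")
    if x.shape[0] < 3:
        raise ValueError("need at least 3 subjects")
    if not np.isfinite(x).all():
        raise ValueError("ratings contain missing cells")
    if np.ptp(x) == 0:
        raise ValueError("ICC undefined for a constant table")
    n = x.shape[0]
    msr, msc, mse = two_way_mean_squares(x)
    if form == "agreement":
        denom = msr + mse + (2.0 / n) * (msc - mse)
    elif form == "consistency":
        denom = msr + mse
    else:
        raise ValueError(f"form must be 'agreement' or 'consistency', got {form!r}")
    return float((msr - mse) / denom)


@dataclass(frozen=True)
class BlandAltman:
    bias: float
    bias_ci: tuple[float, float]
    sd_diff: float
    loa: tuple[float, float]
    n: int


def bland_altman(a, b) -> BlandAltman:
    """Bland-Altman analysis of paired series (differences d = a - b).

    bias = mean(d); 95% CI of the bias uses t(n-1); limits of agreement use
    the conventional 1.96 multiplier on the sample SD of differences.
    """
    x = _as_series(a, "a")
    y = _as_series(b, "b")
    if x.size != y.size:
        raise ValueError(f"length mismatch: {x.size} vs {y.size}")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 pairs")
    d = x - y
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    half = float(stats.t.ppf(0.975, n - 1)) * sd / np.sqrt(n)
    return BlandAltman(
        bias=bias,
        bias_ci=(bias - half, bias + half),
        sd_diff=sd,
        loa=(bias - LOA_MULTIPLIER * sd, bias + LOA_MULTIPLIER * sd),
        n=n,
    )


def recover_sd_from_ci(ci: tuple[float, float], n: int) -> tuple[float, float]:
    """Invert a printed t-based 95% bias CI to (bias, sd of differences).

    bias is the CI midpoint; sd = half-width * sqrt(n) / t(n-1, 0.975).
    Together with the 1.96 multiplier this reconstructs the limits of
    agreement implied by a published confidence interval.
    """
    low, high = ci
    if not low < high:
        raise ValueError("CI must satisfy low < high")
    if n < 3:
        raise ValueError("need n >= 3")
    bias = (low + high) / 2.0
    half = (high - low) / 2.0
    sd = half * np.sqrt(n) / float(stats.t.ppf(0.975, n - 1))
    return float(bias), float(sd)


@dataclass(frozen=True)
class AgreementReport:
    """All agreement quantities for one actual-vs-predicted comparison."""

    n: int
    mae: float
    mse: float
    pearson_r: float | None
    icc_agreement: float | None
    icc_consistency: float | None
    bias: float
    bias_ci: tuple[float, float]
    sd_diff: float
    loa: tuple[float, float]

    def to_frame(self) -> pd.DataFrame:
        """Metric table with the conventional row labels."""
        values = [self.mae, self.mse, self.pearson_r,
                  self.icc_agreement, self.icc_consistency]
        return pd.DataFrame({"value": values}, index=REPORT_ROW_LABELS)

    def summary(self) -> str:
        lines = [f"Agreement report (n={self.n})", "-" * 34]
        lines.append(f"{'MAE (mm)':34s}{self.mae:10.2f}")
        lines.append(f"{'MSE (mm^2)':34s}{self.mse:10.2f}")
        for label, v in (("Pearson correlation coefficient", self.pearson_r),
                         ("ICC (Agreement)", self.icc_agreement),
                         ("ICC (Consistency)", self.icc_consistency)):
            lines.append(f"{label:34s}" + (f"{v:10.3f}" if v is not None else "       n/a"))
        lines.append(f"{'Bias (mm)':34s}{self.bias:10.3f}")
        lines.append(f"{'95% CI of bias':34s}  ({self.bias_ci[0]:.4f}, {self.bias_ci[1]:.4f})")
        lines.append(f"{'95% limits of agreement':34s}  ({self.loa[0]:.2f}, {self.loa[1]:.2f})")
        return "\n".join(lines)


def build_report(actual, predicted) -> AgreementReport:
    """One pass over a paired sample computing every agreement metric.

    Pearson r and the ICCs are reported as ``None`` when undefined (e.g.
    identical series with zero variance).
    """
    a = _as_series(actual, "actual")
    p = _as_series(predicted, "predicted")
    mae, mse = error_metrics(a, p)
    try:
        r = pearson(a, p)
    except ValueError:
        r = None
    table = np.column_stack([a, p])
    if np.ptp(table) == 0:
        icc_a = icc_c = 1.0 if mae == 0 else None
    else:
        try:
            icc_a = icc(table, "agreement")
            icc_c = icc(table, "consistency")
        except ValueError:
            icc_a = icc_c = None
    if np.allclose(a, p):
        d = a - p
        ba = BlandAltman(bias=float(d.mean()), bias_ci=(float(d.mean()),) * 2,
                         sd_diff=0.0, loa=(float(d.mean()),) * 2, n=a.size)
    else:
        ba = bland_altman(a, p)
    return AgreementReport(n=a.size, mae=mae, mse=mse, pearson_r=r,
                           icc_agreement=icc_a, icc_consistency=icc_c,
                           bias=ba.bias, bias_ci=ba.bias_ci,
                           sd_diff=ba.sd_diff, loa=ba.loa)


class MethodAgreement:
    """Model-style facade: ``MethodAgreement(actual, predicted).fit()``.

    ``fit`` returns the :class:`AgreementReport` results object; ``plot``
    helpers (scatter and Bland-Altman) hang off the fitted report.
    """

    def __init__(self, actual, predicted, name: str = ""):
        self.actual = _as_series(actual, "actual")
        self.predicted = _as_series(predicted, "predicted")
        self.name = name

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame, actual_col: str,
                       predicted_col: str, name: str = "") -> "MethodAgreement":
        return cls(frame[actual_col].to_numpy(), frame[predicted_col].to_numpy(), name)

    def fit(self) -> AgreementReport:
        return build_report(self.actual, self.predicted)

    def plot(self, path=None):
        """Scatter + Bland-Altman panel (requires matplotlib)."""
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        report = self.fit()
        fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(9, 4))
        ax1.scatter(self.actual, self.predicted, s=12, alpha=0.6)
        lims = [min(self.actual.min(), self.predicted.min()),
                max(self.actual.max(), self.predicted.max())]
        ax1.plot(lims, lims, "k--", lw=1)
        ax1.set_xlabel("gold standard (mm)")
        ax1.set_ylabel("predicted (mm)")
        ax1.set_title(f"{self.name} scatter".strip())
        mean = (self.actual + self.predicted) / 2
        diff = self.actual - self.predicted
        ax2.scatter(mean, diff, s=12, alpha=0.6)
        ax2.axhline(report.bias, color="k", lw=1)
        for bound in report.loa:
            ax2.axhline(bound, color="r", ls="--", lw=1)
        ax2.set_xlabel("mean of methods (mm)")
        ax2.set_ylabel("difference (mm)")
        ax2.set_title(f"{self.name} Bland-Altman".strip())
        fig.tight_layout()
        if path is not None:
            fig.savefig(path, dpi=120)
            plt.close(fig)
        return fig
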