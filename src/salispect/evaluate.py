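"""Agreement and validation statistics for segmentation and quantification.

The statistics mirror standard method-agreement practice in quantitative
imaging: Dice similarity coefficient (DSC) for voxel overlap, mean
absolute percentage error (MAPE) and squared Pearson correlation (R^2)
for paired %ID values, Bland-Altman bias with 95% limits of agreement,
paired t tests, and the two-way intraclass correlation coefficient
(single measure, absolute agreement — McGraw & Wong's ICC(A,1)) for
rater reproducibility.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .quantify import quantify_study
from .volumes import GLAND_CODES, GLAND_NAMES, GlandLabelMap, StudyRecord

__all__ = [
    "AgreementReport",
    "ICCResult",
    "DegenerateInputError",
    "dice",
    "mape",
    "icc_two_way",
    "bland_altman",
    "paired_t",
    "r_squared",
    "compare_segmentations",
]


class DegenerateInputError(ValueError):
    """Raised when a statistic is undefined for the given data."""


# ---------------------------------------------------------------------------
# Elementary statistics
# ---------------------------------------------------------------------------

def dice(p: np.ndarray, t: np.ndarray) -> Optional[float]:
    """Dice similarity coefficient 2|P n T| / (|P| + |T|).

    Returns None (reported missing) when both masks are empty, so that
    absent glands do not inflate cohort averages.
    """
    p = np.asarray(p, dtype=bool)
    t = np.asarray(t, dtype=bool)
    if p.shape != t.shape:
        raise ValueError("mask shapes differ")
    denom = int(p.sum()) + int(t.sum())
    if denom == 0:
        return None
    return 2.0 * int((p & t).sum()) / denom


def mape(reference: Sequence[float], test: Sequence[float]) -> tuple[float, float]:
    """Mean absolute percentage error vs the reference; returns (mean, SD)."""
    ref = np.asarray(reference, dtype=np.float64)
    tst = np.asarray(test, dtype=np.float64)
    if ref.shape != tst.shape:
        raise ValueError("length mismatch")
    if np.any(ref <= 0):
        raise ValueError("reference values must be positive")
    ape = 100.0 * np.abs(tst - ref) / ref
    sd = float(ape.std(ddof=1)) if ape.size > 1 else 0.0
    return float(ape.mean()), sd


def bland_altman(a: Sequence[float], b: Sequence[float]) -> tuple[float, float, float]:
    """Bland-Altman bias and 95% limits of agreement.

    Differences ``d = a - b``; bias = mean(d); limits = bias +/- 1.96 x
    sample SD of d.  Returns (bias, lower, upper).
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("need two equal-length vectors of at least 2 values")
    d = a - b
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return bias, bias - 1.96 * sd, bias + 1.96 * sd


def paired_t(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Classical paired t test; returns (t, two-sided p with n-1 df)."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("need two equal-length vectors of at least 2 values")
    if np.var(a - b, ddof=1) == 0:
        raise DegenerateInputError("zero variance of paired differences")
    res = stats.ttest_rel(a, b)
    return float(res.statistic), float(res.pvalue)


def r_squared(a: Sequence[float], b: Sequence[float]) -> float:
    """Squared Pearson correlation of two paired measurement vectors."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape or a.size < 3:
        raise ValueError("need equal-length vectors of at least 3 values")
    if a.std() == 0 or b.std() == 0:
        raise DegenerateInputError("constant input")
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


# ---------------------------------------------------------------------------
# Intraclass correlation
# ---------------------------------------------------------------------------

@dataclass
class ICCResult:
    """Two-way single-measure absolute-agreement ICC with F-based 95% CI."""

    icc: float
    ci95: tuple[float, float]
    n_subjects: int
    k_raters: int
    ms_rows: float  # between-subject mean square
    ms_cols: float  # between-rater mean square
    ms_error: float
    model: str = "two-way random, single measure, absolute agreement (ICC(A,1))"

    def __post_init__(self) -> None:
        lo, hi = self.ci95
        if not (lo <= self.icc <= hi):
            raise ValueError("CI must contain the point estimate")


def icc_two_way(ratings: np.ndarray, alpha: float = 0.05) -> ICCResult:
    """ICC of a two-way model on an n-subjects x k-raters complete table.

    Single-measure absolute agreement:
    ``ICC = (MSR - MSE) / (MSR + (k-1) MSE + (k/n)(MSC - MSE))``
    with the Satterthwaite F-based confidence interval of McGraw & Wong.
    """
    x = np.asarray(ratings, dtype=np.float64)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("ratings must be an n>=2 by k>=2 table")
    if np.isnan(x).any():
        raise ValueError("ratings table must be complete")
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
    if ss_total == 0:
        raise DegenerateInputError("constant ratings table")

    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    if denom == 0:
        raise DegenerateInputError("zero total variance decomposition")
    icc = (msr - mse) / denom

    if mse == 0 and msc == mse:
        ci = (icc, icc)  # perfect agreement
    else:
        a = (k * icc) / (n * (1.0 - icc)) if icc < 1 else np.inf
        b = 1.0 + (k * icc * (n - 1)) / (n * (1.0 - icc)) if icc < 1 else np.inf
        if np.isinf(a) or np.isinf(b):
            ci = (icc, icc)
        else:
            num_v = (a * msc + b * mse) ** 2
            den_v = (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
            v = num_v / den_v
            f_star = stats.f.ppf(1 - alpha / 2, n - 1, v)
            f_star2 = stats.f.ppf(1 - alpha / 2, v, n - 1)
            lower = (
                n * (msr - f_star * mse)
                / (f_star * (k * msc + (k * n - k - n) * mse) + n * msr)
            )
            upper = (
                n * (f_star2 * msr - mse)
                / (k * msc + (k * n - k - n) * mse + n * f_star2 * msr)
            )
            ci = (float(min(lower, icc)), float(max(upper, icc)))
    return ICCResult(
        icc=float(icc), ci95=ci, n_subjects=n, k_raters=k,
        ms_rows=float(msr), ms_cols=float(msc), ms_error=float(mse),
    )


# ---------------------------------------------------------------------------
# Cohort-level comparison of two segmentation sources
# ---------------------------------------------------------------------------

@dataclass
class AgreementReport:
    """Agreement summary between two segmentation sources on a cohort."""

    per_gland: pd.DataFrame  # study_id, gland, dsc, pid20_a, pid20_b, voi_a, voi_b
    dsc_mean: float
    dsc_sd: float
    dsc_range: tuple[float, float]
    mape_mean: float
    mape_sd: float
    r2: float
    bias: float
    loa: tuple[float, float]
    t_stat: Optional[float]
    p_value: Optional[float]
    n: int

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "n": self.n,
                    "dsc_mean": self.dsc_mean,
                    "dsc_sd": self.dsc_sd,
                    "dsc_min": self.dsc_range[0],
                    "dsc_max": self.dsc_range[1],
                    "mape_mean": self.mape_mean,
                    "mape_sd": self.mape_sd,
                    "r2": self.r2,
                    "bias": self.bias,
                    "loa_low": self.loa[0],
                    "loa_high": self.loa[1],
                    "t": self.t_stat,
                    "p": self.p_value,
                }
            ]
        )

    def to_csv(self, path) -> None:
        self.per_gland.to_csv(path, index=False, float_format="%.6g")


def compare_segmentations(
    cohort: Sequence[StudyRecord],
    labels_a: Sequence[GlandLabelMap],
    labels_b: Sequence[GlandLabelMap],
    decay_correct: bool = True,
    gland_codes: Sequence[int] = GLAND_CODES,
) -> AgreementReport:
    """Compare two per-study segmentation sources on one cohort.

    Source ``a`` is the reference (e.g. manual); ``b`` the test (e.g.
    network output).  Produces per-gland DSC and paired %ID/volume values
    plus the pooled MAPE, R^2, Bland-Altman and paired-t summaries of the
    20-min %ID.
    """
    if not (len(cohort) == len(labels_a) == len(labels_b)):
        raise ValueError("cohort and label sources must have equal length")
    rows = []
    for rec, la, lb in zip(cohort, labels_a, labels_b):
        if la is None or lb is None:
            raise ValueError(f"missing label source for study {rec.study_id}")
        qa = {q.gland_code: q for q in quantify_study(
            rec.spect20, rec.spect40, la, rec.injected_activity_MBq, decay_correct)}
        qb = {q.gland_code: q for q in quantify_study(
            rec.spect20, rec.spect40, lb, rec.injected_activity_MBq, decay_correct)}
        for code in gland_codes:
            d = dice(la.labels == code, lb.labels == code)
            if d is None:
                continue
            rows.append(
                {
                    "study_id": rec.study_id,
                    "gland": GLAND_NAMES[code],
                    "dsc": d,
                    "pid20_a": qa[code].pid20,
                    "pid20_b": qb[code].pid20,
                    "pid40_a": qa[code].pid40,
                    "pid40_b": qb[code].pid40,
                    "voi_a": qa[code].voi_volume_mL,
                    "voi_b": qb[code].voi_volume_mL,
                }
            )
    per_gland = pd.DataFrame(rows)
    if per_gland.empty:
        raise ValueError("no comparable glands in the cohort")
    dscs = per_gland["dsc"].to_numpy()
    a20 = per_gland["pid20_a"].to_numpy()
    b20 = per_gland["pid20_b"].to_numpy()
    m_mean, m_sd = mape(a20, b20)
    bias, lo, hi = bland_altman(a20, b20)
    try:
        t_stat, p_val = paired_t(a20, b20)
    except DegenerateInputError:
        t_stat, p_val = None, None
    try:
        r2 = r_squared(a20, b20)
    except DegenerateInputError:
        r2 = np.nan
    return AgreementReport(
        per_gland=per_gland,
        dsc_mean=float(dscs.mean()),
        dsc_sd=float(dscs.std(ddof=1)) if dscs.size > 1 else 0.0,
        dsc_range=(float(dscs.min()), float(dscs.max())),
        mape_mean=m_mean,
        mape_sd=m_sd,
        r2=r2,
        bias=bias,
        loa=(lo, hi),
        t_stat=t_stat,
        p_value=p_val,
        n=len(per_gland),
    )


def bland_altman_plot(a, b, ax=None, label_a: str = "A", label_b: str = "B"):
    """Bland-Altman scatter with bias and 95% limits of agreement."""
    import matplotlib.pyplot as plt

    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    bias, lo, hi = bland_altman(a, b)
    if ax is None:
        _, ax = plt.subplots()
    ax.scatter((a + b) / 2, a - b, s=14, alpha=0.7)
    for y, style in ((bias, "-"), (lo, "--"), (hi, "--")):
        ax.axhline(y, color="k", linestyle=style, linewidth=1)
    ax.set_xlabel(f"mean of {label_a} and {label_b}")
    ax.set_ylabel(f"{label_a} - {label_b}")
    return ax
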