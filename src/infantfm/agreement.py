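"""Agreement between predicted and reference fat mass.

Final-model evaluation quantifies concordance between equation
predictions and the air-displacement-plethysmography reference with:

* Bland-Altman analysis of the paired differences (predicted - measured):
  bias, 1.96-SD limits of agreement (LoA), their 95% confidence intervals
  (classical approximations: bias CI uses sd/sqrt(n), each LoA CI uses
  sd*sqrt(3/n)), and the share of differences outside the limits;
* Deming errors-in-variables regression of predicted on measured, with
  jackknife confidence intervals and one-sample tests of slope = 1 and
  intercept = 0 (both must hold for method equivalence);
* Pearson correlation (with its t-test p-value) and R² = r²;
* a predicted-vs-measured mean comparison: Student's t-test when both
  samples pass Shapiro-Wilk normality at alpha = 0.05, otherwise the
  two-sided Mann-Whitney U test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Optional, Union

import numpy as np
from scipy import stats

from .cohort import CohortTable
from .linmodel import LinearFMModel

logger = logging.getLogger(__name__)

__all__ = [
    "BlandAltman",
    "DemingFit",
    "AgreementReport",
    "bland_altman",
    "deming_regression",
    "correlation_and_r2",
    "compare_means",
    "validate_model",
]


@dataclass(frozen=True)
class BlandAltman:
    n: int
    bias: float
    sd_diff: float
    loa_lower: float
    loa_upper: float
    ci_bias: tuple[float, float]
    ci_loa_lower: tuple[float, float]
    ci_loa_upper: tuple[float, float]
    pct_below_loa: float
    pct_above_loa: float


@dataclass(frozen=True)
class DemingFit:
    n: int
    slope: float
    intercept: float
    ci_slope: tuple[float, float]
    ci_intercept: tuple[float, float]
    p_slope_vs_1: float
    p_intercept_vs_0: float
    equivalence: bool
    variance_ratio: float


@dataclass(frozen=True)
class AgreementReport:
    """Every agreement statistic for one model on one cohort."""

    n: int
    bias: float
    loa_lower: float
    loa_upper: float
    ci_bias: tuple[float, float]
    ci_loa_lower: tuple[float, float]
    ci_loa_upper: tuple[float, float]
    pct_below_loa: float
    pct_above_loa: float
    deming_slope: float
    deming_intercept: float
    ci_deming_slope: tuple[float, float]
    ci_deming_intercept: tuple[float, float]
    p_slope_vs_1: float
    p_intercept_vs_0: float
    deming_equivalence: bool
    pearson_r: float
    p_pearson: float
    r_squared: float
    mean_predicted: float
    mean_measured: float
    mean_comparison_test: str
    mean_comparison_p: float

    def to_dict(self) -> dict:
        return asdict(self)


def bland_altman(
    predicted: np.ndarray,
    measured: np.ndarray,
    loa_multiplier: float = 1.96,
) -> BlandAltman:
    """Bland-Altman agreement of `predicted` against `measured` (kg).

    Differences are oriented predicted - measured. Limits of agreement
    are bias ± `loa_multiplier` · SD (sample SD, n-1 denominator). The
    bias CI is bias ± t(0.975, n-1)·sd/√n; each limit's CI is
    limit ± t(0.975, n-1)·sd·√(3/n) (the classical approximation).
    "Outside" counts are strict inequalities.
    """
    predicted = np.asarray(predicted, dtype=float)
    measured = np.asarray(measured, dtype=float)
    if predicted.shape != measured.shape:
        raise ValueError("predicted and measured must have equal length")
    n = len(predicted)
    if n < 3:
        raise ValueError(f"need at least 3 pairs, got {n}")
    d = predicted - measured
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    if sd == 0:
        logger.info("zero-variance differences: limits of agreement collapse to the bias")
    lower = bias - loa_multiplier * sd
    upper = bias + loa_multiplier * sd
    t = stats.t.ppf(0.975, n - 1)
    half_bias = t * sd / np.sqrt(n)
    half_loa = t * sd * np.sqrt(3.0 / n)
    return BlandAltman(
        n=n,
        bias=bias,
        sd_diff=sd,
        loa_lower=lower,
        loa_upper=upper,
        ci_bias=(bias - half_bias, bias + half_bias),
        ci_loa_lower=(lower - half_loa, lower + half_loa),
        ci_loa_upper=(upper - half_loa, upper + half_loa),
        pct_below_loa=100.0 * float((d < lower).mean()),
        pct_above_loa=100.0 * float((d > upper).mean()),
    )


def _deming_slope_intercept(
    x: np.ndarray, y: np.ndarray, variance_ratio: float
) -> tuple[float, float]:
    sxx = float(np.var(x, ddof=1))
    syy = float(np.var(y, ddof=1))
    sxy = float(np.cov(x, y, ddof=1)[0, 1])
    if sxy == 0:
        # vertical/horizontal degenerate cloud: fall back to a slope from
        # the variance ratio alone
        return float(np.sqrt(syy / sxx)), float(y.mean() - np.sqrt(syy / sxx) * x.mean())
    delta = variance_ratio
    slope = (syy - delta * sxx + np.sqrt((syy - delta * sxx) ** 2 + 4 * delta * sxy**2)) / (
        2 * sxy
    )
    return float(slope), float(y.mean() - slope * x.mean())


def deming_regression(
    x: np.ndarray,
    y: np.ndarray,
    variance_ratio: float = 1.0,
) -> DemingFit:
    """Errors-in-variables regression of `y` (predicted) on `x` (measured).

    `variance_ratio` is the assumed ratio of the error variance in y to
    that in x; 1 gives orthogonal regression, and as the ratio grows the
    fit approaches ordinary least squares of y on x. Confidence intervals
    and the one-sample tests of slope = 1 / intercept = 0 use the
    leave-one-out jackknife with a t reference on n - 2 degrees of
    freedom. ``equivalence`` is True when both CIs cover their target and
    both p-values exceed 0.05.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    n = len(x)
    if n < 3:
        raise ValueError(f"need at least 3 pairs, got {n}")
    if np.var(x) == 0 or np.var(y) == 0:
        raise ValueError("zero variance in x or y: Deming regression is undefined")
    slope, intercept = _deming_slope_intercept(x, y, variance_ratio)

    # leave-one-out jackknife
    idx = np.arange(n)
    js, ji = np.empty(n), np.empty(n)
    for i in range(n):
        keep = idx != i
        js[i], ji[i] = _deming_slope_intercept(x[keep], y[keep], variance_ratio)
    ps_slope = n * slope - (n - 1) * js  # pseudo-values
    ps_icept = n * intercept - (n - 1) * ji
    se_slope = float(ps_slope.std(ddof=1) / np.sqrt(n))
    se_icept = float(ps_icept.std(ddof=1) / np.sqrt(n))
    df = n - 2
    t_crit = stats.t.ppf(0.975, df)
    ci_slope = (slope - t_crit * se_slope, slope + t_crit * se_slope)
    ci_icept = (intercept - t_crit * se_icept, intercept + t_crit * se_icept)

    def _p(est: float, target: float, se: float) -> float:
        if se == 0:
            return 1.0 if est == target else 0.0
        return float(2 * stats.t.sf(abs(est - target) / se, df))

    p_slope = _p(slope, 1.0, se_slope)
    p_icept = _p(intercept, 0.0, se_icept)
    equivalence = bool(
        ci_slope[0] <= 1.0 <= ci_slope[1]
        and ci_icept[0] <= 0.0 <= ci_icept[1]
        and p_slope > 0.05
        and p_icept > 0.05
    )
    return DemingFit(
        n=n,
        slope=slope,
        intercept=intercept,
        ci_slope=ci_slope,
        ci_intercept=ci_icept,
        p_slope_vs_1=p_slope,
        p_intercept_vs_0=p_icept,
        equivalence=equivalence,
        variance_ratio=variance_ratio,
    )


def correlation_and_r2(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Pearson r (with two-sided t-test p-value) and R² = r².

    R² is reported as the squared Pearson correlation between the two
    measurement series, pairing naturally with the printed r values; a
    sum-of-squares R² is deliberately not used here.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need two equal-length arrays with at least 3 points")
    if np.var(x) == 0 or np.var(y) == 0:
        raise ValueError("zero variance: correlation undefined")
    res = stats.pearsonr(x, y)
    r = float(res.statistic)
    return r, float(res.pvalue), r * r


def compare_means(
    predicted: np.ndarray, measured: np.ndarray, alpha_normality: float = 0.05
) -> tuple[str, float, float]:
    """Compare predicted and measured FM as two samples.

    Shapiro-Wilk on each sample decides the branch: both normal at
    `alpha_normality` → two-sample Student's t-test; otherwise the
    two-sided Mann-Whitney U test.

    Returns ``(test_name, statistic, p_value)``.
    """
    predicted = np.asarray(predicted, dtype=float)
    measured = np.asarray(measured, dtype=float)
    if len(predicted) < 3 or len(measured) < 3:
        raise ValueError("need at least 3 observations per sample")

    def _normal(sample: np.ndarray) -> bool:
        if np.ptp(sample) == 0:
            return False  # constant sample: Shapiro undefined, clearly non-normal
        return stats.shapiro(sample).pvalue > alpha_normality

    if _normal(predicted) and _normal(measured):
        res = stats.ttest_ind(predicted, measured)
        return "student_t", float(res.statistic), float(res.pvalue)
    res = stats.mannwhitneyu(predicted, measured, alternative="two-sided")
    return "mann_whitney_u", float(res.statistic), float(res.pvalue)


def validate_model(
    model: LinearFMModel,
    cohort: CohortTable,
    variance_ratio: float = 1.0,
    plots_dir: Optional[Union[str, Path]] = None,
) -> AgreementReport:
    """Score `cohort` with `model` and compile the full agreement report.

    Requires measured FM on every record. When `plots_dir` is given,
    Bland-Altman and Deming plots are written there as PNG files.
    """
    predicted = model.predict(cohort)
    measured = cohort.fm_array()
    ba = bland_altman(predicted, measured)
    dm = deming_regression(measured, predicted, variance_ratio)
    r, p_r, r2 = correlation_and_r2(measured, predicted)
    test_name, _, p_means = compare_means(predicted, measured)
    report = AgreementReport(
        n=ba.n,
        bias=ba.bias,
        loa_lower=ba.loa_lower,
        loa_upper=ba.loa_upper,
        ci_bias=ba.ci_bias,
        ci_loa_lower=ba.ci_loa_lower,
        ci_loa_upper=ba.ci_loa_upper,
        pct_below_loa=ba.pct_below_loa,
        pct_above_loa=ba.pct_above_loa,
        deming_slope=dm.slope,
        deming_intercept=dm.intercept,
        ci_deming_slope=dm.ci_slope,
        ci_deming_intercept=dm.ci_intercept,
        p_slope_vs_1=dm.p_slope_vs_1,
        p_intercept_vs_0=dm.p_intercept_vs_0,
        deming_equivalence=dm.equivalence,
        pearson_r=r,
        p_pearson=p_r,
        r_squared=r2,
        mean_predicted=float(predicted.mean()),
        mean_measured=float(measured.mean()),
        mean_comparison_test=test_name,
        mean_comparison_p=p_means,
    )
    if plots_dir is not None:
        plots_dir = Path(plots_dir)
        plots_dir.mkdir(parents=True, exist_ok=True)
        tag = model.visit.value
        plot_bland_altman(predicted, measured, ba, plots_dir / f"bland_altman_{tag}.png")
        plot_deming(measured, predicted, dm, plots_dir / f"deming_{tag}.png")
    return report


def plot_bland_altman(
    predicted: np.ndarray, measured: np.ndarray, ba: BlandAltman, path: Union[str, Path]
) -> None:
    """Classic Bland-Altman scatter: mean of methods vs difference."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    mean_pair = (np.asarray(predicted) + np.asarray(measured)) / 2.0
    d = np.asarray(predicted) - np.asarray(measured)
    fig, ax = plt.subplots(figsize=(6, 4.5))
    ax.scatter(mean_pair, d, s=18, alpha=0.7, edgecolors="none")
    for yv, style, label in [
        (ba.bias, "-", f"bias = {ba.bias:.3f}"),
        (ba.loa_lower, "--", f"LoA = ({ba.loa_lower:.3f}, {ba.loa_upper:.3f})"),
        (ba.loa_upper, "--", None),
    ]:
        ax.axhline(yv, color="crimson", linestyle=style, linewidth=1, label=label)
    ax.set_xlabel("Mean of predicted and measured FM (kg)")
    ax.set_ylabel("Predicted - measured FM (kg)")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_deming(
    measured: np.ndarray, predicted: np.ndarray, dm: DemingFit, path: Union[str, Path]
) -> None:
    """Scatter of predicted vs measured with the Deming line and identity."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    x = np.asarray(measured)
    y = np.asarray(predicted)
    fig, ax = plt.subplots(figsize=(5.2, 5))
    ax.scatter(x, y, s=18, alpha=0.7, edgecolors="none")
    grid = np.linspace(x.min(), x.max(), 10)
    ax.plot(grid, dm.intercept + dm.slope * grid, color="crimson",
            label=f"Deming: y = {dm.intercept:.3f} + {dm.slope:.3f}x")
    ax.plot(grid, grid, color="gray", linestyle=":", label="identity")
    ax.set_xlabel("Measured FM (kg)")
    ax.set_ylabel("Predicted FM (kg)")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
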