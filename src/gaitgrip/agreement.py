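"""Agreement and precision statistics.

Implements the two-way random-effects absolute-agreement intraclass
correlation (single- and average-measures forms) from the ANOVA mean
squares, qualitative interpretation bands, Bland-Altman limits of agreement
with outer confidence limits, and probability-distribution bounds on the
measurement success rate K_A.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "AgreementReport",
    "BlandAltmanReport",
    "KABounds",
    "icc",
    "interpret_icc",
    "interpret_r",
    "interpret_r2",
    "agreement_report",
    "bland_altman",
    "ka_bounds",
]


class UndefinedICCError(ValueError):
    """Raised when the ICC is undefined (no between- or within-target variance)."""


def _anova_mean_squares(data: np.ndarray) -> tuple[float, float, float, int, int]:
    """Two-way (targets x raters) ANOVA mean squares for an n x k table."""
    n, k = data.shape
    if n < 3:
        raise ValueError("need at least 3 targets for the ICC ANOVA")
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((data - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    return msr, msc, mse, n, k


def icc(a, b=None, form: str = "(2,1)") -> float:
    """Two-way random-effects, absolute-agreement intraclass correlation.

    Parameters
    ----------
    a, b
        Either two equal-length 1D rating vectors, or a single n x k table
        (targets x raters) passed as ``a`` with ``b=None``.
    form
        ``"(2,1)"`` for single measures, ``"(2,k)"`` for average measures.
    """
    if b is not None:
        a = np.asarray(a, dtype=float)
        b = np.asarray(b, dtype=float)
        if a.shape != b.shape or a.ndim != 1:
            raise ValueError("rating vectors must be equal-length 1D arrays")
        data = np.column_stack([a, b])
    else:
        data = np.asarray(a, dtype=float)
        if data.ndim != 2 or data.shape[1] < 2:
            raise ValueError("rating table must be n x k with k >= 2")
    msr, msc, mse, n, k = _anova_mean_squares(data)
    if msr == 0 and mse == 0 and msc == 0:
        raise UndefinedICCError("zero variance in all raters and targets")
    if form == "(2,1)":
        denom = msr + (k - 1) * mse + k * (msc - mse) / n
    elif form == "(2,k)":
        denom = msr + (msc - mse) / n
    else:
        raise ValueError(f"unsupported ICC form: {form!r}")
    if denom == 0:
        raise UndefinedICCError("degenerate ANOVA: zero denominator")
    return float((msr - mse) / denom)


def interpret_icc(v: float) -> str:
    """Excellent (>0.750) / good (0.600-0.749) / fair (0.400-0.599) / poor."""
    if v > 0.750:
        return "excellent"
    if v >= 0.600:
        return "good"
    if v >= 0.400:
        return "fair"
    return "poor"


def interpret_r(v: float) -> str:
    """Large (>0.499) / medium (0.300-0.499) / small (0.100-0.299) / none."""
    v = abs(v)
    if v > 0.499:
        return "large"
    if v >= 0.300:
        return "medium"
    if v >= 0.100:
        return "small"
    return "none"


def interpret_r2(v: float) -> str:
    """Large (>0.26) / medium (0.14-0.26) / small (0.02-0.13) / none (<0.02)."""
    if v > 0.26:
        return "large"
    if v >= 0.14:
        return "medium"
    if v >= 0.02:
        return "small"
    return "none"


@dataclass(frozen=True)
class AgreementReport:
    icc21: float
    icc2k: float
    mae: float
    adj_r2: float | None
    pearson_r: float
    icc_band: str
    r_band: str
    r2_band: str | None


def agreement_report(reference, estimated, adj_r2: float | None = None) -> AgreementReport:
    """Bundle the agreement statistics for a (reference, estimate) pair."""
    reference = np.asarray(reference, dtype=float)
    estimated = np.asarray(estimated, dtype=float)
    icc21 = icc(reference, estimated, form="(2,1)")
    icc2k = icc(reference, estimated, form="(2,k)")
    mae = float(np.mean(np.abs(estimated - reference)))
    r = float(stats.pearsonr(reference, estimated)[0])
    return AgreementReport(
        icc21=icc21, icc2k=icc2k, mae=mae, adj_r2=adj_r2, pearson_r=r,
        icc_band=interpret_icc(icc21), r_band=interpret_r(r),
        r2_band=None if adj_r2 is None else interpret_r2(adj_r2),
    )


@dataclass(frozen=True)
class BlandAltmanReport:
    """Bland-Altman statistics with LoA outer confidence limits.

    ``bias`` is mean(estimated - reference); the limits of agreement are
    ``bias +/- 1.96 sigma`` and each carries a large-sample confidence
    half-width ``1.96 sigma sqrt(3/n)``.
    """

    n: int
    bias: float
    bias_p: float
    sigma: float
    uloa: float
    lloa: float
    uuloa: float
    luloa: float
    ulloa: float
    llloa: float
    prop_r: float
    prop_p: float
    prop_slope: float
    prop_intercept: float
    ks_p: float
    degenerate: bool


def bland_altman(reference, estimated) -> BlandAltmanReport:
    """Bland-Altman comparison of an estimated against a reference method."""
    reference = np.asarray(reference, dtype=float)
    estimated = np.asarray(estimated, dtype=float)
    if reference.shape != estimated.shape or reference.ndim != 1:
        raise ValueError("inputs must be equal-length 1D arrays")
    n = reference.size
    if n < 8:
        raise ValueError("need at least 8 paired measurements")
    diffs = estimated - reference
    means = (estimated + reference) / 2.0
    bias = float(diffs.mean())
    sigma = float(diffs.std(ddof=1))
    degenerate = sigma <= 1e-12
    if degenerate:
        ks_p = bias_p = prop_p = float("nan")
        prop_r = prop_slope = 0.0
        prop_intercept = bias
    else:
        # Normality gate for the parametric bias tests.
        ks_p = float(stats.kstest(diffs, "norm", args=(bias, sigma)).pvalue)
        bias_p = float(stats.ttest_1samp(diffs, 0.0).pvalue)
        prop_r, prop_p = (float(v) for v in stats.pearsonr(means, diffs))
        slope, intercept = np.polyfit(means, diffs, 1)
        prop_slope, prop_intercept = float(slope), float(intercept)
    uloa = bias + 1.96 * sigma
    lloa = bias - 1.96 * sigma
    half = 1.96 * sigma * np.sqrt(3.0 / n)
    return BlandAltmanReport(
        n=n, bias=bias, bias_p=bias_p, sigma=sigma,
        uloa=uloa, lloa=lloa,
        uuloa=uloa + half, luloa=uloa - half,
        ulloa=lloa + half, llloa=lloa - half,
        prop_r=prop_r, prop_p=prop_p,
        prop_slope=prop_slope, prop_intercept=prop_intercept,
        ks_p=ks_p, degenerate=degenerate,
    )


@dataclass(frozen=True)
class KABounds:
    k_al: float
    k_au: float
    mu_t_ci: tuple[float, float]
    sigma_a_ci: tuple[float, float]
    sigma_t_ci: tuple[float, float]
    interval: tuple[float, float]


def _normal_mass(lo: float, hi: float, mu, sigma):
    return stats.norm.cdf((hi - mu) / sigma) - stats.norm.cdf((lo - mu) / sigma)


def _sigma_ci(res: np.ndarray, conf: float) -> tuple[float, float]:
    n = res.size
    s2 = res.var(ddof=1)
    alpha = 1.0 - conf
    lo = np.sqrt((n - 1) * s2 / stats.chi2.ppf(1 - alpha / 2, n - 1))
    hi = np.sqrt((n - 1) * s2 / stats.chi2.ppf(alpha / 2, n - 1))
    return float(lo), float(hi)


def ka_bounds(
    train_res, test_res, conf: float = 0.95, grid: int = 201,
    coverage: float = 0.95, interval: tuple[float, float] | None = None,
) -> KABounds:
    """Bounds on the measurement success rate K_A.

    Training residuals define a symmetric agreement interval
    ``+/- 1.96 sigma_AU`` (upper confidence limit of the training residual
    SD).  Test residuals are modelled as N(mu_T, sigma_T^2) with mu_T and
    sigma_T only known up to confidence intervals; K_A bounds are the
    extremes of the normal mass inside the agreement interval over the
    (mu_T, sigma_T) confidence rectangle, divided by ``coverage`` and
    clipped at 1.
    """
    train_res = np.asarray(train_res, dtype=float)
    test_res = np.asarray(test_res, dtype=float)
    if train_res.size < 3 or test_res.size < 3:
        raise ValueError("need at least 3 residuals in each set for the CIs")
    alpha = 1.0 - conf

    sigma_a_ci = _sigma_ci(train_res, conf)
    sigma_t_ci = _sigma_ci(test_res, conf)
    mu_t = test_res.mean()
    se = test_res.std(ddof=1) / np.sqrt(test_res.size)
    tcrit = stats.t.ppf(1 - alpha / 2, test_res.size - 1)
    mu_t_ci = (float(mu_t - tcrit * se), float(mu_t + tcrit * se))

    if interval is None:
        lo, hi = -1.96 * sigma_a_ci[1], 1.96 * sigma_a_ci[1]
    else:
        lo, hi = interval
    mus = np.linspace(mu_t_ci[0], mu_t_ci[1], grid)
    sigmas = np.linspace(max(sigma_t_ci[0], 1e-12), sigma_t_ci[1], grid)
    mass = _normal_mass(lo, hi, mus[:, None], sigmas[None, :])
    k_au = min(float(mass.max()) / coverage, 1.0)
    k_al = min(float(mass.min()) / coverage, 1.0)
    return KABounds(
        k_al=k_al, k_au=k_au, mu_t_ci=mu_t_ci,
        sigma_a_ci=sigma_a_ci, sigma_t_ci=sigma_t_ci, interval=(lo, hi),
    )
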