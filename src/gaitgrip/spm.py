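"""1D statistical parametric mapping over the gait cycle.

Finds %GC intervals where the 9-channel foot-motion waveform correlates
with a scalar outcome: a node-wise canonical-correlation (CCA) curve with a
random-field-theory (RFT) threshold gates Sidak-corrected per-channel
Pearson curves; maximal supra-threshold runs become gait phase clusters
(GPCs), filtered to the quadriceps-activation windows Q_t; the integral
average of the waveform over a cluster is the scalar predictor fed to model
selection.

The %GC grid is 1-based (columns 1..100, stance 1-60, swing 61-100) and all
intervals are closed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.optimize import brentq

__all__ = [
    "CHANNELS",
    "QT_WINDOWS",
    "SPMCurve",
    "GPC",
    "IMSPredictorDef",
    "sidak_alpha",
    "estimate_fwhm",
    "rft_threshold",
    "spm_cca_curve",
    "spm_pearson_curves",
    "extract_gpcs",
    "intersect_qt",
    "ims_predictor_value",
    "discover_predictors",
    "permutation_threshold",
]

CHANNELS = ("Ax", "Ay", "Az", "Gx", "Gy", "Gz", "Ex", "Ey", "Ez")

#: Quadriceps-activation %GC windows used to filter GPCs (closed intervals).
QT_WINDOWS = ((1, 16), (48, 70), (92, 100))

_4LOG2 = 4.0 * math.log(2.0)


@dataclass(frozen=True)
class SPMCurve:
    """A statistic curve over the 100-node %GC grid with its RFT threshold."""

    z: np.ndarray                       # statistic at each node, shape (100,)
    kind: str                           # "chi2_cca" or "t_pearson"
    dof: float
    fwhm: float
    threshold: float
    alpha: float
    channel: str | None = None
    mask: np.ndarray | None = None      # boolean (100,); None = full domain
    two_sided: bool = False

    def supra(self) -> np.ndarray:
        """Boolean supra-threshold indicator (restricted to the mask)."""
        stat = np.abs(self.z) if self.two_sided else self.z
        out = stat > self.threshold
        if self.mask is not None:
            out = out & self.mask
        return out


@dataclass(frozen=True)
class GPC:
    """A gait phase cluster: one channel's significant closed %GC interval."""

    channel: str
    t_s: int
    t_e: int
    peak_stat: float = float("nan")
    threshold: float = float("nan")

    def __post_init__(self) -> None:
        if not (1 <= self.t_s <= self.t_e <= 100):
            raise ValueError(f"invalid %GC interval [{self.t_s}, {self.t_e}]")


@dataclass(frozen=True)
class IMSPredictorDef:
    """Definition of a waveform predictor: channel + closed %GC interval."""

    channel: str
    t_s: int
    t_e: int

    @property
    def name(self) -> str:
        if self.t_s == self.t_e:
            return f"{self.channel}_{self.t_s}"
        return f"{self.channel}_{self.t_s}_{self.t_e}"


def sidak_alpha(m: int, alpha: float = 0.05) -> float:
    """Sidak-corrected per-test level: 1 - (1 - alpha)^(1/m)."""
    if m < 1:
        raise ValueError("m must be >= 1")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    return 1.0 - (1.0 - alpha) ** (1.0 / m)


def estimate_fwhm(residuals: np.ndarray) -> float:
    """Estimate field smoothness (FWHM, in node units) from residuals.

    Uses the standard gradient-based estimator on variance-normalized
    residuals; ``residuals`` is (n_obs, n_nodes) or a stack of such arrays
    (pooled across the leading axes).
    """
    r = np.asarray(residuals, dtype=float)
    if r.ndim > 2:
        r = r.reshape(-1, r.shape[-1])
    ssq = (r ** 2).sum(axis=0)
    grad = np.gradient(r, axis=1)
    v = (grad ** 2).sum(axis=0) / (ssq + np.finfo(float).eps)
    v = v[np.isfinite(v) & (v > 0)]
    if v.size == 0:
        return float(r.shape[1])
    resels_per_node = np.sqrt(v / _4LOG2)
    return float(1.0 / resels_per_node.mean())


def _ec_density_t(u: np.ndarray | float, nu: float) -> np.ndarray | float:
    """1D EC density of a t-field (per resel)."""
    return (math.sqrt(_4LOG2) / (2.0 * math.pi)
            * (1.0 + np.asarray(u, dtype=float) ** 2 / nu) ** (-(nu - 1) / 2.0))


def _ec_density_chi2(u: np.ndarray | float, k: float) -> np.ndarray | float:
    """1D EC density (upcrossing rate per resel) of a chi-square field.

    Derived from Rice's formula: with z a k-vector of iid smooth unit
    Gaussian fields and chi = |z|^2, the conditional derivative
    chi' | chi = u is N(0, 4 lambda u), giving the rate
    2 sqrt(lambda u / 2 pi) f_chi2(u); lambda = 4 ln 2 / FWHM^2.  Matches
    the two-sided Gaussian rate at k = 1.
    """
    u = np.asarray(u, dtype=float)
    return (math.sqrt(_4LOG2) * math.sqrt(2.0 / math.pi)
            * u ** ((k - 1) / 2.0) * np.exp(-u / 2.0)
            / (2.0 ** (k / 2.0) * math.gamma(k / 2.0)))


def _expected_ec(u: float, kind: str, dof: float, resels: float,
                 two_sided: bool) -> float:
    if kind == "t":
        val = stats.t.sf(u, dof) + resels * _ec_density_t(u, dof)
        return 2.0 * val if two_sided else val
    if kind == "chi2":
        return stats.chi2.sf(u, dof) + resels * _ec_density_chi2(u, dof)
    raise ValueError(f"unknown field kind: {kind!r}")


def rft_threshold(kind: str, dof: float, n_nodes: int, fwhm: float,
                  alpha: float = 0.05, two_sided: bool = False) -> float:
    """Critical value controlling the family-wise rate of supra-threshold
    excursions of a smooth 1D statistic field.

    Smallest u whose expected Euler characteristic (point exceedance plus
    resel-weighted EC density) is <= alpha.  ``fwhm`` below one node is
    clamped to the grid resolution.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    fwhm = max(float(fwhm), 1.0)
    resels = max(n_nodes - 1, 0) / fwhm

    def f(u: float) -> float:
        return _expected_ec(u, kind, dof, resels, two_sided) - alpha

    # Pointwise critical value is a lower bracket (extra EC term >= 0).
    if kind == "t":
        lo = stats.t.ppf(1 - (alpha / 2 if two_sided else alpha), dof)
    else:
        lo = stats.chi2.ppf(1 - alpha, dof)
    lo = max(lo, 1e-6)
    if f(lo) <= 0:
        return float(lo)
    hi = lo + 1.0
    while f(hi) > 0:
        hi *= 2.0
        if hi > 1e8:  # pragma: no cover - pathological alpha/fwhm
            break
    return float(brentq(f, lo, hi, xtol=1e-10))


def _center(a: np.ndarray) -> np.ndarray:
    return a - a.mean(axis=0, keepdims=True)


def spm_cca_curve(grids: np.ndarray, y: np.ndarray,
                  alpha: float = 0.05) -> SPMCurve:
    """Node-wise canonical correlation of the 9-channel response with y.

    ``grids`` is (N, 9, 100).  With a scalar design the squared canonical
    correlation equals the multiple R^2 of y on the 9 channels; it is
    mapped to a chi-square-type statistic via the Bartlett-Wilks transform
    (dof = 9) and thresholded by RFT at ``alpha``.
    """
    grids = np.asarray(grids, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p, q = grids.shape
    if n < 20:
        raise ValueError("need at least 20 datasets for the CCA curve")
    yc = _center(y[:, None])
    yss = float((yc.T @ yc).item())
    x2 = np.empty(q)
    mult = n - 1 - 0.5 * (p + 1 + 1)
    for j in range(q):
        yj = _center(grids[:, :, j])
        beta, *_ = np.linalg.lstsq(yj, yc, rcond=None)
        fitted = yj @ beta
        r2 = float((fitted.T @ yc).item()) / yss if yss > 0 else 0.0
        r2 = min(max(r2, 0.0), 1.0 - 1e-12)
        x2[j] = -mult * math.log1p(-r2)
    # smoothness from the component-channel residual fields (channel ~ y),
    # pooled across channels -- the statistic field inherits their roughness
    gc = grids - grids.mean(axis=0, keepdims=True)
    slope = (gc * yc[:, :, None]).sum(axis=0) / yss
    resid = (gc - yc[:, :, None] * slope[None]).reshape(n * p, q)
    fwhm = estimate_fwhm(resid)
    thr = rft_threshold("chi2", p, q, fwhm, alpha)
    return SPMCurve(z=x2, kind="chi2_cca", dof=p, fwhm=fwhm,
                    threshold=thr, alpha=alpha)


def spm_pearson_curves(grids: np.ndarray, y: np.ndarray,
                       mask: np.ndarray | None = None,
                       alpha: float = 0.05,
                       n_channels_correction: int | None = None,
                       ) -> list[SPMCurve]:
    """Per-channel Pearson SPM{t} curves at the Sidak-corrected level.

    ``mask`` (boolean over nodes, typically the CCA supra-threshold set)
    restricts where clusters may be reported; thresholds are computed over
    the full domain (conservative).  Returns one two-sided curve per
    channel.
    """
    grids = np.asarray(grids, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p, q = grids.shape
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if not mask.any():
            return []
    m = n_channels_correction if n_channels_correction is not None else p
    a_c = sidak_alpha(m, alpha)
    dof = n - 2
    yc = _center(y)
    ysd = yc.std()
    curves = []
    for c in range(p):
        w = grids[:, c, :]
        wc = _center(w)
        wsd = wc.std(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            r = (wc * yc[:, None]).mean(axis=0) / (wsd * ysd)
        r = np.nan_to_num(np.clip(r, -1.0 + 1e-12, 1.0 - 1e-12))
        t = r * np.sqrt(dof / (1.0 - r ** 2))
        # residuals of the node-wise simple regression of the channel on y
        slope = np.where(ysd > 0, (wc * yc[:, None]).mean(axis=0) / ysd ** 2, 0.0)
        resid = wc - yc[:, None] * slope[None, :]
        fwhm = estimate_fwhm(resid)
        thr = rft_threshold("t", dof, q, fwhm, a_c, two_sided=True)
        curves.append(SPMCurve(z=t, kind="t_pearson", dof=dof, fwhm=fwhm,
                               threshold=thr, alpha=a_c,
                               channel=CHANNELS[c] if c < len(CHANNELS) else str(c),
                               mask=mask, two_sided=True))
    return curves


def extract_gpcs(curves: list[SPMCurve]) -> list[GPC]:
    """Maximal runs of consecutive supra-threshold nodes, per channel."""
    out: list[GPC] = []
    for curve in curves:
        supra = curve.supra()
        idx = np.flatnonzero(supra)
        if idx.size == 0:
            continue
        breaks = np.flatnonzero(np.diff(idx) > 1)
        starts = np.concatenate([[0], breaks + 1])
        ends = np.concatenate([breaks, [idx.size - 1]])
        for s, e in zip(starts, ends):
            t_s, t_e = int(idx[s]) + 1, int(idx[e]) + 1  # 1-based %GC
            seg = np.abs(curve.z[idx[s]:idx[e] + 1])
            out.append(GPC(channel=curve.channel or "", t_s=t_s, t_e=t_e,
                           peak_stat=float(seg.max()),
                           threshold=curve.threshold))
    return out


def intersect_qt(gpcs: list[GPC],
                 qt: tuple[tuple[int, int], ...] = QT_WINDOWS) -> list[GPC]:
    """Intersect each cluster with the Q_t windows; splits are kept apart."""
    out: list[GPC] = []
    for g in gpcs:
        for lo, hi in qt:
            s, e = max(g.t_s, lo), min(g.t_e, hi)
            if s <= e:
                out.append(GPC(channel=g.channel, t_s=s, t_e=e,
                               peak_stat=g.peak_stat, threshold=g.threshold))
    return out


def ims_predictor_value(grid: np.ndarray, pdef: IMSPredictorDef) -> float:
    """Integral (trapezoidal) average of one channel over a closed interval.

    ``grid`` is the 9 x 100 normalized stride matrix.  A degenerate
    single-node interval returns the node value itself.
    """
    if not (1 <= pdef.t_s <= pdef.t_e <= 100):
        raise ValueError(f"interval [{pdef.t_s}, {pdef.t_e}] outside 1..100")
    c = CHANNELS.index(pdef.channel)
    w = np.asarray(grid, dtype=float)[c, pdef.t_s - 1:pdef.t_e]
    if pdef.t_s == pdef.t_e:
        return float(w[0])
    return float(np.trapezoid(w) / (pdef.t_e - pdef.t_s))


def discover_predictors(grids: np.ndarray, y: np.ndarray,
                        alpha: float = 0.05,
                        qt: tuple[tuple[int, int], ...] = QT_WINDOWS,
                        ) -> tuple[list[IMSPredictorDef], dict]:
    """Full SPM stage: CCA gate -> per-channel Pearson -> GPCs -> Q_t filter.

    Returns the predictor definitions plus a detail dict with the curves
    and intermediate cluster lists.
    """
    cca = spm_cca_curve(grids, y, alpha=alpha)
    mask = cca.supra()
    pec = spm_pearson_curves(grids, y, mask=mask, alpha=alpha)
    gpcs = extract_gpcs(pec)
    filtered = intersect_qt(gpcs, qt)
    defs = [IMSPredictorDef(g.channel, g.t_s, g.t_e) for g in filtered]
    return defs, {"cca": cca, "pearson": pec, "gpcs": gpcs,
                  "gpcs_qt": filtered}


def permutation_threshold(grids: np.ndarray, y: np.ndarray,
                          n_perm: int = 500, alpha: float = 0.05,
                          rng: np.random.Generator | None = None,
                          channel: int = 0) -> float:
    """Permutation FWER threshold for a single-channel Pearson t curve.

    Test oracle only -- not used in the analysis path.
    """
    rng = rng or np.random.default_rng()
    grids = np.asarray(grids, dtype=float)
    y = np.asarray(y, dtype=float)
    n = y.size
    dof = n - 2
    w = _center(grids[:, channel, :])
    wsd = w.std(axis=0)
    maxima = np.empty(n_perm)
    for i in range(n_perm):
        yp = _center(y[rng.permutation(n)])
        ysd = yp.std()
        r = (w * yp[:, None]).mean(axis=0) / (wsd * ysd)
        r = np.clip(r, -1 + 1e-12, 1 - 1e-12)
        t = np.abs(r) * np.sqrt(dof / (1 - r ** 2))
        maxima[i] = t.max()
    return float(np.quantile(maxima, 1 - alpha))
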