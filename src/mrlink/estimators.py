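"""Causal-effect estimators for two-sample Mendelian randomization.

All estimators consume a :class:`~mrlink.harmonize.HarmonizedSet` (or raw
effect arrays for the Wald ratio) and return an :class:`MREstimate` on the
log-odds scale; odds ratios are exponentiated views computed at
construction, never stored separately.

Methods: per-variant Wald ratio; inverse-variance-weighted (IVW) average
under fixed or multiplicative random effects; MR-Egger regression (slope +
intercept); weighted median; weighted and simple mode.  The IVW estimate is
identical whether computed as the precision-weighted mean of Wald ratios or
as a weighted regression of outcome on exposure effects through the origin;
both derivations are exposed so they can be cross-checked.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .harmonize import HarmonizedSet

Z95 = sps.norm.ppf(0.975)


class InsufficientInstrumentsError(ValueError):
    """Fewer instruments than the estimator's minimum."""


@dataclass(frozen=True)
class MREstimate:
    """One method's causal estimate with CI, p, and odds-ratio view."""

    method: str
    beta: float
    se: float
    ci_low: float
    ci_high: float
    pval: float
    n_snp: int

    @property
    def or_value(self) -> float:
        return float(np.exp(self.beta))

    @property
    def or_low(self) -> float:
        return float(np.exp(self.ci_low))

    @property
    def or_high(self) -> float:
        return float(np.exp(self.ci_high))

    def as_dict(self) -> dict:
        return {
            "method": self.method, "n_snp": self.n_snp,
            "beta": self.beta, "se": self.se,
            "ci_low": self.ci_low, "ci_high": self.ci_high, "pval": self.pval,
            "or": self.or_value, "or_low": self.or_low, "or_high": self.or_high,
        }


def _estimate(method: str, beta: float, se: float, n_snp: int,
              dist: str = "norm", t_df: int | None = None) -> MREstimate:
    beta, se = float(beta), float(se)
    if se > 0:
        if dist == "t":
            q = sps.t.ppf(0.975, t_df)
            p = 2.0 * sps.t.sf(abs(beta / se), t_df)
        else:
            q = Z95
            p = 2.0 * sps.norm.sf(abs(beta / se))
        lo, hi = beta - q * se, beta + q * se
    else:  # degenerate: zero sampling variance
        lo = hi = beta
        p = 0.0 if beta != 0 else 1.0
    p = float(min(max(p, np.nextafter(0.0, 1.0)), 1.0))
    return MREstimate(method=method, beta=beta, se=se,
                      ci_low=lo, ci_high=hi, pval=p, n_snp=n_snp)


# ------------------------------------------------------------------ Wald
def wald_ratio(beta_x: float, se_x: float, beta_y: float, se_y: float,
               second_order: bool = False) -> MREstimate:
    """Single-variant causal estimate beta_y / beta_x.

    First-order delta-method se is se_y/|beta_x|; ``second_order`` adds the
    exposure-uncertainty term beta_y²·se_x²/beta_x⁴ under the variance.
    """
    if beta_x == 0:
        raise ValueError("beta_x must be nonzero for a Wald ratio")
    beta = beta_y / beta_x
    var = se_y**2 / beta_x**2
    if second_order:
        var += beta_y**2 * se_x**2 / beta_x**4
    return _estimate("wald_ratio", beta, np.sqrt(var), 1)


# ------------------------------------------------------------------- IVW
def _ivw_core(r: np.ndarray, v: np.ndarray) -> tuple[float, float, float]:
    """(beta, fixed-effects se, Cochran's Q) from ratios and variances."""
    w = 1.0 / v
    beta = float(np.sum(w * r) / np.sum(w))
    se_fe = float(1.0 / np.sqrt(np.sum(w)))
    q = float(np.sum(w * (r - beta) ** 2))
    return beta, se_fe, q


def ivw(h: HarmonizedSet, model: str = "mre") -> MREstimate:
    """Inverse-variance-weighted estimate.

    ``model="fixed"`` uses the fixed-effects se; ``model="mre"`` multiplies
    it by √max(1, Q/(k−1)) — multiplicative random effects with no
    under-dispersion.  Requires ≥ 2 instruments (use the Wald ratio for a
    single instrument).
    """
    if model not in {"fixed", "mre"}:
        raise ValueError("model must be 'fixed' or 'mre'")
    r, v = h.ratios()
    k = r.size
    if k < 2:
        raise InsufficientInstrumentsError("ivw requires >= 2 instruments")
    beta, se_fe, q = _ivw_core(r, v)
    method = "ivw_fe"
    se = se_fe
    if model == "mre":
        method = "ivw_mre"
        se = se_fe * float(np.sqrt(max(1.0, q / (k - 1))))
    return _estimate(method, beta, se, k)


def ivw_regression(h: HarmonizedSet) -> tuple[float, float]:
    """IVW via weighted regression of beta_y on beta_x through the origin,
    weights 1/se_y² — the dual derivation of :func:`ivw` (fixed effects)."""
    bx, by, w = h.beta_x, h.beta_y, 1.0 / h.se_y**2
    denom = np.sum(w * bx**2)
    beta = float(np.sum(w * bx * by) / denom)
    se = float(1.0 / np.sqrt(denom))
    return beta, se


# ----------------------------------------------------------------- Egger
def egger(h: HarmonizedSet) -> tuple[MREstimate, MREstimate]:
    """MR-Egger regression: (slope, intercept) estimates.

    Weighted regression of beta_y on beta_x with a free intercept, weights
    1/se_y², after orienting every row so beta_x ≥ 0.  The slope is the
    pleiotropy-robust causal estimate under InSIDE; the intercept is the
    average directional pleiotropy.  Standard errors carry the
    multiplicative random-effects inflation √max(1, σ̂²); p-values use
    t(k−2).
    """
    bx, by, w = h.beta_x.copy(), h.beta_y.copy(), 1.0 / h.se_y**2
    k = bx.size
    if k < 3:
        raise InsufficientInstrumentsError("egger requires >= 3 instruments")
    flip = bx < 0
    bx[flip], by[flip] = -bx[flip], -by[flip]

    sw = np.sum(w)
    mx, my = np.sum(w * bx) / sw, np.sum(w * by) / sw
    sxx = np.sum(w * (bx - mx) ** 2)
    sxy = np.sum(w * (bx - mx) * (by - my))
    slope = sxy / sxx
    intercept = my - slope * mx
    resid = by - intercept - slope * bx
    sigma2 = float(np.sum(w * resid**2) / (k - 2))
    infl = max(1.0, sigma2)
    se_slope = np.sqrt(infl / sxx)
    se_int = np.sqrt(infl * (1.0 / sw + mx**2 / sxx))
    return (
        _estimate("egger_slope", slope, se_slope, k, dist="t", t_df=k - 2),
        _estimate("egger_intercept", intercept, se_int, k, dist="t", t_df=k - 2),
    )


# -------------------------------------------------------------- medians
def _weighted_median_point(r: np.ndarray, w: np.ndarray) -> float:
    order = np.argsort(r, kind="mergesort")
    r, w = r[order], w[order]
    s = (np.cumsum(w) - 0.5 * w) / np.sum(w)
    return float(np.interp(0.5, s, r))


def _bootstrap_se(h: HarmonizedSet, point_fn, n_boot: int, seed: int) -> float:
    """Parametric bootstrap: resample per-SNP betas from their sampling
    distributions, recompute the point estimate, take the SD."""
    rng = np.random.default_rng(seed)
    bx, sx, by, sy = h.beta_x, h.se_x, h.beta_y, h.se_y
    k = bx.size
    bxs = rng.normal(bx, sx, size=(n_boot, k))
    bys = rng.normal(by, sy, size=(n_boot, k))
    ests = np.array([point_fn(bxs[i], bys[i], sy) for i in range(n_boot)])
    return float(np.std(ests, ddof=1))


def weighted_median(h: HarmonizedSet, n_boot: int = 1000, seed: int = 0) -> MREstimate:
    """Weighted-median estimator: consistent when valid instruments carry
    more than half the total weight.  The estimate interpolates the ordered
    Wald ratios against standardized cumulative inverse-variance weights at
    0.5; the se comes from a parametric bootstrap (deterministic under
    ``seed``)."""
    r, v = h.ratios()
    k = r.size
    if k < 3:
        raise InsufficientInstrumentsError("weighted_median requires >= 3 instruments")
    point = _weighted_median_point(r, 1.0 / v)

    def point_fn(bx, by, sy):
        return _weighted_median_point(by / bx, bx**2 / sy**2)

    se = _bootstrap_se(h, point_fn, n_boot, seed)
    return _estimate("weighted_median", point, se, k)


# ----------------------------------------------------------------- modes
def _mode_point(r: np.ndarray, w: np.ndarray, phi: float) -> float:
    """Kernel-density mode of the ratio set with normal kernel.

    Rule-of-thumb bandwidth (median-absolute-deviation based):
    h = phi · 0.9 · min(sd, MAD/0.6745) · k^(−1/5); degenerate spreads
    return the common ratio directly.
    """
    k = r.size
    sd = np.std(r, ddof=1) if k > 1 else 0.0
    mad = np.median(np.abs(r - np.median(r))) / 0.6745
    s = 0.9 * min(sd, mad if mad > 0 else np.inf) * k ** (-0.2)
    if not np.isfinite(s) or s <= 0:
        return float(np.median(r))
    bw = phi * s
    grid = np.linspace(r.min() - 3 * bw, r.max() + 3 * bw, 1024)
    dens = (w[None, :] * np.exp(-0.5 * ((grid[:, None] - r[None, :]) / bw) ** 2)).sum(axis=1)
    return float(grid[np.argmax(dens)])


def mode_estimator(h: HarmonizedSet, variant: str = "weighted",
                   bandwidth_phi: float = 1.0, n_boot: int = 1000,
                   seed: int = 0) -> MREstimate:
    """Mode-based estimate: the kernel-density mode of the Wald-ratio
    distribution, unweighted (``variant="simple"``) or inverse-variance
    weighted (``variant="weighted"``).  se by parametric bootstrap."""
    if variant not in {"simple", "weighted"}:
        raise ValueError("variant must be 'simple' or 'weighted'")
    if bandwidth_phi <= 0:
        raise ValueError("bandwidth_phi must be > 0")
    r, v = h.ratios()
    k = r.size
    if k < 3:
        raise InsufficientInstrumentsError("mode estimator requires >= 3 instruments")
    w = 1.0 / v if variant == "weighted" else np.ones(k)
    point = _mode_point(r, w / w.sum(), bandwidth_phi)

    def point_fn(bx, by, sy):
        rr = by / bx
        ww = bx**2 / sy**2 if variant == "weighted" else np.ones(k)
        return _mode_point(rr, ww / ww.sum(), bandwidth_phi)

    se = _bootstrap_se(h, point_fn, n_boot, seed)
    return _estimate(f"{variant}_mode", point, se, k)


# ------------------------------------------------------------- reporting
def all_estimates(h: HarmonizedSet, n_boot: int = 1000, seed: int = 0) -> list[MREstimate]:
    """The full method panel: both IVW variants, Egger slope + intercept,
    weighted median, weighted and simple mode (requires ≥ 3 instruments)."""
    slope, intercept = egger(h)
    return [
        ivw(h, "fixed"),
        ivw(h, "mre"),
        slope,
        intercept,
        weighted_median(h, n_boot=n_boot, seed=seed),
        mode_estimator(h, "weighted", n_boot=n_boot, seed=seed + 1),
        mode_estimator(h, "simple", n_boot=n_boot, seed=seed + 2),
    ]
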