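"""Heterogeneity, pleiotropy, outlier, directionality, and influence diagnostics.

* Cochran's Q over the per-variant Wald ratios, with I² = max(0, (Q−df)/Q).
* MR-PRESSO: a parametric-simulation residual-sum-of-squares test for
  horizontal pleiotropy with per-variant outlier detection, an
  outlier-corrected IVW estimate, and a distortion test.
* Leave-one-out IVW influence table.
* Steiger directionality: compare the variance each instrument explains in
  exposure versus outcome; instruments explaining more outcome than
  exposure variance are filtered, and the aggregate comparison gives the
  inferred causal direction.
* Funnel table (per-SNP ratio vs precision) for asymmetry plots.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .estimators import (InsufficientInstrumentsError, MREstimate, _estimate,
                         _ivw_core, ivw)
from .harmonize import HarmonizedSet


@dataclass
class PressoReport:
    global_rss: float
    global_pval: float
    outlier_pvals: pd.Series          # indexed by snp_id
    outlier_flags: pd.Series
    raw_estimate: MREstimate
    corrected_estimate: MREstimate | None
    distortion_pval: float | None

    @property
    def n_outliers(self) -> int:
        return int(self.outlier_flags.sum())


@dataclass
class SensitivityReport:
    q_stat: float
    q_df: int
    q_pval: float
    i2: float
    egger_intercept: float
    egger_intercept_pval: float
    presso: PressoReport | None
    loo_table: pd.DataFrame
    steiger_direction: str
    steiger_pval: float


def cochran_q(h: HarmonizedSet) -> tuple[float, int, float, float]:
    """Cochran's Q across Wald ratios about the fixed-effects IVW mean.

    Returns (Q, df, p, I²) with df = k−1, p from chi-square(df), and
    I² = max(0, (Q − df)/Q)·100, zero when Q = 0.
    """
    r, v = h.ratios()
    k = r.size
    if k < 2:
        raise InsufficientInstrumentsError("cochran_q requires >= 2 instruments")
    _, _, q = _ivw_core(r, v)
    df = k - 1
    p = float(sps.chi2.sf(q, df))
    i2 = 0.0 if q <= 0 else max(0.0, (q - df) / q) * 100.0
    return q, df, p, i2


# ------------------------------------------------------------- MR-PRESSO
def _loo_slopes(bx: np.ndarray, by: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Leave-one-out IVW (regression-through-origin) slope for each SNP,
    vectorized: slope_(−i) = (S1 − w_i·bx_i·by_i)/(S2 − w_i·bx_i²)."""
    s1 = np.sum(w * bx * by)
    s2 = np.sum(w * bx**2)
    return (s1 - w * bx * by) / (s2 - w * bx**2)


def mr_presso(h: HarmonizedSet, n_sim: int = 1000, seed: int = 0,
              outlier_alpha: float = 0.05) -> PressoReport:
    """MR-PRESSO global, outlier, and distortion tests.

    The observed statistic is the inverse-variance-weighted residual sum of
    squares of each SNP against the IVW slope fitted without it.  Its null
    distribution comes from ``n_sim`` parametric simulations of outcome
    (and exposure) effects under the no-pleiotropy model beta_y = β·beta_x.
    Per-SNP squared residuals against their own simulated nulls give
    outlier p-values, Bonferroni-flagged at ``outlier_alpha``/k.  When
    outliers are flagged, the outlier-corrected IVW is reported together
    with a distortion p-value comparing the observed estimate shift against
    shifts from removing random same-size subsets.  Deterministic under
    ``seed``.
    """
    bx, sx, by, sy = h.beta_x, h.se_x, h.beta_y, h.se_y
    k = bx.size
    if k < 4:
        raise InsufficientInstrumentsError("mr_presso requires >= 4 instruments")
    rng = np.random.default_rng(seed)
    w = 1.0 / sy**2

    slopes_loo = _loo_slopes(bx, by, w)
    obs_resid2 = w * (by - slopes_loo * bx) ** 2
    obs_rss = float(np.sum(obs_resid2))

    # parametric null: redraw both sides around the no-pleiotropy model
    beta0 = float(np.sum(w * bx * by) / np.sum(w * bx**2))
    bx_sim = rng.normal(bx, sx, size=(n_sim, k))
    by_sim = rng.normal(beta0 * bx, sy, size=(n_sim, k))
    s1 = np.sum(w * bx_sim * by_sim, axis=1, keepdims=True)
    s2 = np.sum(w * bx_sim**2, axis=1, keepdims=True)
    slopes_sim = (s1 - w * bx_sim * by_sim) / (s2 - w * bx_sim**2)
    sim_resid2 = w * (by_sim - slopes_sim * bx_sim) ** 2
    sim_rss = sim_resid2.sum(axis=1)

    global_pval = float((np.sum(sim_rss >= obs_rss) + 1) / (n_sim + 1))
    outlier_p = (np.sum(sim_resid2 >= obs_resid2, axis=0) + 1) / (n_sim + 1)
    flags = outlier_p < outlier_alpha / k

    snp_ids = h.df["snp_id"]
    outlier_pvals = pd.Series(outlier_p, index=snp_ids, name="outlier_pval")
    outlier_flags = pd.Series(flags, index=snp_ids, name="outlier")

    raw = ivw(h, "mre")
    corrected = None
    distortion_pval = None
    n_out = int(flags.sum())
    if 0 < n_out < k - 1:
        corrected = ivw(h.drop(snp_ids[flags]), "mre")
        obs_dist = (corrected.beta - raw.beta) / abs(raw.beta) if raw.beta != 0 else 0.0
        null_dist = np.empty(n_sim)
        r, v = h.ratios()
        wr = 1.0 / v
        inlier_idx = np.flatnonzero(~flags)
        for i in range(n_sim):
            keep = rng.choice(inlier_idx, size=k - n_out, replace=True)
            b = np.sum(wr[keep] * r[keep]) / np.sum(wr[keep])
            null_dist[i] = (b - raw.beta) / abs(raw.beta) if raw.beta != 0 else 0.0
        distortion_pval = float(
            (np.sum(np.abs(null_dist) >= abs(obs_dist)) + 1) / (n_sim + 1))
    return PressoReport(global_rss=obs_rss, global_pval=global_pval,
                        outlier_pvals=outlier_pvals, outlier_flags=outlier_flags,
                        raw_estimate=raw, corrected_estimate=corrected,
                        distortion_pval=distortion_pval)


# --------------------------------------------------------- leave-one-out
def leave_one_out(h: HarmonizedSet) -> pd.DataFrame:
    """IVW (multiplicative random effects) omitting each SNP in turn, plus
    the all-SNP estimate as the reference row labelled "All"."""
    if len(h) < 3:
        raise InsufficientInstrumentsError("leave_one_out requires >= 3 instruments")
    rows = []
    for s in h.df["snp_id"]:
        est = ivw(h.drop([s]), "mre")
        rows.append({"snp_id": s, **{k2: v for k2, v in est.as_dict().items()
                                     if k2 != "method"}})
    full = ivw(h, "mre")
    rows.append({"snp_id": "All", **{k2: v for k2, v in full.as_dict().items()
                                     if k2 != "method"}})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------- Steiger
def _r2_per_snp(beta: np.ndarray, se: np.ndarray, eaf: np.ndarray,
                n: int, binary: bool, case_fraction: float | None) -> np.ndarray:
    """Variance explained per SNP.  With allele frequencies the
    2·maf(1−maf)·beta² formula is used (times K(1−K) on the observed scale
    for a binary trait); otherwise the F-based z²/(z²+n−2) approximation."""
    eaf = np.asarray(eaf, float)
    have_freq = np.isfinite(eaf) & (eaf > 0) & (eaf < 1)
    z2 = (beta / se) ** 2
    r2 = z2 / (z2 + max(n - 2, 1))
    if have_freq.any():
        maf = np.minimum(eaf, 1 - eaf)
        freq_r2 = 2.0 * maf * (1.0 - maf) * beta**2
        if binary and case_fraction is not None:
            freq_r2 = freq_r2 * case_fraction * (1.0 - case_fraction)
        r2 = np.where(have_freq, freq_r2, r2)
    return r2


def steiger(h: HarmonizedSet, n_exposure: int | None = None,
            n_outcome: int | None = None) -> tuple[pd.Series, str, float]:
    """Steiger directionality test and per-SNP filtering flags.

    Returns (keep flags indexed by snp_id, direction, p).  A SNP is kept
    when it explains strictly more variance in the exposure than in the
    outcome.  Direction is ``exposure_to_outcome`` when the summed exposure
    r² over kept SNPs exceeds the summed outcome r², the reverse otherwise,
    ``undetermined`` when nothing is kept.  The p-value compares the two
    aggregate correlations with a Fisher-z test.
    """
    n_x = n_exposure or h.n_exposure
    n_y = n_outcome or h.n_outcome
    if not n_x or not n_y:
        raise ValueError("steiger requires exposure and outcome sample sizes")
    r2_x = _r2_per_snp(h.beta_x, h.se_x, h.df["eaf_exposure"].to_numpy(),
                       n_x, False, None)
    r2_y = _r2_per_snp(h.beta_y, h.se_y, h.df["eaf_outcome"].to_numpy(),
                       n_y, h.outcome_binary, h.outcome_case_fraction)
    keep = pd.Series(r2_x > r2_y, index=h.df["snp_id"], name="steiger_keep")

    if keep.any():
        tot_x = float(np.sum(r2_x[keep.to_numpy()]))
        tot_y = float(np.sum(r2_y[keep.to_numpy()]))
    else:
        tot_x = float(np.sum(r2_x))
        tot_y = float(np.sum(r2_y))
    if tot_x > tot_y:
        direction = "exposure_to_outcome"
    elif tot_y > tot_x:
        direction = "outcome_to_exposure"
    else:
        direction = "undetermined"
    if not keep.any() and tot_x == tot_y:
        direction = "undetermined"

    rx = np.sqrt(min(tot_x, 1.0 - 1e-12))
    ry = np.sqrt(min(tot_y, 1.0 - 1e-12))
    z = (np.arctanh(rx) - np.arctanh(ry)) / np.sqrt(1.0 / (n_x - 3) + 1.0 / (n_y - 3))
    pval = float(2.0 * sps.norm.sf(abs(z)))
    return keep, direction, pval


def funnel_table(h: HarmonizedSet) -> pd.DataFrame:
    """Per-SNP Wald ratio and precision (1/se of the ratio) for funnel plots."""
    if len(h) < 1:
        raise InsufficientInstrumentsError("funnel_table requires >= 1 instrument")
    r, v = h.ratios()
    return pd.DataFrame({
        "snp_id": h.df["snp_id"], "ratio": r, "precision": 1.0 / np.sqrt(v)})


def sensitivity_suite(h: HarmonizedSet, n_sim: int = 1000, seed: int = 0) -> SensitivityReport:
    """Run the full diagnostic panel on one harmonized set."""
    from .estimators import egger

    q, df, qp, i2 = cochran_q(h)
    _, intercept = egger(h)
    presso = None
    if len(h) >= 4:
        presso = mr_presso(h, n_sim=n_sim, seed=seed)
    loo = leave_one_out(h)
    try:
        _, direction, sp = steiger(h)
    except ValueError:
        direction, sp = "undetermined", float("nan")
    return SensitivityReport(
        q_stat=q, q_df=df, q_pval=qp, i2=i2,
        egger_intercept=intercept.beta, egger_intercept_pval=intercept.pval,
        presso=presso, loo_table=loo,
        steiger_direction=direction, steiger_pval=sp)
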