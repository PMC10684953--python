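"""Multivariable Mendelian randomization: direct effects conditional on covariates.

Instruments are the union of each exposure's genome-wide-significant
variants, jointly LD-clumped with each variant ranked by its minimum p
across exposures.  The estimator is a weighted multiple regression of
outcome effects on the matrix of exposure effects with no intercept,
weights 1/se_y², with multiplicative random-effects se inflation
(df = rows − exposures).  The default pipeline adjusts one covariate at a
time; a joint all-covariate model is available behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .estimators import InsufficientInstrumentsError, MREstimate, _estimate
from .harmonize import HarmonizedSet, harmonize
from .instruments import EmptyInstrumentError, InstrumentConfig, select_significant
from .ld import LDReference
from .sumstats import SummaryStats


class CollinearityError(ValueError):
    """Exposure effect columns are (near-)collinear."""


@dataclass
class MVHarmonizedSet:
    """Per-variant effects for several exposures and one outcome, all on the
    same allele orientation per row."""

    snp_ids: list[str]
    exposure_names: list[str]
    beta_x: np.ndarray       # (n_snp, n_exposure)
    se_x: np.ndarray
    beta_y: np.ndarray       # (n_snp,)
    se_y: np.ndarray
    exclusions: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        n, p = self.beta_x.shape
        if n < p + 2:
            raise InsufficientInstrumentsError(
                f"MVMR needs at least exposures+2 = {p + 2} rows, got {n}")

    @property
    def n_snp(self) -> int:
        return self.beta_x.shape[0]

    @property
    def n_exposure(self) -> int:
        return self.beta_x.shape[1]


def mvmr_select_instruments(
    exposures: list[SummaryStats],
    ld: LDReference,
    config: InstrumentConfig | None = None,
) -> list[str]:
    """Union of per-exposure significant variants, jointly clumped by the
    minimum p across exposures."""
    from .instruments import ld_clump

    config = config or InstrumentConfig()
    if len(exposures) < 2:
        raise ValueError("MVMR requires >= 2 exposures")
    union: dict[str, tuple[float, str, int]] = {}
    for stats in exposures:
        for s in select_significant(stats, config.p_threshold):
            row = stats.df.loc[stats.df.snp_id == s].iloc[0]
            p = float(row.pval)
            if s not in union or p < union[s][0]:
                union[s] = (p, str(row.chrom), int(row.pos))
    if not union:
        raise EmptyInstrumentError("mvmr significance")

    merged = SummaryStats(
        trait_name="mvmr_union",
        df=pd.DataFrame([
            {"snp_id": s, "chrom": c, "pos": pos, "effect_allele": "A",
             "other_allele": "G", "eaf": np.nan, "beta": 0.0, "se": 1.0,
             "pval": p, "n": 1}
            for s, (p, c, pos) in union.items()]),
        sample_n=1)
    return ld_clump(list(union), merged, ld, config.clump_r2,
                    config.clump_window_kb)


def mv_harmonize(
    instruments: list[str],
    exposures: list[SummaryStats],
    outcome: SummaryStats,
    palindrome_policy: str = "infer",
) -> MVHarmonizedSet:
    """Harmonize each exposure against the outcome and intersect on the
    variants retained by every pairwise harmonization."""
    sets: list[HarmonizedSet] = []
    for exp in exposures:
        sets.append(harmonize(instruments, exp, outcome, palindrome_policy))
    common = set(sets[0].df.snp_id)
    for hs in sets[1:]:
        common &= set(hs.df.snp_id)
    common_sorted = [s for s in instruments if s in common]
    if not common_sorted:
        raise EmptyInstrumentError("mvmr harmonization")

    frames = [hs.df.set_index("snp_id").loc[common_sorted] for hs in sets]
    beta_x = np.column_stack([f["beta_exposure"].to_numpy(float) for f in frames])
    se_x = np.column_stack([f["se_exposure"].to_numpy(float) for f in frames])
    beta_y = frames[0]["beta_outcome"].to_numpy(float)
    se_y = frames[0]["se_outcome"].to_numpy(float)
    exclusions = {s: hs.exclusions.get(s, "dropped by co-exposure")
                  for hs in sets for s in hs.exclusions}
    return MVHarmonizedSet(
        snp_ids=common_sorted,
        exposure_names=[e.trait_name for e in exposures],
        beta_x=beta_x, se_x=se_x, beta_y=beta_y, se_y=se_y,
        exclusions=exclusions)


def mvmr_ivw(m: MVHarmonizedSet) -> list[MREstimate]:
    """Weighted multiple regression of beta_y on the beta_x matrix, no
    intercept, weights 1/se_y².  One estimate per exposure; se carries the
    multiplicative random-effects factor √max(1, RSS/(n−p))."""
    X, y, w = m.beta_x, m.beta_y, 1.0 / m.se_y**2
    n, p = X.shape

    # collinearity guard: name the offending pair (an all-zero column is
    # instead resolved to a zero slope by the pseudoinverse fit below)
    if p > 1:
        with np.errstate(invalid="ignore", divide="ignore"):
            corr = np.corrcoef(X, rowvar=False)
        for i in range(p):
            for j in range(i + 1, p):
                if np.isfinite(corr[i, j]) and abs(corr[i, j]) > 1 - 1e-10:
                    raise CollinearityError(
                        f"exposures '{m.exposure_names[i]}' and "
                        f"'{m.exposure_names[j]}' are collinear")

    fit = sm.WLS(y, X, weights=w).fit()
    dof = n - p
    sigma2 = float(fit.scale)  # weighted RSS / dof
    infl = np.sqrt(max(1.0, sigma2))
    # se under unit residual variance, inflated by the floor:
    # pinv also resolves degenerate (all-zero) columns to se = 0
    cov_unit = np.linalg.pinv(X.T @ (w[:, None] * X))
    base_se = np.sqrt(np.maximum(np.diag(cov_unit), 0.0))
    out = []
    for j, name in enumerate(m.exposure_names):
        beta = float(fit.params[j])
        se = float(base_se[j] * infl)
        est = _estimate(f"mvmr_ivw[{name}]", beta, se, n, dist="t", t_df=dof)
        out.append(est)
    return out


def conditional_f(m: MVHarmonizedSet) -> list[float]:
    """Conditional instrument-strength F per exposure: the weighted F of
    each exposure's effects after regressing out the other exposures
    (standard MVMR hygiene, reported alongside the estimates)."""
    X, p = m.beta_x, m.beta_x.shape[1]
    out = []
    for j in range(p):
        xj = X[:, j]
        others = np.delete(X, j, axis=1)
        w = 1.0 / m.se_x[:, j] ** 2
        if others.size:
            proj = others @ np.linalg.lstsq(others, xj, rcond=None)[0]
            resid = xj - proj
        else:
            resid = xj
        out.append(float(np.sum(w * resid**2) / m.n_snp))
    return out
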