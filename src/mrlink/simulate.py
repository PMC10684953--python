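"""Synthetic GWAS summary statistics with known ground truth.

Generates the three kinds of inputs the analysis consumes:

* a block-diagonal LD reference (``simulate_ld_reference``),
* an exposure/outcome summary-statistics pair with a known causal effect and
  configurable horizontal pleiotropy (``simulate_mr_sumstats``), and
* per-variant z-scores following the LD-score-regression model
  (``simulate_ldsc_zscores``).

All generators are pure functions of (config, seed): the same seed gives
byte-identical output.

The statistical model behind ``simulate_mr_sumstats``: per-variant true
exposure effects γ_i are drawn i.i.d. normal and rescaled so the variance
they explain, Σ 2·maf_i(1−maf_i)·γ_i², equals the configured total R² on a
unit-variance exposure.  Observed exposure effects are γ_i plus sampling
noise with se_i = 1/√(2·maf_i(1−maf_i)·n_x).  Outcome effects are
β·γ_i + α_i + noise, where β is the causal effect on the log-odds scale and
α_i the direct (pleiotropic) effect of invalid instruments; the outcome se
additionally scales by 1/√(K(1−K)) for a binary outcome with case
fraction K.  Pleiotropy modes: ``balanced`` (zero-mean α), ``directional``
(nonzero-mean α, InSIDE holds), ``correlated`` (α proportional to γ,
violating InSIDE).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ld import LDReference
from .sumstats import SummaryStats


class SimulationError(ValueError):
    """Configuration cannot be realized (e.g. infeasible total R²)."""


@dataclass
class MRSimConfig:
    """Parameters of one exposure→outcome summary-statistics simulation."""

    # defaults emulate a urate-scale continuous exposure instrumented by ~90
    # independent genome-wide-significant SNPs explaining ~8% of variance,
    # against a low-prevalence binary outcome of comparable cohort size
    n_snp: int = 89
    causal_beta: float = 0.0
    n_exposure: int = 288_649
    n_outcome: int = 274_660
    maf_range: tuple[float, float] = (0.05, 0.5)
    exposure_r2_total: float = 0.0792
    prop_invalid: float = 0.0
    pleiotropy_mode: str = "none"  # none | balanced | directional | correlated
    pleiotropy_sd: float = 0.0
    pleiotropy_mean: float = 0.0
    outcome_binary: bool = True
    outcome_case_fraction: float = 2_843 / 274_660
    seed: int = 0

    def validate(self) -> None:
        if not 0 <= self.prop_invalid < 1:
            raise SimulationError("prop_invalid must be in [0, 1)")
        if not 0 < self.exposure_r2_total < 1:
            raise SimulationError("exposure_r2_total must be in (0, 1)")
        if self.pleiotropy_sd < 0:
            raise SimulationError("pleiotropy_sd must be >= 0")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise SimulationError("maf_range must lie within (0, 0.5]")
        if self.pleiotropy_mode not in {"none", "balanced", "directional", "correlated"}:
            raise SimulationError(f"unknown pleiotropy_mode {self.pleiotropy_mode!r}")
        if self.outcome_binary and not 0 < self.outcome_case_fraction < 1:
            raise SimulationError("outcome_case_fraction must be in (0, 1)")


@dataclass
class SimTruth:
    """Ground truth of one simulated dataset — the test oracle."""

    causal_beta: float
    gamma: np.ndarray          # per-variant true exposure effects
    alpha: np.ndarray          # per-variant pleiotropic (direct) effects
    invalid: np.ndarray        # boolean invalid-instrument flags
    maf: np.ndarray

    def to_frame(self, snp_ids) -> pd.DataFrame:
        return pd.DataFrame({
            "snp_id": snp_ids, "maf": self.maf, "gamma": self.gamma,
            "alpha": self.alpha, "invalid": self.invalid,
        })


@dataclass
class LDSCSimConfig:
    """Parameters of a two-trait LD-score-regression z-score simulation."""

    m_variants: int = 20_000
    h2_trait1: float = 0.1
    h2_trait2: float = 0.05
    rg_true: float = 0.0
    n1: int = 50_000
    n2: int = 50_000
    n_overlap: int = 0
    pheno_corr: float | None = None  # defaults to rg_true
    ld_score_shape: float = 2.0      # gamma shape for ℓ − 1
    ld_score_scale: float = 20.0     # gamma scale for ℓ − 1
    seed: int = 0

    def validate(self) -> None:
        if not -1 <= self.rg_true <= 1:
            raise SimulationError("|rg_true| must be <= 1")
        for h2 in (self.h2_trait1, self.h2_trait2):
            if not 0 <= h2 <= 1:
                raise SimulationError("h2 values must be in [0, 1]")
        if self.n_overlap < 0 or self.n_overlap > min(self.n1, self.n2):
            raise SimulationError("n_overlap must be in [0, min(n1, n2)]")


# --------------------------------------------------------------------------
def simulate_ld_reference(
    n_block: int,
    block_size: int,
    within_block_r2: float = 0.5,
    maf_range: tuple[float, float] = (0.05, 0.5),
    seed: int = 0,
    decay: bool = True,
) -> LDReference:
    """Block-diagonal LD reference.

    r² between variants of different blocks is exactly 0.  Within a block the
    r² between variants at index distance d is ``within_block_r2 ** d`` when
    ``decay`` is set, else the constant ``within_block_r2``.  LD scores are
    1 + Σ r² over the block, so ``block_size=1`` gives ℓ = 1 everywhere.
    """
    if block_size < 1:
        raise SimulationError("block_size must be >= 1")
    rng = np.random.default_rng(seed)
    m = n_block * block_size
    block_ids = np.repeat(np.arange(n_block), block_size)
    # one variant per kb, blocks 1 Mb apart so windows behave sensibly
    pos = 1 + block_ids * 1_000_000 + np.tile(np.arange(block_size), n_block) * 1_000
    index = pd.DataFrame({
        "snp_id": [f"rs{i + 1}" for i in range(m)],
        "chrom": "1",
        "pos": pos,
        "maf": rng.uniform(*maf_range, size=m),
    })

    def r2_within(i: int, j: int) -> float:
        d = abs(i - j)
        return within_block_r2 ** d if decay else within_block_r2

    return LDReference.from_blocks(index, block_ids, r2_within)


def _exposure_se(maf: np.ndarray, n: int) -> np.ndarray:
    return 1.0 / np.sqrt(2.0 * maf * (1.0 - maf) * n)


def simulate_mr_sumstats(
    config: MRSimConfig,
    ld: LDReference | None = None,
) -> tuple[SummaryStats, SummaryStats, SimTruth]:
    """Draw an exposure/outcome summary-statistics pair with known truth.

    Instruments are LD-independent (one per block) unless an explicit
    reference with correlated variants is supplied; this isolates estimator
    behaviour from clumping behaviour.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    k = config.n_snp

    if ld is not None and len(ld.snp_ids) >= k:
        snp_ids = ld.snp_ids[:k]
        maf = ld.index["maf"].to_numpy()[:k] if "maf" in ld.index.columns \
            else rng.uniform(*config.maf_range, size=k)
        chrom = [ld.chromosome(s) for s in snp_ids]
        pos = [ld.position(s) for s in snp_ids]
    else:
        snp_ids = [f"rs{i + 1}" for i in range(k)]
        maf = rng.uniform(*config.maf_range, size=k)
        chrom = ["1"] * k
        pos = (1 + np.arange(k) * 1_000_000).tolist()

    var_g = 2.0 * maf * (1.0 - maf)
    # effects reported for the exposure-raising allele: half-normal magnitudes
    gamma = np.abs(rng.standard_normal(k))
    raw_r2 = float(np.sum(var_g * gamma**2))
    gamma *= np.sqrt(config.exposure_r2_total / raw_r2)
    if np.sum(var_g * gamma**2) >= 1:
        raise SimulationError("exposure_r2_total infeasible after scaling")

    n_invalid = int(round(config.prop_invalid * k))
    invalid = np.zeros(k, dtype=bool)
    if n_invalid:
        invalid[rng.choice(k, size=n_invalid, replace=False)] = True

    alpha = np.zeros(k)
    mode = config.pleiotropy_mode
    if mode == "balanced":
        alpha[invalid] = rng.normal(0.0, config.pleiotropy_sd, size=n_invalid)
    elif mode == "directional":
        alpha[invalid] = rng.normal(config.pleiotropy_mean, config.pleiotropy_sd,
                                    size=n_invalid)
    elif mode == "correlated":
        # direct effects proportional to instrument strength: violates InSIDE
        sd_g = float(np.std(gamma)) or 1.0
        alpha[invalid] = (config.pleiotropy_mean
                          + config.pleiotropy_sd * gamma[invalid] / sd_g)

    se_x = _exposure_se(maf, config.n_exposure)
    beta_x = gamma + rng.normal(0.0, se_x)

    se_y = _exposure_se(maf, config.n_outcome)
    if config.outcome_binary:
        kk = config.outcome_case_fraction
        se_y = se_y / np.sqrt(kk * (1.0 - kk))
    beta_y = config.causal_beta * gamma + alpha + rng.normal(0.0, se_y)

    from scipy import stats as sps
    p_x = 2.0 * sps.norm.sf(np.abs(beta_x / se_x))
    p_y = 2.0 * sps.norm.sf(np.abs(beta_y / se_y))
    tiny = np.nextafter(0.0, 1.0)
    p_x = np.clip(p_x, tiny, 1.0)
    p_y = np.clip(p_y, tiny, 1.0)

    alleles_ea = rng.choice(["A", "C"], size=k)
    alleles_oa = np.where(alleles_ea == "A", "G", "T")  # never palindromic

    def frame(beta, se, pval, n):
        return pd.DataFrame({
            "snp_id": snp_ids, "chrom": chrom, "pos": pos,
            "effect_allele": alleles_ea, "other_allele": alleles_oa,
            "eaf": maf, "beta": beta, "se": se, "pval": pval, "n": n,
        })

    exposure = SummaryStats(
        trait_name="sim_exposure",
        df=frame(beta_x, se_x, p_x, config.n_exposure),
        is_binary=False, sample_n=config.n_exposure)
    if config.outcome_binary:
        n_case = int(round(config.outcome_case_fraction * config.n_outcome))
        outcome = SummaryStats(
            trait_name="sim_outcome",
            df=frame(beta_y, se_y, p_y, config.n_outcome),
            is_binary=True, n_case=n_case,
            n_control=config.n_outcome - n_case)
    else:
        outcome = SummaryStats(
            trait_name="sim_outcome",
            df=frame(beta_y, se_y, p_y, config.n_outcome),
            is_binary=False, sample_n=config.n_outcome)

    truth = SimTruth(causal_beta=config.causal_beta, gamma=gamma,
                     alpha=alpha, invalid=invalid, maf=maf)
    return exposure, outcome, truth


def simulate_ldsc_zscores(
    config: LDSCSimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, np.ndarray]:
    """Per-variant z statistics following the LD-score-regression model.

    For variant j with LD score ℓ_j out of m variants,
    E[z1²] = 1 + n1·h1²·ℓ_j/m and
    E[z1·z2] = r_g·√(h1²·h2²)·√(n1·n2)·ℓ_j/m + n_overlap·r_p/√(n1·n2),
    with r_p the phenotypic correlation in the overlapping samples
    (defaults to r_g).  z pairs are drawn bivariate normal with those
    moments.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    m = config.m_variants
    ell = 1.0 + rng.gamma(config.ld_score_shape, config.ld_score_scale, size=m)

    var1 = 1.0 + config.n1 * config.h2_trait1 * ell / m
    var2 = 1.0 + config.n2 * config.h2_trait2 * ell / m
    r_p = config.rg_true if config.pheno_corr is None else config.pheno_corr
    cov = (config.rg_true * np.sqrt(config.h2_trait1 * config.h2_trait2)
           * np.sqrt(config.n1 * config.n2) * ell / m
           + config.n_overlap * r_p / np.sqrt(config.n1 * config.n2))

    # draw (z1, z2) via Cholesky of the 2x2 covariance per variant
    s1 = np.sqrt(var1)
    rho = np.clip(cov / np.sqrt(var1 * var2), -1.0, 1.0)
    u1 = rng.standard_normal(m)
    u2 = rng.standard_normal(m)
    z1 = s1 * u1
    z2 = np.sqrt(var2) * (rho * u1 + np.sqrt(1.0 - rho**2) * u2)

    snp_ids = [f"rs{i + 1}" for i in range(m)]
    t1 = pd.DataFrame({"snp_id": snp_ids, "z": z1, "n": config.n1})
    t2 = pd.DataFrame({"snp_id": snp_ids, "z": z2, "n": config.n2})
    return t1, t2, ell
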