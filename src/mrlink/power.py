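"""Statistical power for Mendelian randomization with a binary outcome.

Non-centrality-parameter calculation for a case-control outcome:

    b   = K·(OR/(1 + K·(OR − 1)) − 1)        attenuated effect on the
                                             observed (risk-difference) scale
    v   = (K·(1 − K) − b²)/(N·R²)            variance of the IV estimator
    NCP = b²/v
    power = P[χ²(1, NCP) > χ²₁(1 − α) quantile]

with N the total outcome sample size, K the case fraction, R² the variance
of the exposure explained by the instruments, OR the odds ratio per
exposure unit, and α the two-sided significance level.  At OR = 1 the NCP
is zero and power equals α exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps


@dataclass(frozen=True)
class PowerInputs:
    n_total: int
    case_fraction: float
    r2_instruments: float
    odds_ratio: float
    alpha: float = 0.05

    def validate(self) -> None:
        if not 0 < self.case_fraction < 1:
            raise ValueError("case_fraction must be in (0, 1)")
        if not 0 < self.r2_instruments < 1:
            raise ValueError("r2_instruments must be in (0, 1)")
        if self.odds_ratio <= 0:
            raise ValueError("odds_ratio must be > 0")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.n_total < 1:
            raise ValueError("n_total must be positive")


def ncp(p: PowerInputs) -> float:
    """Non-centrality parameter of the association chi-square."""
    p.validate()
    k, orr = p.case_fraction, p.odds_ratio
    b = k * (orr / (1.0 + k * (orr - 1.0)) - 1.0)
    v = (k * (1.0 - k) - b**2) / (p.n_total * p.r2_instruments)
    return b**2 / v


def mr_power_binary(p: PowerInputs) -> float:
    """Power to detect the configured odds ratio at level ``alpha``: the
    upper-tail mass of a non-central chi-square(1, NCP) beyond the central
    (1 − α) quantile."""
    p.validate()
    lam = ncp(p)
    crit = sps.chi2.ppf(1.0 - p.alpha, df=1)
    if lam == 0.0:
        return p.alpha
    return float(sps.ncx2.sf(crit, df=1, nc=lam))


def power_report(p: PowerInputs) -> str:
    """Human-readable report with the pinned formula spelled out."""
    lam = ncp(p)
    pw = mr_power_binary(p)
    return (
        "MR power (binary outcome, NCP method)\n"
        f"  N total          : {p.n_total}\n"
        f"  case fraction K  : {p.case_fraction:.6g}\n"
        f"  instrument R^2   : {p.r2_instruments:.6g}\n"
        f"  odds ratio       : {p.odds_ratio:.6g}\n"
        f"  alpha            : {p.alpha:.6g}\n"
        f"  NCP              : {lam:.6g}\n"
        f"  power            : {pw:.4f}\n"
        "  formula: b = K*(OR/(1+K*(OR-1)) - 1); v = (K*(1-K) - b^2)/(N*R^2);\n"
        "           NCP = b^2/v; power = P[chi2(1, NCP) > chi2_1(1-alpha)]\n"
    )
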