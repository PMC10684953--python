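"""LD score regression: SNP heritability and cross-trait genetic correlation.

Univariate model: for variant j with LD score ℓ_j out of m variants and
study size n, E[z_j²] = 1 + n·h²·ℓ_j/m + (intercept − 1), estimated by a
weighted regression of z² on n·ℓ/m with a free intercept (the intercept
absorbs confounding and population stratification).  Cross-trait model:
E[z1_j·z2_j] = √(n1·n2)·ρ_g·ℓ_j/m + intercept, where the intercept absorbs
sample overlap; the genetic correlation is r_g = ρ_g/√(h1²·h2²).

Weights combine the heteroskedasticity term 1/(1 + n·h²·ℓ/m)² with the 1/ℓ
oversampling correction, applied in two passes (initial weights, then
weights from the first-pass estimate).  Uncertainty comes from a
delete-one block jackknife over contiguous variant blocks (a proxy for
genomic order), applied to the full ratio statistic for r_g.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps


class InsufficientDataError(ValueError):
    """Too few variants for the requested jackknife."""


@dataclass
class LDSCResult:
    h2_1: float
    h2_1_se: float
    h2_2: float | None
    h2_2_se: float | None
    intercept_1: float
    intercept_2: float | None
    intercept_cross: float | None
    rg: float | None
    rg_se: float | None
    rg_pval: float | None
    n_blocks: int
    rg_clamped: bool = False
    degenerate: bool = False


def _block_bounds(m: int, n_blocks: int) -> list[tuple[int, int]]:
    edges = np.linspace(0, m, n_blocks + 1).astype(int)
    return [(edges[i], edges[i + 1]) for i in range(n_blocks)]


def _wls(x: np.ndarray, y: np.ndarray, w: np.ndarray,
         mask: np.ndarray | None = None) -> tuple[float, float]:
    """Weighted least squares of y on x with intercept → (slope, intercept)."""
    if mask is not None:
        x, y, w = x[mask], y[mask], w[mask]
    sw = np.sum(w)
    mx, my = np.sum(w * x) / sw, np.sum(w * y) / sw
    sxx = np.sum(w * (x - mx) ** 2)
    if sxx <= 0:
        raise InsufficientDataError("LD scores are constant: slope and "
                                    "intercept are not separately identifiable")
    slope = np.sum(w * (x - mx) * (y - my)) / sxx
    return float(slope), float(my - slope * mx)


def _resolve_blocks(m: int, n_blocks: int) -> int:
    while m < 2 * n_blocks and n_blocks > 2:
        n_blocks //= 2
    if m < n_blocks:
        raise InsufficientDataError(
            f"{m} variants cannot support {n_blocks} jackknife blocks")
    return n_blocks


def _h2_weights(ell: np.ndarray, n: int, h2: float, m: int) -> np.ndarray:
    ell = np.maximum(ell, 1.0)
    het = 1.0 / (1.0 + n * max(h2, 0.0) * ell / m) ** 2
    return het / ell


def _fit_h2(z2, x, ell, n, m, mask=None) -> tuple[float, float]:
    """Two-pass weighted fit of z² on x = n·ℓ/m → (h2, intercept)."""
    w0 = _h2_weights(ell, n, 0.0, m)
    h2_0, _ = _wls(x, z2, w0, mask)
    w1 = _h2_weights(ell, n, h2_0, m)
    return _wls(x, z2, w1, mask)


def estimate_h2(z: np.ndarray, n: int, ld_scores: np.ndarray, m: int,
                n_blocks: int = 200) -> tuple[float, float, float]:
    """SNP heritability by LD score regression.

    ``z``/``ld_scores`` are aligned per-variant arrays; ``m`` is the total
    variant count the LD scores refer to.  Returns (h², jackknife se,
    intercept).  ``n_blocks`` halves automatically while variants < 2×blocks.
    """
    z = np.asarray(z, float)
    ell = np.asarray(ld_scores, float)
    mv = z.size
    n_blocks = _resolve_blocks(mv, n_blocks)
    x = n * ell / m
    z2 = z**2

    h2, intercept = _fit_h2(z2, x, ell, n, m)

    deletes = np.empty(n_blocks)
    for b, (lo, hi) in enumerate(_block_bounds(mv, n_blocks)):
        mask = np.ones(mv, bool)
        mask[lo:hi] = False
        deletes[b], _ = _fit_h2(z2, x, ell, n, m, mask)
    se = float(np.sqrt((n_blocks - 1) / n_blocks
                       * np.sum((deletes - deletes.mean()) ** 2)))
    return float(h2), se, float(intercept)


def _fit_gencov(zz, x, ell, n1, n2, h2_1, h2_2, m, mask=None) -> tuple[float, float]:
    """Weighted fit of z1·z2 on x = √(n1 n2)·ℓ/m → (ρ_g, cross intercept)."""
    ell_ = np.maximum(ell, 1.0)
    v1 = 1.0 + n1 * max(h2_1, 0.0) * ell_ / m
    v2 = 1.0 + n2 * max(h2_2, 0.0) * ell_ / m
    w = 1.0 / (v1 * v2) / ell_
    return _wls(x, zz, w, mask)


def estimate_rg(z1: np.ndarray, z2: np.ndarray, n1: int, n2: int,
                ld_scores: np.ndarray, m: int, n_blocks: int = 200) -> LDSCResult:
    """Cross-trait LD score regression → :class:`LDSCResult`.

    Both z vectors must be aligned to the same (munged) variant universe.
    r_g, its se, and p come from a delete-one block jackknife of the full
    ratio statistic ρ_g/√(h1²·h2²); r_g is clamped to [−1, 1] with a flag.
    A non-positive h² estimate marks the result degenerate and leaves r_g
    undefined.
    """
    z1 = np.asarray(z1, float)
    z2 = np.asarray(z2, float)
    ell = np.asarray(ld_scores, float)
    mv = z1.size
    n_blocks = _resolve_blocks(mv, n_blocks)

    x1 = n1 * ell / m
    x2 = n2 * ell / m
    xc = np.sqrt(n1 * n2) * ell / m
    zz = z1 * z2

    def full(mask=None):
        h2_1, int_1 = _fit_h2(z1**2, x1, ell, n1, m, mask)
        h2_2, int_2 = _fit_h2(z2**2, x2, ell, n2, m, mask)
        rho_g, int_c = _fit_gencov(zz, xc, ell, n1, n2, h2_1, h2_2, m, mask)
        return h2_1, int_1, h2_2, int_2, rho_g, int_c

    h2_1, int_1, h2_2, int_2, rho_g, int_c = full()

    h2_1_dels = np.empty(n_blocks)
    h2_2_dels = np.empty(n_blocks)
    rg_dels = np.empty(n_blocks)
    ok = True
    for b, (lo, hi) in enumerate(_block_bounds(mv, n_blocks)):
        mask = np.ones(mv, bool)
        mask[lo:hi] = False
        a, _, c, _, r, _ = full(mask)
        h2_1_dels[b], h2_2_dels[b] = a, c
        if a <= 0 or c <= 0:
            ok = False
            rg_dels[b] = np.nan
        else:
            rg_dels[b] = r / np.sqrt(a * c)

    def jk_se(d):
        return float(np.sqrt((n_blocks - 1) / n_blocks
                             * np.nansum((d - np.nanmean(d)) ** 2)))

    h2_1_se, h2_2_se = jk_se(h2_1_dels), jk_se(h2_2_dels)

    if h2_1 <= 0 or h2_2 <= 0 or not ok:
        return LDSCResult(h2_1=h2_1, h2_1_se=h2_1_se, h2_2=h2_2, h2_2_se=h2_2_se,
                          intercept_1=int_1, intercept_2=int_2,
                          intercept_cross=int_c, rg=None, rg_se=None,
                          rg_pval=None, n_blocks=n_blocks, degenerate=True)

    rg = rho_g / np.sqrt(h2_1 * h2_2)
    rg_se = jk_se(rg_dels)
    clamped = abs(rg) > 1
    rg_val = float(np.clip(rg, -1.0, 1.0))
    if rg_se > 0:
        rg_pval = float(2.0 * sps.norm.sf(abs(rg / rg_se)))
    else:
        rg_pval = 0.0 if rg != 0 else 1.0
    return LDSCResult(h2_1=float(h2_1), h2_1_se=h2_1_se, h2_2=float(h2_2),
                      h2_2_se=h2_2_se, intercept_1=float(int_1),
                      intercept_2=float(int_2), intercept_cross=float(int_c),
                      rg=rg_val, rg_se=rg_se, rg_pval=rg_pval,
                      n_blocks=n_blocks, rg_clamped=bool(clamped))
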