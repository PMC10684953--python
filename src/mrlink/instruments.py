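"""Instrumental-variable selection from exposure summary statistics.

Selection composes: genome-wide significance (p < 5×10⁻⁸, strict), greedy
LD clumping (r² < 0.001 within ±10,000 kb of each index variant), and the
weak-instrument filter F = beta²/se² > 10.  Steiger filtering needs outcome
data and runs later, after harmonization.  Proxy lookup against the LD
reference is implemented but disabled by default: the primary analysis uses
no proxies, while the r² > 0.8 proxy rule remains available behind a flag.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .ld import LDReference
from .sumstats import SummaryStats

logger = logging.getLogger(__name__)

GENOME_WIDE_P = 5e-8
DEFAULT_CLUMP_R2 = 0.001
DEFAULT_CLUMP_WINDOW_KB = 10_000
DEFAULT_F_MIN = 10.0
DEFAULT_PROXY_R2 = 0.8


class EmptyInstrumentError(RuntimeError):
    """No instrument survived a selection stage."""

    def __init__(self, stage: str):
        self.stage = stage
        super().__init__(f"no instruments remain after stage '{stage}'")


@dataclass
class InstrumentConfig:
    p_threshold: float = GENOME_WIDE_P
    clump_r2: float = DEFAULT_CLUMP_R2
    clump_window_kb: int = DEFAULT_CLUMP_WINDOW_KB
    f_min: float = DEFAULT_F_MIN
    proxy_r2: float = DEFAULT_PROXY_R2
    use_proxies: bool = False


@dataclass
class InstrumentMetrics:
    snp_id: str
    f_stat: float
    r2_explained: float
    passed_filters: set = field(default_factory=set)


def f_statistic(beta: float, se: float) -> float:
    """Per-SNP instrument-strength F statistic, beta²/se²."""
    if se <= 0:
        raise ValueError("se must be > 0")
    return (beta / se) ** 2


def variance_explained(maf: float, beta: float) -> float:
    """Variance in a unit-variance trait explained by one variant,
    2·maf·(1−maf)·beta².  ``beta`` must be on the standardized-trait scale;
    fold eaf > 0.5 to 1−eaf before calling.  Total instrument R² is the sum
    over instruments."""
    if not 0 < maf <= 0.5:
        raise ValueError("maf must be in (0, 0.5]")
    return 2.0 * maf * (1.0 - maf) * beta**2


def select_significant(stats: SummaryStats, p_threshold: float = GENOME_WIDE_P) -> list[str]:
    """Variants with p strictly below the threshold, sorted ascending by p
    with snp_id as the deterministic tie-break."""
    if not 0 < p_threshold < 1:
        raise ValueError("p_threshold must be in (0, 1)")
    df = stats.df
    hits = df[df["pval"] < p_threshold]
    hits = hits.sort_values(["pval", "snp_id"], kind="mergesort")
    return list(hits["snp_id"])


def ld_clump(
    candidates: list[str],
    stats: SummaryStats,
    ld: LDReference,
    r2_max: float = DEFAULT_CLUMP_R2,
    window_kb: int = DEFAULT_CLUMP_WINDOW_KB,
) -> list[str]:
    """Greedy LD clumping.

    Repeatedly take the lowest-p remaining candidate as an index variant and
    remove every remaining candidate on the same chromosome within
    ``window_kb`` of it AND with r² ≥ ``r2_max`` against it.  Index variants
    are returned in selection order.  Ties on p keep the smaller genomic
    coordinate, then lexicographic snp_id.  Candidates absent from the LD
    reference are treated as independent (logged).
    """
    df = stats.df.set_index("snp_id")
    missing = [s for s in candidates if s not in ld]
    if missing:
        logger.info("%d candidates absent from LD reference, treated as "
                    "independent: %s", len(missing), missing[:5])

    def sort_key(s: str):
        row = df.loc[s]
        return (float(row.pval), int(row.pos), s)

    remaining = sorted(set(candidates), key=sort_key)
    window = window_kb * 1_000
    kept: list[str] = []
    while remaining:
        index_snp = remaining.pop(0)
        kept.append(index_snp)
        if index_snp not in ld:
            continue
        survivors = []
        for s in remaining:
            if s in ld and ld.chromosome(s) == ld.chromosome(index_snp) \
                    and abs(ld.position(s) - ld.position(index_snp)) <= window \
                    and ld.r2(index_snp, s) >= r2_max:
                continue
            survivors.append(s)
        remaining = survivors
    return kept


def find_proxy(
    target: str,
    available: set[str],
    ld: LDReference,
    r2_min: float = DEFAULT_PROXY_R2,
) -> str | None:
    """Best proxy for ``target`` among ``available``: the variant with the
    highest r² strictly above ``r2_min``; ties broken by nearest position,
    then lexicographic snp_id.  None when nothing qualifies or the target is
    not in the reference."""
    if target not in ld:
        logger.info("proxy target %s absent from LD reference", target)
        return None
    tpos = ld.position(target)
    best = None
    for s in sorted(available):
        if s == target or s not in ld:
            continue
        r2 = ld.r2(target, s)
        if r2 <= r2_min:
            continue
        key = (-r2, abs(ld.position(s) - tpos), s)
        if best is None or key < best[0]:
            best = (key, s)
    return None if best is None else best[1]


def apply_instrument_filters(
    stats: SummaryStats,
    ld: LDReference,
    config: InstrumentConfig | None = None,
) -> tuple[list[str], dict[str, InstrumentMetrics], dict]:
    """Compose significance → clumping → F filter.

    Returns the surviving snp_ids (clump order), per-SNP metrics, and an
    audit log of removal counts per stage.  Raises
    :class:`EmptyInstrumentError` when a stage empties the set.
    """
    config = config or InstrumentConfig()
    audit = {"input": len(stats)}

    sig = select_significant(stats, config.p_threshold)
    audit["significant"] = len(sig)
    audit["removed_not_significant"] = len(stats) - len(sig)
    if not sig:
        raise EmptyInstrumentError("significance")

    clumped = ld_clump(sig, stats, ld, config.clump_r2, config.clump_window_kb)
    audit["after_clump"] = len(clumped)
    audit["removed_clump"] = len(sig) - len(clumped)
    if not clumped:
        raise EmptyInstrumentError("clumping")

    df = stats.df.set_index("snp_id")
    metrics: dict[str, InstrumentMetrics] = {}
    kept: list[str] = []
    for s in clumped:
        row = df.loc[s]
        f = f_statistic(float(row.beta), float(row.se))
        eaf = float(row.eaf)
        if np.isfinite(eaf) and 0 < eaf < 1:
            maf = min(eaf, 1 - eaf)
            r2 = variance_explained(maf, float(row.beta))
        else:
            # no frequency: fall back to the F-based approximation
            n = int(row.n)
            r2 = f / (f + max(n - 2, 1))
        passed = {"significance", "clump"}
        if f > config.f_min:
            passed.add("f_stat")
            kept.append(s)
        metrics[s] = InstrumentMetrics(snp_id=s, f_stat=f, r2_explained=r2,
                                       passed_filters=passed)
    audit["after_f_filter"] = len(kept)
    audit["removed_weak_f"] = len(clumped) - len(kept)
    if not kept:
        raise EmptyInstrumentError("f_filter")
    return kept, metrics, audit


def mean_f(metrics: dict[str, InstrumentMetrics], snp_ids: list[str]) -> float:
    """Mean F across instruments (reported alongside the per-SNP minimum)."""
    return float(np.mean([metrics[s].f_stat for s in snp_ids]))


def total_r2(metrics: dict[str, InstrumentMetrics], snp_ids: list[str]) -> float:
    return float(np.sum([metrics[s].r2_explained for s in snp_ids]))
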