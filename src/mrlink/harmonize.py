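"""Allele harmonization of exposure and outcome effects.

Every estimator consumes a :class:`HarmonizedSet`: one row per instrument
with exposure and outcome effects expressed for the same effect allele.
Resolution order per variant: identical orientation is kept as-is; swapped
alleles flip the outcome beta (and eaf → 1−eaf); a strand flip
(A↔T, C↔G complement) is undone first when that reconciles the pairs;
palindromic variants (A/T, C/G) are resolved by allele frequency when both
frequencies fall on the same side of 0.5 and outside the ambiguity zone
[0.42, 0.58], else dropped; anything irreconcilable is dropped.  Every drop
is logged with its reason, so output rows + exclusions = input instruments.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .sumstats import SummaryStats, complement_allele, is_palindromic

AMBIGUITY_ZONE = (0.42, 0.58)

HARMONIZED_COLUMNS = [
    "snp_id", "effect_allele", "other_allele",
    "beta_exposure", "se_exposure", "pval_exposure", "eaf_exposure",
    "beta_outcome", "se_outcome", "pval_outcome", "eaf_outcome",
]


class EmptyHarmonizedError(RuntimeError):
    """Every instrument was dropped during harmonization."""


@dataclass
class HarmonizedSet:
    """Per-variant aligned exposure/outcome effects; the estimator input."""

    df: pd.DataFrame
    exposure_name: str = "exposure"
    outcome_name: str = "outcome"
    outcome_binary: bool = False
    n_exposure: int | None = None
    n_outcome: int | None = None
    outcome_case_fraction: float | None = None
    exclusions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in HARMONIZED_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"harmonized frame lacks columns {missing}")
        if self.df["snp_id"].duplicated().any():
            raise ValueError("duplicated snp_id in harmonized set")
        if (self.df[["se_exposure", "se_outcome"]] <= 0).any().any():
            raise ValueError("non-positive se in harmonized set")
        self.df = self.df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def beta_x(self) -> np.ndarray:
        return self.df["beta_exposure"].to_numpy(float)

    @property
    def se_x(self) -> np.ndarray:
        return self.df["se_exposure"].to_numpy(float)

    @property
    def beta_y(self) -> np.ndarray:
        return self.df["beta_outcome"].to_numpy(float)

    @property
    def se_y(self) -> np.ndarray:
        return self.df["se_outcome"].to_numpy(float)

    def ratios(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-SNP Wald ratios and their first-order variances."""
        r = self.beta_y / self.beta_x
        v = self.se_y**2 / self.beta_x**2
        return r, v

    def drop(self, snp_ids) -> "HarmonizedSet":
        snp_ids = set(snp_ids)
        keep = self.df[~self.df["snp_id"].isin(snp_ids)].copy()
        return HarmonizedSet(
            df=keep, exposure_name=self.exposure_name,
            outcome_name=self.outcome_name, outcome_binary=self.outcome_binary,
            n_exposure=self.n_exposure, n_outcome=self.n_outcome,
            outcome_case_fraction=self.outcome_case_fraction,
            exclusions=dict(self.exclusions))

    @classmethod
    def from_arrays(cls, beta_x, se_x, beta_y, se_y, snp_ids=None, **meta) -> "HarmonizedSet":
        """Build directly from aligned effect arrays (simulation shortcut)."""
        from scipy import stats as sps
        beta_x = np.asarray(beta_x, float)
        k = beta_x.size
        snp_ids = snp_ids if snp_ids is not None else [f"rs{i+1}" for i in range(k)]
        se_x = np.asarray(se_x, float)
        beta_y = np.asarray(beta_y, float)
        se_y = np.asarray(se_y, float)
        df = pd.DataFrame({
            "snp_id": snp_ids,
            "effect_allele": "A", "other_allele": "G",
            "beta_exposure": beta_x, "se_exposure": se_x,
            "pval_exposure": 2 * sps.norm.sf(np.abs(beta_x / se_x)),
            "eaf_exposure": np.nan,
            "beta_outcome": beta_y, "se_outcome": se_y,
            "pval_outcome": 2 * sps.norm.sf(np.abs(beta_y / se_y)),
            "eaf_outcome": np.nan,
        })
        return cls(df=df, **meta)

    def to_csv(self, path, sep: str = "\t") -> None:
        self.df.to_csv(path, sep=sep, index=False)


def _freq_resolves(eaf_x: float, eaf_y: float) -> tuple[bool, bool]:
    """(resolvable, needs_flip) for a palindromic variant from frequencies."""
    lo, hi = AMBIGUITY_ZONE
    if not (np.isfinite(eaf_x) and np.isfinite(eaf_y)):
        return False, False
    if lo <= eaf_x <= hi or lo <= eaf_y <= hi:
        return False, False
    same_side = (eaf_x < 0.5) == (eaf_y < 0.5)
    return True, not same_side


def harmonize(
    instruments: list[str],
    exposure: SummaryStats,
    outcome: SummaryStats,
    palindrome_policy: str = "infer",
) -> HarmonizedSet:
    """Align outcome effects to the exposure's effect allele per instrument.

    ``palindrome_policy``: "infer" resolves palindromic variants by allele
    frequency where decisive, "drop" removes them all.
    """
    if not instruments:
        raise ValueError("instruments must be nonempty")
    if palindrome_policy not in {"infer", "drop"}:
        raise ValueError("palindrome_policy must be 'infer' or 'drop'")

    exp = exposure.df.set_index("snp_id")
    out = outcome.df.set_index("snp_id")
    rows = []
    exclusions: dict[str, str] = {}

    for s in instruments:
        if s not in exp.index:
            exclusions[s] = "absent from exposure"
            continue
        if s not in out.index:
            exclusions[s] = "absent from outcome"
            continue
        e, o = exp.loc[s], out.loc[s]
        if isinstance(e, pd.DataFrame) or isinstance(o, pd.DataFrame):
            exclusions[s] = "duplicated snp_id"
            continue
        ea_x, oa_x = e.effect_allele, e.other_allele
        ea_y, oa_y = o.effect_allele, o.other_allele
        if len(ea_x) > 1 or len(oa_x) > 1 or len(ea_y) > 1 or len(oa_y) > 1:
            exclusions[s] = "indel / multi-allelic"
            continue

        beta_y, eaf_y = float(o.beta), float(o.eaf)
        pal = is_palindromic(ea_x, oa_x)

        if pal:
            if palindrome_policy == "drop":
                exclusions[s] = "palindromic (policy drop)"
                continue
            if {ea_y, oa_y} != {ea_x, oa_x}:
                exclusions[s] = "allele mismatch"
                continue
            # orient outcome to exposure's allele labels first
            if (ea_y, oa_y) == (oa_x, ea_x):
                beta_y, eaf_y = -beta_y, 1.0 - eaf_y
            resolvable, flip = _freq_resolves(float(e.eaf), eaf_y)
            if not resolvable:
                exclusions[s] = "palindromic, frequency ambiguous"
                continue
            if flip:
                beta_y, eaf_y = -beta_y, 1.0 - eaf_y
        else:
            if (ea_y, oa_y) == (ea_x, oa_x):
                pass
            elif (ea_y, oa_y) == (oa_x, ea_x):
                beta_y, eaf_y = -beta_y, 1.0 - eaf_y
            else:
                cea, coa = complement_allele(ea_y), complement_allele(oa_y)
                if (cea, coa) == (ea_x, oa_x):
                    pass
                elif (cea, coa) == (oa_x, ea_x):
                    beta_y, eaf_y = -beta_y, 1.0 - eaf_y
                else:
                    exclusions[s] = "allele mismatch"
                    continue

        rows.append({
            "snp_id": s, "effect_allele": ea_x, "other_allele": oa_x,
            "beta_exposure": float(e.beta), "se_exposure": float(e.se),
            "pval_exposure": float(e.pval), "eaf_exposure": float(e.eaf),
            "beta_outcome": beta_y, "se_outcome": float(o.se),
            "pval_outcome": float(o.pval), "eaf_outcome": eaf_y,
        })

    if not rows:
        raise EmptyHarmonizedError(
            f"all {len(instruments)} instruments dropped during harmonization")

    meta = {}
    if exposure.sample_n:
        meta["n_exposure"] = exposure.sample_n
    if outcome.sample_n:
        meta["n_outcome"] = outcome.sample_n
    return HarmonizedSet(
        df=pd.DataFrame(rows),
        exposure_name=exposure.trait_name,
        outcome_name=outcome.trait_name,
        outcome_binary=outcome.is_binary,
        outcome_case_fraction=outcome.case_fraction,
        exclusions=exclusions,
        **meta)
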