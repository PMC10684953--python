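"""GWAS summary-statistics I/O, quality filtering ("munging"), and the variant data model.

A trait's association results live in a :class:`SummaryStats`: a pandas
DataFrame in canonical column order plus trait metadata (name, binary flag,
case/control counts).  Matching across traits is always by rsID; positions
are carried as opaque 1-based coordinates and never lifted over.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

#: Canonical column order used for writing and for internal frames.
CANONICAL_COLUMNS = [
    "snp_id", "chrom", "pos", "effect_allele", "other_allele",
    "eaf", "beta", "se", "pval", "n",
]

_VALID_ALLELES = {"A", "C", "G", "T"}
_PALINDROMIC_PAIRS = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

_TINY_P = np.nextafter(0.0, 1.0)


class SumstatsError(Exception):
    """Base error for summary-statistics handling."""


class ConfigurationError(SumstatsError):
    """A column map or config block is missing something mandatory."""


class InputError(SumstatsError):
    """The input file itself is unusable (empty, unreadable)."""


@dataclass(frozen=True)
class VariantRecord:
    """One variant's association summary.

    ``beta`` is the per-allele effect of ``effect_allele``: log-odds units for
    binary traits, trait units otherwise.
    """

    snp_id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    eaf: float  # may be NaN
    beta: float
    se: float
    pval: float
    n: int

    def __post_init__(self) -> None:
        if self.effect_allele == self.other_allele:
            raise ValueError(f"{self.snp_id}: effect and other allele identical")
        if not self.se > 0:
            raise ValueError(f"{self.snp_id}: se must be > 0")
        if self.pos < 1:
            raise ValueError(f"{self.snp_id}: pos must be >= 1")

    @property
    def is_palindromic(self) -> bool:
        return (self.effect_allele, self.other_allele) in _PALINDROMIC_PAIRS

    @property
    def is_indel(self) -> bool:
        return len(self.effect_allele) > 1 or len(self.other_allele) > 1


@dataclass
class SummaryStats:
    """A trait's full variant collection plus trait metadata."""

    trait_name: str
    df: pd.DataFrame
    is_binary: bool = False
    n_case: int | None = None
    n_control: int | None = None
    sample_n: int | None = None
    audit: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.is_binary:
            if self.n_case is None or self.n_control is None:
                raise ConfigurationError(
                    "binary trait requires n_case and n_control")
            if self.sample_n is None:
                self.sample_n = self.n_case + self.n_control
            elif self.n_case + self.n_control != self.sample_n:
                raise ConfigurationError(
                    "n_case + n_control must equal sample_n for binary traits")
        missing = [c for c in CANONICAL_COLUMNS if c not in self.df.columns]
        if missing:
            raise ConfigurationError(f"summary frame lacks columns {missing}")
        self.df = self.df[CANONICAL_COLUMNS].reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def case_fraction(self) -> float | None:
        if not self.is_binary:
            return None
        return self.n_case / (self.n_case + self.n_control)

    def record(self, snp_id: str) -> VariantRecord:
        row = self.df.loc[self.df["snp_id"] == snp_id]
        if row.empty:
            raise KeyError(snp_id)
        r = row.iloc[0]
        return VariantRecord(
            snp_id=r.snp_id, chrom=str(r.chrom), pos=int(r.pos),
            effect_allele=r.effect_allele, other_allele=r.other_allele,
            eaf=float(r.eaf), beta=float(r.beta), se=float(r.se),
            pval=float(r.pval), n=int(r.n))

    def subset(self, snp_ids) -> "SummaryStats":
        keep = self.df[self.df["snp_id"].isin(set(snp_ids))]
        return replace(self, df=keep.copy(), audit={})


MANDATORY_ROLES = ("snp_id", "effect_allele", "other_allele", "beta", "se", "pval")


def read_sumstats(
    path,
    column_map: Mapping[str, str],
    trait_meta: Mapping | None = None,
    sep: str | None = None,
    default_n: int | None = None,
    default_eaf: float = np.nan,
) -> SummaryStats:
    """Read delimited summary statistics into a :class:`SummaryStats`.

    ``column_map`` maps canonical roles (``snp_id``, ``beta`` ...) to the
    file's header names.  Missing ``eaf``/``n`` columns are allowed and filled
    with ``default_eaf``/``default_n``.  Rows whose numeric fields do not
    parse, or whose se is non-positive, are dropped and counted in the
    returned object's ``audit`` dict.  Gzip is handled transparently.
    """
    trait_meta = dict(trait_meta or {})
    for role in MANDATORY_ROLES:
        if role not in column_map:
            raise ConfigurationError(f"column_map lacks mandatory role '{role}'")

    import csv
    try:
        raw = pd.read_csv(path, sep=sep, engine="python" if sep is None else "c",
                          dtype=str)
    except (pd.errors.EmptyDataError, csv.Error) as exc:
        raise InputError(f"empty or malformed summary-statistics file: {path}") from exc
    if raw.empty:
        raise InputError(f"no data rows in summary-statistics file: {path}")

    for role, col in column_map.items():
        if col not in raw.columns:
            raise ConfigurationError(
                f"column '{col}' (role '{role}') not found in {path}")

    df = pd.DataFrame({role: raw[col] for role, col in column_map.items()})
    n0 = len(df)

    for col in ("beta", "se", "pval", "eaf"):
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="coerce").astype(float)
    if "n" in df.columns:
        df["n"] = pd.to_numeric(df["n"], errors="coerce")
    if "pos" in df.columns:
        df["pos"] = pd.to_numeric(df["pos"], errors="coerce")

    if "chrom" not in df.columns:
        df["chrom"] = "NA"
    if "pos" not in df.columns:
        df["pos"] = 1
    if "eaf" not in df.columns:
        df["eaf"] = default_eaf
    if "n" not in df.columns:
        if default_n is None and "sample_n" in trait_meta:
            default_n = trait_meta["sample_n"]
        if default_n is None:
            raise ConfigurationError(
                "no sample-size column and no default_n/sample_n provided")
        df["n"] = default_n

    bad_numeric = df[["beta", "se", "pval"]].isna().any(axis=1)
    bad_se = df["se"].fillna(-1) <= 0
    bad = bad_numeric | bad_se
    audit = {
        "rows_read": n0,
        "dropped_unparseable": int(bad_numeric.sum()),
        "dropped_nonpositive_se": int((bad_se & ~bad_numeric).sum()),
    }
    df = df[~bad].copy()

    df["effect_allele"] = df["effect_allele"].str.upper()
    df["other_allele"] = df["other_allele"].str.upper()
    df["pos"] = df["pos"].fillna(1).astype(np.int64)
    df["n"] = df["n"].fillna(default_n if default_n is not None else -1).astype(np.int64)
    df["chrom"] = df["chrom"].astype(str)

    zero_p = df["pval"] <= 0
    if zero_p.any():
        warnings.warn(
            f"{int(zero_p.sum())} p-values of 0 clamped to {_TINY_P:g}",
            stacklevel=2)
        df.loc[zero_p, "pval"] = _TINY_P
    audit["clamped_zero_pval"] = int(zero_p.sum())

    return SummaryStats(
        trait_name=trait_meta.get("trait_name", "trait"),
        df=df,
        is_binary=bool(trait_meta.get("is_binary", False)),
        n_case=trait_meta.get("n_case"),
        n_control=trait_meta.get("n_control"),
        sample_n=trait_meta.get("sample_n"),
        audit=audit,
    )


def write_sumstats(stats: SummaryStats, path, sep: str = "\t") -> None:
    """Write in canonical column order; ``.gz`` suffix triggers gzip."""
    stats.df[CANONICAL_COLUMNS].to_csv(path, sep=sep, index=False)


def is_palindromic(ea: str, oa: str) -> bool:
    return (ea, oa) in _PALINDROMIC_PAIRS


def complement_allele(a: str) -> str:
    return "".join(_COMPLEMENT.get(c, "N") for c in a)


def munge(stats: SummaryStats, drop_palindromic: bool = True) -> tuple[SummaryStats, dict]:
    """Quality-filter a :class:`SummaryStats` for downstream analysis.

    Removes indels (any allele longer than one base or outside {A,C,G,T}),
    strand-ambiguous palindromic variants (A/T, C/G) when
    ``drop_palindromic`` is set (the LD-score-regression arm; the MR arm
    keeps them for harmonization to resolve), and *all* copies of any
    duplicated rsID.  Returns the filtered copy plus per-category removal
    counts; the input is not modified.
    """
    df = stats.df
    if df.empty:
        warnings.warn("munge called on empty summary statistics", stacklevel=2)
        return replace(stats, df=df.copy(), audit={}), {
            "indel": 0, "palindromic": 0, "duplicate": 0}

    ea, oa = df["effect_allele"], df["other_allele"]
    indel = (ea.str.len() > 1) | (oa.str.len() > 1) | \
        (~ea.isin(_VALID_ALLELES)) | (~oa.isin(_VALID_ALLELES))
    if drop_palindromic:
        pal = ~indel & np.array(
            [is_palindromic(a, b) for a, b in zip(ea, oa)])
    else:
        pal = pd.Series(False, index=df.index)
    dup = df["snp_id"].duplicated(keep=False) & ~indel & ~pal

    removed = indel | pal | dup
    counts = {
        "indel": int(indel.sum()),
        "palindromic": int(pal.sum()),
        "duplicate": int(dup.sum()),
    }
    out = df[~removed].copy()
    # duplicates may survive if one copy was already removed as indel/palindrome
    still_dup = out["snp_id"].duplicated(keep=False)
    if still_dup.any():
        counts["duplicate"] += int(still_dup.sum())
        out = out[~still_dup]
    if out.empty:
        warnings.warn("munging removed every variant", stacklevel=2)
    return replace(stats, df=out, audit={}), counts
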