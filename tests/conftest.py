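import numpy as np
import pandas as pd
import pytest

from mrlink.harmonize import HarmonizedSet
from mrlink.simulate import MRSimConfig, simulate_mr_sumstats
from mrlink.sumstats import SummaryStats


def make_sumstats(rows, trait_name="trait", **meta):
    """Build a SummaryStats from (snp_id, chrom, pos, ea, oa, eaf, beta, se, p, n) tuples."""
    df = pd.DataFrame(rows, columns=[
        "snp_id", "chrom", "pos", "effect_allele", "other_allele",
        "eaf", "beta", "se", "pval", "n"])
    meta.setdefault("sample_n", int(df["n"].iloc[0]))
    return SummaryStats(trait_name=trait_name, df=df, **meta)


def harmonized_from_ratios(ratios, variances, beta_x=1.0):
    """HarmonizedSet whose Wald ratios and first-order variances equal the
    given values exactly (beta_x fixed, se_y = sqrt(v)·|beta_x|)."""
    ratios = np.asarray(ratios, float)
    variances = np.asarray(variances, float)
    k = ratios.size
    bx = np.full(k, float(beta_x))
    return HarmonizedSet.from_arrays(
        beta_x=bx, se_x=np.full(k, 1e-6),
        beta_y=ratios * bx, se_y=np.sqrt(variances) * np.abs(bx))


def sim_harmonized(cfg: MRSimConfig):
    """Simulate and assemble the aligned estimator input directly (the
    simulator emits both traits on identical alleles, so no harmonization
    step is needed)."""
    exposure, outcome, truth = simulate_mr_sumstats(cfg)
    h = HarmonizedSet.from_arrays(
        beta_x=exposure.df.beta.to_numpy(), se_x=exposure.df.se.to_numpy(),
        beta_y=outcome.df.beta.to_numpy(), se_y=outcome.df.se.to_numpy(),
        snp_ids=list(exposure.df.snp_id),
        outcome_binary=outcome.is_binary,
        n_exposure=exposure.sample_n, n_outcome=outcome.sample_n,
        outcome_case_fraction=outcome.case_fraction)
    return h, truth


@pytest.fixture
def small_exposure():
    return make_sumstats([
        ("rs1", "1", 1000, "A", "G", 0.3, 0.10, 0.010, 1e-20, 100000),
        ("rs2", "1", 2_500_000, "C", "T", 0.2, 0.08, 0.012, 1e-12, 100000),
        ("rs3", "2", 5000, "G", "A", 0.4, -0.06, 0.011, 1e-9, 100000),
    ], trait_name="exposure")


@pytest.fixture
def small_outcome():
    return make_sumstats([
        ("rs1", "1", 1000, "A", "G", 0.31, 0.020, 0.009, 0.03, 250000),
        ("rs2", "1", 2_500_000, "T", "C", 0.79, -0.015, 0.010, 0.12, 250000),
        ("rs3", "2", 5000, "G", "A", 0.41, -0.011, 0.008, 0.17, 250000),
    ], trait_name="outcome", is_binary=True, n_case=2843, n_control=247157)
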