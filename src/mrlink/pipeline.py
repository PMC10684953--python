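"""End-to-end bidirectional MR orchestration and the report bundle.

A run executes: munge (MR arm: indel/duplicate removal, palindromes kept
for harmonization) → instrument selection (significance, clumping, F) →
harmonization → Steiger filtering → estimation (Wald ratio for a single
instrument, the full method panel for ≥ 2) → sensitivity suite → power.
Effects stay on the log-odds scale internally; odds ratios appear only at
serialization.  The primary IVW row is labelled fixed-effects when I² < 50%
and random-effects otherwise, with both variants always reported.

The report bundle is one directory per run: a config snapshot, a stage log
with counts (no timestamps, so identical config + seed reproduces the
bundle byte for byte), and delimited sub-tables (results, harmonized set,
leave-one-out, funnel, per-SNP PRESSO p-values, audit chain).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import estimators as est
from . import sensitivity as sens
from .harmonize import HarmonizedSet, harmonize
from .instruments import (InstrumentConfig, apply_instrument_filters, mean_f,
                          total_r2)
from .ld import LDReference
from .power import PowerInputs, mr_power_binary
from .sumstats import SummaryStats, munge

I2_FIXED_EFFECTS_MAX = 50.0  # below this, the primary IVW is fixed-effects


@dataclass
class MethodConfig:
    n_boot: int = 1000
    presso_n_sim: int = 1000
    palindrome_policy: str = "infer"
    second_order_wald: bool = False
    seed: int = 0


@dataclass
class RunConfig:
    instruments: InstrumentConfig = field(default_factory=InstrumentConfig)
    methods: MethodConfig = field(default_factory=MethodConfig)

    def snapshot(self) -> str:
        return yaml.safe_dump(
            {"instruments": asdict(self.instruments),
             "methods": asdict(self.methods)},
            sort_keys=True)


@dataclass
class ReportBundle:
    direction: str
    results: pd.DataFrame
    harmonized: HarmonizedSet
    sensitivity: sens.SensitivityReport | None
    audit: dict
    power: float | None
    primary_model: str
    log_lines: list[str]

    def write(self, out_dir, config: RunConfig) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "config.yaml").write_text(config.snapshot())
        (out / "log.txt").write_text("\n".join(self.log_lines) + "\n")
        self.results.to_csv(out / "results.tsv", sep="\t", index=False,
                            float_format="%.10g")
        self.harmonized.to_csv(out / "harmonized.tsv")
        (out / "audit.json").write_text(
            json.dumps(self.audit, indent=2, sort_keys=True) + "\n")
        s = self.sensitivity
        if s is not None:
            s.loo_table.to_csv(out / "leave_one_out.tsv", sep="\t",
                               index=False, float_format="%.10g")
            sens.funnel_table(self.harmonized).to_csv(
                out / "funnel.tsv", sep="\t", index=False, float_format="%.10g")
            lines = [
                f"cochran_q\t{s.q_stat:.10g}",
                f"q_df\t{s.q_df}",
                f"q_pval\t{s.q_pval:.10g}",
                f"i2_percent\t{s.i2:.10g}",
                f"egger_intercept\t{s.egger_intercept:.10g}",
                f"egger_intercept_pval\t{s.egger_intercept_pval:.10g}",
                f"steiger_direction\t{s.steiger_direction}",
                f"steiger_pval\t{s.steiger_pval:.10g}",
                f"primary_ivw_model\t{self.primary_model}",
            ]
            if s.presso is not None:
                lines += [
                    f"presso_global_pval\t{s.presso.global_pval:.10g}",
                    f"presso_n_outliers\t{s.presso.n_outliers}",
                    f"presso_distortion_pval\t"
                    f"{'NA' if s.presso.distortion_pval is None else format(s.presso.distortion_pval, '.10g')}",
                ]
                pd.DataFrame({
                    "snp_id": s.presso.outlier_pvals.index,
                    "outlier_pval": s.presso.outlier_pvals.to_numpy(),
                    "outlier": s.presso.outlier_flags.to_numpy(),
                }).to_csv(out / "presso.tsv", sep="\t", index=False,
                          float_format="%.10g")
            (out / "sensitivity.txt").write_text("\n".join(lines) + "\n")
        if self.power is not None:
            (out / "power.txt").write_text(f"power\t{self.power:.10g}\n")


def _results_frame(rows: list[est.MREstimate], labels=None) -> pd.DataFrame:
    recs = [e.as_dict() for e in rows]
    df = pd.DataFrame(recs)
    if labels:
        df.insert(0, "label", labels)
    return df


def run_univariable(
    exposure: SummaryStats,
    outcome: SummaryStats,
    ld: LDReference,
    config: RunConfig | None = None,
    direction: str = "forward",
) -> ReportBundle:
    """One direction of the bidirectional analysis.

    ``direction="reverse"`` swaps the roles of the two datasets (the caller
    passes the same pair either way).  Raises
    :class:`~mrlink.instruments.EmptyInstrumentError` or
    :class:`~mrlink.harmonize.EmptyHarmonizedError` naming the stage that
    emptied the instrument set.
    """
    config = config or RunConfig()
    if direction == "reverse":
        exposure, outcome = outcome, exposure
    elif direction != "forward":
        raise ValueError("direction must be 'forward' or 'reverse'")
    log = [f"direction: {direction}",
           f"exposure: {exposure.trait_name} (n={exposure.sample_n})",
           f"outcome: {outcome.trait_name} (n={outcome.sample_n})"]
    audit: dict = {"direction": direction}

    exposure_m, counts = munge(exposure, drop_palindromic=False)
    audit["munge_exposure"] = counts
    log.append(f"munge exposure: {len(exposure)} -> {len(exposure_m)} {counts}")

    snps, metrics, sel_audit = apply_instrument_filters(
        exposure_m, ld, config.instruments)
    audit["selection"] = sel_audit
    log.append(f"instrument selection: {sel_audit}")

    h = harmonize(snps, exposure_m, outcome,
                  palindrome_policy=config.methods.palindrome_policy)
    audit["harmonization"] = {
        "input": len(snps), "retained": len(h),
        "excluded": dict(h.exclusions)}
    log.append(f"harmonized: {len(snps)} -> {len(h)}")

    steiger_removed: list[str] = []
    if h.n_exposure and h.n_outcome:
        keep, _, _ = sens.steiger(h)
        steiger_removed = list(keep.index[~keep.to_numpy()])
        if steiger_removed and len(steiger_removed) < len(h):
            h = h.drop(steiger_removed)
    audit["steiger_filter"] = {"removed": steiger_removed, "retained": len(h)}
    log.append(f"steiger filter removed {len(steiger_removed)}")

    seed = config.methods.seed
    report: sens.SensitivityReport | None = None
    power_val = None
    primary_model = "NA"

    if len(h) == 1:
        row = h.df.iloc[0]
        e = est.wald_ratio(row.beta_exposure, row.se_exposure,
                           row.beta_outcome, row.se_outcome,
                           second_order=config.methods.second_order_wald)
        results = _results_frame([e], labels=["wald_ratio"])
        log.append("single instrument: Wald ratio only")
    elif len(h) == 2:
        rows = [est.ivw(h, "fixed"), est.ivw(h, "mre")]
        _, _, _, i2 = sens.cochran_q(h)
        primary_model = "fixed" if i2 < I2_FIXED_EFFECTS_MAX else "random"
        primary = rows[0] if primary_model == "fixed" else rows[1]
        results = _results_frame([primary] + rows,
                                 labels=["ivw_primary", "ivw_fe", "ivw_mre"])
    else:
        panel = est.all_estimates(h, n_boot=config.methods.n_boot, seed=seed)
        report = sens.sensitivity_suite(
            h, n_sim=config.methods.presso_n_sim, seed=seed + 10)
        primary_model = "fixed" if report.i2 < I2_FIXED_EFFECTS_MAX else "random"
        primary = panel[0] if primary_model == "fixed" else panel[1]
        results = _results_frame(
            [primary] + panel,
            labels=["ivw_primary", "ivw_fe", "ivw_mre", "egger_slope",
                    "egger_intercept", "weighted_median", "weighted_mode",
                    "simple_mode"])
        log.append(f"I2 = {report.i2:.2f}% -> primary IVW model: {primary_model}")

    if outcome.is_binary and outcome.case_fraction and len(h) >= 1:
        r2 = total_r2(metrics, list(h.df["snp_id"]))
        ivw_beta = float(results.iloc[0]["beta"])
        if 0 < r2 < 1:
            power_val = mr_power_binary(PowerInputs(
                n_total=outcome.sample_n,
                case_fraction=outcome.case_fraction,
                r2_instruments=r2,
                odds_ratio=float(np.exp(ivw_beta))))
            log.append(f"instrument R2 = {r2:.4g}, power = {power_val:.4f}")
    log.append(f"mean F across instruments: "
               f"{mean_f(metrics, list(h.df['snp_id'])):.4g}")

    return ReportBundle(direction=direction, results=results, harmonized=h,
                        sensitivity=report, audit=audit, power=power_val,
                        primary_model=primary_model, log_lines=log)


def run_bidirectional(exposure, outcome, ld, config=None) -> dict[str, ReportBundle]:
    return {
        "forward": run_univariable(exposure, outcome, ld, config, "forward"),
        "reverse": run_univariable(exposure, outcome, ld, config, "reverse"),
    }


def run_mvmr(
    exposure: SummaryStats,
    covariates: list[SummaryStats],
    outcome: SummaryStats,
    ld: LDReference,
    config: RunConfig | None = None,
    joint: bool = False,
) -> pd.DataFrame:
    """Covariate-adjusted direct effects of the exposure.

    Default: one covariate at a time (exposure + single covariate two-
    exposure model), one row per covariate; per-covariate failures are
    isolated into an ``error`` column.  ``joint=True`` fits a single model
    with all covariates instead.
    """
    from .mvmr import (CollinearityError, conditional_f, mv_harmonize,
                       mvmr_ivw, mvmr_select_instruments)

    config = config or RunConfig()
    groups = [covariates] if joint else [[c] for c in covariates]
    rows = []
    for group in groups:
        names = "+".join(c.trait_name for c in group)
        try:
            exps = [exposure] + group
            snps = mvmr_select_instruments(exps, ld, config.instruments)
            m = mv_harmonize(snps, exps, outcome,
                             config.methods.palindrome_policy)
            ests = mvmr_ivw(m)
            cf = conditional_f(m)
            e0 = ests[0]  # the exposure's conditional (direct) effect
            rows.append({
                "covariate": names, "n_snp": m.n_snp,
                "beta": e0.beta, "se": e0.se,
                "ci_low": e0.ci_low, "ci_high": e0.ci_high, "pval": e0.pval,
                "or": e0.or_value, "or_low": e0.or_low, "or_high": e0.or_high,
                "conditional_f": cf[0], "error": "",
            })
        except (CollinearityError, Exception) as exc:  # noqa: BLE001 - isolate per covariate
            rows.append({"covariate": names, "n_snp": 0, "beta": np.nan,
                         "se": np.nan, "ci_low": np.nan, "ci_high": np.nan,
                         "pval": np.nan, "or": np.nan, "or_low": np.nan,
                         "or_high": np.nan, "conditional_f": np.nan,
                         "error": f"{type(exc).__name__}: {exc}"})
    return pd.DataFrame(rows)
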