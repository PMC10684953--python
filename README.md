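# mrlink

Bidirectional two-sample Mendelian randomization (MR) from GWAS summary
statistics, built for epidemiologists who want a complete, auditable
pipeline: instrument selection, allele harmonization, five causal
estimators with a full sensitivity suite, multivariable MR, LD score
regression, and statistical power — plus a synthetic-GWAS generator with
known ground truth, so every statistical claim in the package is backed by
a simulation the test suite actually runs.

## The statistics

A genetic variant that robustly associates with an exposure (say, serum
urate) can serve as an instrumental variable for the exposure's causal
effect on an outcome (say, diabetic neuropathy), because alleles are
assigned at conception and are therefore free of the confounding and
reverse causation that plague observational estimates. With per-variant
summary effects `β̂_x ± se_x` (exposure) and `β̂_y ± se_y` (outcome,
log-odds for a binary trait), each instrument gives a Wald ratio
`r_i = β̂_y/β̂_x`, and the package combines them with:

- **IVW** — precision-weighted mean `Σ w_i r_i / Σ w_i`, `w_i = β̂_x²/se_y²`,
  fixed-effects and multiplicative random-effects (se × `√max(1, Q/(k−1))`);
- **MR-Egger** — weighted regression `β̂_y = a + b·β̂_x`; the intercept a
  tests directional pleiotropy, the slope b is robust under InSIDE;
- **weighted median** — consistent while valid instruments hold > 50% of
  the weight;
- **weighted & simple mode** — kernel-density mode of the ratios;
- **Cochran's Q / I²**, **MR-PRESSO** (global/outlier/distortion),
  **leave-one-out**, **Steiger directionality filtering**, funnel tables;
- **MVMR** — weighted multi-exposure regression for direct effects;
- **LDSC** — h² and cross-trait genetic correlation r_g from the
  regression of z-statistics on LD scores, block-jackknife uncertainty;
- **power** — non-central chi-square power for a binary outcome.

Instruments pass `p < 5×10⁻⁸`, LD clumping (`r² < 0.001` within
10,000 kb), and `F = β²/se² > 10` before harmonization; Steiger filtering
then removes variants that explain more outcome than exposure variance.
See `docs/methods.md` for every formula, default, and design choice.

## Worked example

Simulate a study — ~90 independent instruments explaining ~8% of a
continuous exposure, a binary outcome of 274,660 with true log-odds effect
0.2 per exposure unit — and run the forward analysis:

```bash
mrlink simulate --n-snp 89 --causal-beta 0.2 --r2-total 0.0792 \
    --seed 7 --out demo
mrlink run --config demo_config.yaml --direction forward --seed 7 --out demo_run
```

(the config file points at the simulated `exposure.tsv` / `outcome.tsv` /
LD reference and declares the outcome's case/control counts; see
`tests/test_pipeline.py::TestCLI` for a complete one). The same analysis
from Python:

```python
from mrlink import MRSimConfig, RunConfig, run_univariable
from mrlink.simulate import simulate_ld_reference, simulate_mr_sumstats

ld = simulate_ld_reference(n_block=89, block_size=1, seed=7)
exposure, outcome, truth = simulate_mr_sumstats(
    MRSimConfig(causal_beta=0.2, seed=7), ld)
bundle = run_univariable(exposure, outcome, ld, RunConfig(), "forward")
print(bundle.results[["label", "n_snp", "beta", "se", "or", "pval"]])
```

prints (seed 7):

```
          label  n_snp      beta       se       or     pval
    ivw_primary     62  0.164817 0.067970 1.179177 0.015315
         ivw_fe     62  0.164817 0.067970 1.179177 0.015315
        ivw_mre     62  0.164817 0.068903 1.179177 0.016756
    egger_slope     62  0.360422 0.138907 1.433935 0.011882
egger_intercept     62 -0.012856 0.007960 0.987227 0.111557
weighted_median     62  0.222569 0.104143 1.249282 0.032586
  weighted_mode     62  0.304977 0.126216 1.356594 0.015679
    simple_mode     62  0.203800 0.183278 1.226053 0.266151
```

62 of the 89 planted instruments survive selection; the IVW odds ratio
1.18 (per exposure unit) estimates the true `exp(0.2) = 1.22` within its
95% CI, the Egger intercept shows no directional pleiotropy (as
simulated), and `bundle.sensitivity` carries Q/I², MR-PRESSO, leave-one-out
and Steiger results (here I² ≈ 2.7%, so the primary IVW row is labelled
fixed-effects). `bundle.power` reports 0.75 power for this design at the
estimated odds ratio.

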