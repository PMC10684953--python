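# Methods

`mrlink` implements bidirectional two-sample Mendelian randomization (MR)
from GWAS summary statistics, together with the diagnostics that normally
accompany it: instrument quality control, allele harmonization, five causal
estimators, heterogeneity/pleiotropy/outlier/directionality tests,
multivariable MR, LD score regression, and binary-outcome power. This note
records the statistical model behind each component, the defaults and why
they were chosen, and what the synthetic-data generator does and does not
emulate.

## The MR model

Each instrument i is a genetic variant with estimated effect
`beta_x_i ± se_x_i` on the exposure and `beta_y_i ± se_y_i` on the outcome
(log-odds units for a binary outcome), taken from two non-overlapping
samples. Under the instrumental-variable assumptions (relevance,
independence from confounders, exclusion restriction), each Wald ratio
`r_i = beta_y_i / beta_x_i` estimates the same causal effect β.

* **Wald ratio.** First-order delta-method variance `se_y²/beta_x²` by
  default; the second-order term `beta_y²·se_x²/beta_x⁴` is available via a
  flag. First-order is the common default and keeps the IVW weights
  consistent with the estimator.
* **IVW.** Precision-weighted mean of ratios with weights `1/v_i`,
  `v_i = se_y_i²/beta_x_i²`; algebraically identical to a weighted
  regression of `beta_y` on `beta_x` through the origin (the package
  exposes both routes and tests their equality). The multiplicative
  random-effects (MRE) variant multiplies the fixed-effects standard error
  by `√max(1, Q/(k−1))`; the floor at 1 disallows under-dispersion, which
  matters only for borderline confidence intervals and is therefore stated
  here explicitly.
* **MR-Egger.** Weighted regression with a free intercept after orienting
  all rows to `beta_x ≥ 0`. The slope is a pleiotropy-robust estimate under
  InSIDE (pleiotropic effects independent of instrument strength); the
  intercept estimates average directional pleiotropy. Standard errors carry
  the same `√max(1, σ̂²)` inflation; inference uses t with k−2 df.
* **Weighted median.** Order ratios, standardize cumulative weights
  `s_i = (Σ_{j≤i} w_j − w_i/2)/Σw`, and linearly interpolate r against s at
  0.5. Consistent when valid instruments carry > 50% of the weight.
  Standard error by parametric bootstrap: per-SNP betas are redrawn from
  `N(beta, se²)`, the estimate recomputed, and the bootstrap SD reported
  (default 1,000 draws; every report records the seed).
* **Weighted / simple mode.** Kernel-density mode of the ratio set with a
  normal kernel. The rule-of-thumb bandwidth is
  `phi · 0.9 · min(sd, MAD/0.6745) · k^(−1/5)` with `phi = 1` by default;
  a degenerate spread (all ratios equal) returns the common ratio exactly.
  The weighted variant weights each kernel by `1/v_i`. Bootstrap se as for
  the median.

P-values are normal for ratio/IVW/median/mode and t(k−2) for Egger.
Effects stay on the log-odds scale everywhere inside the pipeline; odds
ratios are exponentiated only at serialization, which removes any chance
of double exponentiation.

## Instrument selection

The selection chain is: genome-wide significance (`p < 5×10⁻⁸`, strict
inequality), greedy LD clumping, and the weak-instrument filter
`F = beta²/se² > 10`. Clumping repeatedly takes the lowest-p remaining
candidate and removes candidates on the same chromosome within ±10,000 kb
that also have `r² ≥ 0.001` against it — removal requires *both* proximity
and correlation; a distant same-chromosome variant is never removed however
high its r². Ties on p keep the smaller coordinate, then the
lexicographically smaller rsID, making the output fully deterministic.
Per-variant variance explained is `R² = 2·maf·(1−maf)·beta²` (beta on a
standardized-trait scale), summed over instruments for the power input;
when frequencies are missing the `F/(F+n−2)` approximation is used
instead. Both the per-SNP minimum F and the mean F across instruments are
reported, since either convention appears in applied work.

Proxy lookup (best available variant with `r² > 0.8`, ties to the nearest
position) is implemented but **disabled by default**: the primary analysis
design uses no proxies, and the flag exists for the secondary design that
does. Steiger filtering runs after harmonization (it needs outcome data)
and before estimation, so it belongs to instrument selection in the audit
chain.

## Harmonization

Outcome effects are aligned to the exposure's effect allele per variant:
matching orientation is kept; swapped alleles negate the outcome beta and
reflect its allele frequency; a strand flip (A↔T, C↔G complement) is undone
first when that reconciles the pairs. Palindromic variants (A/T, C/G)
cannot be resolved from alleles alone: under the default `infer` policy
they are kept when both allele frequencies are outside the ambiguity zone
[0.42, 0.58] and on the same side of 0.5 (opposite sides imply a strand
flip); otherwise, and whenever either frequency is missing, they are
dropped. The zone width follows the convention widely used by harmonization
tools; it is exposed in config because the choice is genuinely open.
Every exclusion carries a reason, and the invariant
`rows out + exclusions = instruments in` is tested.

## Sensitivity suite

* **Cochran's Q / I².** Q over ratios about the fixed-effects IVW mean;
  `I² = max(0, (Q − df)/Q)·100`. The pipeline labels the primary IVW
  fixed-effects when I² < 50% and random-effects otherwise, and always
  reports both variants.
* **MR-PRESSO.** The observed statistic is the inverse-variance-weighted
  residual sum of squares of each SNP against the IVW slope fitted without
  it (weighting makes the statistic scale-free; the simulation arm applies
  the identical weights, so the global test stays calibrated). The null
  distribution comes from parametric simulations redrawing both exposure
  and outcome effects under the no-pleiotropy model. Per-SNP squared
  residuals against their own simulated nulls give outlier p-values,
  Bonferroni-flagged at 0.05/k (the convention of the reference
  implementation of this test). When outliers are flagged the
  outlier-corrected IVW is reported with a distortion p-value comparing the
  observed estimate shift to shifts from removing random same-size inlier
  subsets; the distortion resampling budget equals the global-test budget
  (one knob). Empirical p-values use the (r+1)/(n+1) convention, so the
  smallest achievable p with 1,000 simulations is ≈ 0.001 — with more than
  ~50 instruments the Bonferroni threshold can drop below it, in which
  case `n_sim` should be raised.
* **Steiger.** Per SNP, variance explained in exposure versus outcome;
  SNPs explaining more outcome than exposure variance are removed, and the
  aggregate comparison gives the inferred causal direction with a Fisher-z
  p-value. For a binary outcome the observed-scale approximation
  `2·maf(1−maf)·beta²·K(1−K)` (K the case fraction) is used — scale choice
  moves borderline flags, which is why it is stated here prominently.
  Without frequencies the `z²/(z²+n−2)` form substitutes.
* **Leave-one-out** IVW table (each SNP omitted in turn plus the all-SNP
  reference row) and a **funnel table** (ratio vs precision `1/se_ratio`)
  are emitted for influence and asymmetry inspection; no statistic is
  attached to the funnel output.

## Multivariable MR

Instruments are the union of each exposure's genome-wide-significant
variants, jointly clumped with each variant ranked by its minimum p across
exposures (the union rule is the default because the selection rule is
genuinely open; it is stated in the run log). The estimator is a weighted
multiple regression of `beta_y` on the matrix of exposure effects with no
intercept, weights `1/se_y²`, MRE inflation `√max(1, RSS_w/(n−p))`, and
t(n−p) inference. With a single exposure this reduces exactly to
MRE IVW (tested to 10⁻¹⁰). The pipeline adjusts one covariate at a time —
exposure plus a single covariate per model — because that is the design the
package reproduces; a joint all-covariate model sits behind `joint=True`.
Collinear exposure pairs raise an error naming the pair; an all-zero
effect column is resolved to a zero slope by the pseudoinverse instead of
failing. Conditional instrument-strength F per exposure (effects
residualized on the other exposures) is reported as standard MVMR hygiene.

## LD score regression

Univariate: weighted regression of `z²` on `n·ℓ/m` with a free intercept;
the slope is h², the intercept absorbs confounding. Weights combine the
heteroskedasticity term `1/(1 + n·h²·ℓ/m)²` with the `1/ℓ` oversampling
correction in two passes (initial weights from h²=0, then weights from the
first-pass slope). Cross-trait: `z1·z2` regressed on `√(n1·n2)·ℓ/m`; the
slope is the genetic covariance ρ_g, the intercept absorbs sample overlap,
and `r_g = ρ_g/√(h1²·h2²)`. Uncertainty comes from a delete-one block
jackknife over 200 contiguous variant blocks (halved automatically while
variants < 2×blocks); for r_g the jackknife is applied to the full ratio
statistic. r_g is clamped to [−1, 1] with a flag; a non-positive h²
estimate marks the result degenerate rather than reporting a number.
Constant LD scores make slope and intercept inseparable and raise an
explicit error. There is no constrained-intercept mode.

## Power

Binary-outcome power uses the non-centrality-parameter formulation:
`b = K·(OR/(1+K·(OR−1)) − 1)`, `v = (K(1−K) − b²)/(N·R²)`, `NCP = b²/v`,
`power = P[χ²(1, NCP) > χ²₁(1−α)]`. At OR = 1 the power equals α exactly.
The formula is printed in the report so the number is reproducible from
its inputs alone.

## Synthetic-data generator

`simulate_mr_sumstats` draws per-variant true exposure effects γ_i with
half-normal magnitudes — effects are reported for the exposure-raising
allele, as harmonized real instruments are — rescaled so
`Σ 2·maf(1−maf)·γ²` equals the target total R² on a unit-variance
exposure. Observed effects add sampling noise with
`se = 1/√(2·maf(1−maf)·n)`, consistent with the R² formula inverted;
binary-outcome se additionally scales by `1/√(K(1−K))`. Outcome effects
are `β·γ + α + noise` with α the direct (pleiotropic) effect of the
invalid-instrument subset: zero-mean (`balanced`), nonzero-mean
(`directional`, InSIDE holds), or proportional to γ (`correlated`,
violating InSIDE). Default study conditions: 89 instruments explaining
7.92% of the exposure in n = 288,649, a binary outcome with 2,843 cases in
274,660 (K ≈ 0.0104) — a urate-on-diabetic-neuropathy-scale design. At
these settings a single forward run has an IVW standard error of ≈ 0.07
on the log-odds scale, so one-off point estimates scatter accordingly;
calibration claims in the test suite rest on replicate averages.

Instruments are simulated LD-independent (one per block) unless a
correlated reference is supplied, which keeps estimator tests independent
of clumping tests. `simulate_ld_reference` builds a block-diagonal r²
structure (within-block decay `r2^distance` or constant), with LD scores
`1 + Σ r²` over the block. `simulate_ldsc_zscores` draws bivariate-normal
z pairs with `E[z²] = 1 + n·h²·ℓ/m` and
`E[z1z2] = r_g·√(h1²h2²·n1·n2)·ℓ/m + n_overlap·r_p/√(n1n2)`, where the
phenotypic correlation r_p of the overlapping samples defaults to r_g
(pure genetic sharing). All generators are pure functions of
(config, seed).

What the generator does **not** emulate: linkage between instruments and
non-instrument variants, winner's-curse selection from a genome-wide scan
(instruments are planted, then thresholded), allele-frequency differences
between cohorts, population stratification, assortative mating, or sample
overlap between exposure and outcome studies (for the MR arm). Passing
tests therefore demonstrate correctness of the estimators and their
calibration under the stated model, not robustness to those real-data
complications.

## Monte-Carlo budgets and numerical choices

Recovery tests use 500 replicates and calibration tests 2,000 (IVW type-I)
or 200 (MR-PRESSO) replicates — large enough that the Monte-Carlo standard
error is several times smaller than each test's tolerance, small enough
for a desk-scale run. Empirical p-values use (r+1)/(n+1). P-values of
exactly 0 on input are clamped to the smallest positive double with a
warning. Kernel-mode optimization evaluates a 1,024-point grid spanning
the ratio range ± 3 bandwidths. The weighted-median interpolation uses
`numpy.interp` on the standardized cumulative weights. Clumping, proxy
search, and significance selection all break ties deterministically
(p, then position, then rsID), so identical config + seed reproduces every
report byte for byte.

## Known limitations

* Egger, median, and mode estimators are vulnerable to the usual failure
  modes (InSIDE violation, > 50% invalid weight, bandwidth sensitivity);
  the suite demonstrates the ordering of biases under the stated scenarios,
  not immunity.
* MR-PRESSO's smallest outlier p is bounded by the simulation budget (see
  above).
* The LDSC weights assume the generator's variance model; with real,
  mis-munged summary statistics the intercepts absorb more than sample
  overlap.
* Steiger's binary-outcome r² is an observed-scale approximation; a
  liability-scale treatment would move borderline keep flags.
* The MVMR covariate loop isolates failures per covariate; it does not
  attempt joint identification diagnostics beyond conditional F and the
  pairwise collinearity guard.
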