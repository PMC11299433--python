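# Methods

## Setting and assumptions

The package implements two-sample summary-data Mendelian randomization: the
SNP–exposure and SNP–outcome associations come from non-overlapping GWAS
samples, instruments are assumed relevant (enforced via F > 10), independent
of confounders, and — for the IVW point estimate to be unbiased — free of
horizontal pleiotropy. MR-Egger relaxes the last assumption to InSIDE
(instrument strength independent of direct effects); the weighted median
requires only that at least half the instrument weight comes from valid SNPs.
The mediation model is a linear path diagram X → M → Y with an additional
direct X → Y path: total effect β = direct + β₁β₂.

## Instrument selection and harmonization

- Significance: strict `P < p_threshold`, default 5×10⁻⁸ for exposures and
  5×10⁻⁶ for mediator traits (the relaxed threshold conventionally used for
  protein panels and for traits with no genome-wide-significant hits). A
  threshold ≥ 1 disables p filtering, making selection the identity in the
  limit.
- Clumping: greedy by ascending p-value, ties broken by SNP id for
  determinism; a candidate survives iff every kept SNP on the same chromosome
  within the window (default 10,000 kb) has known pairwise r² < 0.001.
  Without LD information window-mates are conservatively removed; SNPs on
  different chromosomes or beyond the window are treated as unlinked. The
  simulator spaces SNPs > 10,000 kb apart, so clumping is a no-op on its
  output unless an LD table is supplied.
- Instrument strength: F = β²/se², kept iff F strictly exceeds `f_min`
  (default 10).
- Harmonization: outcome effects are expressed on the exposure's effect
  allele; swapped allele pairs negate BETA and reflect EAF, strand flips are
  resolved through complements. Palindromic (A/T, C/G) SNPs are oriented by
  which side of 0.5 the allele frequency falls on in each study, and dropped
  when EAF is missing or within 0.08 of 0.5 in either study (the conventional
  default band; configurable). Instruments absent from the outcome are
  dropped, not proxied — no LD reference panel is shipped or queried. Every
  per-SNP action is logged to an audit table.

## Estimators

All estimators operate on the harmonized per-SNP pairs
(β̂\_Xj, se\_Xj, β̂\_Yj, se\_Yj) with outcome-side weights w\_j = 1/se²\_Yj.

- **IVW.** β̂ = Σw\_j β̂\_Xj β̂\_Yj / Σw\_j β̂²\_Xj; fixed-effects
  se = (Σw\_j β̂²\_Xj)^(−1/2). Cochran's Q = Σw\_j (β̂\_Yj − β̂ β̂\_Xj)² on k−1
  df; when its p-value is below 0.05 (configurable) the multiplicative
  random-effects se inflates the fixed se by √max(1, Q/(k−1)) — the floor
  at 1 means the random model never reports less uncertainty than the fixed
  one. One instrument degrades to the Wald ratio with a logged note;
  p-values use the normal approximation.
- **MR-Egger.** Weighted regression of β̂\_Y on β̂\_X with intercept, after
  orienting every β̂\_X ≥ 0 (flipping β̂\_Y in tandem) so the intercept is
  interpretable as average directional pleiotropy. Inference uses t on k−2
  df with the residual variance estimate floored at 1, mirroring the IVW
  convention. Requires k ≥ 3.
- **Weighted median.** Per-SNP ratios ordered ascending, weights
  (β̂\_Xj/se\_Yj)² normalized; the estimate linearly interpolates the
  midpoint cumulative weights at 0.5. The se is the standard deviation of
  the statistic over a parametric bootstrap (β̂\_X\*, β̂\_Y\* redrawn from
  their normal sampling distributions; default 1,000 draws, seeded — an
  analytic se is not offered, and the bootstrap choice is stamped in the
  estimate's metadata).
- 95% CIs use the fixed quantile 1.959964 (normal) or the t quantile
  (Egger); odds-ratio scale is exp-transformed throughout.

## Sensitivity suite

- **MR-PRESSO** (k ≥ 4, ≥ 100 simulations, default 1,000, seeded). Observed
  statistic: RSS = Σ w\_j (β̂\_Yj − β̂₍₋ⱼ₎ β̂\_Xj)² with β̂₍₋ⱼ₎ the
  leave-one-out IVW slope. Null distribution: parametric replicates
  β̂\_Y\*ⱼ ~ N(β̂₍₋ⱼ₎ β̂\_Xj, se\_Yj), β̂\_X\*ⱼ ~ N(β̂\_Xj, se\_Xj) with the
  leave-one-out slopes recomputed per replicate; global p by rank with the
  add-one correction (so p ≥ 1/(n\_sim+1)). Outlier test: each SNP's observed
  weighted squared residual ranked against its own simulated distribution,
  flagged below the Bonferroni-adjusted 0.05/k. Distortion test: the relative
  shift (β̂\_corrected − β̂\_full)/|β̂\_corrected| ranked two-sidedly against
  removals of random same-size subsets. Under strong contamination the
  leave-one-out fits are themselves biased, so a gross outlier can drag a
  second high-leverage SNP over the flagging threshold — the corrected
  estimate then simply excludes both.
- **Leave-one-out** (k ≥ 3): per-omitted-SNP fixed-effects IVW plus the
  all-SNP row (k+1 rows always), flagging omissions that change the sign or
  the 0.05 significance of the estimate.
- **Steiger.** Per-SNP variance explained approximated by r²\_j =
  z²\_j/(z²\_j + N), summed per trait over the instruments and compared via
  Fisher z-transforms of √Σr² with a two-sample z-test on the two study
  sizes. Direction is *forward* iff the instruments explain more exposure
  than outcome variance; an exact tie breaks to forward with a warning. The
  reverse-causality gate used by screening and the pipeline fails when the
  direction is reverse *or* the test is inconclusive (p > 0.05); failing
  pairs trigger an automatic reverse-direction UVMR. For case-control traits
  the same approximation is applied on the log-odds scale without a
  liability-scale conversion — a documented limitation. A per-SNP Steiger
  filter is available (`steiger_filter`) but is off by default; the test is
  applied globally.

## Mediation

The mediated proportion is 100·β₁β₂/β (percent), with β the *total* effect
from univariable MR — not a multivariable direct effect. Its 95% CI uses the
first-order delta method treating the three estimates as independent
(different samples):

var ≈ (β₂/β)² se₁² + (β₁/β)² se₂² + (β₁β₂/β²)² se\_β².

The variant name is stamped into every output row. First-order propagation is
quantitatively accurate when the relative standard errors are small (≲ 10%);
with a noisy denominator (se\_β/β around 20%) the true sampling sd of the
ratio exceeds the first-order value by ~20%, so reported CIs are
anti-conservative in that regime — negative proportions (an indirect path
opposing the total effect) are legal outputs either way. Screening keeps a
mediator iff both legs reach IVW p < 0.05 (no multiple-testing correction by
default, matching the conventional per-protein screen; Bonferroni/BH options
exist behind a flag) and both legs pass the Steiger gate.

## Synthetic data

The generator emulates standardized-trait GWAS: per-SNP exposure effects
γ\_j = |N(0, σ²\_γ)| (effects reported for the exposure-increasing allele — a
convention, not a loss of generality), MAF uniform on (0.05, 0.5],
se ≈ 1/√(2p(1−p)N) with an extra 1/√(φ(1−φ)) factor for case-control traits
on the log-odds scale, and independent estimation noise in every trait table
(non-overlapping samples). Mediator-specific instruments get pQTL-scale
effects δ\_j = |N(0, 0.15²)| on a separate SNP block, reflecting that protein
GWAS find few, strong cis signals; the exposure block influences the mediator
only through β₁γ\_j, which at the default sizes stays below the mediator's
instrument threshold — without this separation the mediator→outcome leg would
be estimated from SNPs whose ratio is β/β₁ rather than β₂. Horizontal
pleiotropy adds α\_j ~ N(μ, σ²\_α) to a configurable fraction of exposure
instruments (μ = 0 enforced for balanced mode). Defaults: 100 exposure and
100 mediator SNPs; N = 200,000 (exposure), 30,000 (mediator, pQTL-scale),
200,000 (outcome); σ\_γ = 0.03 (complex-trait effect sizes); β = 0.1,
β₁ = 0.2, β₂ = 0.05 (so 10% of the total effect is mediated); pleiotropy
α-sd 0.01 with mean 0.02 in directional mode. Simulated SNPs are unlinked and
positions are spaced beyond the clump window; LD can only enter through an
explicit LD table, so LD-related behaviour of real panels (proxy structure,
clumping of true signals) is *not* exercised by passing tests. Sample overlap
between studies, population stratification and liability-scale binary-trait
genetics are likewise not modelled.

## Pipeline and determinism

Phase 1 analyses every exposure × outcome pair (selection with a one-step
relaxation to 5×10⁻⁶ when nothing passes 5×10⁻⁸, harmonization, the three
estimators, Q, PRESSO, leave-one-out, Steiger, conditional reverse MR);
phase-2 eligibility is the conjunction IVW p < 0.05 AND Steiger forward AND
no significant reverse-direction signal. Phase 2 screens the mediator panel
per eligible pair and emits one mediation row per survivor. Per-pair failures
are logged and skipped, never fatal.

Every stochastic stage (weighted-median bootstrap, PRESSO simulations,
mediation screening) receives a child seed derived as
sha256(master\_seed:stage\_name) mod 2³¹, so the full run is a pure function
of (config, seed) — the test suite asserts byte-identical output trees — and
any stage can be reproduced in isolation. Reports are TSV (tables) and JSON
(nested results, sorted keys); no binary formats.

## Test-scale choices

The operating-characteristic tests use 200 replicates per study: recovery and
pleiotropy studies at k = 100 (k = 50 for the Egger-intercept study) with
N = 10⁶ so that instrument noise is negligible against effect sizes;
MR-PRESSO calibration/power at k = 20 instruments and 500 simulations per
replicate; mediation recovery at the generator defaults. These sizes give
Monte-Carlo standard errors well below the tested tolerances (e.g. binomial
se ≈ 1.5% on a 95% coverage estimate from 200 replicates) while keeping the
whole suite to about a minute of CPU.
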