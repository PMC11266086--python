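# Methods

## Scope and data model

`mrlink` operates entirely at the summary level: a GWAS is a table of
per-SNP records (variant ID, effect/other allele, effect-allele
frequency, beta, SE, p, N). Exposure and outcome effects are assumed to
come from non-overlapping samples (the two-sample design), traits are
treated as standardized (continuous traits in SD units, binary traits
on the log-odds scale), and instruments are assumed independent after
LD clumping. Only biallelic A/C/G/T variants are supported; indels are
rejected at parse time.

## Instrument selection

Variants associated with the exposure at P ≤ 5×10⁻⁸ are selected; if
fewer than `min_ivs` (default 3) survive, selection is relaxed once to
P ≤ 5×10⁻⁶ and the threshold actually used is recorded. A set still
below the minimum is flagged unusable and the downstream analysis is
skipped with a logged reason rather than raising. Greedy clumping
visits candidates by ascending p (ties broken lexicographically by
variant ID, so results never depend on input row order) and accepts a
variant iff its r² with every accepted variant within 10,000 kb on the
same chromosome is below 0.001. LD is supplied as a square r² matrix
(identity assumed when absent — the synthetic generator produces
independent instruments); computing LD from a genotype reference panel
is out of scope.

Instrument strength: per-SNP strength is the single-SNP chi-square
(β/SE)²; the aggregate F uses F = r²(N−k−1)/((1−r²)k) with
r² = Σ 2p(1−p)β² on the standardized scale. The r² composition rule is
a design choice — the F formula is standard but the way r² is obtained
from summary data is not uniquely determined; the standardized-trait sum
is the conventional one and is exact under the generator's model.

## Harmonization

Records are aligned to the exposure's effect allele: identical alleles
are kept; swapped alleles negate the outcome beta and reflect its EAF;
strand-complement matches are complemented first. Palindromic variants
(A/T, C/G) carry no strand information in their alleles, so orientation
is inferred from EAF sidedness in the two studies, and the variant is
dropped whenever either EAF falls in the ambiguity window
\[0.42, 0.58\] (configurable; the conventional "action = 2" behavior)
or is missing. Unresolvable allele pairs are dropped as incompatible.
Every shared variant appears in a drop log with its flag, so
kept + dropped = shared always holds.

## Estimators

All three estimators consume the harmonized quadruples
(γ̂ⱼ, σ_γⱼ, Γ̂ⱼ, σ_Γⱼ) and weight by the outcome variance only
(wⱼ = 1/σ_Γⱼ² on the effect scale; exposure uncertainty enters IVW-style
estimates only through the first-order Wald approximation, the standard
NOME-style simplification).

- **IVW** is weighted regression through the origin solved in closed
  form. The fixed-effect SE is (Σ γ̂ⱼ²/σ_Γⱼ²)^(−1/2); the
  multiplicative-random-effects SE multiplies it by
  √(max(1, Q/(k−1))) — the max(·) clamp prevents underdispersion from
  shrinking the SE below fixed. `mode="auto"` (the pipeline default)
  uses MRE exactly when the Cochran-Q p-value is below 0.05 and records
  which model produced the headline estimate. One SNP degenerates to
  the Wald ratio.
- **MR-Egger** first orients every SNP so γ̂ⱼ ≥ 0 (negating both
  effects where needed; the intercept magnitude is invariant to this
  convention), then fits a weighted regression with intercept via the
  normal equations. Both SEs are inflated by max(1, √(RSS/(k−2))).
  P-values use the normal reference by default for internal consistency
  with the other estimators; a Student-t reference (k−2 df) is
  available via `pval_reference="t"` for cross-checking against R
  implementations that use `summary.lm`.
- **Weighted median** sorts the Wald ratios, normalizes wⱼ = γ̂ⱼ²/σ_Γⱼ²,
  and linearly interpolates the ratio at centred cumulative weight 0.5.
  Its SE is the SD over 1,000 parametric-bootstrap resamples (Gaussian
  perturbation of both γ̂ and Γ̂), generated from an explicit seed; this
  bootstrap convention is the package's documented SE definition.

95% CIs use the 1.96 normal quantile throughout. Two-sided normal
p-values are floored at 1e-300 so they remain in (0, 1\] after floating
underflow (|z| > 38).

## Sensitivity diagnostics

**Cochran's Q** is the weighted dispersion of the Wald ratios around
the IVW estimate (identically, the weighted RSS of the origin
regression), referred to χ²(k−1).

**MR-PRESSO.** The observed global statistic is the leave-one-out RSS
Σⱼ (Γ̂ⱼ − β̂₍₋ⱼ₎ γ̂ⱼ)²/σ_Γⱼ² with β̂₍₋ⱼ₎ the IVW estimate omitting SNP
j. The null distribution redraws Γⱼ* ~ N(β̂₍₋ⱼ₎ γ̂ⱼ, σ_Γⱼ²) and
recomputes the statistic — including the leave-one-out fits — on each
of the 1,000 simulated datasets (vectorized, so the cost is one
(n_sim × k) matrix pass). Empirical p-values use the (r+1)/(n+1)
estimator and so can never be zero. Per-SNP outlier p-values compare
each SNP's observed residual term against its simulated terms and are
Bonferroni-adjusted within the dataset (a deliberately conservative
choice over the per-SNP-threshold convention). A consequence worth
knowing: the smallest achievable raw p is 1/(n_sim+1), so outlier
detection at level α requires n_sim ≥ k/α — the 1,000 default is
adequate up to k ≈ 50 at α = 0.05; raise `n_sim` for larger sets. The
distortion test compares the with/without-outlier IVW shift against
random pseudo-outlier sets of the same size.

**Outlier-removal loop.** Following the design in which MR-PRESSO is
invoked when the Egger intercept is significant, the loop: tests the
intercept; if p < 0.05 runs MR-PRESSO, drops flagged outliers, and
repeats (max 5 rounds, stopping early if nothing is flagged or fewer
than 4 SNPs would remain, with the terminal state recorded). A power
caveat, reproduced faithfully rather than patched: a single extreme
outlier inflates the Egger residual variance, so the intercept test —
the loop's trigger — is usually *not* significant even though
MR-PRESSO flags the SNP essentially always. The loop therefore
guarantees "final state has no detectable directional pleiotropy", not
"every PRESSO-flaggable outlier is removed"; users wanting
unconditional removal can call `mr_presso` directly.

## Mediation

The indirect effect is the product β_a·β_b with first-order
delta-method SE √(β_a²σ_b² + β_b²σ_a²); the Sobel z is exactly
indirect/SE, keeping the test and CI internally consistent. (A
second-order variant adding σ_a²σ_b² is available behind a flag but is
not the default, precisely to preserve that identity.) The proportion
mediated β_a·β_b/β_c gets a delta-method ratio CI assuming independence
of the three estimates — justified by the three non-overlapping GWAS
samples in the intended design. When the total effect is not
significant at 0.05 the proportion is reported as NA while the indirect
effect is still reported (a mediated path can exist without a
detectable total effect); the rule used is recorded on the result.

## FDR and orchestration

Benjamini–Hochberg q-values (via statsmodels) are computed within
explicitly defined families: all p-values of one method across the
outcomes of one direction. The family definition is deliberately
explicit because q-values are meaningless without it. The pipeline
(`run_pipeline` / `mrlink run`) executes the four-step plan — forward,
reverse, exposure→mediator, mediator→outcome — running selection,
clumping, harmonization, the outlier loop, all three estimators and the
sensitivity report per step, then assembles the mediation result from
the three IVW estimates. Every stochastic stage (bootstrap, PRESSO,
simulation) is seeded from the config seed, so re-runs are
bit-identical; the run log records thresholds, SNP counts after every
filter, the fixed/MRE choice and skip reasons.

## Synthetic generator

The generator emulates the post-clumping world of a biobank-scale
two-sample study. Per SNP: MAF pⱼ ~ U(0.05, 0.5); true exposure effects
are Gaussian, rescaled so Σ 2pⱼ(1−pⱼ)γⱼ² equals the target variance
explained exactly; true outcome effects are total·γⱼ + αⱼ with αⱼ the
pleiotropic effect (N(mean, sd²), optionally overwritten with a fixed
outlier effect for a chosen number of SNPs); observed effects add
sampling noise with SE = 1/√(2pⱼ(1−pⱼ)n) for each sample. Defaults
encode the intended study scale: 300 instruments, exposure n = 435,516,
outcome n = 396,054, mediator n = 681,275, exposure variance explained
0.10, mediator 0.048, direct effect θ = 0.042, paths β_a = 0.04,
β_b = 0.663 (total 0.0685 on the log-odds scale). The mediation triplet
shares one set of true SNP→X effects between the X→Y and X→M pairs
(independent noise, i.e. non-overlapping samples) and gives the
mediator its own instrument set for M→Y.

What the generator does *not* model — and hence what passing tests do
not establish about real data: liability-scale/binary-outcome subtleties
(log-odds effects are simulated with the same Gaussian machinery, the
standard summary-level simplification), residual LD between instruments
(a block-LD helper exists only to exercise clumping), sample overlap,
winner's-curse selection bias, allele-frequency differences between
studies, and population stratification.

## Problem sizes and numerical choices

Test and acceptance runs use: 200 replicates × 300 SNPs for
calibration (Egger test size, IVW coverage; 3-binomial-SE bands fixed
in advance), 100 replicates × 50 SNPs × 1,000 PRESSO simulations for
spike-in detection, 200 seeded triplets (100 SNPs each) for
indirect-effect recovery with a 3-Monte-Carlo-SE band, and 500 null
replicates for Sobel test size. Oracle equivalence (IVW/Egger vs a
generic WLS solver; weighted median vs a scalar quantile re-derivation)
is asserted at 1e-10 relative error on 100 random 50-SNP datasets.
Degenerate inputs are states, not crashes: unusable instrument sets and
missing mediators skip with logged reasons; harmonization drops are
logged, never raised.

## Known limitations

No proxy-SNP lookup for variants absent from the outcome study; no
multivariable MR (single mediator only); no mode-based or robust
(RAPS-style) estimators; LD matrices must be supplied, not computed;
forest/funnel plots are emitted as TSV tables, not graphics.
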