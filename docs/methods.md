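# Methods

This note documents the statistical model behind `twosmr`, the defaults and
why they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical conventions that a user reproducing or extending
an analysis should know.

## Model and estimators

Two-sample MR treats genetic variants as instruments: variant *j* carries
effects bxⱼₖ on K exposures (estimated in one GWAS sample) and byⱼ on a
binary outcome (log odds ratio, estimated in an independent sample). The
working model is

    byⱼ = Σₖ θₖ bxⱼₖ + αⱼ + εⱼ,  εⱼ ~ N(0, se_yⱼ²),

with θ the causal effects and αⱼ direct variant-outcome effects
(horizontal pleiotropy).

**MR-IVW** (`ivw_multivariable`, `ivw_univariable`) assumes αⱼ ≡ 0 and
solves weighted least squares with no intercept, weights wⱼ = 1/se_yⱼ².
Numerically this is a scaled QR solve (`numpy.linalg.lstsq` on
√w-multiplied rows) preceded by an SVD rank check, so exact collinearity is
reported by exposure name rather than surfacing as a LinAlgError.

**MR-Egger** (`egger_multivariable`) re-parameterizes per exposure of
interest: every variant is first oriented so its effect on that exposure is
non-negative (equivalent to recoding the effect allele; zero effects are
untouched, making orientation idempotent), then the same weighted
regression is fitted with a free intercept. The intercept estimates the
weighted mean direct effect of the oriented variants; a nonzero value
indicates directional pleiotropy. A full Egger table runs K separate fits,
re-orienting each time, because the intercept is only meaningful relative
to an orientation convention.

**Wald ratio** (`wald_ratio`): θ = by/bx for a single variant. The default
95% CI propagates outcome uncertainty only — the per-allele outcome CI
endpoints divided by bx, ordered ascending — and the p-value equals the
outcome-association p. This first-order form is what monogenic single-SNP
analyses conventionally report; passing `se_x` switches to the full
delta-method variant.

**Standard errors.** Model-based (fixed-effect) covariance is
(XᵀWX)⁻¹. The default is *multiplicative random-effects* scaling: SEs are
inflated by √max(1, Q/df), so between-variant heterogeneity widens but can
never narrow intervals. Coefficient p-values use the t distribution with
residual df by default (`pvalue_dist="normal"` available); the difference
is negligible at hundreds of instruments. When a fit is exactly determined
(J = K, e.g. a one-variant univariable panel) the SE falls back to the
fixed-effect form and the reference distribution to the normal, and the
estimate coincides with the Wald ratio.

**Heterogeneity** (`cochran_q`): Q = Σ wⱼ(byⱼ − fittedⱼ)² with the same
weights as the fit, df = J − p, H² = Q/df, I² = max(0, (Q − df)/Q)·100.
I² labels collapse the conventional 25/50/75 reference values onto
low [0, 25), moderate [25, 75), high [75, 100), with a "moderate-to-high"
annotation on [50, 75) so the 50 cut-point is not lost.

**PRESSO-style outlier test** (`presso_test`). For each variant the model
is refitted without it; the observed statistic is the sum of weighted
squared leave-one-out residuals. The null is parametric: outcome effects
are redrawn as byⱼ* ~ N(Bⱼ·θ₍₋ⱼ₎, se_yⱼ) with exposure effects held fixed
(two-sample independence; exposure noise is second order at
genome-wide-significant instruments; a full two-sided simulation is out of
scope). The global p uses add-one smoothing, (1 + #{≥ obs})/(n_sim + 1).
Per-variant p-values are the *raw* exceedance proportions, Bonferroni
multiplied by J and capped at 1 — raw, not smoothed, because a variant
displaced far beyond the null must be flaggable at p < α even when
J/(n_sim + 1) > α. All leave-one-out fits use rank-one downdates of the
K×K weighted normal matrix, so one test is a handful of batched matrix
products rather than n_sim × J regressions; results are bit-reproducible
given (panel, n_sim, seed). The distortion correction and iterated
exclusion are deliberately not implemented.

**Pleiotropy screening** (`pleiotropy_crosstab`, `restricted_set_filter`):
percentage of each trait's instruments whose p-value in each secondary
trait falls below a Bonferroni threshold α/m (m supplied by the caller,
conventionally the total number of instruments tested). Instruments absent
from a secondary dataset shrink that cell's denominator rather than
counting as non-pleiotropic; an empty denominator yields NaN, never a
silent 0. The any-of composite column applies the same per-trait threshold
with no multiplicity re-adjustment. The restricted-set filter reports the
fraction of surviving secondary p-values below 0.1 as a left-shift
diagnostic (0.1 expected under a uniform null).

## Harmonization conventions

- Reference allele = the first exposure's effect allele (deterministic and
  order-stable). Other traits are matched by same, swapped,
  strand-complement, or swapped-complement alleles; swaps negate beta and
  replace eaf by 1 − eaf; unmatched allele pairs are dropped and counted.
- Palindromic (A/T, C/G) variants cannot be strand-resolved from alleles.
  Default policy: align by allele-frequency concordance, dropping variants
  whose frequency is missing or inside [0.42, 0.58]; `drop_palindromic=True`
  removes them all.
- Complete-case across all K+1 traits; every dropped class (missing,
  palindromic, incompatible) is logged with counts.
- Positions are 1-based; all intervals are closed. Genome-wide selection
  uses strict p < α (default 1e-8). Clumping is greedy: most significant
  first (ties: position, then rsid), removing same-chromosome variants
  within ±10 Mb at r² > 0.01; pairs absent from the LD matrix count as
  unlinked with a logged warning; cross-chromosome LD is ignored. The
  window is a radius around the index variant, the common clumping-tool
  convention. Locus windows are ±1 Mb around the TSS.
- Validation is strict by default in library calls (first bad row raises,
  naming the rsid) and lenient (drop + log) in pipeline/CLI runs.

## The synthetic-data generator

`simulate_sumstats` emulates the structure of the real multi-trait GWAS
inputs entirely at the summary level: no genotypes or logistic outcomes are
drawn, because the estimators are defined on (and the pipeline consumes)
summary statistics. Given γ (J×K), θ, and α, the true outcome association
is byⱼ = Σₖ γⱼₖθₖ + αⱼ; observed effects add independent exposure-side and
outcome-side Gaussian noise with SE = 1/√(2·maf·(1−maf)·n) — the standard
error of a per-allele coefficient for a standardized trait at sample size
n. Defaults mirror a lipids-to-CAD study: three exposures in SD units,
θ = (0.44, −0.15, 0.21) (the log odds ratios 1.55, 0.86, 1.23), exposure
GWAS n = 300k, outcome n = 550k, maf ~ U(0.05, 0.5), 300 variants.

Effect-size law: nonzero γ magnitudes are `gamma_scale × U(0.5, 2)` —
bounded away from zero, as effects at variants that reached genome-wide
significance are; a law with mass near zero would make a configured
pleiotropy fraction undetectable at any sample size. Under the sparse
default each variant has one primary exposure (round-robin over
`primary_exposures`) and, with probability `pleiotropy_frac` (default 0.3),
one secondary exposure from `secondary_traits`; `gamma_density="dense"`
gives every variant an effect on every exposure. `gamma_sign="positive"`
codes every effect allele as trait-increasing. Direct effects αⱼ ~
N(alpha_mean, alpha_sd) are assigned to a `direct_frac` fraction of
variants. LD fixtures are block-diagonal with constant or AR-decaying
within-block r² and block gaps of 20 Mb so blocks sit outside the clumping
window of each other.

What the generator does *not* emulate: real LD maps, allele-frequency /
effect-size coupling, winner's curse, sample overlap (an option exists for
none; noise is strictly independent across samples), population
stratification, or binary-exposure liability scales. Passing recovery tests
therefore demonstrates correctness of the estimators under the model they
assume, not robustness to those real-data complications.

### Measurement error, and the "strong instruments" regime

With GWAS-scale exposure noise, regressors are measured with error. Two
visible consequences, both real and intentional: (i) residual dispersion
exceeds se_y², so I² is well above zero even with no simulated pleiotropy —
the same mechanism that makes real multi-trait MR fits heterogeneous; and
(ii) Egger's orientation step flips variants whose exposure-of-interest
effect is noise-dominated, leaving a small intercept offset. Calibration
and recovery scenarios therefore use `STRONG_INSTRUMENTS`
(gamma_scale = 0.2, n_exp = 1e10): the regime where exposure effects are
essentially noise-free, i.e. the NOME condition under which IVW, Egger, and
the PRESSO parametric null are exact. Under that regime the directional
pleiotropy scenario additionally uses dense, positively signed γ so that
orientation flips nothing and the intercept estimand is exactly the
simulated constant α.

## Problem sizes used in validation

The validation suite and `scripts/acceptance.py` use: five 50×3 random
panels for the normal-equations comparison (agreement to ~1e-12 relative);
200 replicates of J = 300, K = 3 for IVW recovery (bias in MC-SE units,
per-exposure 95% coverage) and for the Egger intercept under constant
α = 0.01; 200 null replicates of J = 60 with n_sim = 500 for PRESSO type-I
rate and 50 runs with a +10·se_y displaced variant for power; 20-variant
block-LD fixtures against an exhaustive clumping oracle; and one J = 3000
six-trait study for the pleiotropy cross-table round-trip. These sizes give
Monte-Carlo resolution comfortably finer than the property bounds being
checked while keeping a full run under a minute.

## Known limitations

- Correlated instruments are not modeled in the estimators (clumping is
  assumed to have been applied); generalized IVW with an LD-aware
  covariance is out of scope.
- Weighted-median/mode estimators, Steiger filtering, and the PRESSO
  distortion correction are not provided.
- The Wald-ratio default ignores exposure-side uncertainty (documented
  above; delta-method variant available).
- Bonferroni (not FDR) multiplicity control throughout, matching the
  conventions of the tabulated analyses this package targets.
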