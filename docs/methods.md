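# Methods

## The model

`tsmr` estimates the causal effect θ of an exposure X on an outcome Y
(both in SD units) from two independent GWAS. For each instrument SNP j
the exposure study reports (β̂_Xj, σ_Xj) and the outcome study
(β̂_Yj, σ_Yj). Under the instrumental-variable assumptions (relevance,
independence from confounders, exclusion restriction), β_Yj = θ·β_Xj, so
each SNP yields a Wald ratio

    θ̂_j = β̂_Yj / β̂_Xj,   se(θ̂_j) = σ_Yj / |β̂_Xj|   (first order),

and the estimators combine the ratios:

* **IVW** — θ̂ = Σ w_j θ̂_j / Σ w_j with w_j = 1/se(θ̂_j)². Identical to
  WLS of β̂_Y on β̂_X through the origin with weights 1/σ_Yj². Fixed-effect
  se is (Σ w_j)^(-1/2); the default multiplicative random-effects model
  inflates it by max(1, √(Q/(n−1))), so heterogeneity can widen but never
  narrow the interval.
* **MR-Egger** — WLS of β̂_Y on β̂_X with a free intercept after orienting
  every β̂_X positive. The slope estimates θ under InSIDE (instrument
  strength independent of direct effects); the intercept estimates the
  average directional pleiotropic effect. Inference uses t(n−2) for both
  coefficients; the residual scale is floored at 1 so an under-dispersed
  fit cannot shrink the standard errors. The t-inference choice is forced
  by internal consistency of reported MR tables: a slope/se pair like
  −0.417/0.243 with 66 SNPs reproduces the conventional p ≈ 0.091 only
  under t(64), not the normal.
* **Weighted median** — the 50% point of the weight-interpolated empirical
  distribution of ratios (cumulative weight S_j = (Σ_{k≤j} w_k − w_j/2)/Σw,
  linear interpolation at S = 0.5). Consistent while valid instruments
  hold ≥ 50% of the weight. Standard error by parametric bootstrap:
  both betas are redrawn from N(β̂, σ²), the statistic recomputed, and the
  SD over replicates taken (default 1000 replicates).
* **Simple / weighted mode** — the maximizer of a Gaussian-kernel density
  of the ratios with unit or IVW weights; bandwidth is the modified
  Silverman rule 0.9·min(sd, MAD)·n^(-1/5) scaled by the tuning factor φ
  (default 1). Standard error by the same parametric bootstrap.

Sensitivity suite: Cochran's Q = Σ w_j (θ̂_j − θ̂_fixed)² with
p from χ²(n−1) and I² = max(0, (Q−df)/Q)·100; the Egger intercept t-test
for directional pleiotropy; leave-one-out IVW re-estimation; and
Benjamini–Hochberg adjustment of the method p-values (per
exposure–outcome pair by default — the grouping is configurable because
adjustment families differ between studies). The advisory
method-selection rule follows common practice: report MR-Egger as primary
when the intercept test rejects, IVW otherwise; heterogeneity
(Q-test p < α or I² > 50%, reported separately and as a union flag) only
switches IVW to its random-effects variant.

## Instrument selection

Fixed order, each step audited: genome-wide significance (p < 5×10⁻⁸) →
greedy clumping (most significant SNP indexes a clump; removal within a
5000 kb radius on the same chromosome and, when an r² matrix is supplied,
at r² ≥ 0.001 anywhere; ties on p broken by chromosome, position, id —
deterministic without a seed) → static confounder blacklist (a 2-column
TSV replaces interactive catalogue queries) → weak-instrument removal
(F = β²/se² ≤ 10 dropped, strict). The 5000 kb figure is read as the
exclusion radius around each index SNP. Clumping degrades to
distance-only with a logged warning when no r² matrix is given; the
package never computes LD from genotypes.

Harmonization matches by rsID and aligns outcome records to the exposure
effect allele: direct match, allele swap (negate β, reflect EAF), strand
complement (tried only after direct and swapped fail), and palindromic
A/T / C/G SNPs resolved by allele frequency — both EAFs must lie outside
[0.5 − w, 0.5 + w] with w = 0.08 by default (set w = 0.5 to drop all
palindromes); opposite sides of 0.5 flip the sign. Unmatched, ambiguous,
or irreconcilable SNPs are dropped with a per-reason audit count;
kept + dropped always equals the number of candidates.

## The synthetic-data generator

`tsmr.simulate` emulates two non-overlapping GWAS over a shared panel of
independent SNPs: maf_j ~ U(0.05, 0.5); γ_j ~ N(0, γ_sd²) in SD units;
standard errors 1/√(2·maf(1−maf)·n) tie instrument strength to sample
size; observed betas are drawn independently around the truths; and the
outcome re-encodes a fraction of SNPs (swapped labels 25%, opposite
strand 20%, palindromic pairs 10%, small EAF cohort noise) to exercise
harmonization. Defaults — 70 SNPs, θ = −0.2, γ_sd = 0.025
(mean F ≈ 50, matching the instrument strength typical of anthropometric
GWAS panels), n_exposure = 200,000, n_outcome = 60,000 — describe a
well-powered abdominal-obesity → bone-density style study.

Pleiotropy regimes give a fraction (default 30%) of SNPs direct outcome
effects a_j ~ N(α_mean·s, α_sd²) **in the exposure-increasing allele
frame** (Γ_j = θγ_j + sign(γ_j)·a_j), with s = ±1 under "balanced" and
s = +1 under "directional". The frame matters: with symmetric γ, applying
directional effects in the arbitrary recorded-allele frame would cancel
in ratio space and no estimator could distinguish the regimes. Defaults
α_mean = 0.03, α_sd = 0.01 put the pleiotropic ratio shift
(≈ α_mean/E|γ| ≈ 1.5) well clear of per-instrument ratio noise
(≈ σ_Y/E|γ| ≈ 0.3) — the contamination regime the robust estimators
target.

What the generator does **not** model: LD beyond the optional
block-correlated mode, sample overlap, winner's curse from discovery
selection, population stratification, case-control traits, or
non-normal effect distributions. Passing tests therefore demonstrate
estimator correctness and calibration under the stated two-sample model,
not robustness to those real-data complications.

## Numerical and statistical choices

* First-order Wald se ignores σ_X. The resulting attenuation of ratio
  estimators is of order |θ|/F̄ (≈ 2% at F̄ ≈ 50); the F > 10 filter
  bounds it in pipeline use, and the parameter-recovery tests use a
  strong-instrument condition (γ_sd = 0.06, F̄ ≈ 300) where it is far
  below Monte-Carlo resolution. A documented limitation, standard in
  summary-data MR.
* Egger orientation uses the sign of the observed β̂_X; at finite
  instrument strength occasional sign errors attenuate the intercept's
  tracking of the mean direct effect (measured ≈ 25% at F̄ ≈ 50) and
  nudge the slope — inherent to the estimator, not removed.
* The 40%-invalid robustness claim for the weighted median holds per
  replicate only while valid instruments keep the weight majority; with
  χ²-skewed weights (γ² under a normal γ), 40% by count crosses 50% by
  weight in roughly one replicate in six, and there the median's premise
  fails by construction.
* Bootstrap and mode estimators draw from substreams keyed by
  (method name, seed) via CRC32, so adding or removing one method never
  changes another's numbers and all stochastic output is bit-reproducible.
* Degenerate inputs: a single usable pair collapses IVW to the lone Wald
  ratio; median/mode/Egger refuse < 3 pairs; an exact-fit Egger
  regression (zero residual scale) reports zero standard errors rather
  than dividing by zero; identical ratios give Q = 0, I² = 0; mode
  bandwidth falls back to the sd-based rule when the MAD degenerates.
* p-values are floored at 10⁻³⁰⁰ on generation so serialized tables stay
  inside (0, 1].
* Positions are 1-based; alleles upper-cased on read; validation drops
  rows (counted, one rule each) and never edits values.

## Problem sizes in the tests

The suite simulates at the study's own scale (70 SNPs, n up to 2×10⁵)
because summary-statistic MR is cheap: 500-replicate recovery, 1000-replicate
intercept calibration, and 200-replicate robustness runs complete in
seconds. Bootstrap counts are reduced (25–200) in end-to-end tests where
only point estimates or IVW inference are asserted; the pipeline default
stays 1000.

## Known limitations

No proxy-SNP search, no multivariable MR, no MR-PRESSO/Steiger/CAUSE,
no reference-panel LD, no VCF input, no reverse-direction orchestration
(swap the inputs to get it). The method-selection rule is advisory; all
five estimates are always reported.
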