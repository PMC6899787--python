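# Methods

This note documents the statistical models mrpipe implements, the design of
the synthetic-data generator, the numerical choices, and the limits of what
the bundled validation shows.  Nothing here states an empirical result the
test suite or `scripts/acceptance.py` does not itself compute.

## Summary-statistics model

Throughout, a variant's association with a standardized trait is summarized
by a per-allele effect β, its standard error SE, effect-allele frequency
(EAF), p-value and sample size N.  On the standardized-genotype scale
(β_std = β·sqrt(2·EAF·(1−EAF))) the sampling error of β̂_std is
approximately N(0, 1/N), which is the approximation every downstream
formula and the generator rely on.  Positions are 1-based GRCh37; alleles
are uppercase, single-nucleotide, forward strand.

## Quality control and cross-cohort alignment

Filters are strict inequalities — MAF > `maf_min` (default 0.01) and
imputation INFO > `info_min` (default 0.8) — so boundary values are
removed.  Records with a missing INFO pass only when `info_min = 0`; the
CLI applies this automatically to panels whose INFO column is entirely
missing, the situation of a sequenced (non-imputed) cohort.  Alignment to a
reference cohort negates β and complements EAF when a cohort reports the
allele pair swapped; pairs that match neither directly nor after the swap
are dropped and counted.  No strand complementing is attempted at this
stage because panels entering a meta-analysis are expected to be
pre-standardized to the forward strand; harmonization against an external
outcome GWAS (below) does attempt complements, since two independently
processed studies cannot be assumed to share strand conventions.

Variant keys are rsid when present, else `chrom:pos`.  Within-cohort
duplicate keys keep the smallest-SE record (the best-measured copy) and are
logged.

## Meta-analysis

Fixed effects: weights w_i = 1/SE_i², pooled β = Σw_iβ_i/Σw_i,
SE = (Σw_i)^(−1/2).  Random effects use the DerSimonian–Laird moment
estimator τ² = max(0, (Q−(k−1))/(Σw − Σw²/Σw)) and re-pool with
w*_i = 1/(SE_i²+τ²); with homogeneous inputs τ² truncates to zero and the
two models coincide.  Heterogeneity: Q = Σw_i(β_i−β̄)², referred to
χ²(k−1), and I² = max(0,(Q−(k−1))/Q).  Pooled EAF is the N-weighted mean.

Two-sided p-values come from the normal approximation to β/SE and are also
reported as −log10(p) (computed from the log survival function), because
genome-wide signals underflow double precision near p ≈ 1e−320; locus
ranking uses the log scale.

The genomic inflation factor is λ = median(χ²)/median(χ²₁) with
median(χ²₁) = 0.4549364 (scipy's `chi2.ppf(0.5, 1)`).

Per-variant variance explained uses r² = β²/(β²+N·SE²), the identity
linking a variant's z-statistic to its r² on a standardized trait; it was
verified against the three published per-locus values it is meant to
reproduce before being adopted.

Locus definition is greedy clumping: repeatedly take the strongest
unassigned significant variant (p < 5×10⁻⁸) and absorb all significant
variants within ±`window_bp` on the same chromosome.  The ±500 kb default
is a conventional choice, configurable.  Lead SNPs of distinct loci are
therefore separated by more than the window.

### Conditional scan

On the standardized scale, for SNP j with LD correlation r to the lead:
β_{j|lead} = (β_j − r·β_lead)/(1−r²) and SE_{j|lead} = SE_j/sqrt(1−r²) —
the two-predictor least-squares solution expressed through marginal
statistics.  SNPs with r² > 0.9 to the lead are reported `ignored`
(collinear; no stable estimate), and SNPs more than 10 Mb away are assumed
in linkage equilibrium and returned unconditioned.  The implementation is
validated against an explicit two-SNP OLS fit on simulated individual-level
data (n = 5000) at r ∈ {0, 0.3, 0.5, 0.8}, agreeing within 2 SE.

## Harmonization, palindromes, proxies, Steiger

Outcome effects are re-oriented to the exposure's effect allele.
Non-palindromic mismatches are re-tested after strand-complementing the
outcome alleles before being dropped.  Palindromic variants (A/T, C/G)
carry no letter information about strand, so under the default `infer`
policy the orientation is chosen to put both EAFs on the same side of 0.5;
variants whose EAF falls inside the ambiguity band (0.42, 0.58), where
frequency cannot resolve strand reliably, are dropped.  The band is a
package default (configurable); inference near 0.5 is intrinsically
unreliable no matter the band chosen.

Proxy search returns the available SNP with maximal r² ≥ 0.8 to a missing
instrument, ties broken by physical distance then id.  The proxy's own
alleles and effects are used as-is; no translation onto the target's
alleles is attempted.

Steiger filtering computes per-SNP r² = z²/(z²+N) in each trait and
retains instruments with strictly r²_exposure > r²_outcome.  The Fisher-z
statistic (atanh r_exp − atanh r_out)/sqrt(1/(N_exp−3)+1/(N_out−3)) and its
p-value are reported per SNP; by default no significance gate is applied
(retention is the pure direction comparison), and `steiger_alpha` adds a
one-sided gate for users who want one.

## MR estimators

All estimators consume the harmonized table; estimates are in outcome SD
(or log-odds) per exposure SD.

* **Wald ratio** β_Y/β_X with first-order SE = SE_Y/|β_X|; a second-order
  option inflates by sqrt(1 + β_Y²SE_X²/(β_X²SE_Y²)), checked against a
  Monte-Carlo delta oracle.
* **IVW**: zero-intercept weighted regression of β_Y on β_X with weights
  1/SE_Y², algebraically the 1/SE_ratio²-weighted mean of Wald ratios
  (asserted to 1e−12 in the tests).  The random-effects variant uses the
  multiplicative over-dispersion model, SE inflated by
  max(1, sqrt(Q/(k−1))) — inflation floored at 1 so a quiet instrument set
  cannot shrink the SE below its fixed-effects value.
* **MR-Egger**: exposure effects re-oriented positive, weighted regression
  with free intercept (directional pleiotropy), k−2 df over-dispersion
  with the same floor.  Needs ≥3 instruments.
* **Weighted median**: ratios ordered, cumulative midpoint weights
  p_j = Σ_{k≤j}w_k − w_j/2, estimate interpolated at 0.5; SE from a
  parametric bootstrap (default 1000 draws, seed required).
* **Radial outliers**: the IVW fit expressed radially gives per-SNP Q
  contributions q_j = w_j(ratio_j − θ̂)², referred to χ²₁; SNPs below
  `alpha` (default 0.05) are flagged, and an optional re-fit drops them.

`run_mr_suite` runs every estimator whose instrument-count precondition
holds and records the rest as "not applicable" rather than failing — a
two-instrument exposure yields Wald ratios and IVW only, which is exactly
the situation of a protein GWAS with two significant loci.  Bidirectional
analysis is two suite calls with the trait roles swapped.  Binary outcomes
are analyzed on the log-odds scale and exponentiated to odds ratios only
for display.

## Colocalization

Wakefield log ABFs, lABF = ½[ln(V/(V+W)) + z²·W/(V+W)] with V = SE² and
W the effect-size prior variance (prior SD 0.15 for quantitative traits,
0.2 for case-control — the conventional defaults).  Hypothesis scores are
log-sum-exp accumulations of per-configuration terms; the cross-pair sum
for H3 uses Σ_{i≠j} = Σ_iΣ_j − Σ_{i=j} evaluated in log space, so nothing
underflows up to |z| = 50 and a single-SNP region simply has no H3 mass.
Priors default to p1 = p2 = 1e−4, p12 = 1e−5; the colocalization flag is
PP4 ≥ 0.80.  The implementation is checked to 1e−10 in log posterior
against an explicit enumeration of all single-causal-variant
configurations for regions of up to 5 SNPs.

The beta/SE form of the ABF is used (rather than frequency/sample-size
approximations) because it is self-contained in the regional inputs.

## Simplified LD-score regression

LD scores ℓ_j sum r² over SNPs within a physical window (self included, so
ℓ ≥ 1).  The regression E[χ²_j] = intercept + (N·h²/M)·ℓ_j is fitted by
two-pass weighted least squares: an OLS pass, then weights
1/(2·Ê[χ²_j]²) with predictions clipped below at 0.1 to keep weights
finite.  An unweighted flag exists because the noise-free line-recovery
check is only exact without reweighting.  SEs come from a delete-one-block
jackknife over 200 contiguous index blocks (var = (g−1)/g·Σ(θ_(i)−θ̄)²),
implemented by subtracting per-block sufficient statistics so the 200
refits are O(1) each.  h² is reported unconstrained with an out-of-range
flag rather than clamped.  This is the single-trait core only: no
annotation partitioning, no cross-trait genetic covariance, no reference
SNP-list filtering.

## Synthetic-data generator

The generator emulates the pipeline's target study at toy scale with known
ground truth:

* **Region**: block-diagonal AR(1) LD, r_jk = ρ^|j−k| within a block
  (default ρ = 0.7), zero across blocks; default 200 variants in 10
  blocks spaced 100 kb apart so distinct blocks emulate distinct loci
  outside a ±500 kb clumping window.  MAFs uniform on (0.05, 0.5).
* **Exposure**: four cohorts of 7292/1041/1316/935 samples (≈10.6k total)
  measuring the same standardized phenotype.  Two causal variants in
  distinct blocks jointly explain h² = 2.4% of the exposure, split 5:1
  (one ~2% signal, one ~0.4%), matching a strong lead locus plus a modest
  second locus at this sample size.  Marginal effects are R·b; estimates
  add MVN(0, R)-correlated noise scaled by the analytic SE; EAFs are
  binomially resampled at 2N draws; imputed cohorts get INFO ~ U(0.85, 1)
  while one cohort (index 2) emulates a sequenced study with no INFO.
* **Outcome**: a single GWAS (default N = 426,824) whose true marginal
  effects are θ·(exposure marginals) plus the LD-convolution of direct
  (pleiotropic) effects N(α, σ_p²) planted at the causal variants, signed
  relative to the exposure-increasing allele — directional pleiotropy is
  only meaningful in that orientation, and the Egger intercept estimates
  exactly that quantity.  Default θ = −0.12 outcome SD per exposure SD.
  Binary mode keeps the linear mechanics on the log-odds scale with the
  SE reflecting the Bernoulli variance at the case fraction.
* **Independent instruments** (`simulate_instruments`): for estimator
  recovery studies, k unlinked instruments with per-SNP exposure
  variance ~0.5% at N = 50k (mean F ≈ 250, magnitudes uniform within
  [0.5, 1.5]× around the mean).  The strength is deliberately high so the
  no-measurement-error assumption Egger regression relies on holds; weaker
  instruments would show the well-known regression-dilution bias of the
  Egger slope, which is a property of the estimator, not a defect of the
  implementation.
* **Individual-level oracle**: continuous standardized dosages
  X ~ MVN(0, R) with y = X·b + e.  This carries exactly the correlation
  structure the summary-level formulas assume and exists solely as the
  reference for the conditional scan; it does not emulate hard genotype
  calls, Hardy–Weinberg sampling, or case-control ascertainment.

All generators are pure functions of (config, seed); per-cohort streams are
split by CRC-hashing the stream label into the seed sequence.

**What passing tests do and do not show.**  The generator draws effects
from the approximations the estimators themselves assume (normal sampling
error, analytic SEs, linear LD convolution, InSIDE-valid pleiotropy).
Recovery on this data validates the algebra and the code, and calibration
checks (type-I error, Q-p uniformity, λ on null data) validate the
distributional approximations at realistic sizes — but none of this
guards against real-data pathologies such as population stratification,
sample overlap between exposure and outcome GWASs, mis-specified LD
references, or selection effects.  Published headline causal estimates can
only be reproduced with the original outcome GWAS files, which are not
redistributable here; the acceptance study therefore demonstrates recovery
of effects of the same magnitude under the same sample sizes.

## Numerical choices and degenerate inputs

* p-values via `norm.logsf`; −log10(p) carried alongside p everywhere.
* Conditioning is refused (flagged, not computed) when 1−r² < 1e−8.
* LD matrices validate symmetry, unit diagonal and PSD to 1e−6 on load.
* Weighted-median interpolation handles duplicate ratios by cumulative
  weight; bootstrap draws with a zero exposure effect are excluded from
  that draw's ratio set.
* Jackknife block boundaries are `linspace`-rounded contiguous index
  ranges, so block sizes differ by at most one SNP.
* TSV output rounds to 6 significant digits; JSON keeps full precision;
  every CLI run writes a manifest (config hash, seed, versions, input
  checksums) and identical manifests imply byte-identical outputs.

## Problem sizes used in validation

Recovery grids use 100–200 replicates per cell (θ ∈ {−0.2, 0, 0.2},
k ∈ {2, 10, 50}, N = 50k), 2000 null replicates for the IVW type-I error,
200 replicates at M = 20k SNPs / N = 10k for LD-score recovery, n = 5000
individuals for the conditional-scan oracle, and 25 full pipeline runs at
the four-cohort design for end-to-end causal-effect recovery.  These sizes
keep Monte-Carlo error comfortably below the tolerances being asserted.

## Known limitations

* Single-causal-variant assumption in coloc (no SuSiE-style multi-signal
  decomposition) and a single-lead conditional scan (no stepwise joint
  model selection).
* No sample-overlap correction in MR; no MR-PRESSO, mode-based or
  multivariable estimators.
* LD must be supplied (or simulated); the package computes no LD from
  genotype panels and performs no liftover, VCF parsing or INDEL handling.
* The λ statistic and LDSC intercept are computed, but no genomic-control
  correction is ever applied to the statistics.
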