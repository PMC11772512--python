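# Methods

This note records the statistical models implemented in `targetmr`, the
defaults and why they were chosen, what the synthetic-data generator does
and does not emulate, and the numerical choices a maintainer would want to
know about.

## Summary-statistic model

All analyses operate on per-SNP association records (effect β per copy of
the effect allele, standard error, p, allele frequency, sample size);
effects are log odds ratios for binary traits and SD units for
quantitative traits. Positions are 1-based, intervals closed. Alleles are
matched by SNP id during harmonization; when the outcome's effect allele
is the exposure's other allele the outcome β is sign-flipped. A/T and C/G
SNPs are dropped unconditionally — with summary data alone their strand is
unresolvable and no frequency-based rescue is attempted. Duplicate SNP ids
are rejected rather than silently resolved.

LD clumping is greedy: repeatedly keep the remaining SNP with the smallest
p (ties broken by smaller position, then lexicographic id — determinism is
required, and the tie-break is arbitrary but fixed) and remove remaining
SNPs with r² ≥ the ceiling within the window. The window bounds the LD
search; distance alone never removes a SNP. The LD reference is a
user-supplied signed correlation matrix per region; no reference panel
ships with the package.

## Instruments

Cis instruments for a gene: eQTL p < 5×10⁻⁸, |pos − TSS| ≤ 100 kb,
MAF > 0.01, then clumping at r² < 0.001 within 10,000 kb. The wider
"cis universe" (±1 Mb of the gene) and all thresholds are configurable.
The TSS is used as annotated, with no strand-dependent shift, since the
window is symmetric. Instrument strength per SNP uses the standardized
approximation R² = 2p(1−p)β² (capped below 1) and F = (n−2)R²/(1−R²); the
exact per-SNP variance formula depends on unavailable phenotype variances,
and the 2pq approximation is standard for standardized traits. Missing
allele frequency or sample size makes strength unavailable (an error when
requested explicitly, NaN inside instrument sets).

## SMR and HEIDI

SMR at the top cis-eQTL: b = β_y/β_x, T = z_x²z_y²/(z_x²+z_y²) ~ χ²(1),
se(b) = |b|·√(1/z_x² + 1/z_y²) (delta method; at z_y = 0 the limit
se_y/|β_x| is used). T is symmetric in the two z-scores and bounded by
min(z_x², z_y²), so the test is conservative unless the eQTL is strong —
which the p < 5×10⁻⁸ eligibility rule guarantees in practice.

HEIDI selects up to 20 cis-SNPs with eQTL p < 1.57×10⁻³ and r² to the top
SNP in [0.05, 0.9] (the conventions of the original SMR tool; at least 3
required, otherwise the p-value is reported missing with a reason). For
each, d_i = b_i − b_top with delta-method variances and LD-derived
covariances (two-sample designs make the eQTL and GWAS errors independent;
within each trait, cov(β̂_i, β̂_j) = r_ij·se_i·se_j). The statistic
Σ(d_i/sd_i)² is a correlated chi-square sum; its p-value uses Satterthwaite
moment matching (scale = Var/2·Mean, df = 2·Mean²/Var with
Var = 2·ΣΣρ²_ij). This is an approximation — it matches two moments, not
the full distribution — and simulation places its size near nominal
(rejection ≈ 0.03–0.05 at α = 0.05 under a shared causal variant).

HEIDI is reported, not gated, by default: the screen's published usage
retains genes with very small HEIDI p, so filtering is opt-in via a
threshold.

## Two-sample MR

Per-SNP ratios β_y/β_x carry first-order delta standard errors se_y/|β_x|
(exposure uncertainty ignored — standard two-sample practice with strong
instruments). Instruments with β_x = 0 are dropped with a warning.

* **Wald ratio** (1 SNP): the primary estimator under the strict clumping,
  which frequently leaves a single instrument.
* **IVW** (≥ 2): inverse-variance-weighted mean; the standard error is the
  fixed-effect value inflated by √max(1, Q/(k−1)) — multiplicative random
  effects, never deflated. The fixed-effect se is also exposed.
* **MR-Egger** (≥ 3): weighted least squares of β_y on β_x with intercept,
  weights 1/se_y², exposure effects oriented non-negative first. The same
  max(1, ·) over-dispersion rule applies; intercept and slope p-values are
  two-sided normal.
* **Weighted median** (≥ 3): midpoint-interpolated weighted quantile at
  0.5; a ratio carrying more than half the weight is returned directly
  (it is the median by definition; interpolation conventions disagree only
  at the sorted boundary). se by parametric bootstrap (1000 draws, seeded,
  both β̂_x and β̂_y perturbed).
* **Weighted mode** (≥ 3): argmax of an inverse-variance-weighted normal
  kernel density on a 1024-point grid; bandwidth = factor × weighted-MAD
  scale (1.4826·MAD about the weighted median, factor default 1). Zero
  scale (identical ratios) returns the common ratio with se 0. Bootstrap
  se as above.

Diagnostics: Cochran's Q = Σw_i(ratio_i − β_IVW)² with p ~ χ²(k−1)
(reported, not gated); leave-one-out IVW with flagging when omission flips
the sign or moves the estimate by more than a configurable multiple
(default 1) of the full-model se; Benjamini–Hochberg FDR preserving input
order. Odds-ratio reporting uses z₀.₉₇₅ = 1.959964 internally. The screen
requires sign concordance across all computed methods — a gene whose
estimators disagree in direction is excluded at stage 2.

## Colocalization

Per-SNP Wakefield log-ABFs, lABF = ½[ln(V/(V+W)) + z²W/(V+W)] with
V = se², W = prior_sd². Prior effect-size SDs default to 0.15
(quantitative) and 0.2 log-odds (binary) — the conventions of the standard
coloc implementation; the per-SNP priors default to p1 = p2 = 10⁻⁴,
p12 = 10⁻⁵. Hypothesis weights are assembled entirely in log space
(log-sum-exp; the H3 cross-term uses log1p of a difference), which keeps
z-scores beyond 40 finite. A single-SNP region makes H3 impossible and
PPH3 is exactly 0. The decision rule (PPH4 > 0.75, else PPH3 + PPH4 > 0.8)
records which clause fired, because the second clause can promote a
linkage-dominated region; the screen relies on later stages (druggability,
and the analyst reading `rule_fired`) rather than merging the clauses.

## MVMR and mediation

Multivariable IVW: weighted least squares of outcome effects on the
exposure-effect matrix, no intercept, weights 1/se_y², with the same
multiplicative ≥ 1 over-dispersion; a rank-deficient matrix raises a
collinearity error naming the dependent columns. Conditional instrument
strength per exposure is a Q-statistic analogue (weighted regression of
that exposure's effects on the others', residuals standardized by the
exposure's ses, divided by k−p+1); it ignores covariance between exposure
estimates and is reported as an approximation, or omitted when exposure
ses are unavailable. Joint instrument sets are formed as the union of
per-exposure instruments re-clumped together.

Mediation by the coefficient product: indirect = β_{X→M}·β_{M→Y},
se by the product delta method √(β₁²s₂² + β₂²s₁²), direct = total −
indirect, proportion = indirect/total. Proportions outside [0, 1] are
reported verbatim and flagged "inconsistent mediation" — such values are
legitimate outputs of this decomposition. The mediator→outcome coefficient
may be taken from MVMR (adjusted) or univariable MR; both are supported
and neither is hard-wired, since the choice is analysis-specific.

## Synthetic data

The generator works on the standardized-genotype scale: the causal eQTL
effect is √(variance explained); true marginal effects are the LD matrix
times the causal vector; observed effects are multivariate normal around
truth with correlation equal to LD (Cholesky with 1e-10 jitter); per-allele
effects divide by √(2p(1−p)). Quantitative-trait ses are 1/√n; binary-trait
ses use the case-control approximation 1/√(2p(1−p)·n·φ(1−φ)) with case
fraction φ. Defaults mirror the consortium scales the screen targets:
eQTL n = 31,684; GWAS 7,495 cases / 71,934 controls; AR(1) LD with
ρ = 0.9 (a block model is available for linkage scenarios); MAF uniform on
(0.05, 0.5). Scenario H4 routes the SNP's outcome effect through
expression (standardized outcome effect = causal_effect × √v); H2/H3 give
the distinct GWAS variant the same standardized magnitude so power is
comparable across scenarios; the H3 variant separation is chosen to hit a
target r² under AR(1).

What it does not emulate: allele-frequency-dependent LD structure, multiple
independent cis signals per gene, sample overlap between exposure and
outcome panels, population stratification, winner's-curse selection of the
published top SNPs, or genotype-level data. Passing tests therefore show
the estimators are correct and calibrated under clean two-sample,
single-causal-signal conditions — not that real consortium data meet those
conditions.

The 20-gene benchmark plants 3 strong druggable H4 genes (expression
variance 5%, causal effect 1.0 log-OR per SD — strong enough that recovery
is essentially deterministic across seeds) among causal-but-undruggable,
linkage (H3), eQTL-only (H1) and pure-noise decoys. The H3 decoys
deliberately pass colocalization through the PPH3+PPH4 clause and are
excluded only by druggability, exercising that path.

## Numerical and design choices

* All randomness flows through explicit integer seeds
  (`numpy.random.default_rng`); no global state. Re-running any pipeline
  with the same seed and config is bit-identical.
* Simulation scale in the test suite and acceptance script (regions of
  30–200 SNPs, 200–500 replicates) was chosen to give Monte-Carlo error
  comfortably inside the asserted bands while keeping the whole suite
  around a minute of simulation time.
* p-values are clipped to [1e-300, 1] when generated from z-scores;
  validation accepts p ∈ (0, 1].
* Ties in top-SNP selection break by (p, position, id), matching the
  clumping tie-break.
* A missing LD reference suppresses HEIDI at stage 1 and makes stage 2
  untestable (clumping needs LD); colocalization under the
  single-causal-variant ABF model needs no LD and proceeds.
* File formats are plain TSV with `.` for missing; the gene annotation
  table is BED-like (0-based half-open for its two coordinate columns
  only).

## Known limitations

* Single-causal-variant colocalization only (no SuSiE-style multi-signal
  decomposition); regions with several independent signals dilute PPH4.
* HEIDI's Satterthwaite p-value is approximate in the far tail.
* First-order ratio ses understate uncertainty for weak instruments; the
  F statistics are reported so analysts can check.
* The conditional-F approximation in MVMR ignores cross-exposure
  estimation covariance.
* No MR-PRESSO, Steiger filtering, or cross-ancestry support.
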