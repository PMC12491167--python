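# Methods

## Scope and data model

`medmr` operates on GWAS summary statistics only: per SNP, an identifier,
chromosome/position (1-based), effect and other allele, effect-allele
frequency (EAF), effect size β (log-odds for binary traits), its standard
error, a p-value and the sample size. Three aligned sets — exposure,
mediator, outcome — plus cis-eQTL summaries and a pairwise LD (r²) lookup
are the complete inputs; the package never touches genotypes.

## Harmonization

Exposure and outcome effects are aligned to the same effect allele. When
outcome alleles are reported in swapped order the outcome β changes sign;
alleles on the opposite strand are complemented before comparison.
Palindromic SNPs (A/T, C/G) are removed by default because strand cannot
be resolved from alleles alone — no frequency-based rescue is attempted,
matching the conservative convention of dropping rather than inferring.
SNPs missing from the outcome are excluded without proxy lookup. Every
excluded SNP is logged with exactly one stage label, so input count =
pairs + exclusions always holds.

## Instrument selection

Filters run in a fixed order — exposure-p → MAF → LD clump → outcome-p →
F — with per-stage exclusion counts. Defaults: exposure p < 5×10⁻⁶,
MAF ≥ 0.01 (MAF = min(EAF, 1−EAF)), greedy clumping at r² < 0.01 within a
symmetric 10,000 kb window (index SNPs visited by ascending exposure p,
ties broken lexicographically by SNP id, so output is independent of row
order), and F > 10 where R² = β²/(β² + N·SE²) (the 2·EAF(1−EAF) factor in
the textbook formula cancels) and F = R²(N−2)/(1−R²).

The outcome-association screen is configurable because the two natural
directions disagree: dropping SNPs *associated* with the outcome
(`exclude_below`, the default — it serves the confounding rationale) or
the literal opposite (`exclude_above`). Neither is asserted as correct.
Note the screen is only coherent when instruments affect the outcome
undetectably; under a strong genuine causal effect (as in the synthetic
recovery design, total effect −0.56 with n = 100,000) every valid
instrument is outcome-associated *through the exposure*, so recovery
analyses run with the screen off.

## Estimators

All multi-SNP estimators consume per-SNP Wald ratios r_j = β_Yj/β_Xj with
first-order ratio variance se²_Yj/β²_Xj (second-order available for the
single-SNP Wald ratio by flag; the difference is ~½(r·se_X/se_Y)²
relative, negligible for F > 100).

* **IVW** — weighted regression through the origin, weights 1/se²_Y.
  Default effects model is multiplicative random effects: the SE is
  inflated by max(1, √(Q/(n−1))) and never deflated below the
  fixed-effects SE. Fixed effects by flag. p two-sided normal.
* **MR-Egger** — weighted regression with intercept after orienting all
  instruments to β_X ≥ 0 (the intercept is orientation-dependent). Fitted
  by weighted least squares (statsmodels); slope and intercept p-values
  from t on n−2 df; the same never-deflate SE convention applies. The
  intercept estimates average directional pleiotropy.
* **Weighted median** — linear interpolation of the ratio order statistics
  at cumulative weight 0.5; SE by parametric bootstrap (default 1000
  resamples of both β_X and β_Y from their sampling distributions; the
  seed is mandatory — there is no silent nondeterminism anywhere in the
  package).
* **Mode (simple/weighted)** — argmax of a normal-kernel density of the
  ratios on a 512-point grid spanning the data ±3 bandwidths; bandwidth is
  the modified Silverman rule 0.9·min(sd, MAD)·n^(−1/5) times a
  configurable factor (default 1). Grid ties resolve to the lowest point;
  zero spread falls back to the weighted median. SE by the same bootstrap.

With one instrument only the Wald ratio is reported; with two, IVW only
(Egger/median/mode need ≥ 3).

## Sensitivity

Cochran's Q uses IVW ratio weights about the fixed-effects IVW estimate
(df n−1) or Egger residuals (df n−2). Leave-one-out re-estimates on each
(n−1)-subset. Steiger sums single-SNP variance explained per trait and
compares Fisher-transformed √R² at the two sample sizes; ties resolve to
"direction not established" with p = 1, never to reverse causation. The
power calculation for binary outcomes is a noncentral-normal
approximation, power = Φ(λ − z_{1−α/2}) + Φ(−λ − z_{1−α/2}) with
λ = √(N·R²·cf(1−cf))·|ln OR| — a declared stand-in convention (no
published formula was specified), validated against Monte-Carlo simulation
of the Wald test in the test-suite. Exposures with power < 0.5 at the
observed effect are conventionally set aside.

## Mediation

Two-step MR: β₁ (exposure→mediator) and β₃ (exposure→outcome) from the
exposure's instruments, β₂ (mediator→outcome) from the mediator's own
instruments. Two-step validity requires mediator instruments not to act
through the exposure, so SNPs whose exposure p passes the instrument
threshold are removed from the mediator leg — without this, any direct
exposure→outcome path leaks into β₂ (in the synthetic recovery design the
leak inflates β₂ from −0.2 to ≈ −0.26). β₁ is always on the coefficient
scale: when an upstream estimate arrives as an OR, take ln(OR) first.

The decomposition is exact arithmetic: mediation = β₁β₂, direct = β₃ −
β₁β₂ (bitwise, by construction), proportion = β₁β₂/β₃ (undefined at
β₃ = 0, no exception). The sign-consistency rule — report only when
mediation and total agree in sign — sets a flag used by the reporting
layer; numbers are never mutated. The delta-method SE of the product is
√(β₂²se₁² + β₁²se₂²).

## SMR and HEIDI

SMR: b = β_GWAS/β_eQTL at the gene's top cis-eQTL,
T = z²_G z²_E/(z²_G+z²_E) ~ χ²(1), se = |b|/√T. HEIDI tests whether other
cis SNPs imply the same b: differences d_j = b_j − b_top are standardized
by a first-order covariance that combines LD-induced correlation of GWAS
and eQTL effects with the shared top-SNP term; the statistic Σz² is
referred to its exact null — a weighted sum of χ²(1) with weights the
eigenvalues of the correlation matrix of d — via Imhof's inversion
integral (Satterthwaite two-moment fallback if quadrature fails).
Eligibility follows the reference tool's conventions (no thresholds were
specified): eQTL p < 1.57×10⁻³, r² with the top SNP in [0.05, 0.9], at
least 3 and at most 20 candidates; fewer than 3 returns an undefined
p_HEIDI, which the decision rule counts as a failure with a reason.
Decision rule: pass iff p_SMR < 0.10 and p_HEIDI > 0.05.

Limitation: LD arrives as r², so the signed correlation is taken as
+√r². With signed LD available the covariance would be exact; with r²
only, regions with negative allelic correlation are mis-covaried. All
calibration tests use structures where the sign is immaterial.

## Synthetic generator

The generator encodes exposure → mediator → outcome with a direct
exposure→outcome path. SNPs split (default 50/50) into exposure
instruments (γ_j ~ N(0, γ_sd²)) and mediator instruments (δ_j, same sd,
zero exposure effect) — the mediator leg of two-step MR is unidentifiable
without the latter. Optional pleiotropic SNPs receive direct outcome
effects π_j ~ N(0, 0.05²), violating the exclusion restriction. True
effects: mediator = b₁γ + δ; outcome = b_direct·γ + b₂·(mediator) + π.
Observed β are true effects plus N(0, se²) noise with
se = 1/√(2N·EAF(1−EAF)); EAFs (uniform on [0.05, 0.5]) are shared across
cohorts; p-values two-sided normal, clamped into (0,1]. One master seed
spawns independent per-trait streams; identical configs are byte-identical.
A `noiseless` flag gives the N→∞ limit. LD is block-diagonal (configurable
block size and within-block r², default independent SNPs) on a map of
contiguous 100 kb-spaced SNPs, 1000 per chromosome.

Defaults are the recovery design: 200 SNPs, three cohorts of 100,000,
b₁ = 0.3, b₂ = −0.2, b_direct = −0.5 (total −0.56, proportion mediated
3/28 ≈ 10.71%), no pleiotropy. γ_sd = 0.2 was fixed analytically before
any acceptance run: MR-Egger's intercept test is only nominally calibrated
when regression dilution from noise in β̂_X is negligible relative to the
intercept's SE. With half-normal |γ| (orientation makes E[x̄] > 0), the
attenuation 1−λ = se²_X/(Var|γ|+se²_X) puts an intercept bias of
≈ (1−λ)·|β|·E|γ| against an SE of ≈ se_Y·√(1/k + x̄²/S_xx) over k
instruments; at γ_sd = 0.05 the ratio is ≈ 0.75 SE (empirical type-I
≈ 11%), at 0.1 ≈ 0.38 SE (≈ 6.7%), at 0.2 ≈ 0.19 SE (nominal). Effects of
this size correspond to top microbiome-abundance loci (a few percent of
variance each); in aggregate the panel explains more heritability than a
real 16S GWAS would, which is the price of desk-scale calibration.

What a green recovery test establishes: the estimators and decomposition
recover the generative parameters under correct model specification,
independent errors between cohorts (a true two-sample design), shared
EAFs, and normal sampling noise. It does not establish robustness to
sample overlap, allele-frequency mismatch between cohorts, winner's-curse
selection, binary-trait non-collapsibility, or realistic LD — none of
which the generator emulates.

## Multiple testing and significance

Benjamini–Hochberg step-up (via statsmodels, with range validation) within
one (exposure-set × outcome) analysis batch — the family is a recorded
config choice, since none is canonical. The dual rule flags significance
iff raw p < 0.05 and adjusted p < 0.10.

## Numerical conventions

p-values are clamped into (0, 1] (smallest positive double) rather than
reported as 0; bootstrap SEs are floored at the smallest positive double
to keep z-statistics finite; odds ratios and CIs are exp(β) and
exp(β ∓ 1.96·se) by construction. Degenerate inputs (β_X = 0 instruments,
fewer instruments than an estimator supports, unreconcilable alleles,
r² ≥ 1) raise typed errors or produce logged exclusions — never silent
drops.
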