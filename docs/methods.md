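# Methods

`transfine` implements a trans-ethnic GWAS analysis chain for a quantitative
kidney-function phenotype (eGFR): per-study association testing with genomic
control, fixed-effects meta-analysis across ancestry groups, Bayesian
fine-mapping via a partition model over studies, and regulatory-annotation
enrichment of the fine-mapping posteriors. A synthetic multi-ancestry data
generator provides inputs with known ground truth so every stage can be
validated by recovery and calibration experiments.

## Phenotype and per-study association

eGFR is computed with the IDMS-traceable four-variable MDRD study equation

    eGFR = 175 · Scr^−1.154 · age^−0.203 · 0.742^[female] · 1.212^[Black]

with serum creatinine in mg/dL and eGFR in mL/min/1.73 m². Chronic kidney
disease is the binary outcome eGFR < 60 (strict inequality).

Association uses an additive dosage model: ordinary least squares of
phenotype on dosage with an intercept and study covariates (linear trait),
or maximum-likelihood logistic regression (CKD). Per-variant OLS is computed
by residualizing phenotype and dosages on the covariates once
(Frisch–Waugh–Lovell), which is numerically identical to the full fit and
fast across thousands of variants. Dosages collinear with the covariates
(monomorphic variants, or variants in perfect LD with the conditioning
variant) return NaN rather than raising; complete separation in the
logistic fit is flagged per variant, not raised.

Imputation quality control keeps variants with info ≥ 0.4 (IMPUTE2 dialect)
or r² ≥ 0.3 (MaCH/Minimac dialect), both thresholds inclusive.

Genomic control computes λ = median(z²)/median(χ²₁) and, when λ > 1,
inflates standard errors by √λ (equivalently divides χ² statistics by λ),
recomputing p-values and leaving effect estimates untouched. λ is floored
at 1: deflation is never applied. The same operation serves as the
second-round correction applied to meta-analysis statistics.

Conditional analysis re-runs the linear model with the lead variant's
dosage appended to the covariates; a conditional meta-analysis p below
1 × 10⁻⁵ (a Bonferroni correction for roughly 5,000 variants per locus)
flags a distinct association signal.

## Meta-analysis

Per-variant fixed-effects inverse-variance weighting: β̂ = Σwᵢβᵢ/Σwᵢ with
wᵢ = 1/SEᵢ², SE = 1/√Σwᵢ, two-sided normal p. Heterogeneity is Cochran's
Q = Σwᵢ(βᵢ−β̂)² against χ² with k−1 degrees of freedom. A sample-size
weighted z combination (z = Σzᵢ·signᵢ·√nᵢ/√Σnᵢ) is provided for the
case/control meta-analysis, and a two-sample z-test
(β₁−β₂)/√(SE₁²+SE₂²) compares allelic effects between cohorts.

Variants contributing less than 50% of the total sample size are excluded
(inclusive at exactly 50%). Effect alleles are harmonized to the first
study's orientation by allele-pair matching with strand-complement
resolution; palindromic A/T and C/G pairs are oriented by effect-allele
frequency proximity and dropped when neither orientation brings the
frequency difference below a configurable cap (default 0.2). Combined
records are reported with the trait-decreasing allele as effect allele.

Loci are defined greedily: the smallest-p unclaimed variant below the
significance threshold (default 5 × 10⁻⁸) becomes a lead and claims
± 500 kb; the process repeats until no significant variant is unclaimed.
The clumping rule itself is a package choice — the window size is the
only externally anchored quantity.

## Fine-mapping

The combined per-variant evidence Λⱼ is a Bayes factor averaged over
candidate clusterings ("partitions") of the studies, so the model behaves
like fixed-effects meta-analysis for homogeneous allelic effects and like
a clustered analysis when effects differ between ancestry groups:

1. Study relatedness: D[a,b] = mean absolute effect-allele-frequency
   difference between studies a and b over the shared variant set.
2. Candidate partitions: the nested cuts (K = 1 … n_studies) of the
   average-linkage tree on D. For ≤ 8 studies, an exhaustive enumeration
   of all set partitions is available (`mode="full"`).
3. Within a cluster, effects combine by inverse-variance weighting and the
   cluster contributes a Wakefield approximate Bayes factor with effect
   prior N(0, W): log ABF = ½ln(SE²/(SE²+W)) + (z²/2)·W/(SE²+W). The
   partition's log BF is the sum over its clusters.
4. Λⱼ (log10) is the prior-weighted average over partitions, computed via
   log-sum-exp.

Partition prior: probability 1/2 on the single-cluster partition (the
fixed-effects limit) and the rest uniform over the remaining cuts
(`prior="half-homogeneous"`, default). A uniform prior over K partitions
necessarily sits up to log₁₀K below a dominating single-cluster Bayes
factor; weighting homogeneity at 1/2 keeps the combined BF within log₁₀2 of
the plain fixed-effects value on homogeneous data — desirable because
allelic effects at real kidney-function loci are homogeneous across
ancestries — while strongly heterogeneous data still let a clustered
partition dominate the average. `prior="uniform"` is available.

The effect-size prior SD defaults to 0.2 on the trait scale (W = 0.04),
chosen to cover per-allele effects of a fraction of an eGFR unit up to a
few units; it is configurable and results are insensitive to factor-of-two
changes for well-powered loci.

Posteriors within a locus are πⱼ = Λⱼ/ΣₖΛₖ (a softmax of log10 BFs,
normalized by log-sum-exp). The 99% credible set ranks variants by
decreasing Λ (ties broken by ascending position) and includes them until
the cumulative posterior strictly exceeds 0.99; a 10⁻⁹ tolerance guards
float noise at exact ties, so 100 variants with π = 1/100 each yield a
100-variant set (99 reach exactly 0.99, which does not exceed it).

Known limitation: because each cluster carries an independent N(0, W)
effect prior, partitioned models over-reward apparent heterogeneity at
marginally powered non-causal variants, which can make trans-ethnic
credible sets larger than single-ancestry ones at moderate power. At
adequate power (combined |z| ≳ 7, the regime of the validation
experiments) the causal variant dominates and the trans-ethnic sets are
never larger at matched total sample size.

## Annotation enrichment

Overlap is binary: a 1-based variant position p occupies 0-based
coordinate p−1 and overlaps a half-open BED interval [start, end) iff
start ≤ p−1 < end.

Consequence aggregation keeps each variant's most severe label under the
standard VEP severity ordering and sums posterior mass per class across
loci.

Two enrichment models are fitted per annotation, one annotation at a time:

* **Fractional logistic regression** of πⱼ on {one intercept per locus,
  the annotation indicator, four genic covariates (3′ UTR, 5′ UTR, coding
  exon, 1 kb upstream of TSS)} with no global intercept (the locus
  indicators span it). The fit is quasi-binomial IRLS — the standard
  likelihood for fractional outcomes — and the annotation coefficient's SE
  is the HC1 heteroskedasticity-robust sandwich. Over a battery of
  annotations, significance is Bonferroni-corrected (0.05/403 ≈ 1.2 × 10⁻⁴
  for the canonical 93 chromatin-state + 145 DHS + 165 TF battery).
  With π exactly 0/1 the fit reduces to ordinary ML logistic regression.
  Calibration caveat: when posteriors concentrate on single driver
  variants, the effective sample size is the locus count and the sandwich
  Wald test is anticonservative at desk scale (tens of loci); the type-I
  calibration test therefore uses diffuse-posterior null loci, the regime
  where the asymptotics are valid.

* **Hierarchical Bayes-factor model**: each locus contains exactly one
  driver variant; the prior that variant j is the driver is
  softmax(γᵀxⱼ) within its locus, so the locus marginal likelihood is
  Σⱼ softmaxⱼ(γᵀx)·BFⱼ. γ̂ maximizes the summed log marginal likelihood by
  Newton ascent with analytic gradient (posterior-minus-prior mean of x)
  and Hessian (posterior-minus-prior covariance); steps are norm-capped at
  2 and damped by halving when the objective decreases. The 95% CI comes
  from observed information; an annotation is enriched when the CI
  excludes 0. With γ = 0 the per-locus posterior is exactly the softmax of
  the BFs, and adding a constant to all log BFs in a locus leaves γ̂
  unchanged. When no driver contrast exists (annotation constant within
  every locus) the effect is unidentifiable and an error is raised; when
  the likelihood is flat in the tail (e.g. no driver overlaps the
  annotation anywhere — the analogue of separation) the estimate is
  flagged unconverged rather than reported.

Agreement between the two analyses is summarized by the squared Spearman
correlation of their effect estimates.

## Synthetic data generator

The generator states a world with the structural features the analysis
exploits and nothing more:

* **Allele-frequency divergence**: Balding–Nichols — per variant, each
  ancestry's frequency is Beta(p(1−F)/F, (1−p)(1−F)/F) around the
  ancestral p, clipped to [0.001, 0.999]. Defaults: four groups (AFR, HIS,
  EUR, EAS) with F = 0.15, 0.08, 0.05, 0.11.
* **LD**: latent Gaussian AR(1) copula thresholded at per-variant normal
  quantiles; marginal frequencies are exact and adjacent-pair LD rises
  monotonically with the copula parameter ρ (defaults 0.80–0.92 by group).
* **Phenotype**: intercept + β·causal dosage + covariate effects +
  N(0, σ). Exactly one causal variant per region by default (matching the
  single-signal conclusion of conditional analysis); a multi-causal mode
  exists for negative tests. Full-cohort defaults are β = −0.9 eGFR units
  per allele (mid-range of reported lead-SNP effects, 0.6–2.0 in absolute
  value) and σ = 24 (the residual scale implied by reported SEs at
  n ≈ 71,600). Desk-scale runs keep β ≈ −1 and shrink σ to 4 so that power
  at the causal variant is ≈ 1 with hundreds rather than tens of thousands
  of individuals; this preserves the power regime, not the sample size.
* **Imputation quality**: scores drawn U[0.3, 1] so the QC filter always
  has work to do.
* **Annotation tracks**: each variant overlaps each track independently
  with probability logit⁻¹(logit(background) + log-odds · causal
  indicator); the enrichment log-odds is capped at 20 so +∞ saturates.
* An eGFR helper inverts the MDRD equation so a latent phenotype can be
  expressed as serum creatinine and recomputed through the real equation.

What the generator does **not** emulate: realistic human haplotype panels,
recombination hotspots, imputation error structure, relatedness,
covariate–genotype confounding. A green recovery test therefore
establishes correctness of the statistical machinery under the stated
model, not robustness to the full complexity of consortium data.

All generators are deterministic given a seed; distinct stages should use
distinct seed streams (the pipeline derives per-stage seeds from the
config seed).

## Numerical choices

* All Bayes-factor arithmetic is in log10 with log-sum-exp mixing;
  results agree with a natural-log implementation to 10⁻⁹.
* Credible-set strict exceedance uses a 10⁻⁹ tolerance at ties.
* Genomic control never deflates (λ floored at 1).
* OLS collinearity is detected by residual dosage variance below 10⁻¹⁰ of
  the largest; covariate-matrix rank is checked and the offending column
  named.
* The meta-analysis coverage filter is inclusive at exactly 50%.
* Newton ascent in the hierarchical model: norm-capped, damped steps;
  |γ| > 20 is treated as divergence and flagged.

## Limitations

* The fine-mapping model is a deterministic surrogate for a full Bayesian
  partition analysis: it averages over at most n_studies (or Bell-number,
  in full mode) partitions rather than sampling the partition posterior.
* Single-driver assumption throughout fine-mapping and hierarchical
  enrichment; multi-signal loci are only handled via conditional analysis
  flags.
* The fractional-logistic sandwich test is anticonservative when posterior
  mass concentrates on a handful of variants (see above).
* Only autosomal, biallelic variants; no mixed-model association; no
  external LD reference panels.
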