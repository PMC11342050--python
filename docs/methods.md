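# Methods

## Scientific setting

CSF Aβ42/40 falls as cortical amyloid plaque burden rises, making it an
in-vivo marker of AD neuropathology. The package tests whether a history of
traumatic brain injury *moderates* the effect of common-variant genetic risk
for AD on this marker: a TBI × PRS interaction on the standardized ratio,
adjusted for age, education, and PTSD symptom severity (CAPS-IV total,
0–136), in a cohort of male veterans. TBI severity follows VA/DOD criteria:
moderate/severe when loss of consciousness ≥ 30 min, post-traumatic amnesia
> 24 h, or altered mental state > 24 h; mild otherwise; with multiple
criteria the higher severity wins. Subjects whose interview records are
discrepant on every severity field are *indeterminate* and excluded from
severity analyses only.

## Genotype processing

Imputed dosages (VCF `DS`/`GP` or TSV) are converted to hard calls at a
call threshold of 0.8. With genotype probabilities, the argmax genotype is
called iff its probability ≥ 0.8. With dosages only, we call `round(d)` iff
`|d − round(d)| ≤ 1 − 0.8`; this is the dosage-space analogue of the
probability rule and is exact when probability mass is confined to the two
nearest genotypes — the natural reading of a bare "call threshold 0.8" for
dosage data. Ties at .5 round half-up (deterministic and monotone).

SNP QC is computed on the hard calls within the analysis sample, matching a
protocol that excludes SNPs "from the calculation" of scores built on hard
calls: exclude when MAF < 0.01 or missingness > 0.05, both strict as
printed (a missing rate of exactly 1/20 passes; the rate is computed as an
integer-count ratio so this boundary is float-safe).

GWAS effect alleles are harmonized to the panel's counted (alt) allele:
direct match keeps β, ref match negates it, and the same rule applies after
strand complementation. Palindromic (A/T, C/G) SNPs are dropped by default
because a strand flip is indistinguishable from an allele swap — the
conservative standard choice where a protocol is silent.

## PRS

`score_i(t) = Σ_j β_j g_ij` over SNPs with GWAS p **strictly below** t
("SNPs *under* the threshold", matching the printed `p < 0.05` notation),
at thresholds 0.05–0.50. Missing calls are mean-imputed with twice the
SNP's counted-allele frequency (expected dosage; equal to 2·MAF whenever
the counted allele is minor), or omitted under `missing_policy="omit"`.
Sum aggregation is the default ("summed together"); per-allele averaging is
provided because downstream inference is invariant to the choice after
standardization. Scores and the outcome are z-scored over the analysis
sample with the n−1 sample SD. The APOE-free score excises
chr19:44,409,039–46,412,650 (GRCh37, inclusive bounds) before threshold
selection. Greedy LD clumping (keep the lowest-p SNP, drop neighbours with
r² above a cutoff inside a kb window) is available but **off** by default:
thresholding-only scoring is the declared procedure, and clumping defaults
would be the main source of divergence between scoring tools.

## Inference

Models are complete-case OLS with two-sided p-values and t-based 95% CIs.
Welch's unequal-variance t-test (with the fractional Welch–Satterthwaite
df) is used for continuous group comparisons — identified by the fractional
dfs such analyses report — and Fisher's exact test for ε4 carrier status,
reporting both the cross-product odds ratio ad/bc and the conditional-MLE
OR. Stratified PRS slopes are covariate-adjusted within each TBI group and
returned alongside the equivalent partial correlation
`r = sign(B)·√(t²/(t²+df))`. The severity ANCOVA treatment-codes severity
(reference: no TBI) and tests the 2-df severity × PRS block with a partial
F against the main-effects model. No multiple-testing adjustment is applied
inside the association module; the threshold family is corrected by the
permutation procedure below, and nothing else is.

## Min-p permutation correction

The six threshold scores are nearly collinear (pairwise r ≳ 0.9 on the
synthetic cohort), so Bonferroni over thresholds would be far too
conservative. Each of B replicates draws one random permutation of subject
indices and applies it to **all** score columns jointly — preserving the
between-threshold correlation exactly while severing any link to phenotype
and covariates — then refits model 3 at every threshold and keeps the
minimum interaction p. The corrected p is the add-one percentile
`(1 + #{min p* ≤ observed min p}) / (B + 1)`: never zero, conservative
under ties, and `corrected ≥ observed min p` by construction. Permuting the
score matrix is numerically identical to permuting genotypes and re-scoring
(a sum-score is a per-subject function of genotypes alone); with clumping
enabled, the clump set is fixed before permutation. A Freedman–Lane
residual-permutation variant is available behind `scheme="freedman_lane"`;
the simple exchange of subject rows is the default because it is the
declared scheme of the analysis this implements. Fits use a batched
closed-form OLS whose equality with statsmodels is asserted in the test
suite; B = 10,000 runs in about a second at n = 88.

## Synthetic cohort generator

The generator emulates the restricted cohort's structure; its defaults are
the study conditions, not tuning knobs.

* **Genotypes.** Block-diagonal AR(1) latent-Gaussian haplotypes: within an
  LD block of 40 SNPs, latent normals with lag-1 correlation 0.7 are
  thresholded at Φ⁻¹(MAF), giving exact marginal allele frequencies,
  within-block LD, and between-block independence. True genotypes are
  blurred with Normal(0, 0.08²) dosage noise clipped to [0,2] and 1% of
  cells are set missing, so hard-calling and missingness QC do real work.
  3% of SNPs are placed inside the APOE-region interval on chr19.
* **GWAS weights.** 10% of SNPs are causal with β ~ Normal(0, 0.05²);
  estimates add noise with se = 1/√(2·N·MAF·(1−MAF)) at N = 50,000 and
  p-values are the two-sided normal tails. These values were chosen from a
  variance-partition argument: a set's score variance is proportional to
  Σz² over its SNPs, so large causal z² concentrates weight mass below
  p < 0.05 and the nested threshold scores correlate at r ≈ 0.93+ — the
  regime real AD scores occupy. An APOE-like tag SNP (region SNP with MAF
  nearest 0.134, so carrier frequency ≈ 25%) is forced causal with a large
  positive β, mirroring APOE's outsized effect.
* **Phenotypes.** Covariates are truncated normals (age 68.3 ± 3.60 y on
  45–90; education 15.1 ± 2.39 y on 8–20; CAPS 46.1 ± 34.8 on 0–136; the
  mean/SD parametrize the *latent* normal, so truncation shifts realized
  moments slightly — e.g. the zero floor raises the realized CAPS mean).
  The outcome is
  `y = 0.01·(age−68.3) − 0.05·(edu−15.1) + 0.01·(caps−46.1) − 0.19·TBI
  − 0.12·PRS_true − 0.45·m(sev)·TBI·PRS_true − 1.12·carrier + ε`, with
  PRS_true the standardized true-β genotype score. By default the residual
  SD is calibrated so Var(y) = 1 — the planted coefficients then already
  live on the standardized-outcome scale the analysis re-standardizes to,
  which is what makes exact parameter recovery meaningful; a fixed
  `noise_sd` can be supplied instead. Severity multipliers m(sev) = 0.6
  (mild) / 1.4 (moderate-severe) implement the dose–response; their
  cohort-weighted mean is ≈ 1, so the pooled interaction stays −0.45.
  Raw analytes are generated ratio-first: Aβ40 ~ log-normal clamped inside
  its 11–43,000 pg/mL technical range, ratio = 0.09 + 0.015·y, and
  Aβ42 = ratio·Aβ40 (only the ratio enters analysis; some Aβ42 draws
  exceed 1,700 pg/mL and are flagged, as in the emulated assay).

What the generator does **not** emulate: haplotype phasing, recombination
maps, population stratification (the emulated design restricts to one
ancestry group precisely to avoid it), genotyping batch effects, assay
drift, and any non-linearity between amyloid burden and CSF analytes.
Passing tests therefore certify the statistical machinery — estimator
correctness, calibration, invariances — not robustness to those real-data
features.

## Numerical choices and problem sizes

* Permutation fits: batched normal-equation OLS in float64; singular
  designs raise naming the threshold; collinear association designs raise
  naming the aliased terms (QR diagnostic).
* Parameter-recovery checks run at n = 5,000 subjects × 200 SNPs (planted
  interaction recovered within ±0.05); type-I calibration of the corrected
  p uses 400 null cohorts at B = 500; the generator's MAF calibration is
  checked at n = 2,000 against binomial 99% bounds. These sizes give tight
  Monte-Carlo error while keeping the default suite fast.
* Seeds: one master seed fans out to per-stage child seeds via a fixed
  sha256 derivation, so every stage is independently reproducible and
  reruns are byte-identical (report timestamps live only in the run log).

## Known limitations

* MAF and missingness are computed within the analysis sample, not against
  an external reference; fine for within-cohort scores, wrong for
  cross-cohort score transfer.
* No genome-build liftover: coordinates are GRCh37 throughout and a build
  mismatch only warns.
* The severity ANCOVA treats severity as unordered; a trend test over the
  ordered levels would be more powerful for a monotone dose–response.
* At n ≈ 88 the interaction estimate is intrinsically noisy (SE ≈ 0.2 on
  the standardized scale); single-cohort estimates should be read
  accordingly.
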