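# Methods

`cogres` implements a proxy-phenotype pipeline for the genetics of
cognitive resilience — the preservation of processing speed in people
whose earlier-life indicators would predict otherwise — together with a
synthetic-cohort generator that reproduces the statistical structure the
analysis assumes. This note records the models, the defaults and why they
were chosen, and what the synthetic runs do and do not demonstrate.

## The quadrant construction

Two proxies bracket roughly four decades of cognition in a 40–69-year-old
cohort: education years (EY) for early-adult performance and reaction time
(RT, ms on a pairs-matching task) for current processing speed.

* **EY** — college attendees are assigned 20 years (their age at completing
  education is not recorded in the source questionnaires); the binary splits
  at ≤ 17 years ("below" average) versus > 17 ("above").
* **RT** — corrected for age with the ordinary least-squares slope of RT on
  age (a correlation has no slope; OLS is the standard reading of
  "the slope of the Pearson correlation"), centred at the sample mean age so
  the correction preserves the mean; the natural log of corrected RT is
  split at its sample mean, ties counting as "faster".

Crossing the binaries yields four groups and two case–control contrasts:
**EY+Res** (cases: below-EY/faster — resilient; controls: above-EY/slower —
declined) and **EY/NonRes** (cases: below-EY/slower; controls:
above-EY/faster — temporally consistent performance, i.e. the education
signal without the resilience signal). Both contrasts are GWASed with
logistic regression per variant (dosage + sex, age, assessment centre,
genotyping array, 8 principal components); a quantitative least-squares
mode covers RT-as-continuous analyses. The association solver is an
in-package iteratively reweighted least-squares routine warm-started at the
covariate-only fit; it matches `statsmodels.Logit` to ~1e-7 in the tests
and exists because thousands of per-variant fits inside simulation loops
need to run in seconds. Non-converged or collinear variants are emitted as
flagged records, never dropped silently.

RT correction and thresholding are computed on the final analysis sample
(individuals with EY, RT and genotypes); re-running the correction on its
own output is a no-op (slope ≈ 0), which the tests assert.

## GWAS-by-subtraction

Let S be the 2×2 genetic covariance matrix of [EY+Res, EY/NonRes] estimated
by LD-score regression and V the sampling covariance of its unique elements
(S11, S12, S22). A two-indicator Cholesky model defines a shared
**EduYears** factor loading on both contrasts and a residual **Resilience**
factor loading on EY+Res only:

    S11 = λ_ee² + λ_re²,   S12 = λ_ee·λ_en,   S22 = λ_en²

so the loadings are λ_en = √S22, λ_ee = S12/√S22, λ_re = √(S11 − S12²/S22),
with λ_en, λ_re ≥ 0 by convention and sampling covariance obtained from V by
the delta method. The model is just-identified: a numerical
V⁻¹-weighted least-squares fit of implied to observed S
(`fit_cholesky_numerical`) coincides with the closed form and serves as an
independent cross-check, not as the implementation. A genuinely
non-positive-semidefinite S (negative residual Resilience variance) raises
an explicit error; nothing is clamped.

Per variant, observed standardized effects are b₁ = Z₁/√(N₁·2pq) and
b₂ = Z₂/√(N₂·2pq), with p the effect-allele frequency from the reference
panel (the simulation's own frequencies in synthetic runs). Regressing both
latent factors on the SNP and solving the just-identified system gives

    β_edu = b₂ / λ_en,   β_res = (b₁ − λ_ee·β_edu) / λ_re.

Standard errors follow by the delta method from var(bᵢ) = 1/(Nᵢ·2pq) and a
cross-trait covariance term `cross_intercept/(√(N₁N₂)·2pq)` taken from the
LDSC cross-trait intercept (the contrasts use disjoint individuals, so this
term is ≈ 0; setting it to zero is an option). Loading uncertainty is
excluded from per-SNP standard errors by default — genome-wide loadings are
treated as fixed — and can be folded in via the delta method when wanted.

**Effective sample size.** Variants are trimmed to MAF strictly between
0.10 and 0.40 (the inversion is biased at both frequency extremes); each
retained variant implies N̂ = (Z/β)²/(2·MAF·(1−MAF)) and the effective N is
their mean (the mean, rather than median, is the documented choice; on
statistics constructed with Z = β·√(N·2pq) the inversion returns N exactly).

## LD-score regression

LD scores are l₂ⱼ = 1 + Σₖ [r²ⱼₖ − (1−r²ⱼₖ)/(n−2)] over neighbours within a
1,000 kb window (configurable), the self term exactly 1 and r² the squared
Pearson correlation of unphased dosages in the reference panel. Munging
harmonises summary statistics to reference alleles (Z negated on A1/A2
swap), removes strand-ambiguous A/T and C/G variants, and applies MAF ≥
0.01 and info ≥ 0.9 filters.

Heritability regresses Z² on N·l₂/M with a free intercept; genetic
covariance regresses Z₁Z₂ on √(N₁N₂)·l₂/M with a free cross-trait
intercept. Weights are the standard heteroskedasticity/over-counting
scheme computed in two passes: a 1/l₂-weighted pass fits per-variant
expectations A = E[Z²] (slope clipped to [0,1]) and C = E[Z₁Z₂], and the
final weights are 1/(l₂·2A²) and 1/(l₂·(A₁A₂ + C²)). The cross form reduces
exactly to the univariate form when the two traits coincide, which makes
rg(trait, itself) = 1 exact. Standard errors and the joint sampling
covariance V of (S11, S12, S22) come from a contiguous block jackknife
(default 200 blocks, reduced automatically so each block holds ≥ 10
variants); V's diagonal equals the squared jackknife SEs by construction.
rg = S12/√(S11·S22) carries a delta-method SE from V, which stays finite
even when a delete-block heritability crosses zero. Following the reference
implementation, regression SNPs can be filtered at χ² > max(80, 0.001·N);
the pipeline applies this cap when estimating S (stabilising the regression
against a few large-effect variants) but never to the statistics entering
the per-SNP subtraction, so large-effect loci remain in the latent output.
At desk-scale M a single extreme-χ² variant can still destabilise the S
regressions (and stricter per-SNP truncation or region-wide exclusion both
bias the remaining bulk when the panel is only a few thousand variants), so
the generator plants large resilience signals as *regions* — a fixed
variance spread over the SNPs of one LD block — rather than as single
mega-effect variants; every per-SNP χ² then stays in the range the standard
weights and cap were designed for, while the region as a whole is
genome-wide significant on the latent scale.

## Locus definition

Genome-wide significant variants (p < 5×10⁻⁸) are greedily clumped in
ascending p (ties broken by position, then id): a variant is independent
significant iff its r² with every previously accepted variant is < 0.6. A
second pass at r² < 0.1 selects lead SNPs. Reference variants at r² ≥ 0.6
with an independent significant SNP are candidate SNPs; the candidate hull
forms the locus interval (1-based inclusive), hulls with an end-to-start
gap ≤ 250 kb merge (the worked boundary cases are 200 kb → merge,
300 kb → separate), and the index SNP is the minimum-p member. Conditional
association (the SNP-as-covariate scan in `run_gwas`) supports checking
whether nearby independent hits survive conditioning on a locus index SNP.
Significant variants absent from the reference panel are kept as
independent with a warning rather than dropped.

## The synthetic cohort

The generator emulates exactly the structure the analysis assumes, with a
truth set for parameter recovery:

* **Genotypes** — hard-call dosages with per-variant MAF uniform on
  (0.05, 0.5); independent sites by default, or AR(1) haplotype-copula LD
  blocks (`ld_block_size`, or a cycling `ld_block_pattern` of heterogeneous
  sizes, with decay `ld_decay`) when local LD matters. Alleles are written
  REF=A/ALT=G so no variant is lost to strand-ambiguity filtering.
* **Factors** — F = Σβⱼg_std,ⱼ + e for EduYears and Resilience separately,
  effects drawn independently on random causal sets and scaled so Σβ² equals
  the configured h² exactly; the environmental term is orthogonalized
  against the genetic value with exact complementary variance, so realized
  heritabilities land within ~0.02 of target at n ≥ 5,000. Optional "major"
  resilience regions (default 0.04 standardized variance spread over 10
  block-aligned consecutive SNPs each) are planted at evenly spaced
  positions for locus-recovery tests.
* **Phenotypes** — education years map monotonically from the F_Edu
  quantile (plus noise, SD 0.5 on the factor scale) onto 14–19 years with
  the top 30% flagged as college (years recorded missing, mirroring the
  biobank questionnaire); RT = 550 + 3·(age − mean age) − 25·F_Edu −
  40·F_Res + small sex/array/centre/PC nuisance effects + N(0, 60²) ms, so
  higher factor scores mean faster responses and age slows responses by
  3 ms/yr within the 40–69 range. The joint EY–RT distribution beyond the
  binarized forms is not specified by the source analysis; this generative
  mapping is a modelling choice and is flagged as such.
* **Seeds** — one master seed spawns named per-stage child streams;
  identical configs produce byte-identical fixture files (VCF v4.2 +
  tab-delimited covariate and truth tables).

Reference end-to-end conditions: n = 20,000 individuals, M = 2,000 SNPs,
h²_edu = 0.3, h²_res = 0.2, 500 causal variants per factor, heterogeneous
AR(1) LD blocks (sizes cycling 1/5/20/40, decay 0.95, 5 kb spacing) and 100
contiguous jackknife blocks. The LD heterogeneity matters twice over: with
fully independent sites every LD score is ≈ 1 and a free-intercept LD-score
regression has no leverage to separate slope from intercept, and even
uniform blocks leave the scores in a band (≈ 1.6–4.5) too narrow for stable
estimates; the mixed sizes spread l₂ over ≈ 1–8.5, as real genomes do. In
the same spirit the pipeline sets the per-SNP cross-trait sampling
covariance to zero (the contrasts use disjoint individuals) instead of
plugging in the noisy estimated cross-intercept, which would rescale every
latent Z-statistic. These
problem sizes keep a five-seed replicate suite plus the acceptance script
within desk-scale compute; they are small by GWAS standards, so LDSC
standard errors are correspondingly large and all truth-recovery checks are
calibrated against those standard errors rather than fixed tolerances.

**Truth definitions.** For a binary contrast, the standardized case
indicator (covariate-residualized) is regressed on the factors' genetic
values within the contrast sample, giving loadings γ. The LDSC estimand
under random causal placement is then γₖ′Bγₗ with B the exact causal-effect
covariance from the truth set (Σβ_E², Σβ_Eβ_R, Σβ_R²); truth loadings are
the Cholesky decomposition of that matrix. Note the simulated resilience
factor also (negatively) touches the EY/NonRes contrast — faster controls
have higher F_Res — so the model's *Resilience* output is the residual
construct the Cholesky defines, not the simulated factor itself; recovery
checks therefore compare against the implied-truth decomposition, and a
rank-enrichment check confirms resilience-specific causal variants rank
higher in EY+Res than in EY/NonRes.

What the synthetic runs do **not** show: robustness to relatedness,
population stratification beyond nuisance PC columns, imputation error
(info is carried but always 1), case–control ascertainment artefacts of
real biobanks, or LD patterns beyond stationary blocks. Passing tests
demonstrate internal consistency and estimator calibration under the
assumed generative model, not external validity on real cohorts.

## Numerical choices and degenerate inputs

* Logistic IRLS: tolerance 1e-10 on the Newton step, 50 iterations max;
  |β| > 30 or a singular information matrix flags the record
  (`no_converge`/`collinear`). Perfect collinearity of a tested variant
  with the conditioning SNP (r² = 1) is flagged, not fitted.
* Hardy–Weinberg: exact conditional test summing configurations no more
  probable than the observed one (log-gamma arithmetic, 1e-12 relative
  slack on the equality boundary); verified against exact-rational
  enumeration.
* QC order: missingness/MAF/info/HWE filters are evaluated on all variants
  (a variant can be counted by several filters); duplicates (same
  chrom:pos:allele-pair in either orientation, or repeated id) keep the
  first occurrence.
* Ties at the RT threshold go to "faster"; ties in clumping break by
  position then id, making locus output invariant to input row order.
* `split_discovery_replication` sizes the discovery half as
  round(fraction·N); a forced-replication list (e.g. imaging participants)
  is honoured before the seeded permutation fills the remainder.
* Cholesky fit refuses S22 ≤ 0 and S11 − S12²/S22 < 0 rather than clamping;
  downstream subtraction refuses λ_re = 0.

## Known limitations

* Single-component LDSC only: no partitioned heritability, no constrained
  intercepts, no sample-overlap correction beyond the free intercept.
* The binary-trait association is plain logistic Wald — no Firth fallback,
  saddlepoint correction or mixed models; rare-variant and unbalanced
  designs will show the usual Wald liberalism.
* Effective-N inversion assumes the Z/β/frequency triplet is internally
  consistent; mixed-provenance summary statistics can violate that.
* The locus pipeline computes r² from a dosage reference panel; haplotype
  phasing and reference/target LD mismatch are out of scope.
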