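# Methods

`waxomics` re-implements, as a tested library, an integrative quantitative
genetics workflow for adult-leaf cuticular waxes and cuticular conductance
(g_c) in a maize inbred diversity panel: multi-environment trait QC and
BLUPs, kinship-controlled mixed-model GWAS and TWAS, Fisher's-combined-test
(FCT) integration, candidate-gene declaration and confidence grouping,
sliding-window GWAS hotspot detection, and random-forest prediction of g_c
from wax traits.  Because the real panel's genotypes, expression and wax
chemistry are not bundled, the package ships a synthetic-data generator that
reproduces the statistical structure the pipeline assumes, together with a
machine-readable truth record that the tests use for parameter recovery.

## Trait model and preparation

Plot-level abundances (µg·dm⁻²) follow a Gaussian mixed model with the grand
mean (and a check-line indicator, when check plots exist) as fixed effects
and genotype, environment, genotype×environment, incomplete block nested in
environment, field-column nested in environment, GC-FID instrument, and
GC-FID column nested in instrument as independent random effects.  The
preparation pipeline runs, in order:

1. **Zero filter** — a trait is dropped when strictly more than 40% of lines
   are entirely undetected (a line counts as zero only when all of its plots
   are zero; the fraction is over lines, not plots).
2. **Zero imputation** — each remaining zero is replaced by a draw from
   Uniform(0, m), m the smallest positive value of that trait in the same
   environment, reflecting abundances below the limit of detection.
3. **Plot-level outlier screen** — Studentized deleted residuals (SDR) from a
   fixed-effects working design of the model terms, removed at the
   Bonferroni-corrected two-sided threshold α = 0.05, one pass.
4. **REML** — variance components by maximizing the REML log-likelihood over
   log-variances (L-BFGS-B with analytic gradients); BLUPs and conditional
   residuals come from the mixed-model equations solved as an augmented
   least-squares system, which stays accurate when the residual variance pins
   near zero.  Non-convergence is flagged, not raised.
5. **Heritability** — on a line-mean basis,
   h² = σ²_G / (σ²_G + σ²_GE/ē + σ²_ε/(ē·r̄)), with ē and r̄ the harmonic
   means of environment count and total plot count per line, clamped to
   [0, 1].  With one plot per line per environment, G×E and the residual are
   aliased; REML splits their sum arbitrarily, but the h² denominator keeps
   the total nearly invariant, which is why recovery is assessed on h² rather
   than on the two components separately.
6. **Box–Cox** — λ maximizes the profile log-likelihood on the grid −2…2
   (step 0.1) and is snapped to the nearest of {−2, −1, −0.5, 0, 0.5, 1, 2}
   lying inside the 95% profile-likelihood interval ("convenient lambda");
   non-positive BLUPs are shifted by min + ε first and the shift recorded.
7. **BLUP-level screen** — a second SDR pass (intercept-only design) on the
   transformed BLUPs; removed lines become missing.

Expression follows the same logic with sequencing-lane structure instead of
GC-FID terms; hidden confounders are removed by column-standardizing the
line × gene matrix and subtracting its top-k singular components (k = 20 by
default).  This truncated-SVD residualization is a deliberate stand-in for
PEER: it removes the same dense low-rank structure without the variational
machinery.  Its known failure mode is shared-cis contamination — a strong
cis effect common to many genes looks like a factor and is absorbed — which
the tests exercise explicitly.

## Association scans

Kinship is the VanRaden centered cross-product, W W′ / (2 Σ p_j (1 − p_j));
for a fully homozygous inbred panel its diagonal averages 1 + f ≈ 2.
SNPs are pre-filtered at MAF ≥ 5% and imputation DR2 ≥ 0.80.

The scan model is y = Xβ + s·b + u + e with u ~ N(0, σ²_g K).  K is
eigendecomposed once; at a fixed variance ratio δ = σ²_e/σ²_g every GLS fit
is a weighted regression in the rotated basis.  δ is profiled on a 61-point
log grid refined by bounded scalar minimization.  GWAS defaults to P3D
(δ estimated once on the null model, reused per SNP); TWAS defaults to
re-estimating δ per gene.  Tests are Wald t-tests on n − p − 1 df; constant
features report p = 1.  Variance explained is the likelihood-ratio R²,
1 − exp(−(2/n)(LL_full − LL_null)), with ML likelihoods evaluated at the
fitted variance ratio.  Null-model selection minimizes
BIC = −2·LL + q·ln n over candidate covariate sets (q counts fixed effects
plus the two variance components); ties go to the smaller model.

A numerical note: the profile likelihood is flat at the δ optimum, so the
located δ (and hence each p-value) is reproducible across algebraically
equivalent input orderings only to ~√machine-ε (observed ~4×10⁻⁸ on p);
exchangeability is therefore asserted at 10⁻⁶.

## Integration and candidates

Per trait, the top 10% of SNPs by GWAS p are assigned to the nearest gene
(distance to the gene interval, 0 inside; ties to the smaller gene start).
Each gene keeps its most significant assigned SNP; its GWAS p is paired with
its TWAS p — 1 when the gene is unexpressed, which is also how GWAS-only
genes enter the test — and combined as X = −2(ln p₁ + ln p₂) against χ²₄,
equivalently exp(−X/2)(1 + X/2).

Candidates: GWAS loci are the top 0.002% of SNPs greedily clumped within
200 kb around successive p-minima; genes overlapping ±200 kb of a peak are
GWAS candidates; the top 0.25% of genes are TWAS/FCT candidates.  All
top-fraction rules use k = max(1, round-half-up(frac·N)), matching
194 of 9,715,072 SNPs and 50 of 20,013 genes.  Genes detected by all three
methods are partitioned: group 1 when one trait is hit by all three methods,
group 2 when the three methods hit traits sharing a wax class, group 3
otherwise.  The g_c–wax intersection reports, per method, genes in both
phenotype families' candidate sets, flagging genes shared by more than one
method.

## Hotspots

200-kb windows tile each chromosome at a 40-kb step; each window counts the
GWAS locus peaks it contains.  The count threshold is the ceiling of the 95%
quantile of the pooled genome-wide per-window counts, floored at 2.
Qualifying windows that partially overlap merge, and the hotspot interval is
their exact union (0-based half-open in outputs).  Intraclass scans use one
class's loci; interclass scans use all traits except the grand total and
additionally require members of ≥ 2 classes.  Coincidence between two
hotspot sets requires ≥ 50% overlap relative to the shorter interval.  For
integer counts the flagged-window fraction is bounded by (1 − q) plus the
probability mass at the threshold count; the null-calibration test asserts
exactly this bound.

## Random-forest prediction

g_c is predicted from the 60-trait BLUP matrix with a CART random forest
(ntree = 1000, mtry = 10 by default), a standard stand-in for
conditional-inference forests; the backend is isolated in one module.
Predictive ability is the Pearson correlation between pooled out-of-fold
predictions and observations, averaged over 50 repeats of 5-fold CV, all
seeded.  Importance is out-of-bag permutation importance over explicit
bootstrap samples (mean increase in a tree's OOB squared error when one
feature is permuted among its OOB lines); a constant feature's importance is
exactly 0 by construction.

## Synthetic-data generator

The generator emulates the panel the pipeline was designed for, not any real
genome:

* **Genotypes** — ~300 fully homozygous lines ({0,2} dosages; a `het_rate`
  option allows heterozygotes).  LD comes from an AR(1) Gaussian copula over
  ordered positions with correlation exp(−d/200 kb), the panel's reported LD
  range; population structure from the Balding–Nichols model.  SNPs whose
  realized MAF drifts outside the configured range are re-thresholded on the
  same latent field, so the stored MAF always matches the emitted dosages.
* **Gene models** — non-overlapping uniform intervals, GFF3 conventions.
* **Expression** — per gene, a cis SNP inside a 50-kb window contributes a
  configurable variance share, dense latent factors (default 5; small by
  design, where 20 PEER factors were used on the real data) contribute
  another, and the remainder is noise; environments share the genetic and
  factor parts.  Genes with no cis SNP are flagged in the truth record.
* **Wax traits** — 53 compounds in the printed class sizes (7 PA, 11 FA,
  9 HC, 4 AD, 14 WE, 8 AC) plus 6 class sums and total wax.  Each class has
  6 shared causal loci acting on contiguous bands of the class's chain-length
  series with a consistent sign (co-regulated elongation pathway: adjacent
  homologs share more loci than distant ones), each compound adds 2 private
  loci with free signs, and 2 weak panel-wide "flux" loci couple the classes.
  Participation rates were calibrated once so the mean within-class |r| of
  genetic values is ≈ 0.34 and the between-class mean is small, the values
  reported for the real panel.  Plot values add environment, G×E, block,
  column, instrument and residual draws at configurable variances
  (defaults: 2 environments, 8 blocks/environment, 1 plot/line/environment,
  2 instruments × 2 columns), then left-censor below a per-trait detection
  threshold chosen so the requested fraction of lines is entirely
  undetected.  Class sums are computed from the censored compounds, so
  sum-consistency is exact.
* **g_c** — a weighted sum of trait genetic values (default: five adjacent
  high-molecular-weight WEs negative, FA 22:0 positive, echoing the
  compounds most predictive of g_c) plus Gaussian noise.

What the generator does *not* emulate: recombination maps or coalescent
genealogies, missing or imputed genotypes, sequencing counts, GC-FID
drift beyond additive instrument effects, or skewed abundance
distributions beyond what censoring induces.  Passing recovery tests
therefore demonstrates the estimators' correctness under the assumed model,
not robustness to real-data pathologies.

## Benchmark problem sizes

The acceptance studies run the full pipeline at desk scale, chosen once:
panels of 150–300 lines (the study's panel size where it matters), 400–4000
markers over 2 × 100-Mb chromosomes (~50–250-kb spacing, comparable to the
200-kb LD range so the causal marker is itself genotyped and its neighbours
are informative but not duplicates), 300–400 genes, 18–54 REML trait fits,
and forests of 150–600 trees.  At these marker counts the top-0.002% rule
selects a single SNP, so "the planted QTL reaches the top set" means the
causal marker must be the genome-wide minimum-p SNP.

## Known limitations

* The CART forest is piecewise-constant; even with a noiseless target its
  pooled out-of-fold Pearson r plateaus near 0.93 under the calibrated
  trait-correlation structure, short of a perfect-score intuition.  The
  null and importance behaviors are unaffected.
* REML uses dense n × n covariance algebra: fine for hundreds of plots, not
  for thousands of lines with replicates.
* G×E and residual variances are unidentifiable with one plot per line per
  environment (see above); h² remains well-estimated.
* The FCT treats GWAS and TWAS p-values as independent, as in the original
  procedure; correlated evidence makes combined p-values anti-conservative.
* Confidence grouping uses "any shared class" for group 2 when a gene's
  methods hit several classes, and the ±200-kb gene search uses interval
  overlap, not midpoint containment.
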