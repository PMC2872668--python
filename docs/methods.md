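# Methods

This note documents the statistical procedures, the synthetic-data model,
the numerical choices and the known limits of the package. It describes
what the code computes; every number quoted here is produced by the test
suite or `scripts/acceptance.py` at run time.

## 1. The analysis model

### eQTL scan

Expression traits are tested against SNP genotypes by one-way
fixed-effects ANOVA on genotype groups. Groups start as the three additive
classes {0, 1, 2}; when the minor-allele homozygote class (the rarer
homozygote by allele frequency — the coding may be ALT- rather than
minor-allele-based) holds fewer than `min_homozygotes = 30` subjects it is
merged with the heterozygotes, giving a 1-df test. If the heterozygote
class of a 3-group split is itself below the cutoff, the two smallest
groups merge — the merging rule is only specified for minor homozygotes,
so this extension is our choice and is configurable.

P-values come from F(k−1, n−k); R² = SS_between / SS_total. A zero-variance
trait returns (F=0, P=1, R²=0). Every association below the storage
threshold (10⁻⁵) is persisted with a Kruskal–Wallis confirmation P
(tie-corrected H on k−1 df; an all-tied vector is reported as P=1) and a
supplementary additive-coding slope. The ANOVA is direction-free but the
mediation logic needs a sign, hence the slope; it is computed on
pairwise-complete samples and is not used for any significance decision.

Study-wise significance requires ANOVA P < 5.78×10⁻¹² **and** KW
P < 10⁻¹⁰. When the scan is run at reduced scale the KW cutoff should be
scaled by the same factor as the ANOVA threshold (the two cutoffs differ
by ×173 at the design scale); `genome_scan` exposes `kw_threshold` for
this.

Chromosome-X SNPs are tested separately in women and men and the per-sex
ANOVA P-values combined by Fisher's method on 4 df. The KW confirmation on
X is likewise computed per sex and Fisher-combined — a well-defined
symmetric rule chosen because no canonical treatment exists for combining
rank-test confirmations across strata. If only one sex is testable, its P
is used and the record flagged uncombined. Males are handled through the
same grouping rule; hemizygote dosages coded 0/2 behave identically to
0/1 coding under a grouped test.

Missing genotypes are excluded pairwise per test, never imputed (except in
the additive slope, where the column mean is substituted only to keep the
sample aligned).

### cis / trans and summaries

cis means: same chromosome and SNP position within
[gene_start − 10⁶, gene_end + 10⁶], 1-based inclusive; BED I/O converts
from 0-based half-open. Tier summaries count associations, distinct genes
(eQTLs) and distinct SNPs (eSNPs) below each P tier; a gene enters a tier
if *any* of its associations passes, and counts cis if it has ≥1 cis eSNP
there and trans if ≥1 trans eSNP — the classes overlap by design.

### Risk factors, enrichment, interaction

Expression is the dependent variable in OLS with the adjustment schemes:
age→(sex); BMI, smoking, √CRP→(age, sex); HDL/LDL/TG/SBP/DBP→(age, sex,
BMI); sex→(). Sex is coded female=1 so positive coefficients mean higher
in women. CRP enters as √CRP (variance stabilization of a right-skewed
marker). Incomplete samples are dropped per risk factor; a collinear
design skips the factor with a recorded reason.

The cis-enrichment odds ratio uses the 2×2 table (risk-factor-associated
and cis; associated not cis; other cis; other traits). The Woolf
(log-normal) CI with z = 1.96 reproduces the published-style interval
arithmetic exactly; there is no continuity correction by default (a
Haldane +0.5 option exists for zero cells).

Interaction models are expression ~ SNP + RF + SNP×RF + scheme covariates
(the covariates are included — the marginal models adjust, so the
interaction model does too; this is an interpretive choice). SNPs under
the merging rule enter with 2-level coding. Benjamini–Hochberg q-values
are computed across the tested pairs.

The functional-category test is a one-sided binomial tail
P(X ≥ observed) at p₀ = expected/n_genes, Bonferroni-multiplied by the
number of categories; category counts are supplied by the user (no
ontology database is bundled).

### Stability selection

Each replicate halves the cohort at random (screening half gets the odd
sample). Screening: genes with covariate-adjusted univariate partial-F
P < 3.9×10⁻⁶ become candidates (capped at the 100 smallest P to guard the
stepwise in pathological simulations; configurable); forward stepwise —
no removal step — adds the candidate with the smallest partial-F P while
it is < 0.01, with the risk factor as dependent variable. Validation:
joint OLS of the risk factor on covariates plus the selected genes in the
held-out half. A gene counts in a replicate iff selected at screening
**and** its validation per-gene P < 0.01 — the validation-sample P, not
the screening P, because validation is what the split exists for. The
global P is the nested-model F-test of the full versus covariates-only
model; an empty selection records global P = 1 by convention. Defaults:
250 replicates, report frequency > 0.25, output sorted by frequency
descending; per-replicate seeds are master_seed + replicate index, so
results are bit-reproducible.

### Mediation and attenuation

The triangle test requires three covariate-adjusted associations with
coherent signs. Default per-leg thresholds: SNP→phenotype 0.05,
SNP→expression 3.9×10⁻⁶, expression→phenotype 0.05 — there is no single
canonical rule for this screen, so the thresholds are explicit, configurable
and reported with every verdict, which is re-derivable from the stored
legs. A locus with no tag SNP at r² ≥ 0.8 (or no candidate gene) is
"untestable". The verdict is invariant to flipping the coded allele: all
three signs flip coherently.

The attenuation analysis fits outcome ~ RF + age + sex with and without
mediator expressions, by ordinary linear regression on the count (t-values
are the reporting convention; a Poisson GLM is available as an option).
Verdict "attenuated" iff the risk factor is significant (P < 0.05) alone
and non-significant with mediators. The best-cis-eSNP outcome test is an
additive age/sex-adjusted regression per SNP with Bonferroni correction
over the tested list.

### Design calculators

Threshold: α/(n_a·n_b), reported to 3 significant digits. Minimum
detectable R²: invert the central F at (df1, n−df1−1) and convert through
R² = df1·F*/(df1·F* + n−df1−1). Power: noncentral-F tail with
λ = n·R²/(1−R²), df1 = 1 by default (the additive / merged-group
contrast). This parametrization is allele-frequency-free; tools that
parametrize by allele frequency and per-allele effect give slightly
different values, so the package checks its power claim against its own
Monte-Carlo simulation of the test (agreement within ±0.02) and against
the ≥80 % design bound, and reports the exact analytic value (0.824 at
n=1,490, α=5.78×10⁻¹², R²=0.04).

## 2. The synthetic-data model

The simulator emulates the statistical structure the analysis assumes —
not array physics.

* **Genotypes.** Per-SNP MAF ~ U(maf_range); a latent standard normal per
  sample is thresholded at the HWE quantiles ((1−q)², 2q(1−q), q²). LD
  within blocks of `ld_block_size` consecutive same-chromosome SNPs comes
  from an equicorrelated Gaussian copula (shared factor √ρ·u). This
  reproduces tunable genotype r² (verified against a Monte-Carlo oracle of
  the thresholded copula) without modelling recombination maps. A
  configurable missing rate (default 0) makes call-rate QC testable.
* **Layout.** SNPs and genes are placed deterministically, evenly spaced
  along the declared chromosomes; genes get 20 kb intervals and a 50 bp
  probe at the 3′ end. Helpers pick cis (within 1 Mb) or trans
  (other-chromosome) SNPs for planting; placement violations raise.
* **Risk factors.** Sex ~ Bernoulli(760/1490 male); per-sex Gaussians with
  the cohort means/SDs (e.g. male BMI 27.6 (3.9), female HDL 69.2 (17.8),
  male/female smoking 16.8 %/15.5 %); CRP is generated on the √ scale
  (draws truncated at 0, ≈3 % of mass) so √CRP is Gaussian to the stratum
  parameters. Triglycerides and other skewed variables are simulated
  Gaussian — a simplification; only CRP's transform is modelled because
  only CRP's transform is part of the analysis.
* **Expression.** baseline (default 8, an arcsinh-scale intensity) + Σ
  planted terms + N(0, noise_sd²). Genetic effects may be declared by
  per-allele beta or by expected R²; in the latter case
  β² = R²·Var(rest)/((1−R²)·Var(g)) with Var(rest) the realized variance
  of everything already in the gene, so the sample variance fraction
  matches the request in expectation (within ±0.04 at n≈1,500 in tests).
  Effects planted later see earlier ones in their "rest", so stacking
  several R²-declared effects on one gene dilutes the earlier ones
  slightly — plant on separate genes when exact fractions matter.
  Probe artifacts multiply observed expression by (1−attenuation)^g,
  emulating allele-dependent probe binding.
* **Detection P-values.** Detected genes: P ~ U(0, 0.01) everywhere;
  undetected genes: P ~ U(0.05, 1) in ≈99 % of samples. This is a stand-in
  for a negative-control-based detection call, not a model of any specific
  scanner software.
* **Plaques.** Counts ~ Poisson(exp(η)), η linear in smoking and/or
  standardized expressions. The canonical mediated scenario
  (`plaque_scenario`) plants smoking→GENE1 (β=2.0 on the expression
  scale) and GENE1→plaques (0.12 per SD, intercept 0.7 → ≈2 plaques per
  subject), keeping the log link mild enough that the linear attenuation
  model is well specified while the smoking effect is detected with
  essentially full power at n=1,490.
* **Determinism.** One master seed; each sub-generator (genotypes, risk
  factors, expression, detection, plaques, missingness) derives its own
  `SeedSequence` stream, so outputs are bit-identical given the config.

**What passing tests do and do not show.** The simulator has no batch or
chip effects, no population stratification, no relatedness, no
heavy-tailed expression noise and no bead-level measurement model; planted
effects are exactly additive unless an interaction is planted. Recovery
and calibration results therefore validate the *statistical machinery*
under the model's assumptions, not robustness to real-data artifacts.

## 3. Numerical choices

* HWE QC uses the 1-df chi-square against expected counts from the
  estimated allele frequency, without continuity correction — the
  conventional, deterministic array-QC choice (not the exact test). All
  three QC rules are strict inequalities (MAF > 0.01, call rate > 0.98,
  HWE P > 10⁻⁴); a SNP with zero calls is dropped with reason "no data".
* Quantile normalization maps each sample's ranks onto the across-sample
  mean of sorted values; runs of tied values receive the mean of their
  tied reference positions, which makes the operation idempotent up to tie
  handling.
* The detection filter keeps a gene iff P < 0.05 in *strictly more than*
  5 % of samples. Detection is filtered at gene level after probe
  averaging (per-gene detection P = min across probes), since the
  probe-level ordering of those two steps is not externally specified.
* Symbol filtering drops prefixes KIAA, FLJ, HS, MGC, LOC and the pattern
  C&lt;number&gt;orf, case-sensitively.
* Vectorized OLS treats a dependent column with variance ≤ 10⁻²⁴ of its
  mean square as degenerate (β=0, P=1) to avoid round-off t statistics.
* Stepwise uses the partial-correlation identity t² = df·r²/(1−r²) on
  residualized vectors; ties in the argmin resolve to the lowest candidate
  index (stable order).
* The Woolf CI hard-codes z = 1.96 (the published-interval convention)
  rather than Φ⁻¹(0.975) = 1.95996; the difference is ~10⁻⁴ relative.

## 4. Scales used in tests and the acceptance script

Full-cohort defaults (1,490 samples, 250 replicates, 5.78×10⁻¹²) are the
library defaults. The test suite and acceptance script run reduced
problems chosen to preserve the power relationships being exercised:

* null-scan calibration: 300 samples × 2,000 SNPs × 100 genes, LD off
  (independent tests make the binomial error bars exact);
* planted recovery: 1,490 samples × 500 SNPs × 50 genes with cis effects
  at R² = 0.06/0.10/0.20 and a trans effect at 0.10, scanned at the full
  5.78×10⁻¹² / 10⁻¹⁰ thresholds;
* stability selection: 600 samples × 150 genes × 25 replicates, three
  planted correlates (R²≈0.1 each with the risk factor); specificity from
  100 null runs;
* mediation: 600-sample chains over 60 seeds per scenario; attenuation:
  the canonical plaque scenario over 100 seeds.

## 5. Known limitations

* No permutation thresholds, no mixed-model relatedness correction, no
  penalized-regression alternative to the stepwise — all outside the
  intended recipe.
* The grouped ANOVA discards dosage uncertainty; imputed dosages would
  need a regression-based scan.
* `proxy_search` needs reference genotypes for off-panel lead SNPs; there
  is no remote LD lookup.
* The mediation triangle is a compatibility screen; it estimates no
  mediated effect size and cannot distinguish mediation from pleiotropy.
* Power calculations assume Gaussian residuals and a 1-df contrast.
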