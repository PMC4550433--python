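# Methods

## Analysis model

`pathgsea` tests whether the genes of a predefined set are over-represented
near the top of a genome-wide ranking of per-gene association evidence.

**Phenotypes.** Plasma triglycerides are analyzed on the log10 scale.
Base 10 was chosen because typical plasma TG values (tens to hundreds of
mg/dL) then land on the familiar 1.5–2.9 scale used in lipid reporting;
every association statistic is invariant to the log base up to a constant
factor, so the choice affects reporting only. Outlier removal is a single,
non-iterated pass: individuals whose log10(TG) lies more than k sample SDs
(default k = 3, mean and SD from all values) from the mean are flagged
excluded before anything else is fit. BMI adjustment is an OLS regression
of log10(TG) on BMI over the surviving individuals; the residuals are
divided by their sample SD (ddof = 1), so the adjusted trait has mean 0 and
SD 1 by construction. Covariates enter only through this pre-residualized
trait — there is no covariate-in-model regression. Case/control status
uses the clinical thresholds: TG > 200 mg/dL is a case, TG < 150 mg/dL a
control, and the closed borderline band 150 ≤ TG ≤ 200 is "unknown" and is
excluded from every binary computation, including the permutation universe.
Boundary values (exactly 150 or 200) are assigned to the unknown band.
Status is assigned from raw TG for all individuals; the quantitative
outlier flag does not feed the binary arm.

**Single-marker tests.** Quantitative traits use simple linear regression
of the trait on allele dosage; the statistic is the squared Wald t,
identical to the 1-df F, with P from F(1, n−2). Binary status uses the
allelic 2×2 chi-square (each individual contributes two alleles, 1 df, no
continuity correction); a Cochran–Armitage trend test is available behind a
flag but is not the default, since the allelic test is the standard default
of array-GWAS tooling. Missing genotypes are dropped pairwise per SNP.
P-values are never reported as exactly 0: underflow clamps to the smallest
positive double with an `exact_fit` flag. Both statistics are invariant
under relabeling of the counted allele, which the tests verify.

**Quality control.** A SNP is tested when its minor-allele frequency
exceeds 0.01 and its 1-df Hardy–Weinberg goodness-of-fit P-value exceeds
0.001. The HWE test uses all analysis individuals (the model assumes an
unrelated cohort); an exact-test variant was considered and not implemented
because the chi-square is the convention the thresholds were designed for.
The same thresholds apply in the GWAS and the enrichment arm for
consistency. QC is phenotype-free, so in permutation analyses it is
computed once rather than per replicate — the results are identical and the
cost is B-fold smaller; a consequence is that the number of ranked genes N
is constant across permutations.

**SNP → gene mapping.** A SNP maps to a gene when its position falls in
the gene interval extended by 20 kb on both sides, closed at both
boundaries, with the lower bound clamped at 1. Internal coordinates are
1-based inclusive (the `.map` convention); BED input is converted at the
boundary. Strand is ignored — "upstream/downstream" is symmetric in genomic
coordinates. A SNP inside two overlapping flanked windows counts for both
genes; no unique-assignment or deduplication step is applied. The per-gene
statistic is the maximum over the gene's surviving SNPs; ties for the
reported best SNP break by smaller P then lexicographic SNP id, which
leaves the gene statistic itself unaffected.

**Enrichment score.** Genes are ranked by statistic, descending, with ties
broken deterministically by ascending gene id so that permutation
replicates are reproducible across platforms. For a set with N_H of the N
ranked genes, the running sum increments by |r|^p / N_R at hits and
decrements by 1/(N − N_H) at misses; ES is the maximum after every
position. The weight exponent p defaults to 1; p = 0 gives the classical
unweighted KS statistic and is verified against an independent
implementation. Because the running sum returns to exactly 0 at rank N,
ES lies in [0, 1]: a set concentrated at the bottom scores 0, not a
negative value — testing is one-sided for enrichment at the top only, and
no depletion variant is offered. Sets with 0 covered genes, or covering
every ranked gene (the miss denominator vanishes), are skipped with a
logged reason. If a set's weighted hit mass N_R is zero (all member
statistics exactly 0 with p > 0), hit increments fall back to the
unweighted 1/N_H. Only sets with a covered size in [set_min, set_max]
(default 5–200) are tested — below that the running sum is dominated by
single genes, above it sets are uninformative.

**Permutation nulls.** In phenotype-permutation mode, each of B replicates
shuffles the phenotype labels across the analysis individuals (cases and
controls only, for the binary arm), recomputes every SNP statistic, the
gene statistics, the ranking and each set's ES. Dosage-matrix moments that
do not involve the phenotype are precomputed once, so a replicate costs a
few matrix-vector products. In SNP-label mode the per-SNP statistic vector
(−log10 P from a fixed GWAS) is randomly permuted across SNP labels with
the SNP–gene geometry fixed; the multiset of statistics is preserved
exactly in every replicate. −log10 P is used as the gene statistic in this
mode because it is the natural scale of an externally supplied P-value
file; for a fixed 1-df test family it ranks genes identically to the raw
statistic. The significance-proportion correction used by some
SNP-permutation enrichment tools is deliberately not implemented; the plain
running-sum ES is used in both modes so the two arms differ only in their
null.

**NES, empirical P, FDR.** NES standardizes each set's observed ES by the
mean and sample SD (ddof = 1; the population-SD alternative would shift
all NES by the same factor ~ sqrt(B/(B−1)) and is not exposed) of that
set's own null column; a null column whose SD is at rounding-error scale
(≤ 1e-12 relative) is treated as constant and flagged, with NES 0.
The empirical P is the one-sided (1 + #{ES_null ≥ ES_obs})/(B + 1), so it
is never 0 and its resolution is 1/(B+1); result files print values at the
resolution limit as "<1/(B+1)". The FDR of a set with observed NES* is the
fraction of all pooled standardized null NES values ≥ NES* divided by the
fraction of observed sets with NES ≥ NES* (the denominator is at least
1/n_sets by construction); the ratio is clipped to [0, 1] for reporting and
the raw value retained. Comparisons are on signed NES as the formula
states, not on a positive tail only.

**LD candidate SNPs.** r² is the squared Pearson correlation of allele
dosages over complete pairs (composite, phase-free LD) — symmetric,
invariant to allele relabeling, and returned as a flagged 0 for monomorphic
input. For each of the top-k index SNPs, same-chromosome SNPs within the
search window (default 200 kb) with r² above the threshold (default 0.6)
are reported. Candidate reporting is informational; it does not feed the
enrichment statistics.

## Synthetic studies

The generator emulates the study design the analysis assumes: ~1000
unrelated individuals on an array-like SNP panel at desk scale. Per SNP an
alternate-allele frequency is drawn uniformly from `maf_range` (default
0.05–0.5) and dosages are Binomial(2, f) — Hardy–Weinberg by construction —
with missing-completely-at-random dropout (default 0.2%, an array-like call
rate). Genes are non-overlapping intervals (5–60 kb) separated by 45–120 kb
gaps on 10 chromosomes; 80% of SNPs fall inside genes and the rest are
placed clear of the default 20 kb flanks so that `intergenic_fraction`
means what it says. Gene sets draw members without replacement; sizes
default to 5–50 of 400 genes so every set passes the 5–200 covered-size
filter.

The phenotype is additive on the log scale: log10(TG) = 2.08 + Σ β·dosage +
0.005·(BMI − 30) + N(0, 0.25), with BMI ~ N(30, 8) and TG = 10^log10(TG)
mg/dL. The location/scale defaults put the cohort's log TG mean near 2.08
with SD 0.25, which yields roughly 19% cases (TG > 200) and 65% controls
(TG < 150) — the case/control balance typical of a mixed obese and
normal-weight sample. Each causal gene carries exactly one causal SNP and
all causal genes belong to the designated causal set. When `beta` is left
unset, each causal effect is calibrated so the expected regression
noncentrality matches a target single-marker P (default 1e-4) at the
study's sample size and that SNP's drawn frequency:
β = σ·sqrt(χ²_target / (2f(1−f)n)). Optional LD is produced by copying
each causal SNP into k proxy SNPs 500 bp apart whose entries are
independently redrawn with probability ε (default 0.02), giving
r² ≈ (1−ε)² ≈ 0.96 — enough to exercise the LD stage without a coalescent
simulator.

What the generator does **not** emulate: population structure and
relatedness, realistic genome-wide LD (only local proxies of causal SNPs),
sex-specific effects, genotyping-error models, non-Gaussian BMI structure
(the real design mixed extremely obese and normal-weight strata), or an
empirical effect-size distribution. Passing tests therefore demonstrate the
correctness and calibration of the statistical machinery under its stated
assumptions, not robustness to confounding in real cohorts.

Reproducibility: all randomness flows from `numpy.random.SeedSequence`
children of a single seed, so an identical configuration reproduces a
byte-identical study; the enrichment engine additionally sorts individuals
by id internally, making every output invariant to input row order.

## Numerical and design notes

* PLINK text genotypes are re-polarized at load time so the counted allele
  is the observed minor allele (frequency ties break to the
  lexicographically smaller allele). All downstream statistics are
  allele-label invariant, so this is a normalization, not a modeling
  choice.
* Degenerate inputs are explicit: constant dosage → (stat 0, P 1, flagged);
  exact fits clamp P to the smallest positive double; monomorphic SNPs have
  HWE P = 1 by convention; a 2×2 table with a zero margin scores 0/1
  flagged.
* The genomic-inflation factor is λ = median(χ²₁ quantiles of P)/0.45494;
  QQ and Manhattan plots are side outputs only.
* Problem sizes used by the test suite and the acceptance script — 20 null
  studies and 50 causal studies of 1000 individuals × 2000 SNPs × 400 genes
  × 50 sets at B = 200 permutations — were chosen as the package's
  desk-scale working point: large enough for calibration and power
  statements with binomial error of a few percent, small enough that a full
  run completes in minutes on one CPU. B = 1000 (the conventional
  production setting) is the library default.
* Pipeline logs carry no timestamps and the manifest records seeds,
  thresholds and versions, so rerunning a configuration reproduces the
  output directory byte for byte.
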