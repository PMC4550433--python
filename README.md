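# pathgsea

Pathway-based genome-wide association analysis for plasma triglycerides
(and similar quantitative lipid traits), as a tested, reusable Python
package.

Single-marker GWAS hits explain only a small part of the heritability of
plasma triglyceride (TG) concentrations; variants of modest effect that
cluster in a common biological pathway are invisible to per-SNP multiple
testing but can be detected jointly. `pathgsea` implements the
gene-set-enrichment approach to this problem for array-style genotype data:

1. **Phenotype preparation** — TG (mg/dL) is analyzed as log10(TG), as
   BMI-adjusted log10(TG) (standardized OLS residuals, mean 0 / SD 1), and
   as a ternary case/control/unknown status (case: TG > 200 mg/dL;
   control: TG < 150 mg/dL; the borderline band is ignored). A single-pass
   3-SD outlier screen on log10(TG) precedes the quantitative analyses.
2. **Single-marker association** — per SNP, simple linear regression
   (1-df F = squared Wald t) for quantitative traits or the allelic 1-df
   chi-square for case/control status, after MAF > 0.01 and
   HWE P > 0.001 quality control.
3. **SNP → gene aggregation** — a SNP belongs to a gene if it lies within
   the gene interval ± 20 kb; each gene is represented by the maximum
   statistic over its SNPs, r(j).
4. **Gene-set enrichment** — genes are ranked r(1) ≥ … ≥ r(N) and each set
   S with N_H covered genes is scored with the weighted
   Kolmogorov–Smirnov-like running sum

   ES(S) = max over 1 ≤ j ≤ N of
   [ Σ_{hits ≤ j} |r(j*)|^p / N_R − #{misses ≤ j} / (N − N_H) ],
   N_R = Σ_{hits} |r(j*)|^p, p = 1 by default.

5. **Permutation inference** — either phenotype-label permutation (the
   per-SNP statistics, gene scores, ranking and ES are recomputed for every
   shuffle of the phenotype) or SNP-label permutation on fixed GWAS
   P-values (gene statistic = max −log10 P). Each set's ES is standardized
   by its own null (NES = (ES − mean)/SD), the empirical P is
   (1 + #{ES_null ≥ ES_obs})/(B + 1), and FDR is the ratio of the pooled
   null NES tail to the observed NES tail. Only sets with 5–200 covered
   genes are tested.
6. **LD candidate SNPs** — for top index SNPs, proxies with dosage-r² > 0.6
   within 200 kb are reported (informational).

Because no genotype cohort ships with the package, a first-class
synthetic-study generator (`pathgsea.simulate`) produces cohorts with the
assumed statistical structure — HWE genotypes, a log-normal TG phenotype
with additive SNP effects and a BMI covariate, non-overlapping gene
intervals, gene sets with an optional planted (enriched) causal set, and
optional LD proxies — byte-reproducibly from a seed.

## Worked example

Simulate a cohort of 1000 individuals / 2000 SNPs / 400 genes with 10
causal genes planted in one of 50 gene sets, and test enrichment with 200
phenotype permutations:

```python
from pathgsea.simulate import SimulationConfig, simulate_study
from pathgsea.gsea import GseaConfig, run_gengen

cfg = SimulationConfig(n_causal_genes=10, causal_set_index=0, seed=3)
study = simulate_study(cfg)
res = run_gengen(study, GseaConfig(n_perm=200, seed=3), phenotype="log_tg")
print("causal set:", study.truth["causal_set"])
print(res.head(3)[["set_id", "size_covered", "es", "nes",
                   "empirical_p", "fdr"]].to_string(index=False))
```

prints

```
causal set: S000
set_id  size_covered       es      nes  empirical_p    fdr
  S000            14 0.918429 5.082454     0.004975 0.0000
  S035            36 0.559778 2.542315     0.004975 0.0700
  S001            36 0.564729 2.733580     0.009950 0.0625
```

The planted set S000 attains a near-maximal enrichment score (ES 0.92:
almost all of its covered genes sit at the very top of the ranking), an
empirical P at the permutation resolution 1/(200+1) ≈ 0.005, and an FDR of
0 — no permuted-data NES anywhere reached its observed NES of 5.08. The
runner-up sets are ordinary null sets that happen to share top-ranked genes.

The same analysis is available from the shell:

```bash
pathgsea run-all --out demo_run --seed 7 --perm 200
```

which writes the prepared phenotype table, three GWAS TSVs
(`gwas_log_tg.tsv`, `gwas_log_tg_adj.tsv`, `gwas_binary.tsv` with PLINK-like
columns SNP/CHR/BP/MAF/TEST/STAT/P/N), enrichment tables for both
permutation modes, QQ/Manhattan plots, and a `manifest.json` with every
seed, threshold and the genomic-inflation factors (λ ≈ 1.02 on a null
simulation). Individual stages are exposed as `pathgsea simulate | prep |
gwas | pathway | report`.

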