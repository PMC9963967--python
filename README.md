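# isletmir

Genetic analysis of small-RNA expression in primary tissue, built around
the question of how microRNA expression in human pancreatic islets is
genetically regulated and related to type 2 diabetes. The package
implements, as a tested and reusable pipeline:

- **SNP-based heritability and cis/trans decomposition.** For a
  transformed expression vector *y*, the variance-component model
  *y* = *Wα* + *u*<sub>cis</sub> + *u*<sub>trans</sub> + *ε* with
  *u*<sub>c</sub> ~ N(0, σ²<sub>cis</sub>K<sub>cis</sub>),
  *u*<sub>t</sub> ~ N(0, σ²<sub>trans</sub>K<sub>trans</sub>),
  *ε* ~ N(0, σ²<sub>e</sub>I) is fit by constrained REML, where the
  kinship matrices K = ZZ′/M are built from standardized dosages of
  variants inside/outside a ±250 kb cis window. Derived quantities:
  h<sub>g</sub>² = (σ²<sub>cis</sub>+σ²<sub>trans</sub>)/σ²<sub>tot</sub>,
  h<sub>cis</sub>, h<sub>trans</sub>; transcripts with h<sub>g</sub>² ≥ 0.9
  are called heritable, and feature classes are compared with a Pearson
  χ² (heritable fractions) and a Mann–Whitney U (h<sub>trans</sub>).
- **eQTL mapping** by OLS of transformed expression on dosage +
  covariates, pooled Benjamini–Hochberg FDR, genotype × miRNA
  interaction models, Wald-ratio Mendelian randomization and Sobel
  mediation.
- **Bayesian colocalization** of two association signals from summary
  statistics via Wakefield approximate Bayes factors,
  lABF = ½[log(V/(V+W)) + z²W/(V+W)], combined into posterior
  probabilities PP0–PP4 of the five causal configurations, plus 99%
  credible sets and overlap of credible SNPs with mature-miRNA and
  predicted target-site intervals (filtered on islet expression).
- **Differential expression** with per-feature negative-binomial Wald
  GLMs (median-of-ratios size factors, method-of-moments dispersion),
  fixed-effect inverse-variance meta-analysis across strata (library
  preparations, external cohorts, ancestry groups), and the
  FDR ≤ 5% & |log₂FC| ≥ 1 calling rule.
- **Cell-type deconvolution** of bulk miRNA profiles into alpha/beta
  cell fractions by non-negative least squares on sorted-cell
  signatures, and sensitivity re-analysis of any scan with the
  beta-cell fraction as a covariate.
- **Synthetic data generators** (`isletmir.simulate`) for genotypes,
  expression with exact realized cis/trans variance fractions, paired
  GWAS summary statistics with shared/distinct causal variants, donor
  covariates (sex, age, BMI, T2D status, polygenic score), and
  two-cell-type mixtures — each with recorded ground truth, so every
  stage can be validated against known answers.

## Worked example

Simulate a full input bundle and run the pipeline from the shell:

```bash
isletmir simulate --out bundle --seed 7 --n-samples 57 --n-variants 200 \
                  --h2-cis 0.5 --h2-trans 0.2
isletmir grm          --genotypes bundle/genotypes.vcf --out grm.tsv
isletmir heritability --genotypes bundle/genotypes.vcf --counts bundle/mirna_counts.tsv --out herit.tsv
isletmir eqtl         --genotypes bundle/genotypes.vcf --counts bundle/mirna_counts.tsv \
                      --features bundle/mirnas.bed --out eqtl.tsv
isletmir coloc        --stats1 bundle/gwas_trait1.tsv --stats2 bundle/gwas_trait2.tsv --out coloc.tsv
```

which prints, stage by stage:

```
wrote 12 files to bundle
GRM over 200 variants, 57 samples
4/12 features heritable
11 associations at FDR <= 5% (1200 tests)
PP4 = 1.0000 over 100 SNPs
```

The GRM line confirms the kinship matrix dimensions; the heritability
line counts transcripts with h<sub>g</sub>² ≥ 0.9 at this small sample
size; the eQTL line reports cis associations passing pooled BH FDR ≤ 5%;
and PP4 ≈ 1 is the posterior probability that the two simulated traits
(generated with a shared causal variant at n = 5,000) colocalize.
Python-level entry points mirror the CLI one-to-one — see
`isletmir.varcomp.fit_two_component`, `isletmir.coloc.coloc_abf`,
`isletmir.de.nb_wald_de`, `isletmir.decon.estimate_fractions`.

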