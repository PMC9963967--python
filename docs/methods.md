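# Methods

## Models and procedures

### Heritability and cis/trans decomposition

Expression of each feature is modelled on a transformed scale (default:
rank-inverse-normal per feature, Blom offsets, average-rank ties, then
exact standardization to mean 0 / variance 1; a size-factor + log2
alternative is available). Rank-inverse-normal is the default because
it is robust to the skew of negative-binomial counts and is standard
practice before variance-component and eQTL modelling.

The two-component model is

y = Wα + u_cis + u_trans + ε,
u_cis ~ N(0, σ²_cis K_cis), u_trans ~ N(0, σ²_trans K_trans), ε ~ N(0, σ²_e I),

with kinships K = ZZ′/M over standardized dosages
z = (g − 2f)/√(2f(1−f)), allele frequencies estimated in-sample.
Restricted maximum likelihood is maximized by L-BFGS on the square
roots of the variance components (which enforces non-negativity), with
analytic gradients, three fixed initializations — (0.05, 0.05, 0.90),
(0.30, 0.30, 0.40) and (0.10, 0.60, 0.30) times the sample variance —
keeping the best restricted log-likelihood; when no start converges the
fit falls back to a bounded grid over variance fractions at resolution
0.02 (total variance profiled out in closed form) followed by a local
polish. The single-component fit used for heritability classification
exploits the eigendecomposition of the genome-wide GRM so each feature
costs O(n) per likelihood evaluation; the eigendecomposition is shared
across features.

Classification and decomposition are sequential: h_g² comes from the
single-component fit on the genome-wide GRM, transcripts with
h_g² ≥ 0.9 are called heritable (threshold configurable), and only
heritable transcripts get the two-component decomposition. Feature
classes are compared with a Pearson χ² on the 2×2
heritable-by-class table (df = 1, no continuity correction) and a
two-sided Mann–Whitney U on h_trans (exact enumeration when the
smaller group has ≤ 8 values and there are no ties, otherwise the
normal approximation with tie and continuity corrections).

**Cis window.** Feature intervals are 0-based half-open; variant
positions are kept 1-based as carried in the VCF. The cis window is
[anchor_start − w, anchor_end + w), clipped at zero, with w = 250 kb by
default (20 Mb as the wide alternative). miRNAs anchor on the full
mature-transcript interval; mRNAs on the strand-aware TSS point. A
variant is cis iff it is on the same chromosome and
window_start ≤ pos < window_end; the partition is exhaustive and
disjoint, and the unscaled cross-products satisfy
K_all·M_all = K_cis·M_cis + K_trans·M_trans exactly.

### Association scans, interaction, MR, mediation

The default scan is OLS of transformed expression on dosage plus
covariates (Frisch–Waugh residualization, exact OLS degrees of
freedom), two-sided Wald p, with Benjamini–Hochberg q-values pooled
across all tests of one invocation — matching a single FDR ≤ 5%
criterion rather than per-feature correction. A mixed-model correction
is deliberately not the default: at the target sample sizes (tens of
unrelated donors) the GRM correction is second-order.
The interaction model is y ~ g + m + g·m + covariates with a Wald test
on the product term. Mendelian randomization uses the single-instrument
Wald ratio β_gy/β_gx with the first-order delta-method SE; mediation
uses the product of coefficients with the Sobel SE. Effect-size
concordance across studies is Spearman's rho after allele
harmonization (sign flip on swapped alleles; strand-ambiguous A/T and
C/G pairs dropped).

### Colocalization and credible sets

Per-SNP evidence is the Wakefield log approximate Bayes factor with
prior effect SD 0.15 for quantitative traits and 0.2 (log-odds) for
case-control — the conventional defaults — and per-SNP priors
p1 = p2 = 1e-4, p12 = 1e-5. All configuration sums are accumulated in
log space (log-sum-exp, signed for the H3 subtraction
S1·S2 − S12) so strong signals cannot overflow; PP0–PP4 sum to one to
1e-10, and PP3 is exactly zero for a single-SNP region. 99% credible
sets take per-SNP posteriors ABF_j/ΣABF under a single-causal
assumption, sort them descending with lexicographic variant-id
tie-breaks for bit-reproducibility, and keep the minimal prefix
reaching 0.99. Credible-SNP overlap with mature-miRNA and target-site
intervals uses the same point-in-half-open-interval rule as the cis
window; records are retained when both the miRNA and the target mRNA
pass a mean normalized-abundance threshold (counts-per-million ≥ 1 by
default), with a full audit table preserved.

### Differential expression and meta-analysis

Counts are normalized with median-of-ratios size factors (reference =
per-feature geometric mean over samples, restricted to features with
all-positive counts). Each feature is fit with a log-link NB GLM with
offset log(size factor); dispersion is per-feature method-of-moments
with floor 1e-4, computed on counts normalized by size factors
rescaled to geometric mean 1 so results are invariant to the overall
factor scale. No empirical-Bayes dispersion shrinkage is applied — the
transparent estimator is adequate for the calibration studies here, and
a fixed-dispersion hook is exposed. Binary phenotypes give log2FC per
contrast; continuous phenotypes (age, BMI, polygenic scores) are
standardized so log2FC is per SD. Features whose IRLS fit fails get
p = NA and are excluded from the BH denominator. Strata are combined by
fixed-effect inverse-variance weighting (the simplest defensible choice
with 2–3 strata); BH runs per phenotype across features after
meta-analysis; calls require q ≤ 0.05 and |log2FC| ≥ 1.

### Deconvolution and sensitivity

Bulk profiles are modelled as non-negative linear mixtures of
sorted-cell signature profiles on the counts-per-million scale (mixing
is linear in abundance, not log-abundance). Signature features default
to the top 50 by |log2 ratio| between the sorted profiles; per-sample
fractions come from non-negative least squares renormalized to the
simplex, making the estimate scale-invariant in the bulk profile.
Sensitivity re-analysis re-runs a scan with the beta-cell fraction as
one extra covariate (the alpha fraction is collinear under sum-to-one)
and reports the paired-effect Pearson correlation and maximum absolute
change; a constant fraction vector is dropped with a warning, making
the two fits identical by construction.

## Synthetic data

The generators emulate the structure of a bulk small-RNA study of
pancreatic islets: 57 genotyped donors among 63 with expression, two
library preparations (57 + 6) as strata, T2D prevalence 4/63, sex ~
Bernoulli(0.5), age ~ N(55, 10) years, BMI ~ N(28, 5) kg/m², and a
polygenic score that shares a genetic-liability component with T2D
status (correlation controlled by `pgs_r`, default 0.7). Genotypes are
Binomial(2, f) dosages at f ~ Uniform(0.05, 0.5) in linkage
equilibrium (an adjacent-variant copy-with-flip option provides tunable
LD). Expression is a latent Gaussian whose cis, trans and noise
components are orthogonalized and rescaled so the *realized* variance
fractions equal the targets exactly — this makes parameter-recovery
tests sharp at moderate n — then counted as NB(mean = s_j·μ·e^y,
dispersion φ = 0.2 by default) with log-normal library size factors
(sd 0.2). Defaults of 5 cis- and 20 trans-causal variants per feature
keep the architecture polygenic without washing out single-variant
power experiments, which override them. GWAS pairs follow a
single-causal-variant model (per-standardized-dosage effect 0.12, i.e.
~1% variance explained, cohorts of 5,000) with the causal SNP shared or
distinct; summary statistics come from exact per-SNP marginal OLS on
the simulated cohorts.

What the generators do **not** emulate: realistic LD from reference
panels, isomiR sequence structure, mapping/quantification noise, shared
samples between strata, or empirical mRNA covariance structure. Passing
calibration tests therefore demonstrates correctness of the estimators
under their assumed models, not robustness to those real-data features.

## Study sizes used in tests and `scripts/acceptance.py`

- REML recovery: n = 200 samples, 500 variants (half cis), truth
  (h²_cis, h²_trans) = (0.2, 0.4), 50 replicates.
- Null heritability: same design, pure-noise expression, 50 replicates.
  Note the constrained-REML null mean is bounded below by the sampling
  floor E[max(0, N(0, √(2M)/n))] ≈ 0.06 at this design — the estimator
  is unbiased-at-truncation, not zero-mean.
- Class comparison: 200 features per class at n = 200; miRNA-like
  heritable truth (0.08, 0.82), mRNA-like (0.45, 0.45), heritable
  fractions 0.35 vs 0.60.
- Colocalization: 100 shared- and 100 distinct-causal regions, 100 SNPs,
  n = 5,000 per trait; credible-set coverage over 500 single-causal
  simulations.
- DE chain: 200 features, strata of 57 and 6 samples, 50 replicates for
  the pure null and for the 10%-alternative (|log2FC| = 1.5).
- Interaction type-I: n = 33, 2,000 replicates (Monte-Carlo sd ≈ 0.005
  against the (0.03, 0.08) calibration band).
- Deconvolution: 50 signature miRNAs, 100 samples, fractions uniform on
  (0.05, 0.95), depth 1e5, NB dispersion 0 and 0.1.

## Known limitations

- Variance-component SEs are not reported; only point estimates and the
  restricted log-likelihood.
- The NB differential expression is a transparent Wald GLM, not a full
  re-implementation of shrinkage-based DE machinery; exact numerical
  parity with such tools is out of scope.
- Colocalization assumes at most one causal variant per trait per
  region; multi-signal fine-mapping is out of scope.
- Deconvolution supports exactly two cell types with reference
  signatures; reference-free and multi-type deconvolution are not
  implemented.
- Missing genotypes are mean-imputed per variant (cap 10% missingness);
  phasing/imputation is out of scope.
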