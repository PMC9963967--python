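"""Synthetic-data generators with recorded ground truth.

Every generator is a pure function of its configuration and seed, and
mirrors the statistical structure the analysis stages assume:

* genotypes: Binomial(2, f) dosages at uniform MAFs, optionally with
  copy-with-flip LD blocks;
* expression: latent Gaussian y = cis-genetic + trans-genetic +
  covariates + noise with components orthogonalized and rescaled so the
  *realized* variance fractions hit the cis/trans targets exactly, then
  NB counts with log-normal library size factors;
* paired GWAS summary statistics from a single-causal-variant model with
  a shared or distinct causal SNP;
* two-cell-type bulk mixtures of sorted-cell signature profiles.

Default sample sizes follow the study design this emulates: 63 donors
with small-RNA expression, of whom 57 carry genotypes, and a T2D
prevalence of 4/63.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .grm import partition_cis_trans, standardize_dosages
from .io import FeatureRecord, GenotypeMatrix, VARIANT_COLUMNS

__all__ = [
    "SimConfig",
    "SimTruth",
    "simulate_genotypes",
    "default_features",
    "simulate_covariates",
    "simulate_expression",
    "simulate_de_counts",
    "simulate_gwas_pair",
    "simulate_signatures",
    "simulate_mixture",
    "simulate_bundle",
]

# deterministic substream tags (kept < 2**31 together with the seed)
_STREAMS = {
    "genotypes": 11,
    "covariates": 13,
    "expression": 17,
    "gwas": 19,
    "mixture": 23,
    "de": 29,
}


def _rng(seed: int, stage: str) -> np.random.Generator:
    return np.random.default_rng([int(seed) % (2**31), _STREAMS[stage]])


@dataclass
class SimConfig:
    """Generator configuration; ``seed`` fully determines all output."""

    n_samples: int = 57
    n_variants: int = 500
    maf_range: tuple[float, float] = (0.05, 0.5)
    h2_cis: float = 0.2
    h2_trans: float = 0.4
    nb_dispersion: float = 0.2
    mean_expression: float = 100.0
    seed: int = 0
    n_cis_causal: int = 5
    n_trans_causal: int = 20
    cis_fraction: float = 0.5
    window_size: int = 250_000
    ld_flip_prob: float | None = None
    # covariate model: sex ~ Bernoulli(0.5); age ~ N(55, 10); BMI ~ N(28, 5);
    # T2D by liability threshold at the study prevalence (4 of 63);
    # PGS = pgs_r * standardized genetic liability + sqrt(1-pgs_r^2) * noise
    t2d_prevalence: float = 4.0 / 63.0
    pgs_r: float = 0.7
    covariate_effects: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        for name in ("h2_cis", "h2_trans"):
            if not 0.0 <= getattr(self, name) < 1.0:
                raise ValueError(f"{name} must lie in [0, 1)")
        if self.h2_cis + self.h2_trans >= 1.0:
            raise ValueError("h2_cis + h2_trans must be < 1")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be >= 0")


@dataclass
class SimTruth:
    """Ground truth recorded alongside every simulated dataset."""

    causal_variants: dict = field(default_factory=dict)  # feature -> {id: effect}
    realized_h2_cis: dict = field(default_factory=dict)
    realized_h2_trans: dict = field(default_factory=dict)
    cell_fractions: dict = field(default_factory=dict)  # sample -> {cell: frac}
    true_log2fc: dict = field(default_factory=dict)  # phenotype -> {feature: lfc}
    extras: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, default=float)

    @classmethod
    def from_json(cls, path: str | Path) -> "SimTruth":
        with open(path) as fh:
            return cls(**json.load(fh))


# ---------------------------------------------------------------------------
# genotypes and features
# ---------------------------------------------------------------------------

_FEATURE_CHROM = "chr1"
_FEATURE_START = 1_200_000
_TRANS_CHROM = "chr2"


def simulate_genotypes(config: SimConfig) -> GenotypeMatrix:
    """Binomial(2, f) dosages, f ~ Uniform(maf_range), linkage equilibrium.

    The first ``cis_fraction`` of variants is placed on chr1 within the
    default feature's cis window; the remainder on chr2.  When
    ``ld_flip_prob`` is set, each odd-indexed variant copies its left
    neighbour's dosage with per-allele flip probability, giving tunable
    adjacent-variant LD (flip probability 0 => r^2 = 1).
    """
    rng = _rng(config.seed, "genotypes")
    m, n = config.n_variants, config.n_samples
    freqs = rng.uniform(*config.maf_range, size=m)
    dosages = rng.binomial(2, freqs[None, :], size=(n, m)).astype(float)
    for j in range(m):  # redraw the rare monomorphic column at small n
        tries = 0
        while np.ptp(dosages[:, j]) == 0 and tries < 100:
            dosages[:, j] = rng.binomial(2, freqs[j], size=n)
            tries += 1
    if config.ld_flip_prob is not None:
        p = float(config.ld_flip_prob)
        for j in range(1, m, 2):
            copied = dosages[:, j - 1].copy()
            if p > 0:
                n_flip = rng.binomial(2, p, size=n)  # alleles resampled per sample
                resampled = rng.binomial(n_flip, freqs[j - 1])
                kept = copied * (2 - n_flip) / 2.0
                copied = np.clip(np.round(kept + resampled), 0, 2)
            dosages[:, j] = copied
    n_cis = int(round(m * config.cis_fraction))
    meta = []
    for j in range(m):
        if j < n_cis:
            chrom = _FEATURE_CHROM
            pos = _FEATURE_START - config.window_size // 2 + j * max(
                1, config.window_size // max(n_cis, 1)
            )
            pos = max(1, pos)
        else:
            chrom = _TRANS_CHROM
            pos = 1_000_000 + (j - n_cis) * 1_000
        f = dosages[:, j].mean() / 2.0
        meta.append((f"rs{j:06d}", chrom, pos, "A", "G", min(f, 1 - f)))
    variants = pd.DataFrame(meta, columns=VARIANT_COLUMNS)
    sample_ids = [f"S{i:03d}" for i in range(n)]
    return GenotypeMatrix(dosages, sample_ids, variants)


def default_features(n_features: int = 1, biotype: str = "miRNA") -> list[FeatureRecord]:
    """Features co-located on chr1 so the simulated cis variants fall in
    their shared 250 kb window."""
    return [
        FeatureRecord(
            feature_id=f"{'mir' if biotype == 'miRNA' else 'gene'}{i:04d}",
            chrom=_FEATURE_CHROM,
            start=_FEATURE_START,
            end=_FEATURE_START + 22,
            strand="+",
            biotype=biotype,
        )
        for i in range(n_features)
    ]


# ---------------------------------------------------------------------------
# covariates
# ---------------------------------------------------------------------------


def simulate_covariates(config: SimConfig, genotypes: GenotypeMatrix | None = None) -> pd.DataFrame:
    """Donor metadata: sex, age, BMI, T2D status and a polygenic score.

    The PGS is a noisy version of a standardized genetic liability built
    from the simulated genotypes (pure noise when no genotypes are given);
    T2D is a liability threshold at the configured prevalence, with the
    genetic liability contributing, so PGS-phenotype correlation is
    controlled by ``pgs_r``.
    """
    rng = _rng(config.seed, "covariates")
    n = config.n_samples
    sex = rng.binomial(1, 0.5, size=n)
    age = rng.normal(55.0, 10.0, size=n)
    bmi = rng.normal(28.0, 5.0, size=n)
    if genotypes is not None and genotypes.n_variants > 0:
        z = standardize_dosages(genotypes.dosages)
        weights = rng.normal(size=genotypes.n_variants)
        liab_g = z @ weights
        liab_g = (liab_g - liab_g.mean()) / max(liab_g.std(), 1e-12)
    else:
        liab_g = rng.normal(size=n)
    r = config.pgs_r
    pgs = r * liab_g + np.sqrt(max(1 - r**2, 0.0)) * rng.normal(size=n)
    liability = r * liab_g + np.sqrt(max(1 - r**2, 0.0)) * rng.normal(size=n)
    thresh = np.quantile(liability, 1.0 - config.t2d_prevalence)
    t2d = (liability > thresh).astype(int)
    sample_ids = (
        genotypes.sample_ids if genotypes is not None else [f"S{i:03d}" for i in range(n)]
    )
    return pd.DataFrame(
        {"sex": sex, "age": age, "bmi": bmi, "t2d": t2d, "pgs": pgs},
        index=sample_ids,
    )


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------


def _orthonormal_component(x: np.ndarray, basis: list[np.ndarray]) -> np.ndarray:
    """Center, residualize on previous components, return unit-variance."""
    x = x - x.mean()
    for b in basis:
        x = x - (x @ b) / (b @ b) * b
    sd = x.std(ddof=0)
    if sd < 1e-12:
        raise ValueError("degenerate component in expression simulation")
    return x / sd


def simulate_expression(
    genotypes: GenotypeMatrix,
    features: list[FeatureRecord],
    config: SimConfig,
    covariates: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, SimTruth]:
    """NB counts whose latent log-mean decomposes into cis + trans +
    covariate + noise components with exact realized variance fractions.

    Returns (counts, latent, truth); ``latent`` holds the Gaussian y
    (features x samples) that the counts were generated from, useful for
    Gaussian-model tests.
    """
    rng = _rng(config.seed, "expression")
    n = genotypes.n_samples
    z = standardize_dosages(genotypes.dosages)
    vid = list(genotypes.variants["variant_id"])
    vindex = {v: j for j, v in enumerate(vid)}
    size_factors = np.exp(rng.normal(0.0, 0.2, size=n))
    counts_rows, latent_rows, index = [], [], []
    truth = SimTruth()
    lfc_cfg = {k: float(v) for k, v in config.covariate_effects.items()}
    for feat in features:
        cis_ids, trans_ids = partition_cis_trans(
            genotypes.variants, feat, config.window_size
        )
        if config.h2_cis > 0 and len(cis_ids) == 0:
            raise ValueError(
                f"{feat.feature_id}: no cis variants available but h2_cis > 0"
            )
        parts: list[np.ndarray] = []
        causal: dict[str, float] = {}
        y = np.zeros(n)
        for ids, h2, n_causal in (
            (cis_ids, config.h2_cis, config.n_cis_causal),
            (trans_ids, config.h2_trans, config.n_trans_causal),
        ):
            if h2 <= 0 or len(ids) == 0:
                parts.append(np.zeros(n))
                continue
            chosen = rng.choice(ids, size=min(n_causal, len(ids)), replace=False)
            effects = rng.normal(size=len(chosen))
            raw = z[:, [vindex[c] for c in chosen]] @ effects
            comp = _orthonormal_component(raw, [p for p in parts if p.any()])
            comp = comp * np.sqrt(h2)
            parts.append(comp)
            y = y + comp
            for c, e in zip(chosen, effects):
                causal[str(c)] = float(e)
        cov_comp = np.zeros(n)
        if covariates is not None and lfc_cfg:
            for name, eff in lfc_cfg.items():
                x = covariates[name].to_numpy(dtype=float)
                x = (x - x.mean()) / max(x.std(ddof=0), 1e-12)
                cov_comp = cov_comp + eff * x
        noise = _orthonormal_component(
            rng.normal(size=n), [p for p in parts if p.any()]
        ) * np.sqrt(max(1.0 - config.h2_cis - config.h2_trans, 1e-12))
        y = y + cov_comp + noise
        mu = size_factors * config.mean_expression * np.exp(y - np.log(np.exp(y).mean()))
        phi = config.nb_dispersion
        if phi > 1e-12:
            lam = rng.gamma(shape=1.0 / phi, scale=mu * phi)
            cts = rng.poisson(lam)
        else:
            cts = rng.poisson(mu)
        counts_rows.append(cts)
        latent_rows.append(y)
        index.append(feat.feature_id)
        truth.causal_variants[feat.feature_id] = causal
        total_var = y.var(ddof=0)
        truth.realized_h2_cis[feat.feature_id] = float(
            parts[0].var(ddof=0) / total_var
        )
        truth.realized_h2_trans[feat.feature_id] = float(
            parts[1].var(ddof=0) / total_var
        )
    counts = pd.DataFrame(
        np.asarray(counts_rows, dtype=np.int64), index=index, columns=genotypes.sample_ids
    )
    latent = pd.DataFrame(np.asarray(latent_rows), index=index, columns=genotypes.sample_ids)
    truth.extras["size_factors"] = {
        s: float(v) for s, v in zip(genotypes.sample_ids, size_factors)
    }
    return counts, latent, truth


def simulate_de_counts(
    n_samples: int,
    n_features: int,
    phenotype: np.ndarray,
    log2fc: np.ndarray | float,
    nb_dispersion: float = 0.2,
    mean_expression: float = 100.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, SimTruth]:
    """NB counts with per-feature true log2 fold change on a phenotype.

    Binary phenotypes shift the log-mean by lfc*log(2) per contrast;
    continuous phenotypes per SD.  Library size factors are log-normal.
    """
    rng = _rng(seed, "de")
    ph = np.asarray(phenotype, dtype=float)
    if ph.size != n_samples:
        raise ValueError("phenotype length mismatch")
    levels = np.unique(ph)
    x = (ph == levels[1]).astype(float) if levels.size == 2 else (
        (ph - ph.mean()) / ph.std(ddof=0)
    )
    lfc = np.broadcast_to(np.asarray(log2fc, dtype=float), (n_features,)).copy()
    sf = np.exp(rng.normal(0.0, 0.2, size=n_samples))
    base = mean_expression * np.exp(rng.normal(0.0, 0.5, size=n_features))
    mu = sf[None, :] * base[:, None] * 2.0 ** (lfc[:, None] * x[None, :])
    if nb_dispersion > 1e-12:
        lam = rng.gamma(shape=1.0 / nb_dispersion, scale=mu * nb_dispersion)
        counts = rng.poisson(lam)
    else:
        counts = rng.poisson(mu)
    index = [f"mir{i:04d}" for i in range(n_features)]
    cols = [f"S{i:03d}" for i in range(n_samples)]
    truth = SimTruth(true_log2fc={"phenotype": {f: float(l) for f, l in zip(index, lfc)}})
    truth.extras["size_factors"] = {c: float(v) for c, v in zip(cols, sf)}
    return pd.DataFrame(counts.astype(np.int64), index=index, columns=cols), truth


# ---------------------------------------------------------------------------
# GWAS summary statistics
# ---------------------------------------------------------------------------


def _marginal_stats(g: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized per-SNP OLS of y on dosage (with intercept)."""
    from scipy import stats as sps

    n = y.size
    gc = g - g.mean(axis=0)
    yc = y - y.mean()
    gss = np.einsum("ij,ij->j", gc, gc)
    mono = gss <= 0  # monomorphic in this cohort: no information
    gss_safe = np.where(mono, 1.0, gss)
    beta = (gc.T @ yc) / gss_safe
    resid = yc[:, None] - gc * beta
    sigma2 = np.einsum("ij,ij->j", resid, resid) / (n - 2)
    se = np.sqrt(sigma2 / gss_safe)
    beta[mono] = 0.0
    se[mono] = 1e6
    return beta, se


def simulate_gwas_pair(
    n_snps: int,
    shared: bool,
    n1: int = 5000,
    n2: int = 5000,
    effect_size: float = 0.12,
    seed: int = 0,
    maf_range: tuple[float, float] = (0.05, 0.5),
) -> tuple[pd.DataFrame, pd.DataFrame, SimTruth]:
    """Paired GWAS summary statistics under a single-causal-variant model.

    Each trait gets an independent cohort genotyped at the same SNP panel
    (linkage equilibrium); the causal SNP is shared or distinct.
    ``effect_size`` is the per-standardized-dosage effect in phenotype-SD
    units.  Returns (stats1, stats2, truth).
    """
    if not shared and n_snps < 2:
        raise ValueError("need >= 2 SNPs for distinct causal variants")
    rng = _rng(seed, "gwas")
    freqs = rng.uniform(*maf_range, size=n_snps)
    c1 = int(rng.integers(n_snps))
    c2 = c1 if shared else int(rng.choice([j for j in range(n_snps) if j != c1]))
    frames = []
    from scipy import stats as sps

    for n, causal in ((n1, c1), (n2, c2)):
        g = rng.binomial(2, freqs[None, :], size=(n, n_snps)).astype(float)
        zc = g[:, causal] - g[:, causal].mean()
        sd = zc.std(ddof=0)
        zc = zc / sd if sd > 0 else zc
        noise_sd = np.sqrt(max(1.0 - effect_size**2, 1e-12))
        y = effect_size * zc + rng.normal(0.0, noise_sd, size=n)
        beta, se = _marginal_stats(g, y)
        p = 2.0 * sps.t.sf(np.abs(beta / se), n - 2)
        f = g.mean(axis=0) / 2.0
        frames.append(
            pd.DataFrame(
                {
                    "variant_id": [f"rs{j:06d}" for j in range(n_snps)],
                    "chrom": _FEATURE_CHROM,
                    "pos": _FEATURE_START - 125_000 + np.arange(n_snps) * 500,
                    "beta": beta,
                    "se": se,
                    "p": np.clip(p, 5e-324, 1.0),
                    "n": n,
                    "maf": np.minimum(f, 1 - f),
                    "trait_type": "quantitative",
                }
            )
        )
    truth = SimTruth(
        extras={
            "causal_trait1": f"rs{c1:06d}",
            "causal_trait2": f"rs{c2:06d}",
            "shared": bool(shared),
            "effect_size": float(effect_size),
        }
    )
    return frames[0], frames[1], truth


# ---------------------------------------------------------------------------
# cell mixtures
# ---------------------------------------------------------------------------


def simulate_signatures(
    n_features: int = 50, seed: int = 0, depth: float = 1e5
) -> pd.DataFrame:
    """Two sorted-cell signature profiles with distinct feature usage."""
    rng = _rng(seed, "mixture")
    index = [f"mir{i:04d}" for i in range(n_features)]
    alpha = rng.gamma(2.0, 1.0, size=n_features)
    beta = rng.gamma(2.0, 1.0, size=n_features)
    half = n_features // 2
    alpha[:half] *= 8.0  # alpha-enriched block
    beta[half:] *= 8.0
    sig = pd.DataFrame({"alpha": alpha, "beta": beta}, index=index)
    return (sig / sig.sum(axis=0) * depth).round().astype(np.int64)


def simulate_mixture(
    signatures: pd.DataFrame,
    fractions: pd.DataFrame,
    nb_dispersion: float = 0.1,
    depth: float = 1e5,
    seed: int = 0,
) -> tuple[pd.DataFrame, SimTruth]:
    """Bulk counts as fraction-weighted sums of signature means + NB noise.

    ``fractions``: samples x cell types, rows on the simplex.
    """
    fr = fractions.to_numpy(dtype=float)
    if (fr < 0).any():
        raise ValueError("fractions must be non-negative")
    if not np.allclose(fr.sum(axis=1), 1.0, atol=1e-8):
        raise ValueError("fractions must sum to 1 per sample")
    rng = _rng(seed, "mixture")
    prop = signatures / signatures.sum(axis=0)
    mu = depth * (prop.to_numpy() @ fr.T)  # features x samples
    if nb_dispersion > 1e-12:
        lam = rng.gamma(shape=1.0 / nb_dispersion, scale=mu * nb_dispersion)
        counts = rng.poisson(lam)
    else:
        counts = rng.poisson(mu)
    bulk = pd.DataFrame(
        counts.astype(np.int64), index=signatures.index, columns=fractions.index
    )
    truth = SimTruth(
        cell_fractions={
            str(s): {str(c): float(v) for c, v in zip(fractions.columns, row)}
            for s, row in zip(fractions.index, fr)
        }
    )
    return bulk, truth


# ---------------------------------------------------------------------------
# full input bundle
# ---------------------------------------------------------------------------


def simulate_bundle(outdir: str | Path, config: SimConfig) -> dict[str, Path]:
    """Write a complete pipeline input bundle into ``outdir``.

    Produces genotypes (VCF), feature intervals (BED6+2), miRNA and mRNA
    counts (TSV), donor metadata, paired GWAS summary statistics,
    predicted target sites, sorted-cell signatures, and the ground-truth
    JSON.  Everything derives from ``config.seed``.
    """
    from .io import write_counts, write_genotypes_vcf, write_intervals, write_summary_stats

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    genotypes = simulate_genotypes(config)
    paths["genotypes"] = outdir / "genotypes.vcf"
    write_genotypes_vcf(genotypes, paths["genotypes"])

    n_mir, n_gene = 12, 8
    mirnas = default_features(n_mir, "miRNA")
    genes = default_features(n_gene, "mRNA")
    paths["mirna_bed"] = outdir / "mirnas.bed"
    paths["mrna_bed"] = outdir / "mrnas.bed"
    write_intervals(mirnas, paths["mirna_bed"])
    write_intervals(genes, paths["mrna_bed"])

    covariates = simulate_covariates(config, genotypes)
    paths["metadata"] = outdir / "metadata.tsv"
    covariates.to_csv(paths["metadata"], sep="\t", index_label="sample_id")

    mir_counts, _, truth = simulate_expression(genotypes, mirnas, config, covariates)
    gene_cfg = dataclasses.replace(config, seed=config.seed + 1)
    gene_counts, _, gene_truth = simulate_expression(genotypes, genes, gene_cfg, covariates)
    paths["mirna_counts"] = outdir / "mirna_counts.tsv"
    paths["mrna_counts"] = outdir / "mrna_counts.tsv"
    write_counts(mir_counts, paths["mirna_counts"])
    write_counts(gene_counts, paths["mrna_counts"])

    s1, s2, gwas_truth = simulate_gwas_pair(
        n_snps=100, shared=True, seed=config.seed
    )
    paths["gwas_trait1"] = outdir / "gwas_trait1.tsv"
    paths["gwas_trait2"] = outdir / "gwas_trait2.tsv"
    write_summary_stats(s1, paths["gwas_trait1"])
    write_summary_stats(s2, paths["gwas_trait2"])

    # predicted target sites: 7-mer seed-match intervals near each gene
    rows = []
    rng = _rng(config.seed, "mixture")
    for gi, gene in enumerate(genes):
        mir = mirnas[gi % n_mir]
        start = gene.start + 100 + 50 * gi
        rows.append((gene.chrom, start, start + 7, mir.feature_id, gene.feature_id))
    sites = pd.DataFrame(
        rows, columns=["chrom", "start", "end", "mirna_id", "gene_id"]
    )
    paths["target_sites"] = outdir / "target_sites.tsv"
    sites.to_csv(paths["target_sites"], sep="\t", index=False)

    signatures = simulate_signatures(n_features=n_mir, seed=config.seed)
    signatures.index = [m.feature_id for m in mirnas]
    paths["signatures"] = outdir / "signatures.tsv"
    signatures.to_csv(paths["signatures"], sep="\t", index_label="feature_id")

    alpha = rng.uniform(0.2, 0.8, size=config.n_samples)
    fractions = pd.DataFrame(
        {"alpha": alpha, "beta": 1.0 - alpha}, index=genotypes.sample_ids
    )
    bulk, mix_truth = simulate_mixture(signatures, fractions, seed=config.seed)
    paths["bulk_mixture"] = outdir / "bulk_mixture.tsv"
    write_counts(bulk, paths["bulk_mixture"])

    truth.cell_fractions = mix_truth.cell_fractions
    truth.extras["gwas"] = gwas_truth.extras
    truth.extras["mrna_causal"] = gene_truth.causal_variants
    paths["truth"] = outdir / "truth.json"
    truth.to_json(paths["truth"])
    return paths
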