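"""Bayesian colocalization (PP0-PP4), 99% credible sets, target-site overlap.

Colocalization follows the approximate-Bayes-factor framework for two
traits under a single-causal-variant assumption per trait.  Per-SNP
evidence is the Wakefield log approximate Bayes factor

    lABF = 1/2 [ log(V / (V + W)) + z^2 * W / (V + W) ],   V = se^2, z = beta/se,

with prior effect variance W (sd 0.15 for quantitative traits, 0.2 on
the log-odds scale for case-control).  Configuration sums are
accumulated in log space so strong signals cannot overflow.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy.special import logsumexp

__all__ = [
    "ColocResult",
    "CredibleSet",
    "ColocPriors",
    "wakefield_labf",
    "coloc_abf",
    "credible_set_99",
    "overlap_credible_with_sites",
]

PRIOR_SD_QUANTITATIVE = 0.15
PRIOR_SD_CASE_CONTROL = 0.2


@dataclass
class ColocPriors:
    """Per-SNP prior probabilities of association (p1/p2) and shared
    causality (p12); defaults are the field-standard values."""

    p1: float = 1e-4
    p2: float = 1e-4
    p12: float = 1e-5


@dataclass
class ColocResult:
    region_id: str
    pp0: float
    pp1: float
    pp2: float
    pp3: float
    pp4: float
    n_snps: int
    priors: ColocPriors
    labf1: np.ndarray = field(repr=False, default=None)
    labf2: np.ndarray = field(repr=False, default=None)
    snp_ids: list[str] = field(repr=False, default_factory=list)

    @property
    def pp(self) -> np.ndarray:
        return np.array([self.pp0, self.pp1, self.pp2, self.pp3, self.pp4])


@dataclass
class CredibleSet:
    """Minimal posterior-sorted variant set with cumulative mass >= level."""

    signal_id: str
    variant_ids: list[str]
    posteriors: np.ndarray
    cumulative_mass: float
    level: float = 0.99

    @property
    def size(self) -> int:
        return len(self.variant_ids)


def wakefield_labf(
    beta: np.ndarray | float,
    se: np.ndarray | float,
    prior_sd: float | None = None,
    trait_type: str = "quantitative",
) -> np.ndarray | float:
    """Natural-log Wakefield approximate Bayes factor for association."""
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    if np.any(se <= 0):
        raise ValueError("se must be > 0")
    if prior_sd is None:
        prior_sd = (
            PRIOR_SD_CASE_CONTROL if trait_type == "case_control" else PRIOR_SD_QUANTITATIVE
        )
    if prior_sd < 0:
        raise ValueError("prior effect sd must be >= 0")
    v = se**2
    w = prior_sd**2
    z2 = (beta / se) ** 2
    r = w / (v + w)
    labf = 0.5 * (np.log(v / (v + w)) + z2 * r) if w > 0 else np.zeros_like(v)
    return labf if labf.ndim else float(labf)


def _labf_from_stats(stats: pd.DataFrame, prior_sd: float | None) -> np.ndarray:
    trait_type = (
        stats["trait_type"].iloc[0] if "trait_type" in stats.columns else "quantitative"
    )
    return np.asarray(
        wakefield_labf(
            stats["beta"].to_numpy(), stats["se"].to_numpy(), prior_sd, trait_type
        )
    )


def coloc_abf(
    stats1: pd.DataFrame,
    stats2: pd.DataFrame,
    priors: ColocPriors | None = None,
    prior_sd1: float | None = None,
    prior_sd2: float | None = None,
    region_id: str = "",
) -> ColocResult:
    """Posterior probabilities of the five colocalization configurations.

    H0 neither trait associated; H1/H2 only trait 1/2; H3 both with
    distinct causal variants; H4 both sharing one causal variant.
    Summary stats are joined on variant_id; each input must carry
    beta and se per SNP.
    """
    priors = priors or ColocPriors()
    merged = stats1.merge(stats2, on="variant_id", suffixes=("_1", "_2"))
    if len(merged) == 0:
        raise ValueError("no shared SNPs between traits")
    s1 = merged.rename(
        columns={"beta_1": "beta", "se_1": "se", "trait_type_1": "trait_type"}
    )
    s2 = merged.rename(
        columns={"beta_2": "beta", "se_2": "se", "trait_type_2": "trait_type"}
    )
    l1 = _labf_from_stats(s1, prior_sd1)
    l2 = _labf_from_stats(s2, prior_sd2)
    n = len(merged)
    ls1 = logsumexp(l1)
    ls2 = logsumexp(l2)
    ls12 = logsumexp(l1 + l2)
    # sum_{i != j} ABF1_i ABF2_j = S1*S2 - S12, in log space with signs
    if n > 1:
        ls3, sign3 = logsumexp(
            np.array([ls1 + ls2, ls12]), b=np.array([1.0, -1.0]), return_sign=True
        )
        if sign3 <= 0:  # numerically zero or negative
            ls3 = -np.inf
    else:
        ls3 = -np.inf
    log_unnorm = np.array(
        [
            0.0,
            np.log(priors.p1) + ls1,
            np.log(priors.p2) + ls2,
            (np.log(priors.p1) + np.log(priors.p2) + ls3) if np.isfinite(ls3) else -np.inf,
            np.log(priors.p12) + ls12,
        ]
    )
    denom = logsumexp(log_unnorm)
    pp = np.exp(log_unnorm - denom)
    pp = pp / pp.sum()
    return ColocResult(
        region_id=region_id,
        pp0=float(pp[0]), pp1=float(pp[1]), pp2=float(pp[2]),
        pp3=float(pp[3]), pp4=float(pp[4]),
        n_snps=n,
        priors=priors,
        labf1=l1,
        labf2=l2,
        snp_ids=[str(v) for v in merged["variant_id"]],
    )


def credible_set_99(
    labf: np.ndarray, variant_ids: list[str], signal_id: str = "", level: float = 0.99
) -> CredibleSet:
    """Single-causal credible set: per-SNP posterior ABF_j / sum ABF, sorted
    descending (ties broken by variant id), minimal prefix reaching ``level``."""
    labf = np.asarray(labf, dtype=float)
    if labf.size == 0:
        raise ValueError("need at least one SNP")
    if labf.size != len(variant_ids):
        raise ValueError("labf and variant_ids lengths differ")
    post = np.exp(labf - logsumexp(labf))
    post = post / post.sum()
    order = sorted(range(labf.size), key=lambda j: (-post[j], str(variant_ids[j])))
    cum = 0.0
    chosen: list[int] = []
    for j in order:
        chosen.append(j)
        cum += post[j]
        if cum >= level:
            break
    return CredibleSet(
        signal_id=signal_id,
        variant_ids=[str(variant_ids[j]) for j in chosen],
        posteriors=post[chosen],
        cumulative_mass=float(cum),
        level=level,
    )


def overlap_credible_with_sites(
    credible_snps: pd.DataFrame,
    mirna_intervals: pd.DataFrame,
    target_sites: pd.DataFrame,
    mirna_abundance: pd.Series,
    mrna_abundance: pd.Series,
    expr_threshold: float = 1.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Overlap credible-set SNPs with mature-miRNA and target-site intervals.

    ``credible_snps``: columns variant_id, chrom, pos, signal_id.
    ``mirna_intervals``: chrom, start, end, mirna_id (0-based half-open).
    ``target_sites``: chrom, start, end, mirna_id, gene_id.
    Abundances are mean normalized expression per feature; a record is
    *retained* when both the miRNA and the target mRNA pass
    ``expr_threshold``.  Returns (retained, audit) frames; the audit frame
    keeps every overlap with its expressed flags.
    """
    trees: dict[str, IntervalTree] = {}
    for _, site in target_sites.iterrows():
        trees.setdefault(str(site["chrom"]), IntervalTree()).addi(
            int(site["start"]), int(site["end"]),
            ("site", str(site["mirna_id"]), str(site["gene_id"])),
        )
    for _, mi in mirna_intervals.iterrows():
        trees.setdefault(str(mi["chrom"]), IntervalTree()).addi(
            int(mi["start"]), int(mi["end"]), ("mature_mirna", str(mi["mirna_id"]), "")
        )
    rows = []
    for _, snp in credible_snps.iterrows():
        tree = trees.get(str(snp["chrom"]))
        if tree is None:
            continue
        for iv in sorted(tree[int(snp["pos"])]):
            kind, mirna_id, gene_id = iv.data
            mir_ok = bool(mirna_abundance.get(mirna_id, 0.0) >= expr_threshold)
            mrna_ok = (
                bool(mrna_abundance.get(gene_id, 0.0) >= expr_threshold)
                if kind == "site"
                else True
            )
            rows.append(
                {
                    "variant_id": snp["variant_id"],
                    "signal_id": snp.get("signal_id", ""),
                    "chrom": snp["chrom"],
                    "pos": int(snp["pos"]),
                    "interval_kind": kind,
                    "site_start": iv.begin,
                    "site_end": iv.end,
                    "mirna_id": mirna_id,
                    "gene_id": gene_id,
                    "mirna_expressed": mir_ok,
                    "mrna_expressed": mrna_ok,
                }
            )
    audit = pd.DataFrame(
        rows,
        columns=[
            "variant_id", "signal_id", "chrom", "pos", "interval_kind",
            "site_start", "site_end", "mirna_id", "gene_id",
            "mirna_expressed", "mrna_expressed",
        ],
    )
    retained = audit.loc[audit["mirna_expressed"] & audit["mrna_expressed"]].reset_index(
        drop=True
    )
    return retained, audit
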