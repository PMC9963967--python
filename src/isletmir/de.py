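"""Negative-binomial differential expression and fixed-effect meta-analysis.

Counts are normalized with median-of-ratios size factors; each feature is
fit with a log-link NB GLM (offset log size factor, per-feature
method-of-moments dispersion with a floor) and a Wald test on the
phenotype coefficient, reported as log2 fold change per contrast (binary
phenotypes) or per SD (continuous phenotypes, standardized before the
fit).  Stratum results are combined by inverse-variance weighting and
thresholded at FDR <= 5% and |log2FC| >= 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .qtl import bh_fdr

__all__ = [
    "size_factors",
    "abundance_filter",
    "nb_wald_de",
    "ivw_meta",
    "apply_de_thresholds",
    "mirna_mrna_association",
    "DE_COLUMNS",
    "META_COLUMNS",
]

DE_COLUMNS = ["feature_id", "phenotype", "log2fc", "se", "p", "stratum"]
META_COLUMNS = [
    "feature_id", "phenotype", "log2fc", "se", "p", "q", "n_strata",
]

LN2 = float(np.log(2.0))
DISPERSION_FLOOR = 1e-4


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors.

    Reference = per-feature geometric mean across samples over features
    with all-positive counts; factor_j = median_i count_ij / ref_i.
    """
    mat = counts.to_numpy(dtype=float)
    all_pos = (mat > 0).all(axis=1)
    if not all_pos.any():
        raise ValueError("cannot normalize: no feature with all-positive counts")
    sub = mat[all_pos]
    log_ref = np.mean(np.log(sub), axis=1)
    ratios = np.log(sub) - log_ref[:, None]
    factors = np.exp(np.median(ratios, axis=0))
    return pd.Series(factors, index=counts.columns, name="size_factor")


def abundance_filter(
    counts: pd.DataFrame, min_count: int = 10, min_fraction: float = 0.5
) -> list[str]:
    """Features with count >= min_count in >= min_fraction of samples."""
    if min_count < 0 or min_fraction < 0:
        raise ValueError("thresholds must be >= 0")
    frac = (counts >= min_count).mean(axis=1)
    return list(counts.index[frac >= min_fraction])


def _mom_dispersion(y: np.ndarray, sf: np.ndarray) -> float:
    """Method-of-moments NB dispersion on size-factor-normalized counts.

    Size factors are rescaled to geometric mean 1 first so the estimate
    (and hence every Wald statistic) is invariant to their overall scale.
    """
    sf = sf / np.exp(np.mean(np.log(sf)))
    z = y / sf
    mu = z.mean()
    if mu <= 0:
        return DISPERSION_FLOOR
    var = z.var(ddof=1)
    return float(max((var - mu) / mu**2, DISPERSION_FLOOR))


def nb_wald_de(
    counts: pd.DataFrame,
    phenotype: np.ndarray | pd.Series,
    covariates: pd.DataFrame | np.ndarray | None = None,
    sf: pd.Series | None = None,
    dispersion: float | str = "moments",
    phenotype_name: str = "phenotype",
    stratum: str = "all",
    standardize_continuous: bool = True,
) -> pd.DataFrame:
    """Per-feature NB Wald differential expression.

    Binary phenotypes are recoded 0/1 (log2FC per contrast); continuous
    phenotypes are standardized to unit SD so log2FC is per SD.  Features
    whose IRLS fit fails get p = NA and are excluded downstream from the
    BH denominator.
    """
    ph = np.asarray(phenotype, dtype=float)
    if np.ptp(ph) == 0:
        raise ValueError("phenotype is constant")
    n = counts.shape[1]
    if ph.size != n:
        raise ValueError("phenotype length does not match sample count")
    levels = np.unique(ph)
    is_binary = levels.size == 2
    if is_binary:
        ph = (ph == levels[1]).astype(float)
    elif standardize_continuous:
        ph = (ph - ph.mean()) / ph.std(ddof=0)
    if sf is None:
        sf = size_factors(counts)
    sfv = sf.loc[counts.columns].to_numpy(dtype=float)
    offset = np.log(sfv)
    if covariates is None:
        w = np.ones((n, 1))
    else:
        cv = (
            covariates.to_numpy(dtype=float)
            if isinstance(covariates, pd.DataFrame)
            else np.atleast_2d(np.asarray(covariates, dtype=float))
        )
        if cv.shape[0] != n:
            cv = cv.T
        keep = ~np.all(cv == cv[0, :], axis=0)
        w = np.column_stack([np.ones(n), cv[:, keep]])
    if n < w.shape[1] + 2:
        raise ValueError("too few samples for the requested covariates")
    x = np.column_stack([w, ph])
    j = x.shape[1] - 1
    rows = []
    for fid, row in counts.iterrows():
        y = row.to_numpy(dtype=float)
        alpha = (
            _mom_dispersion(y, sfv) if dispersion == "moments" else float(dispersion)
        )
        log2fc = se = p = np.nan
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = sm.GLM(
                    y, x, family=sm.families.NegativeBinomial(alpha=alpha),
                    offset=offset,
                ).fit(maxiter=100)
            if fit.converged and np.isfinite(fit.bse[j]) and fit.bse[j] > 0:
                log2fc = float(fit.params[j] / LN2)
                se = float(fit.bse[j] / LN2)
                p = float(fit.pvalues[j])
        except (np.linalg.LinAlgError, ValueError, sm.tools.sm_exceptions.PerfectSeparationError):
            pass
        rows.append((fid, phenotype_name, log2fc, se, p, stratum))
    return pd.DataFrame(rows, columns=DE_COLUMNS)


def ivw_meta(stratum_results: list[pd.DataFrame]) -> pd.DataFrame:
    """Fixed-effect inverse-variance meta-analysis across strata.

    Joins per-stratum DE tables on (feature_id, phenotype); strata with
    NA effect or SE are dropped per feature.  BH q-values are computed per
    phenotype across features (NA-effect features excluded from the
    denominator).
    """
    if not stratum_results:
        raise ValueError("need at least one stratum")
    stacked = pd.concat(stratum_results, ignore_index=True)
    rows = []
    for (fid, pheno), grp in stacked.groupby(["feature_id", "phenotype"], sort=False):
        ok = grp.dropna(subset=["log2fc", "se"])
        ok = ok.loc[np.isfinite(ok["se"]) & (ok["se"] > 0)]
        if len(ok) == 0:
            rows.append((fid, pheno, np.nan, np.nan, np.nan, 0))
            continue
        wts = 1.0 / ok["se"].to_numpy() ** 2
        beta = float(np.sum(wts * ok["log2fc"].to_numpy()) / wts.sum())
        se = float(1.0 / np.sqrt(wts.sum()))
        p = float(2.0 * stats.norm.sf(abs(beta / se)))
        rows.append((fid, pheno, beta, se, max(p, 5e-324), len(ok)))
    meta = pd.DataFrame(
        rows, columns=["feature_id", "phenotype", "log2fc", "se", "p", "n_strata"]
    )
    meta["q"] = np.nan
    for pheno, grp in meta.groupby("phenotype", sort=False):
        valid = grp["p"].notna()
        if valid.any():
            meta.loc[grp.index[valid], "q"] = bh_fdr(grp.loc[valid, "p"].to_numpy())
    return meta[META_COLUMNS]


def apply_de_thresholds(
    meta: pd.DataFrame, fdr: float = 0.05, lfc: float = 1.0
) -> list[str]:
    """Features called differentially expressed: q <= fdr and |log2FC| >= lfc."""
    if len(meta) == 0:
        return []
    called = meta.loc[
        (meta["q"] <= fdr) & (meta["log2fc"].abs() >= lfc) & meta["q"].notna()
    ]
    return list(called["feature_id"])


def mirna_mrna_association(
    mirna_expr: pd.DataFrame,
    mrna_expr: pd.DataFrame,
    covariates: pd.DataFrame | np.ndarray | None = None,
    target_pairs: list[tuple[str, str]] | None = None,
    scope: str = "all",
) -> pd.DataFrame:
    """Linear-model association between miRNA and mRNA expression.

    ``scope='all'`` tests every (miRNA, gene) pair; ``scope='targets'``
    restricts to ``target_pairs`` (miRNA_id, gene_id).  Expression inputs
    are transformed matrices over the same samples; BH within scope.
    """
    shared = [s for s in mirna_expr.columns if s in set(mrna_expr.columns)]
    if len(shared) < 10:
        raise ValueError("need >= 10 paired samples")
    if scope == "targets":
        pairs = [
            (m, g)
            for m, g in (target_pairs or [])
            if m in mirna_expr.index and g in mrna_expr.index
        ]
    else:
        pairs = [(m, g) for m in mirna_expr.index for g in mrna_expr.index]
    if not pairs:
        return pd.DataFrame(
            columns=["variant_id", "feature_id", "beta", "se", "p", "q", "n", "scan_type"]
        )
    n = len(shared)
    if covariates is None:
        w = np.ones((n, 1))
    else:
        cv = (
            covariates.to_numpy(dtype=float)
            if isinstance(covariates, pd.DataFrame)
            else np.atleast_2d(np.asarray(covariates, dtype=float))
        )
        if cv.shape[0] != n:
            cv = cv.T
        w = np.column_stack([np.ones(n), cv])
    rows = []
    for mir, gene in pairs:
        ym = mirna_expr.loc[mir, shared].to_numpy(dtype=float)
        yg = mrna_expr.loc[gene, shared].to_numpy(dtype=float)
        fit = sm.OLS(yg, np.column_stack([w, ym])).fit()
        rows.append(
            (mir, gene, float(fit.params[-1]), float(fit.bse[-1]),
             float(fit.pvalues[-1]), n)
        )
    out = pd.DataFrame(rows, columns=["variant_id", "feature_id", "beta", "se", "p", "n"])
    out["q"] = bh_fdr(np.clip(out["p"].to_numpy(), 5e-324, 1.0))
    out["scan_type"] = "mirna_mrna"
    return out[["variant_id", "feature_id", "beta", "se", "p", "q", "n", "scan_type"]]
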