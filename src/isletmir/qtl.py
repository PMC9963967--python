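"""Single-variant association scans, FDR control, interaction, MR, mediation.

The default scan is ordinary least squares of (transformed) expression on
dosage plus covariates with a two-sided Wald test; Benjamini-Hochberg
q-values are pooled across all tests of one scan invocation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import GenotypeMatrix

__all__ = [
    "AssocResult",
    "MRResult",
    "assoc_scan",
    "bh_fdr",
    "interaction_test",
    "mr_wald",
    "mediation_sobel",
    "effect_concordance",
]

ASSOC_COLUMNS = ["variant_id", "feature_id", "beta", "se", "p", "q", "n", "scan_type"]


@dataclass
class AssocResult:
    variant_id: str
    feature_id: str
    beta: float
    se: float
    p: float
    q: float
    n: int
    scan_type: str = "cis_eqtl"


@dataclass
class MRResult:
    """Wald-ratio Mendelian randomization plus Sobel mediation quantities."""

    instrument: str = ""
    exposure: str = ""
    outcome: str = ""
    beta_wald: float = float("nan")
    se_wald: float = float("nan")
    p: float = float("nan")
    a: float = float("nan")
    se_a: float = float("nan")
    b: float = float("nan")
    se_b: float = float("nan")
    ab: float = float("nan")
    sobel_se: float = float("nan")
    sobel_p: float = float("nan")
    direct_beta: float = float("nan")
    direct_p: float = float("nan")


def _check_collinear(w: np.ndarray, names: list[str]) -> None:
    if w.shape[1] > 1 and np.linalg.matrix_rank(w) < w.shape[1]:
        raise ValueError(f"collinear covariates among {names}")


def _covariate_design(n: int, covariates: pd.DataFrame | np.ndarray | None):
    if covariates is None:
        return np.ones((n, 1)), ["intercept"]
    if isinstance(covariates, pd.DataFrame):
        names = [str(c) for c in covariates.columns]
        w = covariates.to_numpy(dtype=float)
    else:
        w = np.atleast_2d(np.asarray(covariates, dtype=float))
        if w.shape[0] != n:
            w = w.T
        names = [f"cov{i}" for i in range(w.shape[1])]
    # drop constant covariates (intercept is added explicitly)
    keep = ~np.all(w == w[0, :], axis=0)
    w = w[:, keep]
    names = [nm for nm, k in zip(names, keep) if k]
    w = np.column_stack([np.ones(n), w])
    _check_collinear(w, ["intercept"] + names)
    return w, ["intercept"] + names


def _ols_scan_one_feature(
    y: np.ndarray, g_mat: np.ndarray, w: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized OLS of y on each dosage column + covariates.

    Uses Frisch-Waugh residualization; SEs carry the exact OLS degrees of
    freedom n - p_cov - 1 (covariates incl. intercept, plus the dosage).
    """
    n, p_cov = w.shape
    q, _ = np.linalg.qr(w)
    proj = lambda x: x - q @ (q.T @ x)  # noqa: E731
    yr = proj(y)
    gr = proj(g_mat)
    gss = np.einsum("ij,ij->j", gr, gr)
    if np.any(gss <= 1e-12):
        raise ValueError("constant (or covariate-collinear) dosage vector in scan")
    beta = (gr.T @ yr) / gss
    resid = yr[:, None] - gr * beta
    dof = n - p_cov - 1
    sigma2 = np.einsum("ij,ij->j", resid, resid) / dof
    se = np.sqrt(sigma2 / gss)
    tstat = beta / se
    p = 2.0 * stats.t.sf(np.abs(tstat), dof)
    return beta, se, p


def assoc_scan(
    expression: pd.DataFrame,
    genotypes: GenotypeMatrix,
    covariates: pd.DataFrame | np.ndarray | None,
    pairs: dict[str, list[str]],
    scan_type: str = "cis_eqtl",
) -> pd.DataFrame:
    """Scan (feature, variant) pairs; returns AssocResult rows with pooled
    Benjamini-Hochberg q-values across the whole invocation.

    ``expression`` is features x samples (transformed); ``pairs`` maps
    feature_id -> list of variant ids to test against it.
    """
    n = genotypes.n_samples
    if n < 10:
        raise ValueError("association scan requires at least 10 samples")
    w, names = _covariate_design(n, covariates)
    vid_index = {v: j for j, v in enumerate(genotypes.variants["variant_id"])}
    rows = []
    for fid, variant_ids in pairs.items():
        if not variant_ids:
            continue
        y = expression.loc[fid].to_numpy(dtype=float)
        cols = [vid_index[v] for v in variant_ids]
        g_mat = genotypes.dosages[:, cols]
        beta, se, p = _ols_scan_one_feature(y, g_mat, w)
        for v, b_, s_, p_ in zip(variant_ids, beta, se, p):
            rows.append((v, fid, b_, s_, max(p_, 5e-324), n, scan_type))
    out = pd.DataFrame(
        rows, columns=["variant_id", "feature_id", "beta", "se", "p", "n", "scan_type"]
    )
    out["q"] = bh_fdr(out["p"].to_numpy()) if len(out) else np.nan
    return out[ASSOC_COLUMNS]


def bh_fdr(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values: q_i = min_{j>=rank(i)} p_(j) m/j."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p <= 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


def interaction_test(
    target_expression: np.ndarray,
    dosage: np.ndarray,
    mirna_expression: np.ndarray,
    covariates: pd.DataFrame | np.ndarray | None = None,
) -> AssocResult:
    """Wald test on the genotype x miRNA product term in
    ``target ~ g + m + g*m + covariates``."""
    y = np.asarray(target_expression, dtype=float)
    g = np.asarray(dosage, dtype=float)
    m = np.asarray(mirna_expression, dtype=float)
    n = y.size
    if np.ptp(g) == 0:
        raise ValueError("constant dosage: interaction not testable")
    if n < 20:
        warnings.warn(f"interaction test at n = {n} (< 20) is low powered")
    w, _ = _covariate_design(n, covariates)
    x = np.column_stack([w, g, m, g * m])
    fit = sm.OLS(y, x).fit()
    j = x.shape[1] - 1
    return AssocResult(
        variant_id="gxm",
        feature_id="interaction",
        beta=float(fit.params[j]),
        se=float(fit.bse[j]),
        p=float(fit.pvalues[j]),
        q=float("nan"),
        n=n,
        scan_type="interaction",
    )


def mr_wald(
    beta_gx: float, se_gx: float, beta_gy: float, se_gy: float,
    instrument: str = "", exposure: str = "", outcome: str = "",
) -> MRResult:
    """Single-instrument Wald ratio beta_gy / beta_gx with first-order
    delta-method SE sqrt(se_gy^2/b_gx^2 + b_gy^2 se_gx^2 / b_gx^4)."""
    if beta_gx == 0:
        raise ValueError("beta_gx = 0: Wald ratio undefined")
    if abs(beta_gx) / se_gx < 2:
        warnings.warn("weak instrument: |beta_gx / se_gx| < 2")
    beta_wald = beta_gy / beta_gx
    se_wald = np.sqrt(se_gy**2 / beta_gx**2 + beta_gy**2 * se_gx**2 / beta_gx**4)
    z = beta_wald / se_wald
    return MRResult(
        instrument=instrument,
        exposure=exposure,
        outcome=outcome,
        beta_wald=float(beta_wald),
        se_wald=float(se_wald),
        p=float(2.0 * stats.norm.sf(abs(z))),
    )


def mediation_sobel(
    exposure: np.ndarray,
    mediator: np.ndarray,
    outcome: np.ndarray,
    covariates: pd.DataFrame | np.ndarray | None = None,
) -> MRResult:
    """Product-of-coefficients mediation with the Sobel standard error.

    a: mediator ~ exposure (+ covariates); b and the direct effect:
    outcome ~ exposure + mediator (+ covariates); ab = a*b,
    sobel_se = sqrt(b^2 se_a^2 + a^2 se_b^2).
    """
    x = np.asarray(exposure, dtype=float)
    m = np.asarray(mediator, dtype=float)
    y = np.asarray(outcome, dtype=float)
    n = x.size
    w, _ = _covariate_design(n, covariates)
    if n <= w.shape[1] + 3:
        raise ValueError(f"n = {n} too small for mediation with {w.shape[1]} covariates")
    fit_a = sm.OLS(m, np.column_stack([w, x])).fit()
    a, se_a = float(fit_a.params[-1]), float(fit_a.bse[-1])
    fit_b = sm.OLS(y, np.column_stack([w, x, m])).fit()
    b, se_b = float(fit_b.params[-1]), float(fit_b.bse[-1])
    direct, direct_p = float(fit_b.params[-2]), float(fit_b.pvalues[-2])
    ab = a * b
    sobel_se = float(np.sqrt(b**2 * se_a**2 + a**2 * se_b**2))
    z = ab / sobel_se if sobel_se > 0 else np.nan
    return MRResult(
        a=a, se_a=se_a, b=b, se_b=se_b, ab=ab,
        sobel_se=sobel_se,
        sobel_p=float(2.0 * stats.norm.sf(abs(z))) if np.isfinite(z) else float("nan"),
        direct_beta=direct, direct_p=direct_p,
    )


_AMBIGUOUS = {frozenset({"A", "T"}), frozenset({"C", "G"})}


def effect_concordance(
    results_a: pd.DataFrame, results_b: pd.DataFrame
) -> tuple[float, int]:
    """Spearman rho of per-(variant, feature) effect sizes across studies.

    Requires columns variant_id, feature_id, beta; optional ref/alt for
    allele harmonization (sign flipped when ref/alt are swapped;
    strand-ambiguous A/T and C/G pairs dropped when alleles present).
    """
    key = ["variant_id", "feature_id"]
    merged = results_a.merge(results_b, on=key, suffixes=("_a", "_b"))
    if {"ref_a", "alt_a", "ref_b", "alt_b"}.issubset(merged.columns):
        amb = merged.apply(
            lambda r: frozenset({r["ref_a"], r["alt_a"]}) in _AMBIGUOUS, axis=1
        )
        merged = merged.loc[~amb].copy()
        same = (merged["ref_a"] == merged["ref_b"]) & (merged["alt_a"] == merged["alt_b"])
        swap = (merged["ref_a"] == merged["alt_b"]) & (merged["alt_a"] == merged["ref_b"])
        merged = merged.loc[same | swap].copy()
        merged.loc[swap[same | swap], "beta_b"] *= -1.0
    if len(merged) == 0:
        raise ValueError("no overlapping (variant, feature) pairs")
    if len(merged) < 3:
        raise ValueError("need at least 3 overlapping pairs for Spearman rho")
    rho, _ = stats.spearmanr(merged["beta_a"], merged["beta_b"])
    return float(rho), int(len(merged))
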