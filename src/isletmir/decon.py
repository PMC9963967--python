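"""Two-cell-type deconvolution from sorted-cell signatures, and
sensitivity re-analysis of association scans with cell fractions as a
covariate.

Bulk abundance is modelled as a non-negative linear mixture of the
sorted alpha- and beta-cell signature profiles (mixing is linear on the
abundance scale, so fitting uses counts-per-million over the signature
features, never log values).  Per-sample fractions come from
non-negative least squares renormalized to the simplex.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import nnls

__all__ = [
    "CellFractions",
    "select_signature_features",
    "estimate_fractions",
    "sensitivity_reanalysis",
]


@dataclass
class CellFractions:
    """Per-sample cell-type fractions on the simplex plus fit residuals."""

    fractions: pd.DataFrame  # samples x cell types
    residual_norm: pd.Series

    def __post_init__(self) -> None:
        if (self.fractions.to_numpy() < -1e-12).any():
            raise ValueError("fractions must be non-negative")


def _cpm(mat: pd.DataFrame) -> pd.DataFrame:
    tot = mat.sum(axis=0)
    return mat * 1e6 / tot.replace(0, np.nan)


def select_signature_features(
    signatures: pd.DataFrame, k: int = 50, pseudo: float = 1.0
) -> list[str]:
    """Top-k features by |log2 ratio| between the two sorted profiles."""
    if signatures.shape[1] != 2:
        raise ValueError("expected exactly two cell-type signature columns")
    cpm = _cpm(signatures)
    ratio = np.log2((cpm.iloc[:, 0] + pseudo) / (cpm.iloc[:, 1] + pseudo))
    order = ratio.abs().sort_values(ascending=False)
    return list(order.index[:k])


def estimate_fractions(
    bulk: pd.DataFrame,
    signatures: pd.DataFrame,
    features: list[str] | None = None,
    sum_to_one: bool = True,
) -> CellFractions:
    """Non-negative least squares of each bulk CPM profile on the
    signature CPM matrix, renormalized to sum to one.

    ``bulk``: features x samples counts (or abundances); ``signatures``:
    features x cell types.  Scale-invariant in the bulk profile.
    """
    if features is None:
        features = [f for f in signatures.index if f in bulk.index]
    if len(features) < 2:
        raise ValueError("need at least two shared signature features")
    sig = _cpm(signatures).loc[features].to_numpy(dtype=float)
    if np.allclose(sig[:, 0], sig[:, 1]):
        raise ValueError("signatures collinear: cell-type profiles are identical")
    blk = _cpm(bulk.loc[bulk.index.intersection(features)].reindex(features).fillna(0.0))
    fracs = []
    resid = []
    for s in blk.columns:
        y = blk[s].to_numpy(dtype=float)
        coef, rnorm = nnls(sig, y)
        total = coef.sum()
        if sum_to_one:
            coef = coef / total if total > 0 else np.full_like(coef, 1.0 / coef.size)
        fracs.append(coef)
        resid.append(rnorm)
    fractions = pd.DataFrame(
        fracs, index=blk.columns, columns=[str(c) for c in signatures.columns]
    )
    return CellFractions(fractions, pd.Series(resid, index=blk.columns, name="residual_norm"))


def sensitivity_reanalysis(
    rerun,
    covariates: pd.DataFrame | None,
    fractions: CellFractions,
    cell_type: str | None = None,
) -> pd.DataFrame:
    """Re-run an association scan with one cell-fraction covariate added
    and compare paired effect sizes.

    ``rerun(covariates)`` must execute the scan (eQTL or DE) with the given
    covariate frame and return a result table containing a ``beta`` or
    ``log2fc`` column keyed identically across calls.  Only one cell type's
    fraction is added (default: the second column, conventionally the
    beta-cell fraction) since the pair is collinear under sum-to-one; a
    constant fraction vector is dropped with a warning, making the two
    fits identical by construction.

    Returns the paired table with columns ``beta_without, beta_with`` plus
    ``pearson_r`` and ``max_abs_delta`` attributes in ``DataFrame.attrs``.
    """
    base = rerun(covariates)
    cell_type = cell_type or str(fractions.fractions.columns[-1])
    frac = fractions.fractions[cell_type]
    degenerate = float(np.ptp(frac.to_numpy())) == 0.0
    if degenerate:
        warnings.warn("cell-fraction covariate is constant; comparison degenerate")
        cov_with = covariates
    else:
        if covariates is None:
            cov_with = pd.DataFrame({f"frac_{cell_type}": frac.to_numpy()})
        else:
            cov_with = covariates.copy()
            cov_with[f"frac_{cell_type}"] = frac.to_numpy()
    augmented = rerun(cov_with)
    effect_col = "beta" if "beta" in base.columns else "log2fc"
    keys = [c for c in ("variant_id", "feature_id", "phenotype") if c in base.columns]
    merged = base.merge(augmented, on=keys, suffixes=("_without", "_with"))
    merged = merged.rename(
        columns={f"{effect_col}_without": "beta_without", f"{effect_col}_with": "beta_with"}
    )
    paired = merged[keys + ["beta_without", "beta_with"]].dropna()
    if len(paired) >= 2 and paired["beta_without"].std() > 0 and paired["beta_with"].std() > 0:
        r = float(np.corrcoef(paired["beta_without"], paired["beta_with"])[0, 1])
    else:
        r = float("nan")
    paired.attrs["pearson_r"] = r
    paired.attrs["max_abs_delta"] = float(
        (paired["beta_without"] - paired["beta_with"]).abs().max()
    ) if len(paired) else float("nan")
    return paired
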