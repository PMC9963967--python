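"""REML heritability and cis/trans variance decomposition.

Model
-----
For a transformed expression vector ``y`` (n samples),

    y = W a + u_cis + u_trans + e,
    u_cis   ~ N(0, sigma2_cis  * K_cis),
    u_trans ~ N(0, sigma2_trans * K_trans),
    e       ~ N(0, sigma2_e * I),

with ``K_cis``/``K_trans`` standardized-dosage GRMs built from variants
inside/outside the feature's cis window.  Restricted maximum likelihood
(REML) estimates the variance components under non-negativity (enforced
by optimizing the square roots), and

    hg2     = (s2_cis + s2_trans) / (s2_cis + s2_trans + s2_e)
    h_cis   = s2_cis / total,   h_trans = s2_trans / total.

A transcript is called *heritable* when hg2 >= 0.9 (the classification
uses the single-component fit on the genome-wide GRM; the two-component
decomposition is run on heritable transcripts).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.linalg import cho_factor, cho_solve

from .grm import KinshipMatrix

__all__ = [
    "VarianceDecomposition",
    "HeritabilityEstimate",
    "ClassComparison",
    "transform_expression",
    "fit_two_component",
    "fit_single_component",
    "compare_heritable_fractions",
    "compare_htrans",
    "HERITABLE_THRESHOLD",
]

HERITABLE_THRESHOLD = 0.9


@dataclass
class VarianceDecomposition:
    """Per-feature variance components and derived heritability fractions."""

    feature_id: str
    sigma2_cis: float
    sigma2_trans: float
    sigma2_e: float
    loglik: float
    converged: bool
    window_size: float = float("nan")

    @property
    def total(self) -> float:
        return self.sigma2_cis + self.sigma2_trans + self.sigma2_e

    @property
    def hg2(self) -> float:
        return (self.sigma2_cis + self.sigma2_trans) / self.total

    @property
    def h_cis(self) -> float:
        return self.sigma2_cis / self.total

    @property
    def h_trans(self) -> float:
        return self.sigma2_trans / self.total

    @property
    def heritable(self) -> bool:
        return self.hg2 >= HERITABLE_THRESHOLD


@dataclass
class HeritabilityEstimate:
    """Single-component (genome-wide GRM) SNP-heritability fit."""

    feature_id: str
    sigma2_g: float
    sigma2_e: float
    hg2: float
    loglik: float
    converged: bool

    @property
    def heritable(self) -> bool:
        return self.hg2 >= HERITABLE_THRESHOLD


@dataclass
class ClassComparison:
    """Heritable-fraction chi-squared and h_trans Mann-Whitney comparison."""

    counts: np.ndarray | None = None
    chi2: float = float("nan")
    p_chi2: float = float("nan")
    u_stat: float = float("nan")
    p_mwu: float = float("nan")
    htrans_a: np.ndarray | None = None
    htrans_b: np.ndarray | None = None


# ---------------------------------------------------------------------------
# expression transform
# ---------------------------------------------------------------------------


def _int_row(x: np.ndarray) -> np.ndarray:
    n = x.size
    r = stats.rankdata(x, method="average")
    q = stats.norm.ppf((r - 0.375) / (n + 0.25))  # Blom offsets
    q = q - q.mean()
    return q / q.std(ddof=0)


def transform_expression(
    counts: pd.DataFrame,
    method: str = "rank-inverse-normal",
    on_constant: str = "error",
) -> pd.DataFrame:
    """Transform a features x samples count matrix for Gaussian modelling.

    ``rank-inverse-normal`` maps each feature to normal quantiles of its
    (average-tied) ranks and standardizes to exact mean 0 / variance 1;
    ``size-factor-log`` is log2(count / size factor + 0.5).
    Constant features raise by default; ``on_constant='skip'`` drops them
    with a warning (batch mode).
    """
    if (counts.to_numpy() < 0).any():
        raise ValueError("counts must be non-negative")
    if method in {"rank-inverse-normal", "int"}:
        rows = {}
        for fid, row in counts.iterrows():
            x = row.to_numpy(dtype=float)
            if np.all(x == x[0]):
                if on_constant == "skip":
                    warnings.warn(f"constant feature {fid!r} skipped by INT")
                    continue
                raise ValueError(f"constant feature {fid!r}: INT ranks undefined")
            rows[fid] = _int_row(x)
        return pd.DataFrame.from_dict(rows, orient="index", columns=counts.columns)
    if method in {"size-factor-log", "log"}:
        from .de import size_factors

        sf = size_factors(counts)
        return np.log2(counts / sf + 0.5)
    raise ValueError(f"unknown transform method {method!r}")


# ---------------------------------------------------------------------------
# REML core
# ---------------------------------------------------------------------------


def _as_matrix(k: KinshipMatrix | np.ndarray) -> np.ndarray:
    return k.values if isinstance(k, KinshipMatrix) else np.asarray(k, dtype=float)


def _design(n: int, covariates: np.ndarray | None) -> np.ndarray:
    if covariates is None:
        return np.ones((n, 1))
    w = np.atleast_2d(np.asarray(covariates, dtype=float))
    if w.shape[0] != n:
        w = w.T
    if not np.any(np.all(w == w[0, :], axis=0) & (w[0, :] != 0)):
        w = np.column_stack([np.ones(n), w])
    return w


def _reml_nll_grad(
    s: np.ndarray, y: np.ndarray, w: np.ndarray, ks: list[np.ndarray]
) -> tuple[float, np.ndarray]:
    """Negative restricted log-likelihood and gradient in sqrt-variances s.

    sigma2_k = s_k**2; the last element of ``ks`` must be the identity.
    """
    n = y.size
    sig = s * s
    v = sum(sg * k for sg, k in zip(sig, ks))
    v[np.diag_indices(n)] += 1e-9  # numerical floor
    try:
        c = cho_factor(v, lower=True)
    except np.linalg.LinAlgError:
        return 1e10, np.zeros_like(s)
    vinv = cho_solve(c, np.eye(n))
    a = vinv @ w
    b = w.T @ a
    try:
        binv = np.linalg.inv(b)
    except np.linalg.LinAlgError:
        return 1e10, np.zeros_like(s)
    p = vinv - a @ binv @ a.T
    py = p @ y
    logdet_v = 2.0 * np.sum(np.log(np.diag(c[0])))
    sign, logdet_b = np.linalg.slogdet(b)
    nll = 0.5 * (logdet_v + logdet_b + float(y @ py))
    grad = np.empty_like(s)
    for i, k in enumerate(ks):
        d_sig = 0.5 * (np.einsum("ij,ji->", p, k) - float(py @ (k @ py)))
        grad[i] = d_sig * 2.0 * s[i]
    return nll, grad


def _profiled_nll(
    fracs: np.ndarray, y: np.ndarray, w: np.ndarray, ks: list[np.ndarray]
) -> tuple[float, float]:
    """Restricted NLL with total variance profiled out, at fixed fractions.

    ``fracs`` are the variance fractions of each component (identity last
    implied as 1 - sum).  Returns (nll, profiled total variance).
    """
    n, p_rank = y.size, w.shape[1]
    h = np.append(fracs, 1.0 - fracs.sum())
    v0 = sum(f * k for f, k in zip(h, ks))
    v0[np.diag_indices(n)] += 1e-9
    try:
        c = cho_factor(v0, lower=True)
    except np.linalg.LinAlgError:
        return 1e10, np.nan
    vinv = cho_solve(c, np.eye(n))
    a = vinv @ w
    b = w.T @ a
    binv = np.linalg.inv(b)
    p = vinv - a @ binv @ a.T
    ypy = float(y @ (p @ y))
    if ypy <= 0:
        return 1e10, np.nan
    s2 = ypy / (n - p_rank)
    logdet_v0 = 2.0 * np.sum(np.log(np.diag(c[0])))
    _, logdet_b = np.linalg.slogdet(b)
    nll = 0.5 * (logdet_v0 + logdet_b + (n - p_rank) * (1.0 + np.log(s2)))
    return nll, s2


def _fit_reml(
    y: np.ndarray,
    w: np.ndarray,
    ks: list[np.ndarray],
    inits: list[np.ndarray],
    grad_tol: float = 1e-4,
) -> tuple[np.ndarray, float, bool]:
    """Best-of-restarts L-BFGS REML in sqrt-variance space; grid fallback."""
    best: tuple[float, np.ndarray, bool] | None = None
    for s0 in inits:
        res = optimize.minimize(
            _reml_nll_grad,
            s0,
            args=(y, w, ks),
            jac=True,
            method="L-BFGS-B",
            options={"maxiter": 200},
        )
        conv = bool(res.success) or float(np.max(np.abs(res.jac))) < grad_tol
        if best is None or res.fun < best[0]:
            best = (float(res.fun), np.asarray(res.x), conv)
    assert best is not None
    nll, s, conv = best
    if not conv:
        # bounded grid over variance fractions, resolution 0.02
        n_comp = len(ks) - 1
        grid = np.arange(0.0, 1.0 + 1e-9, 0.02)
        best_g: tuple[float, np.ndarray] | None = None
        if n_comp == 1:
            combos = [(a,) for a in grid]
        else:
            combos = [(a, b) for a in grid for b in grid if a + b <= 1.0]
        for fr in combos:
            g_nll, s2 = _profiled_nll(np.array(fr), y, w, ks)
            if best_g is None or g_nll < best_g[0]:
                best_g = (g_nll, np.sqrt(np.append(np.array(fr), 1.0 - sum(fr)) * s2))
        assert best_g is not None
        res = optimize.minimize(
            _reml_nll_grad, best_g[1], args=(y, w, ks), jac=True, method="L-BFGS-B",
            options={"maxiter": 200},
        )
        if res.fun < nll:
            nll, s = float(res.fun), np.asarray(res.x)
            conv = bool(res.success) or float(np.max(np.abs(res.jac))) < grad_tol
    return s, nll, conv


def fit_two_component(
    y: np.ndarray,
    k_cis: KinshipMatrix | np.ndarray,
    k_trans: KinshipMatrix | np.ndarray,
    covariates: np.ndarray | None = None,
    feature_id: str = "",
    window_size: float = float("nan"),
) -> VarianceDecomposition:
    """REML fit of the cis + trans + noise variance decomposition.

    Restarts from three fixed initializations and keeps the best
    restricted log-likelihood; falls back to a bounded grid over variance
    fractions when none converges.
    """
    y = np.asarray(y, dtype=float)
    kc, kt = _as_matrix(k_cis), _as_matrix(k_trans)
    n = y.size
    if kc.shape != (n, n) or kt.shape != (n, n):
        raise ValueError("kinship dimensions do not match y")
    w = _design(n, covariates)
    if n <= w.shape[1] + 2:
        raise ValueError(f"n = {n} too small for {w.shape[1]} covariates + 2 components")
    vy = float(np.var(y, ddof=1))
    ks = [kc, kt, np.eye(n)]
    inits = [
        np.sqrt(np.array([0.05, 0.05, 0.90]) * vy),
        np.sqrt(np.array([0.30, 0.30, 0.40]) * vy),
        np.sqrt(np.array([0.10, 0.60, 0.30]) * vy),
    ]
    s, nll, conv = _fit_reml(y, w, ks, inits)
    sig = s * s
    return VarianceDecomposition(
        feature_id=feature_id,
        sigma2_cis=float(sig[0]),
        sigma2_trans=float(sig[1]),
        sigma2_e=float(max(sig[2], 1e-12)),
        loglik=-nll,
        converged=conv,
        window_size=window_size,
    )


def fit_single_component(
    y: np.ndarray,
    k_all: KinshipMatrix | np.ndarray,
    covariates: np.ndarray | None = None,
    feature_id: str = "",
    eig: tuple[np.ndarray, np.ndarray] | None = None,
) -> HeritabilityEstimate:
    """Genome-wide SNP heritability hg2 = s2_g / (s2_g + s2_e) by REML.

    Uses the eigendecomposition of the GRM (pass ``eig=(lam, U)`` to reuse
    across features) to reduce each likelihood evaluation to O(n).
    """
    y = np.asarray(y, dtype=float)
    k = _as_matrix(k_all)
    n = y.size
    if k.shape != (n, n):
        raise ValueError("kinship dimensions do not match y")
    if eig is None:
        lam, u = np.linalg.eigh(k)
    else:
        lam, u = eig
    if np.ptp(lam) < 1e-10:
        raise ValueError("unidentifiable: GRM is (proportional to) the identity")
    lam = np.maximum(lam, 0.0)
    w = _design(n, covariates)
    p_rank = w.shape[1]
    yr, wr = u.T @ y, u.T @ w

    def nll_of_h(h: float) -> tuple[float, float]:
        d = h * lam + (1.0 - h) + 1e-9
        dw = wr / d[:, None]
        b = wr.T @ dw
        try:
            binv = np.linalg.inv(b)
        except np.linalg.LinAlgError:
            return 1e10, np.nan
        alpha = binv @ (dw.T @ yr)
        r = yr - wr @ alpha
        ypy = float(r @ (r / d))
        if ypy <= 0:
            return 1e10, np.nan
        s2 = ypy / (n - p_rank)
        _, logdet_b = np.linalg.slogdet(b)
        nll = 0.5 * (np.sum(np.log(d)) + logdet_b + (n - p_rank) * (1 + np.log(s2)))
        return nll, s2

    grid = np.linspace(0.0, 0.999, 101)
    vals = np.array([nll_of_h(h)[0] for h in grid])
    i = int(np.argmin(vals))
    lo, hi = grid[max(i - 1, 0)], grid[min(i + 1, grid.size - 1)]
    res = optimize.minimize_scalar(
        lambda h: nll_of_h(h)[0], bounds=(lo, hi), method="bounded",
        options={"xatol": 1e-6},
    )
    h_hat = float(res.x) if res.fun <= vals[i] else float(grid[i])
    nll, s2_tot = nll_of_h(h_hat)
    return HeritabilityEstimate(
        feature_id=feature_id,
        sigma2_g=h_hat * s2_tot,
        sigma2_e=(1.0 - h_hat) * s2_tot,
        hg2=h_hat,
        loglik=-nll,
        converged=bool(np.isfinite(nll)),
    )


# ---------------------------------------------------------------------------
# class comparisons
# ---------------------------------------------------------------------------


def compare_heritable_fractions(
    flags_a: np.ndarray, flags_b: np.ndarray
) -> ClassComparison:
    """Pearson chi-squared (df=1, no continuity correction) on the 2x2
    heritable-vs-not by class table."""
    fa = np.asarray(flags_a, dtype=bool)
    fb = np.asarray(flags_b, dtype=bool)
    if fa.size == 0 or fb.size == 0:
        raise ValueError("each class needs at least one feature")
    table = np.array(
        [[fa.sum(), fa.size - fa.sum()], [fb.sum(), fb.size - fb.sum()]], dtype=float
    )
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("degenerate table: a marginal total is zero")
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return ClassComparison(counts=table.astype(int), chi2=float(chi2), p_chi2=float(p))


def compare_htrans(htrans_a: np.ndarray, htrans_b: np.ndarray) -> ClassComparison:
    """Two-sided Mann-Whitney U on h_trans; exact when min(n, m) <= 8 and
    tie-free, else normal approximation with tie and continuity correction."""
    a = np.asarray(htrans_a, dtype=float)
    b = np.asarray(htrans_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("each class needs at least one value")
    no_ties = np.unique(np.concatenate([a, b])).size == a.size + b.size
    method = "exact" if (min(a.size, b.size) <= 8 and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return ClassComparison(
        u_stat=float(res.statistic), p_mwu=float(res.pvalue), htrans_a=a, htrans_b=b
    )
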