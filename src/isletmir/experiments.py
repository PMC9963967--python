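"""Reproducible simulation studies exercising the pipeline end to end.

Each function runs one calibration/recovery experiment on synthetic data
with known ground truth and returns the summary metrics.  They are used
by the test suite and by ``scripts/acceptance.py``; all randomness is
controlled by the ``seed`` argument.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from . import coloc, de, decon, grm, qtl, simulate, varcomp


def _base(seed: int) -> int:
    """Derived-seed base; keeps every spawned seed well below 2**31."""
    return (int(seed) % 20_000) * 100_000

__all__ = [
    "reml_recovery",
    "null_heritability",
    "class_comparison",
    "coloc_calibration",
    "credible_set_coverage",
    "de_error_control",
    "interaction_type1",
    "deconvolution_recovery",
]


def reml_recovery(
    n_reps: int = 50,
    n_samples: int = 200,
    n_variants: int = 500,
    h2_cis: float = 0.2,
    h2_trans: float = 0.4,
    seed: int = 0,
) -> dict:
    """Two-component REML parameter recovery on latent expression."""
    est_c, est_t = [], []
    feats = simulate.default_features(1)
    for rep in range(n_reps):
        cfg = simulate.SimConfig(
            n_samples=n_samples, n_variants=n_variants,
            h2_cis=h2_cis, h2_trans=h2_trans, seed=_base(seed) + rep,
        )
        gm = simulate.simulate_genotypes(cfg)
        _, latent, _ = simulate.simulate_expression(gm, feats, cfg)
        y = latent.iloc[0].to_numpy()
        cis, trans = grm.partition_cis_trans(gm.variants, feats[0], cfg.window_size)
        fit = varcomp.fit_two_component(
            y, grm.compute_grm(gm, cis), grm.compute_grm(gm, trans)
        )
        est_c.append(fit.h_cis)
        est_t.append(fit.h_trans)
    return {
        "mean_h_cis": float(np.mean(est_c)),
        "mean_h_trans": float(np.mean(est_t)),
        "mae_h_cis": float(np.mean(np.abs(np.array(est_c) - h2_cis))),
        "mae_h_trans": float(np.mean(np.abs(np.array(est_t) - h2_trans))),
        "n_reps": n_reps,
    }


def null_heritability(
    n_reps: int = 50, n_samples: int = 200, n_variants: int = 500, seed: int = 0
) -> dict:
    """Single-component hg2 on pure-noise expression (true hg2 = 0)."""
    cfg = simulate.SimConfig(n_samples=n_samples, n_variants=n_variants, seed=seed)
    gm = simulate.simulate_genotypes(cfg)
    k = grm.compute_grm(gm)
    lam, u = np.linalg.eigh(k.values)
    rng = np.random.default_rng(seed + 1)
    est = [
        varcomp.fit_single_component(
            rng.normal(size=n_samples), k, eig=(lam, u)
        ).hg2
        for _ in range(n_reps)
    ]
    return {"mean_hg2": float(np.mean(est)), "n_reps": n_reps}


def _simulate_class(
    h2_cis: float,
    h2_trans: float,
    heritable_fraction: float,
    n_features: int,
    seed: int,
    n_samples: int,
    n_variants: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate one feature class; return (heritable flags, h_trans of
    estimated-heritable features).  Non-heritable features get a weak
    genetic background (h2 = 0.02/0.05)."""
    cfg0 = simulate.SimConfig(
        n_samples=n_samples, n_variants=n_variants,
        h2_cis=h2_cis, h2_trans=h2_trans, seed=seed,
    )
    gm = simulate.simulate_genotypes(cfg0)
    feats = simulate.default_features(1)
    cis, trans = grm.partition_cis_trans(gm.variants, feats[0], cfg0.window_size)
    kc = grm.compute_grm(gm, cis)
    kt = grm.compute_grm(gm, trans)
    ka = grm.compute_grm(gm)
    lam, u = np.linalg.eigh(ka.values)
    rng = np.random.default_rng(seed)
    flags, hts = [], []
    for i in range(n_features):
        is_heritable = rng.uniform() < heritable_fraction
        cfg = dataclasses.replace(
            cfg0,
            seed=seed + i + 1,
            h2_cis=h2_cis if is_heritable else 0.02,
            h2_trans=h2_trans if is_heritable else 0.05,
        )
        _, latent, _ = simulate.simulate_expression(gm, feats, cfg)
        y = latent.iloc[0].to_numpy()
        single = varcomp.fit_single_component(y, ka, eig=(lam, u))
        flags.append(single.heritable)
        if single.heritable:
            hts.append(varcomp.fit_two_component(y, kc, kt).h_trans)
    return np.asarray(flags), np.asarray(hts)


def class_comparison(
    n_per_class: int = 200,
    n_samples: int = 200,
    n_variants: int = 400,
    seed: int = 0,
) -> dict:
    """miRNA-like (trans-dominant) vs mRNA-like (mixed cis/trans) classes.

    Heritable truth: (h2_cis, h2_trans) = (0.08, 0.82) for miRNA-like and
    (0.45, 0.45) for mRNA-like (both total 0.9); the mRNA-like class has
    a larger heritable fraction, mirroring the contrast under study.
    """
    flags_mir, ht_mir = _simulate_class(
        0.08, 0.82, 0.35, n_per_class, _base(seed) + 1, n_samples, n_variants
    )
    flags_mrna, ht_mrna = _simulate_class(
        0.45, 0.45, 0.60, n_per_class, _base(seed) + 50_000, n_samples, n_variants
    )
    mwu = varcomp.compare_htrans(ht_mir, ht_mrna)
    chi2 = varcomp.compare_heritable_fractions(flags_mir, flags_mrna)
    return {
        "median_htrans_mirna_like": float(np.median(ht_mir)),
        "median_htrans_mrna_like": float(np.median(ht_mrna)),
        "p_mwu": mwu.p_mwu,
        "chi2": chi2.chi2,
        "p_chi2": chi2.p_chi2,
        "n_heritable_mirna_like": int(flags_mir.sum()),
        "n_heritable_mrna_like": int(flags_mrna.sum()),
    }


def coloc_calibration(
    n_reps: int = 100, n_snps: int = 100, n: int = 5000, seed: int = 0
) -> dict:
    """Median PP4 under shared-causal and PP3 under distinct-causal sims."""
    pp4s, pp3s = [], []
    for rep in range(n_reps):
        s1, s2, _ = simulate.simulate_gwas_pair(
            n_snps, shared=True, n1=n, n2=n, seed=_base(seed) + rep
        )
        pp4s.append(coloc.coloc_abf(s1, s2).pp4)
        s1, s2, _ = simulate.simulate_gwas_pair(
            n_snps, shared=False, n1=n, n2=n, seed=_base(seed) + 50_000 + rep
        )
        pp3s.append(coloc.coloc_abf(s1, s2).pp3)
    return {
        "median_pp4_shared": float(np.median(pp4s)),
        "median_pp3_distinct": float(np.median(pp3s)),
        "n_reps": n_reps,
    }


def credible_set_coverage(
    n_reps: int = 500, n_snps: int = 100, n: int = 5000, seed: int = 0
) -> dict:
    """Fraction of single-causal sims whose 99% set contains the causal SNP."""
    hits = 0
    for rep in range(n_reps):
        s1, _, truth = simulate.simulate_gwas_pair(
            n_snps, shared=True, n1=n, n2=10, seed=_base(seed) + rep
        )
        labf = np.asarray(
            coloc.wakefield_labf(s1["beta"].to_numpy(), s1["se"].to_numpy())
        )
        cs = coloc.credible_set_99(labf, list(s1["variant_id"]))
        hits += truth.extras["causal_trait1"] in cs.variant_ids
    return {"coverage": hits / n_reps, "n_reps": n_reps}


def de_error_control(
    n_reps: int = 50,
    n_features: int = 200,
    strata_sizes: tuple[int, ...] = (57, 6),
    alt_fraction: float = 0.1,
    alt_lfc: float = 1.5,
    seed: int = 0,
) -> dict:
    """DE -> meta -> threshold chain under a pure null and a 10% alternative."""
    rng = np.random.default_rng(seed)
    null_zero = 0
    sens, fdrs = [], []
    for rep in range(n_reps):
        # pure null
        frames = []
        for si, n in enumerate(strata_sizes):
            ph = rng.binomial(1, 0.5, size=n)
            while np.ptp(ph) == 0:
                ph = rng.binomial(1, 0.5, size=n)
            counts, _ = simulate.simulate_de_counts(
                n, n_features, ph, 0.0, seed=_base(seed) + rep * 10 + si
            )
            frames.append(de.nb_wald_de(counts, ph, stratum=f"lp{si}"))
        null_zero += len(de.apply_de_thresholds(de.ivw_meta(frames))) == 0
        # alternative
        n_alt = int(round(alt_fraction * n_features))
        lfc = np.zeros(n_features)
        alt_idx = rng.choice(n_features, n_alt, replace=False)
        lfc[alt_idx] = rng.choice([-alt_lfc, alt_lfc], size=n_alt)
        frames = []
        for si, n in enumerate(strata_sizes):
            ph = rng.binomial(1, 0.5, size=n)
            while np.ptp(ph) == 0:
                ph = rng.binomial(1, 0.5, size=n)
            counts, _ = simulate.simulate_de_counts(
                n, n_features, ph, lfc, seed=_base(seed) + 50_000 + rep * 10 + si
            )
            frames.append(de.nb_wald_de(counts, ph, stratum=f"lp{si}"))
        called = set(de.apply_de_thresholds(de.ivw_meta(frames)))
        truth_set = {f"mir{i:04d}" for i in alt_idx}
        tp = len(called & truth_set)
        sens.append(tp / n_alt)
        fdrs.append((len(called) - tp) / max(len(called), 1))
    return {
        "null_zero_call_fraction": null_zero / n_reps,
        "sensitivity": float(np.mean(sens)),
        "empirical_fdr": float(np.mean(fdrs)),
        "n_reps": n_reps,
    }


def interaction_type1(n_reps: int = 500, n: int = 33, seed: int = 0) -> dict:
    """Type-I error of the genotype x miRNA interaction Wald test."""
    rng = np.random.default_rng(seed)
    rej = 0
    for _ in range(n_reps):
        g = rng.binomial(2, 0.3, size=n).astype(float)
        while np.ptp(g) == 0:
            g = rng.binomial(2, 0.3, size=n).astype(float)
        m = rng.normal(size=n)
        y = 0.3 * g + 0.2 * m + rng.normal(size=n)  # main effects, no interaction
        rej += qtl.interaction_test(y, g, m).p < 0.05
    return {"type1_error": rej / n_reps, "n_reps": n_reps, "n_samples": n}


def deconvolution_recovery(
    n_samples: int = 100, n_signature_features: int = 50, seed: int = 0
) -> dict:
    """Fraction RMSE under a noiseless mixture and under NB noise."""
    rng = np.random.default_rng(seed)
    sig = simulate.simulate_signatures(n_signature_features, seed=seed)
    alpha = rng.uniform(0.05, 0.95, size=n_samples)
    import pandas as pd

    fractions = pd.DataFrame(
        {"alpha": alpha, "beta": 1 - alpha},
        index=[f"S{i:03d}" for i in range(n_samples)],
    )
    out = {}
    for label, phi in (("noiseless", 0.0), ("nb_noise", 0.1)):
        bulk, truth = simulate.simulate_mixture(
            sig, fractions, nb_dispersion=phi, seed=seed + 1
        )
        est = decon.estimate_fractions(bulk, sig)
        err = est.fractions["alpha"].to_numpy() - alpha
        out[f"rmse_{label}"] = float(np.sqrt(np.mean(err**2)))
    out["n_samples"] = n_samples
    return out
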