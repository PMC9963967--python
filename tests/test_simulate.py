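import numpy as np
import pandas as pd
import pytest
from scipy import stats

from isletmir import simulate
from isletmir.simulate import SimConfig


class TestGenotypes:
    def test_binomial_mean_at_half(self):
        cfg = SimConfig(n_samples=10_000, n_variants=1, maf_range=(0.5, 0.5), seed=3)
        gm = simulate.simulate_genotypes(cfg)
        se = np.sqrt(0.5 / 10_000)  # var of mean dosage = 2 f (1-f) / n
        assert abs(gm.dosages.mean() - 1.0) < 3 * se

    def test_seed_determinism(self):
        cfg = SimConfig(n_samples=50, n_variants=20, seed=9)
        a = simulate.simulate_genotypes(cfg)
        b = simulate.simulate_genotypes(cfg)
        np.testing.assert_array_equal(a.dosages, b.dosages)

    def test_ld_copy_without_flips_is_perfect(self):
        cfg = SimConfig(n_samples=200, n_variants=10, seed=4, ld_flip_prob=0.0)
        gm = simulate.simulate_genotypes(cfg)
        for j in range(1, 10, 2):
            r = np.corrcoef(gm.dosages[:, j - 1], gm.dosages[:, j])[0, 1]
            assert r**2 == pytest.approx(1.0)

    @pytest.mark.parametrize("bad", [(0.0, 0.5), (0.1, 0.6), (-0.1, 0.3)])
    def test_invalid_maf_range_rejected(self, bad):
        with pytest.raises(ValueError, match="maf_range"):
            SimConfig(maf_range=bad)


class TestExpression:
    def test_realized_fractions_hit_targets(self):
        cfg = SimConfig(n_samples=150, n_variants=300, h2_cis=0.25, h2_trans=0.35, seed=5)
        gm = simulate.simulate_genotypes(cfg)
        feats = simulate.default_features(3)
        _, _, truth = simulate.simulate_expression(gm, feats, cfg)
        for fid in truth.realized_h2_cis:
            assert truth.realized_h2_cis[fid] == pytest.approx(0.25, abs=0.02)
            assert truth.realized_h2_trans[fid] == pytest.approx(0.35, abs=0.02)

    def test_null_latent_gives_uniform_association_p(self):
        cfg = SimConfig(n_samples=300, n_variants=500, h2_cis=0.0, h2_trans=0.0, seed=6)
        gm = simulate.simulate_genotypes(cfg)
        feats = simulate.default_features(1)
        _, latent, _ = simulate.simulate_expression(gm, feats, cfg)
        y = latent.iloc[0].to_numpy()
        g = gm.dosages - gm.dosages.mean(axis=0)
        yc = y - y.mean()
        gss = np.einsum("ij,ij->j", g, g)
        beta = (g.T @ yc) / gss
        resid = yc[:, None] - g * beta
        se = np.sqrt(np.einsum("ij,ij->j", resid, resid) / (y.size - 2) / gss)
        p = 2 * stats.t.sf(np.abs(beta / se), y.size - 2)
        assert stats.kstest(p, "uniform").pvalue > 0.01

    def test_poisson_limit_variance_matches_mean(self):
        # phi -> 0 with constant per-feature mixture means: var/mean -> 1
        sig = simulate.simulate_signatures(20, seed=7)
        fractions = pd.DataFrame(
            {"alpha": np.full(2000, 0.5), "beta": np.full(2000, 0.5)},
            index=[f"S{i}" for i in range(2000)],
        )
        bulk, _ = simulate.simulate_mixture(
            sig, fractions, nb_dispersion=0.0, depth=2_000, seed=8
        )
        means = bulk.mean(axis=1)
        big = means > 50  # mean ~100 features
        ratio = bulk.var(axis=1, ddof=1)[big] / means[big]
        assert np.all(np.abs(ratio - 1.0) < 0.10)

    def test_no_cis_variants_with_positive_h2_cis_errors(self):
        cfg = SimConfig(n_samples=50, n_variants=20, cis_fraction=0.0, seed=1)
        gm = simulate.simulate_genotypes(cfg)
        feats = simulate.default_features(1)
        with pytest.raises(ValueError, match="no cis variants"):
            simulate.simulate_expression(gm, feats, cfg)

    def test_seed_determinism(self):
        cfg = SimConfig(n_samples=60, n_variants=100, seed=11)
        gm = simulate.simulate_genotypes(cfg)
        feats = simulate.default_features(2)
        a, _, _ = simulate.simulate_expression(gm, feats, cfg)
        b, _, _ = simulate.simulate_expression(gm, feats, cfg)
        pd.testing.assert_frame_equal(a, b)


class TestGwasPair:
    def test_null_mean_abs_z_is_root_two_over_pi(self):
        s1, _, _ = simulate.simulate_gwas_pair(1000, shared=True, effect_size=0.0, seed=12)
        mean_abs_z = np.mean(np.abs(s1["beta"] / s1["se"]))
        assert mean_abs_z == pytest.approx(np.sqrt(2 / np.pi), abs=0.05)

    def test_shared_flag_controls_causal_identity(self):
        _, _, t_shared = simulate.simulate_gwas_pair(50, shared=True, seed=13)
        assert t_shared.extras["causal_trait1"] == t_shared.extras["causal_trait2"]
        _, _, t_diff = simulate.simulate_gwas_pair(50, shared=False, seed=13)
        assert t_diff.extras["causal_trait1"] != t_diff.extras["causal_trait2"]

    def test_distinct_causals_need_two_snps(self):
        with pytest.raises(ValueError, match=">= 2 SNPs"):
            simulate.simulate_gwas_pair(1, shared=False, seed=0)

    def test_seed_determinism(self):
        a1, a2, _ = simulate.simulate_gwas_pair(30, shared=True, seed=14)
        b1, b2, _ = simulate.simulate_gwas_pair(30, shared=True, seed=14)
        pd.testing.assert_frame_equal(a1, b1)
        pd.testing.assert_frame_equal(a2, b2)


class TestMixture:
    def test_degenerate_mixture_recovers_signature(self):
        sig = simulate.simulate_signatures(30, seed=15)
        fractions = pd.DataFrame(
            {"alpha": np.ones(50), "beta": np.zeros(50)},
            index=[f"S{i}" for i in range(50)],
        )
        bulk, _ = simulate.simulate_mixture(
            sig, fractions, nb_dispersion=0.0, depth=1e6, seed=16
        )
        expected = sig["alpha"] / sig["alpha"].sum() * 1e6
        observed = bulk.mean(axis=1)
        big = expected > 1_000
        rel = np.abs(observed[big] - expected[big]) / expected[big]
        assert np.all(rel < 0.05)

    def test_half_half_mixture_is_linear(self):
        sig = pd.DataFrame({"alpha": [100, 0], "beta": [0, 100]}, index=["g1", "g2"])
        fractions = pd.DataFrame(
            {"alpha": np.full(4000, 0.5), "beta": np.full(4000, 0.5)},
            index=[f"S{i}" for i in range(4000)],
        )
        bulk, _ = simulate.simulate_mixture(
            sig, fractions, nb_dispersion=0.0, depth=100, seed=17
        )
        np.testing.assert_allclose(bulk.mean(axis=1), [50, 50], rtol=0.05)

    def test_negative_fraction_rejected(self):
        sig = simulate.simulate_signatures(10, seed=18)
        fractions = pd.DataFrame({"alpha": [-0.1], "beta": [1.1]}, index=["S0"])
        with pytest.raises(ValueError, match="non-negative"):
            simulate.simulate_mixture(sig, fractions)


class TestCovariatesAndBundle:
    def test_covariate_distributions(self):
        cfg = SimConfig(n_samples=4000, seed=19)
        meta = simulate.simulate_covariates(cfg)
        assert meta["sex"].mean() == pytest.approx(0.5, abs=0.05)
        assert meta["t2d"].mean() == pytest.approx(4 / 63, abs=0.02)
        # PGS correlates with the T2D liability through the shared component
        assert meta.loc[meta["t2d"] == 1, "pgs"].mean() > meta["pgs"].mean()

    def test_bundle_written_and_truth_loadable(self, tmp_path):
        cfg = SimConfig(n_samples=30, n_variants=60, seed=20)
        paths = simulate.simulate_bundle(tmp_path / "bundle", cfg)
        for p in paths.values():
            assert p.exists() and p.stat().st_size > 0
        truth = simulate.SimTruth.from_json(paths["truth"])
        assert truth.causal_variants and truth.cell_fractions
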