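import numpy as np
import pandas as pd
import pytest
from scipy import stats

from isletmir import qtl, simulate
from isletmir.simulate import SimConfig

from conftest import make_genotypes


def _expr(y, feature_id="mirA", samples=None):
    y = np.atleast_2d(np.asarray(y, dtype=float))
    samples = samples or [f"S{i}" for i in range(y.shape[1])]
    return pd.DataFrame(y, index=[feature_id], columns=samples)


class TestAssocScan:
    def test_exact_linear_relation_recovered(self, rng):
        g = rng.binomial(2, 0.4, size=30).astype(float)
        gm = make_genotypes(g[:, None])
        res = qtl.assoc_scan(_expr(0.5 * g), gm, None, {"mirA": ["v0"]})
        assert res.loc[0, "beta"] == pytest.approx(0.5)
        assert res.loc[0, "p"] < 1e-200

    def test_permuted_null_p_uniform(self):
        cfg = SimConfig(n_samples=200, n_variants=1000, seed=31)
        gm = simulate.simulate_genotypes(cfg)
        rng = np.random.default_rng(31)
        y = rng.normal(size=200)
        res = qtl.assoc_scan(
            _expr(y, samples=gm.sample_ids), gm, None,
            {"mirA": list(gm.variants["variant_id"])},
        )
        assert stats.kstest(res["p"], "uniform").pvalue > 0.01

    def test_power_at_study_scale(self):
        # cis-eQTL explaining 25% of variance at n = 57
        rng = np.random.default_rng(32)
        hits = 0
        for _ in range(100):
            g = rng.binomial(2, 0.3, size=57).astype(float)
            while np.ptp(g) == 0:
                g = rng.binomial(2, 0.3, size=57).astype(float)
            z = (g - g.mean()) / g.std()
            y = np.sqrt(0.25) * z + np.sqrt(0.75) * rng.normal(size=57)
            gm = make_genotypes(g[:, None])
            res = qtl.assoc_scan(_expr(y), gm, None, {"mirA": ["v0"]})
            hits += res.loc[0, "p"] < 1e-3
        assert hits >= 80

    def test_beta_shift_and_flip_invariances(self, rng):
        g = rng.binomial(2, 0.4, size=40).astype(float)
        y = 0.3 * g + rng.normal(size=40)
        res1 = qtl.assoc_scan(_expr(y), make_genotypes(g[:, None]), None, {"mirA": ["v0"]})
        res2 = qtl.assoc_scan(_expr(y + 7.0), make_genotypes(g[:, None]), None, {"mirA": ["v0"]})
        res3 = qtl.assoc_scan(_expr(y), make_genotypes((2 - g)[:, None]), None, {"mirA": ["v0"]})
        assert res2.loc[0, "beta"] == pytest.approx(res1.loc[0, "beta"])
        assert res3.loc[0, "beta"] == pytest.approx(-res1.loc[0, "beta"])

    def test_collinear_covariates_rejected(self, rng):
        g = rng.binomial(2, 0.4, size=30).astype(float)
        cov = np.column_stack([rng.normal(size=30)] * 2)
        with pytest.raises(ValueError, match="collinear"):
            qtl.assoc_scan(_expr(g), make_genotypes(g[:, None]), cov, {"mirA": ["v0"]})

    def test_bh_fdr_control_on_mixture(self):
        # 90% null / 10% strong alternative, BH at 5%: empirical FDR <= 0.07
        rng = np.random.default_rng(33)
        fdrs = []
        for _ in range(200):
            n, m = 100, 200
            g = rng.binomial(2, 0.3, size=(n, m)).astype(float)
            alt = rng.choice(m, 20, replace=False)
            y = rng.normal(size=(n,))
            zalt = (g[:, alt] - g[:, alt].mean(0)) / np.maximum(g[:, alt].std(0), 1e-9)
            y = y + zalt @ np.full(20, 0.6)
            gc = g - g.mean(0)
            yc = y - y.mean()
            gss = np.maximum(np.einsum("ij,ij->j", gc, gc), 1e-12)
            beta = (gc.T @ yc) / gss
            resid = yc[:, None] - gc * beta
            se = np.sqrt(np.einsum("ij,ij->j", resid, resid) / (n - 2) / gss)
            p = 2 * stats.t.sf(np.abs(beta / se), n - 2)
            q = qtl.bh_fdr(np.clip(p, 1e-300, 1))
            called = np.flatnonzero(q <= 0.05)
            fp = len(set(called) - set(alt))
            fdrs.append(fp / max(len(called), 1))
        assert np.mean(fdrs) <= 0.07


class TestBhFdr:
    @pytest.mark.parametrize(
        "p,expected",
        [
            ([0.01, 0.04], [0.02, 0.04]),
            ([0.01, 0.02, 0.03, 0.04], [0.04, 0.04, 0.04, 0.04]),
            ([0.5, 0.5, 0.5], [0.5, 0.5, 0.5]),
        ],
    )
    def test_step_up_hand_examples(self, p, expected):
        np.testing.assert_allclose(qtl.bh_fdr(np.array(p)), expected)

    def test_q_monotone_in_p(self, rng):
        p = rng.uniform(1e-6, 1, size=100)
        q = qtl.bh_fdr(p)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)
        assert np.all(q >= p)

    @pytest.mark.parametrize("bad", [[0.0, 0.5], [0.5, 1.5], [np.nan, 0.5]])
    def test_invalid_p_rejected(self, bad):
        with pytest.raises(ValueError):
            qtl.bh_fdr(np.array(bad))


class TestInteraction:
    def test_exact_interaction_coefficient(self, rng):
        g = rng.binomial(2, 0.4, size=50).astype(float)
        m = rng.normal(size=50)
        y = 1 + g + m + 2 * g * m
        res = qtl.interaction_test(y, g, m)
        assert res.beta == pytest.approx(2.0)

    def test_constant_genotype_rejected(self, rng):
        with pytest.raises(ValueError, match="constant dosage"):
            qtl.interaction_test(rng.normal(size=30), np.ones(30), rng.normal(size=30))

    def test_power_with_strong_interaction(self):
        rng = np.random.default_rng(34)
        hits = 0
        for _ in range(100):
            g = rng.binomial(2, 0.4, size=100).astype(float)
            m = rng.normal(size=100)
            gm_ = g * m
            gm_ = (gm_ - gm_.mean()) / gm_.std()
            y = 0.2 * g + 0.2 * m + np.sqrt(0.2) * gm_ + np.sqrt(0.8) * rng.normal(size=100)
            hits += qtl.interaction_test(y, g, m).p < 0.05
        assert hits >= 70


class TestMrAndMediation:
    def test_wald_ratio_and_delta_se(self):
        res = qtl.mr_wald(0.5, 0.05, 0.25, 0.05)
        assert res.beta_wald == pytest.approx(0.5)
        assert res.se_wald == pytest.approx(np.sqrt(0.01 + 0.0025), rel=1e-9)

    def test_zero_outcome_effect(self):
        assert qtl.mr_wald(0.5, 0.05, 0.0, 0.05).beta_wald == 0.0

    def test_zero_instrument_effect_rejected(self):
        with pytest.raises(ValueError, match="Wald ratio undefined"):
            qtl.mr_wald(0.0, 0.05, 0.25, 0.05)

    def test_weak_instrument_warns(self):
        with pytest.warns(UserWarning, match="weak instrument"):
            qtl.mr_wald(0.05, 0.05, 0.25, 0.05)

    def test_sobel_se_formula(self, rng):
        # construct data, then verify sobel_se against the hand formula
        n = 200
        x = rng.normal(size=n)
        m = 0.5 * x + rng.normal(size=n)
        y = 0.4 * m + rng.normal(size=n)
        res = qtl.mediation_sobel(x, m, y)
        assert res.ab == pytest.approx(res.a * res.b)
        assert res.sobel_se == pytest.approx(
            np.sqrt(res.b**2 * res.se_a**2 + res.a**2 * res.se_b**2), rel=1e-9
        )

    def test_null_mediation_centered_at_zero(self):
        rng = np.random.default_rng(35)
        abs_ = []
        for _ in range(200):
            x = rng.normal(size=60)
            m = rng.normal(size=60)  # mediator independent of exposure
            y = 0.5 * m + rng.normal(size=60)
            abs_.append(qtl.mediation_sobel(x, m, y).ab)
        assert abs(np.mean(abs_)) < 3 * np.std(abs_) / np.sqrt(len(abs_)) + 0.01

    def test_full_mediation_kills_direct_effect(self):
        rng = np.random.default_rng(36)
        directs = []
        for _ in range(100):
            x = rng.normal(size=100)
            m = 0.8 * x + 0.3 * rng.normal(size=100)
            y = 0.7 * m + 0.3 * rng.normal(size=100)  # no direct x -> y path
            directs.append(qtl.mediation_sobel(x, m, y).direct_beta)
        assert abs(np.mean(directs)) < 0.02


class TestConcordance:
    def _frame(self, betas):
        return pd.DataFrame(
            {
                "variant_id": [f"rs{i}" for i in range(len(betas))],
                "feature_id": "mirA",
                "beta": betas,
            }
        )

    def test_identical_effects(self, rng):
        a = self._frame(rng.normal(size=10))
        rho, n = qtl.effect_concordance(a, a.copy())
        assert rho == pytest.approx(1.0)
        assert n == 10

    def test_negated_effects(self, rng):
        a = self._frame(rng.normal(size=10))
        b = a.copy()
        b["beta"] = -b["beta"]
        assert qtl.effect_concordance(a, b)[0] == pytest.approx(-1.0)

    def test_rank_formula_by_hand(self):
        rho, _ = qtl.effect_concordance(self._frame([1, 2, 3]), self._frame([3, 1, 2]))
        assert rho == pytest.approx(-0.5)

    def test_allele_swap_flips_sign(self):
        a = self._frame([1.0, 2.0, 3.0])
        a["ref"], a["alt"] = "A", "G"
        b = a.copy()
        b["ref"], b["alt"] = "G", "A"  # swapped alleles: betas must be flipped
        b["beta"] = -b["beta"]
        rho, _ = qtl.effect_concordance(a, b)
        assert rho == pytest.approx(1.0)

    def test_no_overlap_rejected(self):
        a = self._frame([1, 2, 3])
        b = self._frame([1, 2, 3])
        b["variant_id"] = ["x1", "x2", "x3"]
        with pytest.raises(ValueError, match="no overlapping"):
            qtl.effect_concordance(a, b)
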