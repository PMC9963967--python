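import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from isletmir import coloc
from isletmir.coloc import ColocPriors


def _stats(betas, ses, ids=None, **extra):
    n = len(betas)
    frame = pd.DataFrame(
        {
            "variant_id": ids or [f"rs{i}" for i in range(n)],
            "beta": betas,
            "se": ses,
        }
    )
    for k, v in extra.items():
        frame[k] = v
    return frame


class TestWakefield:
    def test_zero_prior_variance_gives_unit_abf(self):
        assert coloc.wakefield_labf(0.7, 0.1, prior_sd=0.0) == pytest.approx(0.0)

    def test_null_beta_hand_value(self):
        # ABF = sqrt(V/(V+W)) = sqrt(1/1.04)
        labf = coloc.wakefield_labf(0.0, 1.0, prior_sd=0.2)
        assert np.exp(labf) == pytest.approx(0.980580675690920, rel=1e-9)

    def test_strong_signal_hand_value(self):
        # lABF = (ln 0.2 + 25 * 0.8) / 2 = 9.19528104...
        labf = coloc.wakefield_labf(0.5, 0.1, prior_sd=0.2)
        assert labf == pytest.approx(9.19528104378295, rel=1e-9)

    def test_nonpositive_se_rejected(self):
        with pytest.raises(ValueError, match="se"):
            coloc.wakefield_labf(0.5, 0.0)

    def test_case_control_uses_logodds_prior(self):
        q = coloc.wakefield_labf(0.5, 0.1, trait_type="quantitative")
        cc = coloc.wakefield_labf(0.5, 0.1, trait_type="case_control")
        assert q == pytest.approx(coloc.wakefield_labf(0.5, 0.1, prior_sd=0.15))
        assert cc == pytest.approx(coloc.wakefield_labf(0.5, 0.1, prior_sd=0.2))


class TestColocAbf:
    def test_single_shared_snp_enumeration(self):
        # ABF1 = ABF2 = 1e6: PP4 = 1e7 / (1 + 100 + 100 + 1e7), PP3 = 0
        labf = np.log(1e6)
        se = 0.1
        # invert the Wakefield formula: pick beta so lABF = log(1e6)
        w = 0.15**2
        z2 = (2 * labf - np.log(se**2 / (se**2 + w))) * (se**2 + w) / w
        beta = np.sqrt(z2) * se
        s1 = _stats([beta], [se])
        s2 = _stats([beta], [se])
        res = coloc.coloc_abf(s1, s2)
        denom = 1 + 100 + 100 + 1e7
        assert res.pp3 == 0.0
        assert res.pp4 == pytest.approx(1e7 / denom, rel=1e-6)
        assert res.pp0 == pytest.approx(1 / denom, rel=1e-6)

    def test_flat_abfs_configuration_counts(self):
        # all ABFs = 1 over 100 SNPs: posteriors prop. to
        # (1, 100 p1, 100 p2, 9900 p1 p2, 100 p12)
        n = 100
        s1 = _stats(np.zeros(n), np.ones(n))
        s2 = _stats(np.zeros(n), np.ones(n))
        res = coloc.coloc_abf(s1, s2, prior_sd1=0.0, prior_sd2=0.0)
        p1 = p2 = 1e-4
        p12 = 1e-5
        expect = np.array([1, n * p1, n * p2, n * (n - 1) * p1 * p2, n * p12])
        np.testing.assert_allclose(res.pp, expect / expect.sum(), rtol=1e-9)
        assert res.pp0 == max(res.pp)

    def test_posteriors_sum_to_one_and_swap_symmetry(self, rng):
        s1 = _stats(rng.normal(0, 0.3, 50), rng.uniform(0.05, 0.2, 50))
        s2 = _stats(rng.normal(0, 0.3, 50), rng.uniform(0.05, 0.2, 50))
        a = coloc.coloc_abf(s1, s2)
        b = coloc.coloc_abf(s2, s1)
        assert abs(a.pp.sum() - 1.0) < 1e-10
        assert b.pp1 == pytest.approx(a.pp2, rel=1e-9)
        assert b.pp2 == pytest.approx(a.pp1, rel=1e-9)
        assert b.pp3 == pytest.approx(a.pp3, rel=1e-6)
        assert b.pp4 == pytest.approx(a.pp4, rel=1e-9)

    def test_no_shared_snps_rejected(self):
        s1 = _stats([0.1], [0.1], ids=["rs1"])
        s2 = _stats([0.1], [0.1], ids=["rs2"])
        with pytest.raises(ValueError, match="no shared"):
            coloc.coloc_abf(s1, s2)

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(
        betas=st.lists(st.floats(-5, 5), min_size=2, max_size=20),
        scale=st.floats(0.01, 2.0),
    )
    def test_property_simplex_and_overflow_safety(self, betas, scale):
        n = len(betas)
        s1 = _stats(betas, [scale * 0.1] * n)
        s2 = _stats(betas, [0.1] * n)
        res = coloc.coloc_abf(s1, s2)
        assert abs(res.pp.sum() - 1.0) < 1e-10
        assert np.all(res.pp >= 0)


class TestCredibleSet:
    def test_dominant_snp_gives_singleton(self):
        labf = np.log(np.array([1e6, 1.0, 1.0]))
        cs = coloc.credible_set_99(labf, ["a", "b", "c"])
        assert cs.variant_ids == ["a"]

    def test_cumulative_sum_by_hand(self):
        post = np.array([0.6, 0.3, 0.08, 0.015, 0.005])
        labf = np.log(post)  # proportional is enough
        cs = coloc.credible_set_99(labf, list("abcde"))
        assert cs.size == 4
        assert cs.cumulative_mass == pytest.approx(0.995)

    def test_uniform_posteriors_take_99_of_100(self):
        cs = coloc.credible_set_99(np.zeros(100), [f"rs{i:03d}" for i in range(100)])
        assert cs.size == 99

    def test_ties_broken_lexicographically(self):
        cs = coloc.credible_set_99(np.zeros(3), ["c", "a", "b"], level=0.5)
        assert cs.variant_ids == ["a", "b"]

    def test_posteriors_sorted_descending_and_normalized(self, rng):
        labf = rng.normal(0, 3, size=40)
        cs = coloc.credible_set_99(labf, [f"rs{i}" for i in range(40)])
        assert np.all(np.diff(cs.posteriors) <= 1e-12)
        full = np.exp(labf - labf.max())
        assert cs.posteriors.max() == pytest.approx((full / full.sum()).max())


class TestOverlap:
    def _snp(self, pos, vid="rs1"):
        return pd.DataFrame(
            {"variant_id": [vid], "chrom": ["chr1"], "pos": [pos], "signal_id": ["sig1"]}
        )

    def _sites(self, rows):
        return pd.DataFrame(rows, columns=["chrom", "start", "end", "mirna_id", "gene_id"])

    def test_half_open_containment(self):
        sites = self._sites([("chr1", 100, 107, "mirA", "geneX")])
        mirnas = pd.DataFrame(columns=["chrom", "start", "end", "mirna_id"])
        ab = pd.Series({"mirA": 10.0})
        gb = pd.Series({"geneX": 10.0})
        hit, _ = coloc.overlap_credible_with_sites(self._snp(100), mirnas, sites, ab, gb)
        miss, _ = coloc.overlap_credible_with_sites(self._snp(99), mirnas, sites, ab, gb)
        at_end, _ = coloc.overlap_credible_with_sites(self._snp(107), mirnas, sites, ab, gb)
        assert len(hit) == 1 and len(miss) == 0 and len(at_end) == 0

    def test_expression_filters_retained_vs_audit(self):
        # 5 credible SNPs, 2 in sites, 1 passing both expression flags
        snps = pd.DataFrame(
            {
                "variant_id": [f"rs{i}" for i in range(5)],
                "chrom": "chr1",
                "pos": [50, 103, 203, 300, 400],
                "signal_id": "sig1",
            }
        )
        sites = self._sites(
            [("chr1", 100, 107, "mirA", "geneHigh"), ("chr1", 200, 207, "mirA", "geneLow")]
        )
        mirnas = pd.DataFrame(columns=["chrom", "start", "end", "mirna_id"])
        mir_ab = pd.Series({"mirA": 5.0})
        mrna_ab = pd.Series({"geneHigh": 5.0, "geneLow": 0.1})
        retained, audit = coloc.overlap_credible_with_sites(
            snps, mirnas, sites, mir_ab, mrna_ab, expr_threshold=1.0
        )
        assert len(audit) == 2
        assert len(retained) == 1
        assert retained.loc[0, "gene_id"] == "geneHigh"

    def test_mature_mirna_overlap_reported(self):
        mirnas = pd.DataFrame(
            [("chr1", 95, 117, "mirA")], columns=["chrom", "start", "end", "mirna_id"]
        )
        sites = self._sites([])
        retained, audit = coloc.overlap_credible_with_sites(
            self._snp(100), mirnas, sites, pd.Series({"mirA": 5.0}), pd.Series(dtype=float)
        )
        assert audit.loc[0, "interval_kind"] == "mature_mirna"
        assert len(retained) == 1
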