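"""In-vitro screen: mixed-model conditional essentiality, Fisher
combination, sign gates, FDR behavior."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from sr_rescue import synthetic_data as sd
from sr_rescue.cohort import Modality, inverse_normal_transform
from sr_rescue.screen_invitro import combine_fisher
from sr_rescue.screen_invitro import fit_conditional_essentiality, step1_screen
from sr_rescue.screen_invitro import test_du_pair_invitro as invitro_pair_test


class TestConditionalEssentiality:
    def test_single_type_recovers_slope(self):
        rng = np.random.default_rng(0)
        g = rng.normal(size=50)
        y = 0.5 * g + rng.normal(scale=0.1, size=50)
        beta, p = fit_conditional_essentiality(y, g, ["T1"] * 50)
        # y is inverse-normal transformed inside, so compare on that scale
        ref = stats.linregress(g, inverse_normal_transform(y))
        assert beta == pytest.approx(ref.slope, abs=1e-12)
        assert p < 1e-6

    def test_single_type_equals_ols(self):
        rng = np.random.default_rng(1)
        g = rng.normal(size=40)
        y = 0.3 * g + rng.normal(size=40)
        beta, p = fit_conditional_essentiality(y, g, ["T1"] * 40)
        ref = stats.linregress(g, inverse_normal_transform(y))
        assert abs(beta - ref.slope) < 1e-8
        assert abs(p - ref.pvalue) < 1e-8

    def test_random_intercept_removes_confounding(self):
        # two cancer types with different intercepts AND different mean g:
        # pooled OLS is biased, the random-intercept fit is not
        rng = np.random.default_rng(2)
        n = 200
        ct = np.array(["A"] * (n // 2) + ["B"] * (n // 2))
        g = rng.normal(size=n) + np.where(ct == "A", 0.0, 3.0)
        y = 0.5 * g + np.where(ct == "A", 0.0, 4.0) + rng.normal(scale=0.5, size=n)
        beta, p = fit_conditional_essentiality(y, g, ct)
        yn = inverse_normal_transform(y)
        pooled = stats.linregress(g, yn).slope
        within = stats.linregress(g[:100], yn[:100]).slope
        # mixed model sits near the within-type slope, pooled OLS is pulled
        # toward the between-type confounded slope
        assert abs(beta - within) < abs(pooled - within)
        assert p < 1e-6

    def test_matches_statsmodels_mixedlm(self):
        from statsmodels.regression.mixed_linear_model import MixedLM

        rng = np.random.default_rng(3)
        n = 90
        groups = np.repeat([0, 1, 2], n // 3)
        g = rng.normal(size=n)
        y = 0.4 * g + np.array([0.5, -0.3, 0.8])[groups] + rng.normal(size=n)
        yn = inverse_normal_transform(y)
        beta, _ = fit_conditional_essentiality(y, g, groups)
        ref = MixedLM(yn, np.column_stack([np.ones(n), g]), groups).fit(reml=False)
        assert beta == pytest.approx(ref.fe_params[1], abs=1e-4)

    def test_constant_covariate_errors(self):
        with pytest.raises(ValueError, match="constant"):
            fit_conditional_essentiality(np.random.default_rng(4).normal(size=20),
                                         np.ones(20), ["T"] * 20)

    def test_too_few_cell_lines_errors(self):
        with pytest.raises(ValueError, match=">= 10"):
            fit_conditional_essentiality(np.arange(5.0), np.arange(5.0), ["T"] * 5)


class TestFisherCombination:
    def test_single_p_identity(self):
        for p in (0.01, 0.3, 0.77):
            assert combine_fisher([p]) == pytest.approx(p, rel=1e-10)

    def test_two_halves(self):
        assert combine_fisher([0.5, 0.5]) == pytest.approx(0.5966, abs=1e-4)

    def test_all_ones(self):
        assert combine_fisher([1.0, 1.0]) == pytest.approx(1.0)

    def test_nonpositive_clamped(self):
        with pytest.warns(UserWarning, match="clamped"):
            p = combine_fisher([0.0, 0.5])
        assert 0 < p < 1e-100


class TestPairTest:
    def test_planted_pair_both_conditions(self, small_truth, small_panel):
        v, r = small_truth.pairs_of_type("DU")[0]
        res = invitro_pair_test(small_panel, (v, r), Modality.MRNA, "DU")
        assert res["sign_ok_i"] and res["sign_ok_ii"]
        assert res["p_i"] < 1e-4 and res["p_ii"] < 1e-4

    def test_null_pair_not_significant(self, small_panel):
        res = invitro_pair_test(small_panel, ("G0050", "G0051"), Modality.MRNA, "DU")
        assert res["p_i"] > 1e-4 or not res["sign_ok_i"]

    def test_inverted_sign_rejected(self, small_truth, small_panel):
        # a planted DD pair has a negative condition-(i) slope: testing it as
        # DU must gate it out no matter how small the raw p is
        v, r = small_truth.pairs_of_type("DD")[0]
        res = invitro_pair_test(small_panel, (v, r), Modality.MRNA, "DU")
        assert not res["sign_ok_i"]
        assert res["p_i"] == 1.0
        # and tested under its true polarity it passes
        res_dd = invitro_pair_test(small_panel, (v, r), Modality.MRNA, "DD")
        assert res_dd["sign_ok_i"] and res_dd["p_i"] < 1e-4

    def test_missing_readout_skipped(self, small_panel):
        res = invitro_pair_test(small_panel, ("NOPE", "G0050"), Modality.MRNA, "DU")
        assert "skip" in res


@pytest.fixture(scope="module")
def screen_result(small_truth, small_panel):
    planted = small_truth.pairs_of_type("DU")
    nulls = [(f"G{i:04d}", f"G{i + 1:04d}") for i in range(41, 59, 2)]
    return planted, nulls, step1_screen([small_panel], planted + nulls, "DU", fdr=0.2)


class TestStep1Screen:
    def test_planted_pass_nulls_fail(self, screen_result):
        planted, nulls, res = screen_result
        assert all(res.loc[p, "pass_step1"] for p in planted)
        assert sum(res.loc[p, "pass_step1"] for p in nulls) <= 1

    def test_monotone_in_fdr(self, small_truth, small_panel, screen_result):
        planted, nulls, res_loose = screen_result
        res_tight = step1_screen([small_panel], planted + nulls, "DU", fdr=0.05)
        tight = set(res_tight.index[res_tight["pass_step1"]])
        loose = set(res_loose.index[res_loose["pass_step1"]])
        assert tight <= loose

    def test_empty_candidates(self, small_panel):
        assert step1_screen([small_panel], [], "DU").empty

    def test_scna_only_significance_passes(self, small_truth):
        # build a panel whose mRNA profiles are pure noise but whose SCNA
        # profiles carry the planted association: the OR rule must pass it
        panel = sd.generate_screen_panel(small_truth, n_cell_lines=100, n_genes=60)
        rng = np.random.default_rng(99)
        noisy_mrna = panel.profiles_mrna.values.copy()
        noisy_mrna.loc[:, :] = rng.normal(size=noisy_mrna.shape)
        from sr_rescue.cohort import GeneMatrix
        from sr_rescue.screen_invitro import ScreenPanel

        scna_strong = GeneMatrix(panel.profiles_mrna.values.copy(), "SCNA")
        panel2 = ScreenPanel(panel.readouts, panel.cancer_types,
                             GeneMatrix(noisy_mrna, "mRNA"), scna_strong)
        planted = small_truth.pairs_of_type("DU")
        res = step1_screen([panel2], planted, "DU", fdr=0.2)
        assert res["pass_step1"].any()
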