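"""Clinical screen: stratified Cox fits, LRT/Wald behavior, sign gates."""

import numpy as np
import pandas as pd
import pytest
from lifelines import CoxPHFitter

import sr_rescue as sr
from sr_rescue.cohort import ClinicalTable, Modality
from sr_rescue.screen_clinical import (fit_stratified_cox, step3_screen,
                                       tumor_purity_controls)


def simulate_survival(n, beta1, strata_rates, rng, censor_frac=3 / 7):
    """Exponential survival with per-stratum baselines and a binary
    indicator effect exp(beta1)."""
    strata = rng.integers(0, len(strata_rates), size=n)
    ind = rng.choice([0, 1], size=n, p=[0.7, 0.3])
    rate = np.asarray(strata_rates)[strata] * np.exp(beta1 * ind)
    t_death = rng.exponential(1.0 / rate)
    t_cens = rng.exponential(1.0 / (np.asarray(strata_rates)[strata] * censor_frac))
    time = np.minimum(t_death, t_cens)
    event = (t_death <= t_cens).astype(int)
    return ind, time, event, strata.astype(str)


class TestFitStratifiedCox:
    def test_recovers_planted_effect(self):
        rng = np.random.default_rng(0)
        ind, time, event, strata = simulate_survival(1000, 0.7, [1.0, 2.0, 0.5], rng)
        fit = fit_stratified_cox(ind, time, event, None, strata)
        assert fit.beta1 == pytest.approx(0.7, abs=0.2)
        assert fit.p_lrt < 1e-6

    def test_single_stratum_matches_unstratified(self):
        rng = np.random.default_rng(1)
        ind, time, event, _ = simulate_survival(300, 0.5, [1.0], rng)
        fit = fit_stratified_cox(ind, time, event, None, None)
        df = pd.DataFrame({"t": time, "e": event, "x": ind})
        ref = CoxPHFitter().fit(df, duration_col="t", event_col="e")
        assert fit.beta1 == pytest.approx(float(ref.params_["x"]), abs=1e-6)

    def test_stratum_relabeling_invariance(self):
        rng = np.random.default_rng(2)
        ind, time, event, strata = simulate_survival(400, 0.4, [1.0, 3.0], rng)
        fit_a = fit_stratified_cox(ind, time, event, None, strata)
        relabeled = np.where(strata == "0", "zebra", "aardvark")
        fit_b = fit_stratified_cox(ind, time, event, None, relabeled)
        assert fit_a.beta1 == pytest.approx(fit_b.beta1, abs=1e-10)
        assert fit_a.p_lrt == pytest.approx(fit_b.p_lrt, abs=1e-10)

    def test_lrt_and_wald_agree_when_well_conditioned(self):
        # moderate effect: p-values in a range where a factor-2 agreement
        # is meaningful; strong effects agree on the log scale instead
        rng = np.random.default_rng(3)
        ind, time, event, strata = simulate_survival(1000, 0.15, [1.0, 2.0], rng)
        fit = fit_stratified_cox(ind, time, event, None, strata)
        assert fit.p_lrt > 0
        ratio = fit.p_lrt / fit.p_wald
        assert 0.5 < ratio < 2.0
        ind, time, event, strata = simulate_survival(1000, 0.6, [1.0, 2.0], rng)
        strong = fit_stratified_cox(ind, time, event, None, strata)
        assert np.log10(strong.p_lrt) == pytest.approx(np.log10(strong.p_wald),
                                                       rel=0.2)

    def test_degenerate_indicator_errors(self):
        with pytest.raises(ValueError, match="degenerate"):
            fit_stratified_cox(np.ones(50), np.arange(1, 51.0), np.ones(50), None, None)

    def test_small_strata_pooled(self):
        rng = np.random.default_rng(4)
        ind, time, event, strata = simulate_survival(200, 0.5, [1.0], rng)
        tiny = strata.copy()
        tiny[:3] = "rare"  # a stratum with < 10 events must be pooled, not dropped
        fit = fit_stratified_cox(ind, time, event, None, tiny)
        assert fit.n_events == int(event.sum())


class TestPurityControls:
    def _clin(self, extra):
        n = 40
        base = pd.DataFrame({
            "time_days": np.arange(1.0, n + 1), "event": [0, 1] * (n // 2),
            "age": 60.0, "sex": "f", "race": "a", "cancer_type": "T",
            "tumor_purity": np.linspace(0.3, 0.9, n)},
            index=[f"s{i}" for i in range(n)])
        for k, v in extra.items():
            base[k] = v
        return ClinicalTable(base)

    def test_single_column(self):
        cov = tumor_purity_controls(self._clin({}))
        assert list(cov.columns) == ["tumor_purity"]

    def test_five_columns_additive(self):
        extra = {f"purity_{m}": np.linspace(0.2, 0.8, 40) for m in "abcd"}
        cov = tumor_purity_controls(self._clin(extra),
                                    ("tumor_purity", *extra.keys()))
        assert cov.shape[1] == 5

    def test_all_missing_dropped(self):
        clin = self._clin({"purity_x": np.nan})
        with pytest.warns(UserWarning, match="all-missing"):
            cov = tumor_purity_controls(clin, ("tumor_purity", "purity_x"))
        assert "purity_x" not in cov.columns

    def test_partial_missing_imputed(self):
        vals = np.linspace(0.2, 0.8, 40)
        vals[5] = np.nan
        cov = tumor_purity_controls(self._clin({"purity_y": vals}),
                                    ("purity_y",))
        assert not cov["purity_y"].isna().any()


class TestStep3Screen:
    def test_planted_pairs_pass_nulls_fail(self, small_truth, small_cohort):
        cohort, _ = small_cohort
        labels = cohort.clinical.data["cancer_type"]
        act = {Modality.MRNA: sr.call_activity(cohort.mrna, labels),
               Modality.SCNA: sr.call_activity(cohort.scna, labels)}
        expr = {Modality.MRNA: cohort.mrna, Modality.SCNA: cohort.scna}
        planted = small_truth.pairs_of_type("DU")
        nulls = [("G0050", "G0051"), ("G0054", "G0055")]
        res = step3_screen(cohort.clinical, expr, act, planted + nulls, "DU")
        assert sum(res.loc[p, "pass_step3"] for p in planted) >= len(planted) - 1
        assert not any(res.loc[p, "pass_step3"] for p in nulls)
        # sign structure: rescued worse survival, non-rescued better
        ok = res.loc[planted]
        assert (ok["beta_rescued_mRNA"] > 0).all()
        assert (ok["beta_non_rescued_mRNA"] < 0).all()

    def test_permuted_survival_kills_signal(self, small_truth, small_cohort):
        cohort, _ = small_cohort
        rng = np.random.default_rng(5)
        perm = cohort.clinical.data.copy()
        idx = rng.permutation(len(perm))
        perm[["time_days", "event"]] = perm[["time_days", "event"]].to_numpy()[idx]
        clin = ClinicalTable(perm)
        labels = clin.data["cancer_type"]
        act = {Modality.MRNA: sr.call_activity(cohort.mrna, labels),
               Modality.SCNA: sr.call_activity(cohort.scna, labels)}
        expr = {Modality.MRNA: cohort.mrna, Modality.SCNA: cohort.scna}
        res = step3_screen(clin, expr, act, small_truth.pairs_of_type("DU"), "DU")
        assert res["pass_step3"].sum() == 0
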