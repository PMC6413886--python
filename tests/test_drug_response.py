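"""Drug-response scoring: SR score C, survival association, RECIST
comparison, unsupervised AUC, anti-circularity exclusion."""

import numpy as np
import pandas as pd
import pytest

from sr_rescue.cohort import ActivityMatrix, ClinicalTable, Modality
from sr_rescue.drug_response import (DrugTargetMap, drug_sr_score,
                                     exclude_treated_patients, recist_compare,
                                     survival_association, unsupervised_auc)
from sr_rescue.pipeline_core import SRNetwork


def _activity(states_by_gene, samples, modality=Modality.MRNA):
    return ActivityMatrix(pd.DataFrame(states_by_gene, index=samples).T, modality)


def _network(edges):
    return SRNetwork(pd.DataFrame(edges, columns=["V", "R", "sr_type"]))


@pytest.fixture
def score_setup():
    samples = ["s1"]
    act_m = _activity({"r1": [1], "r2": [0], "r3": [1], "r4": [-1]}, samples)
    act_s = _activity({"r1": [0], "r2": [0], "r3": [0], "r4": [0]}, samples,
                      Modality.SCNA)
    net = _network([("tgt", r, "DU") for r in ["r1", "r2", "r3", "r4"]])
    dmap = DrugTargetMap({"drugA": {"tgt"}})
    return act_m, act_s, net, dmap


class TestDrugSRScore:
    def test_fraction_upregulated(self, score_setup):
        act_m, act_s, net, dmap = score_setup
        score = drug_sr_score(act_m, act_s, net, dmap, "drugA", "s1")
        assert score.C == 0.5 and score.n_rescuers == 4

    def test_all_up(self, score_setup):
        act_m, act_s, net, dmap = score_setup
        all_up = _activity({r: [1] for r in ["r1", "r2", "r3", "r4"]}, ["s1"])
        assert drug_sr_score(all_up, None, net, dmap, "drugA", "s1").C == 1.0

    def test_scna_or_rule(self, score_setup):
        act_m, _, net, dmap = score_setup
        scna_up = _activity({"r1": [0], "r2": [1], "r3": [0], "r4": [0]}, ["s1"],
                            Modality.SCNA)
        score = drug_sr_score(act_m, scna_up, net, dmap, "drugA", "s1")
        assert score.C == 0.75  # r2 rescued via SCNA on top of r1, r3 via mRNA

    def test_duplicate_edges_are_set_semantics(self, score_setup):
        act_m, act_s, _, dmap = score_setup
        net = _network([("tgt", "r1", "DU"), ("tgt2", "r1", "DU"),
                        ("tgt", "r4", "DU")])
        dmap = DrugTargetMap({"drugA": {"tgt", "tgt2"}})
        score = drug_sr_score(act_m, act_s, net, dmap, "drugA", "s1")
        assert score.n_rescuers == 2 and score.C == 0.5

    def test_agonist_only_drug_rejected_at_construction(self):
        with pytest.raises(ValueError, match="no usable"):
            DrugTargetMap({"drugB": set()})

    def test_no_rescuers_errors(self, score_setup):
        act_m, act_s, _, _ = score_setup
        net = _network([("other", "r1", "DU")])
        with pytest.raises(ValueError, match="no DU rescuers"):
            drug_sr_score(act_m, act_s, net, DrugTargetMap({"drugA": {"tgt"}}),
                          "drugA", "s1")


class TestRecistCompare:
    def test_exact_small_sample_p(self):
        scores = pd.Series([0.8, 0.9, 0.1, 0.2], index=list("abcd"))
        labels = pd.Series(["PD", "SD", "CR", "PR"], index=list("abcd"))
        p, direction = recist_compare(scores, labels)
        assert p == pytest.approx(1 / 6)
        assert direction == "non-responders higher"

    def test_identical_groups(self):
        scores = pd.Series([0.5, 0.5, 0.5, 0.5], index=list("abcd"))
        labels = pd.Series(["PD", "SD", "CR", "PR"], index=list("abcd"))
        p, _ = recist_compare(scores, labels)
        assert p >= 0.5

    def test_reversed_direction_flag(self):
        scores = pd.Series([0.1, 0.2, 0.8, 0.9], index=list("abcd"))
        labels = pd.Series(["PD", "SD", "CR", "PR"], index=list("abcd"))
        _, direction = recist_compare(scores, labels)
        assert direction == "responders higher"

    def test_empty_group_errors(self):
        scores = pd.Series([0.1, 0.2], index=list("ab"))
        labels = pd.Series(["CR", "PR"], index=list("ab"))
        with pytest.raises(ValueError):
            recist_compare(scores, labels)


class TestUnsupervisedAUC:
    def test_perfect_separation(self):
        scores = pd.Series([0.9, 0.8, 0.1, 0.2], index=list("abcd"))
        responder = pd.Series([False, False, True, True], index=list("abcd"))
        assert unsupervised_auc(scores, responder) == 1.0

    def test_flip_rule(self):
        # separation in the unexpected direction (responders have HIGHER C):
        # raw AUC 1.0 with responder mean higher -> reported as 0.0
        scores = pd.Series([0.1, 0.2, 0.8, 0.9], index=list("abcd"))
        responder = pd.Series([False, False, True, True], index=list("abcd"))
        auc = unsupervised_auc(scores, responder)
        assert auc == 0.0

    def test_null_near_half(self):
        rng = np.random.default_rng(0)
        idx = [f"s{i}" for i in range(1000)]
        scores = pd.Series(rng.random(1000), index=idx)
        responder = pd.Series(rng.random(1000) < 0.5, index=idx)
        assert unsupervised_auc(scores, responder) == pytest.approx(0.5, abs=0.05)

    def test_output_in_unit_interval(self):
        rng = np.random.default_rng(1)
        idx = [f"s{i}" for i in range(50)]
        scores = pd.Series(rng.random(50), index=idx)
        responder = pd.Series(rng.random(50) < 0.3, index=idx)
        assert 0.0 <= unsupervised_auc(scores, responder) <= 1.0


def _clinical(n, rng, c_effect=0.0, c=None):
    strata_rate = 1.0 / 500.0
    if c is None:
        c = rng.random(n)
    rate = strata_rate * np.exp(c_effect * (c - c.mean()) / c.std())
    t_death = rng.exponential(1.0 / rate)
    t_cens = rng.exponential(1.0 / (strata_rate * 3 / 7))
    df = pd.DataFrame({
        "time_days": np.maximum(np.minimum(t_death, t_cens), 0.5),
        "event": (t_death <= t_cens).astype(int),
        "age": rng.normal(60, 10, n), "sex": rng.choice(["m", "f"], n),
        "race": "a", "cancer_type": rng.choice(["T1", "T2"], n),
        "tumor_purity": rng.beta(5, 2, n), "gii": rng.beta(2, 10, n)},
        index=[f"s{i}" for i in range(n)])
    return ClinicalTable(df), pd.Series(c, index=df.index)


class TestSurvivalAssociation:
    def test_recovers_positive_association(self):
        rng = np.random.default_rng(2)
        clin, c = _clinical(400, rng, c_effect=0.5)
        beta, p = survival_association(c, clin)
        assert beta > 0 and p < 0.01

    def test_null_not_significant(self):
        rng = np.random.default_rng(3)
        clin, c = _clinical(400, rng, c_effect=0.0)
        _, p = survival_association(c, clin)
        assert p > 0.001

    def test_too_few_patients(self):
        rng = np.random.default_rng(4)
        clin, c = _clinical(100, rng)
        with pytest.raises(ValueError):
            survival_association(c.iloc[:10], clin)


class TestExcludeTreated:
    def test_exclusion_counts(self):
        rng = np.random.default_rng(5)
        clin, _ = _clinical(100, rng)
        treated = pd.DataFrame({"sample_id": [f"s{i}" for i in range(10)],
                                "drug": "drugA"})
        out = exclude_treated_patients(clin, "drugA", treated)
        assert len(out.data) == 90
        untouched = exclude_treated_patients(clin, "drugB", treated)
        assert len(untouched.data) == 100
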