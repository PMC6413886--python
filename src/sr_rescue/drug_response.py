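"""Predicting patient drug response from rescuer activation.

A drug inhibiting gene V should be less effective in tumors where V's DU
rescuers are already upregulated.  The drug-tumor SR score C is the
fraction of the drug's targets' rescuers (union over targets, set
semantics) that are upregulated in the pre-treatment tumor (tertile state
+1 in mRNA or SCNA).  Downstream: association of C with post-treatment
survival (stratified Cox), comparison against RECIST response classes
(one-sided rank-sum), and an unsupervised AUC with an orientation flip when
the score separates classes in the unexpected direction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import OVER, ActivityMatrix, ClinicalTable, inverse_normal_transform
from .pipeline_core import SRNetwork
from .screen_clinical import fit_stratified_cox

__all__ = [
    "DrugTargetMap",
    "read_drug_target_map",
    "SRScore",
    "drug_sr_score",
    "survival_association",
    "recist_compare",
    "unsupervised_auc",
    "exclude_treated_patients",
]

RESPONDER_CLASSES = {"CR", "PR"}
NON_RESPONDER_CLASSES = {"PD", "SD"}


@dataclass
class DrugTargetMap:
    """drug -> set of (non-agonist) target genes."""

    targets: dict

    def __post_init__(self) -> None:
        empty = [d for d, t in self.targets.items() if not t]
        if empty:
            raise ValueError(f"drugs with no usable (non-agonist) targets: {empty}")

    def __getitem__(self, drug: str) -> set:
        return self.targets[drug]

    def __contains__(self, drug: str) -> bool:
        return drug in self.targets


def read_drug_target_map(path) -> DrugTargetMap:
    """Read a TSV with columns drug, target_gene, action; targets whose
    mechanism is annotated as agonist are excluded."""
    df = pd.read_csv(path, sep="\t")
    required = {"drug", "target_gene", "action"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: missing columns {required - set(df.columns)}")
    targets: dict = {}
    for _, row in df.iterrows():
        targets.setdefault(row["drug"], set())
        if str(row["action"]).lower() != "agonist":
            targets[row["drug"]].add(row["target_gene"])
    return DrugTargetMap(targets)


@dataclass
class SRScore:
    sample_id: str
    drug: str
    C: float
    n_rescuers: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.C <= 1.0):
            raise ValueError("C must lie in [0, 1]")
        if self.n_rescuers <= 0:
            raise ValueError("score undefined without rescuers")


def _rescuers_of(network: SRNetwork, targets: set) -> set:
    edges = network.edges
    mask = edges["V"].isin(targets) & (edges["sr_type"] == "DU")
    return set(edges.loc[mask, "R"])


def drug_sr_score(act_mrna: ActivityMatrix, act_scna: ActivityMatrix | None,
                  network: SRNetwork, drug_map: DrugTargetMap, drug: str,
                  sample: str) -> SRScore:
    """Fraction C of the drug's DU rescuers upregulated in one tumor.

    A rescuer counts as upregulated when its tertile state is +1 in mRNA or
    in SCNA (pass ``act_scna=None`` for mRNA-only scoring).  Raises if the
    drug has no rescuers in the network or the sample lacks activity calls.
    """
    rescuers = _rescuers_of(network, drug_map[drug])
    rescuers = {g for g in rescuers if g in act_mrna.states.index}
    if not rescuers:
        raise ValueError(f"no DU rescuers in the network for drug {drug!r}")
    if sample not in act_mrna.states.columns:
        raise KeyError(f"sample {sample!r} missing from activity matrix")
    up = 0
    for g in sorted(rescuers):
        st_m = act_mrna.states.at[g, sample]
        st_s = (act_scna.states.at[g, sample]
                if act_scna is not None and g in act_scna.states.index
                and sample in act_scna.states.columns else 0)
        if st_m == OVER or st_s == OVER:
            up += 1
    return SRScore(sample, drug, up / len(rescuers), len(rescuers))


def survival_association(scores: pd.Series, clinical: ClinicalTable):
    """Stratified Cox association of the SR score C with survival.

    Model: h_g(t) = h_0g(t) exp(b1 C + b2 age + b3 GII) with strata over
    cancer type x sex x race; C, age and GII inverse-normal transformed.
    Returns (beta1, LRT p).  Requires >= 30 scored patients.
    """
    scores = scores.dropna()
    common = clinical.data.index.intersection(scores.index)
    if len(common) < 30:
        raise ValueError(f"need >= 30 treated patients with scores, got {len(common)}")
    c = scores.loc[common].astype(float)
    if c.nunique() < 2:
        raise ValueError("constant SR score")
    cdf = clinical.data.loc[common]
    cov = pd.DataFrame({"C": inverse_normal_transform(c.to_numpy()),
                        "age": cdf["age"].to_numpy(dtype=float),
                        "gii": cdf["gii"].to_numpy(dtype=float)}, index=common)
    strata = (cdf["cancer_type"].astype(str) + "|" + cdf["race"].astype(str)
              + "|" + cdf["sex"].astype(str))
    # reuse the screen-3 machinery with C as the tested "indicator"
    fit = fit_stratified_cox(cov["C"], cdf["time_days"], cdf["event"],
                             cov[["age", "gii"]], strata, normalize_covariates=True)
    return fit.beta1, fit.p_lrt


def recist_compare(scores: pd.Series, recist_labels: pd.Series):
    """One-sided rank-sum test that non-responders (PD/SD) carry higher SR
    scores than responders (CR/PR).  Returns (p, direction)."""
    labels = recist_labels.reindex(scores.index)
    resp = scores[labels.isin(RESPONDER_CLASSES)].dropna()
    non = scores[labels.isin(NON_RESPONDER_CLASSES)].dropna()
    if resp.empty or non.empty:
        raise ValueError("both responder and non-responder groups must be non-empty")
    _, p = stats.mannwhitneyu(non, resp, alternative="greater")
    direction = ("non-responders higher" if non.mean() > resp.mean()
                 else "responders higher")
    return float(p), direction


def unsupervised_auc(scores: pd.Series, responder_labels: pd.Series) -> float:
    """Rank-based AUC of C for predicting non-response, with the orientation
    flip: if the computed AUC exceeds 0.5 while the mean score is higher in
    responders, 1 - AUC is reported instead."""
    labels = responder_labels.reindex(scores.index).astype(bool)
    non = scores[~labels].dropna()
    resp = scores[labels].dropna()
    if non.empty or resp.empty:
        raise ValueError("both classes must be present")
    u, _ = stats.mannwhitneyu(non, resp, alternative="two-sided")
    auc = float(u / (len(non) * len(resp)))
    if auc > 0.5 and resp.mean() > non.mean():
        auc = 1.0 - auc
    return auc


def exclude_treated_patients(clinical: ClinicalTable, drug: str,
                             treatment_table: pd.DataFrame) -> ClinicalTable:
    """Drop patients who received ``drug`` (anti-circularity: a drug's SR
    network must not be inferred from the patients used to evaluate it).
    ``treatment_table`` has columns sample_id, drug."""
    treated = set(treatment_table.loc[treatment_table["drug"] == drug, "sample_id"])
    keep = [s for s in clinical.data.index if s not in treated]
    return ClinicalTable(clinical.data.loc[keep])
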