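"""Screen 3: stratified Cox proportional-hazards survival screen.

For each candidate pair and each modality the hazard of death is modeled as

    h_g(t) = h_0g(t) * exp(b1 I + b2 g(V) + b3 g(R) + b4 age + b5 GII + b6 TP)

with per-stratum baseline hazards over the full cross of cancer type x race
x sex (strata with too few events are pooled).  I is the binary indicator
of the pair state (rescued or non-rescued); continuous covariates are
inverse-normal transformed, the indicator is left binary.  Significance of
b1 comes from a 1-df likelihood-ratio test against the model without the
indicator, alongside a Wald test.  A pair passes when the rescued state
predicts worse survival (b1 > 0) and the non-rescued state better survival
(b1 < 0), each at BH FDR < 0.05, in both mRNA and SCNA.

Partial-likelihood ties use the Efron approximation (lifelines default).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.exceptions import ConvergenceError
from scipy.stats import chi2

from ._fdr import bh_fdr
from .cohort import (ActivityMatrix, ClinicalTable, GeneMatrix, Modality,
                     PairState, SRType, inverse_normal_transform, pair_states)

__all__ = ["CoxFit", "fit_stratified_cox", "tumor_purity_controls", "step3_screen"]

MIN_EVENTS_PER_STRATUM = 10
MIN_STATE_SAMPLES = 10


@dataclass
class CoxFit:
    beta1: float
    betas: dict
    p_lrt: float
    p_wald: float
    n_events: int
    strata_used: int
    converged: bool = True


def _pool_strata(strata: pd.Series, events: pd.Series,
                 min_events: int = MIN_EVENTS_PER_STRATUM) -> pd.Series:
    """Merge strata with fewer than ``min_events`` observed events into one
    pooled stratum so every baseline hazard is identifiable."""
    ev_counts = events.groupby(strata).sum()
    small = set(ev_counts.index[ev_counts < min_events])
    return strata.where(~strata.isin(small), other="_pooled")


def fit_stratified_cox(indicator, durations, events, covariates: pd.DataFrame | None,
                       strata=None, min_events_per_stratum: int = MIN_EVENTS_PER_STRATUM,
                       normalize_covariates: bool = True) -> CoxFit:
    """Stratified Cox fit of a binary state indicator plus covariates.

    ``covariates`` columns are inverse-normal transformed (unless already
    normalized); the indicator stays binary.  Returns coefficients, the
    1-df LRT p against the no-indicator null, and the Wald p.  A constant
    indicator is an error; non-convergence is reported as p = 1 with
    ``converged=False``.
    """
    ind = pd.Series(np.asarray(indicator, dtype=float))
    if ind.nunique() < 2:
        raise ValueError("degenerate indicator: constant across samples")
    n = len(ind)
    df = pd.DataFrame({"time": np.asarray(durations, dtype=float),
                       "event": np.asarray(events, dtype=int),
                       "indicator": ind.to_numpy()})
    cov_cols: list[str] = []
    if covariates is not None:
        for col in covariates.columns:
            vals = np.asarray(covariates[col], dtype=float)
            if np.nanstd(vals) == 0:
                warnings.warn(f"dropping constant covariate {col!r}")
                continue
            if normalize_covariates:
                vals = inverse_normal_transform(vals)
            if np.isnan(vals).any():  # mean-impute residual missingness
                vals = np.where(np.isnan(vals), np.nanmean(vals), vals)
            df[col] = vals
            cov_cols.append(col)

    strata_col = None
    if strata is not None:
        s = pd.Series(np.asarray(strata).astype(str))
        s = _pool_strata(s, df["event"], min_events_per_stratum)
        if s.nunique() > 1:
            df["stratum"] = s.to_numpy()
            strata_col = "stratum"

    def _fit(columns):
        cph = CoxPHFitter(penalizer=0.0)
        cph.fit(df[["time", "event"] + columns + ([strata_col] if strata_col else [])],
                duration_col="time", event_col="event", strata=strata_col)
        return cph

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            full = _fit(["indicator"] + cov_cols)
            if cov_cols:
                ll_null = _fit(cov_cols).log_likelihood_
            else:
                # null model has no covariates: its partial log-likelihood is
                # the full model's evaluated at beta = 0
                ll_null = full.log_likelihood_ - full.log_likelihood_ratio_test().test_statistic / 2.0
    except (ConvergenceError, np.linalg.LinAlgError, ValueError):
        return CoxFit(np.nan, {}, 1.0, 1.0, int(df["event"].sum()),
                      int(df[strata_col].nunique()) if strata_col else 1, converged=False)

    stat = max(0.0, 2.0 * (full.log_likelihood_ - ll_null))
    p_lrt = float(chi2.sf(stat, df=1))
    beta1 = float(full.params_["indicator"])
    p_wald = float(full.summary.loc["indicator", "p"])
    return CoxFit(beta1, full.params_.to_dict(), p_lrt, p_wald,
                  int(df["event"].sum()),
                  int(df[strata_col].nunique()) if strata_col else 1)


def tumor_purity_controls(clinical: ClinicalTable,
                          purity_columns=("tumor_purity",)) -> pd.DataFrame:
    """Assemble purity covariates: each available purity estimate becomes a
    covariate; missing entries are mean-imputed; all-missing columns are
    dropped with a warning."""
    out = {}
    for col in purity_columns:
        if col not in clinical.data.columns:
            warnings.warn(f"purity column {col!r} absent; skipped")
            continue
        vals = clinical.data[col].astype(float)
        if vals.isna().all():
            warnings.warn(f"purity column {col!r} all-missing; dropped")
            continue
        out[col] = vals.fillna(vals.mean())
    if not out:
        raise ValueError("no usable purity column")
    return pd.DataFrame(out, index=clinical.data.index)


def _clinical_covariates(clinical: ClinicalTable, gV, gR,
                         purity_columns=("tumor_purity",)) -> pd.DataFrame:
    cov = pd.DataFrame({"gV": np.asarray(gV, dtype=float),
                        "gR": np.asarray(gR, dtype=float),
                        "age": clinical.data["age"].to_numpy(dtype=float),
                        "gii": clinical.data["gii"].to_numpy(dtype=float)},
                       index=clinical.data.index)
    return cov.join(tumor_purity_controls(clinical, purity_columns))


def step3_screen(clinical: ClinicalTable,
                 expr: dict, activity: dict,
                 candidates, sr_type: SRType | str = SRType.DU,
                 fdr: float = 0.05, min_state_samples: int = MIN_STATE_SAMPLES,
                 purity_columns=("tumor_purity",)) -> pd.DataFrame:
    """Run the clinical screen over candidate pairs.

    ``expr`` maps modality -> GeneMatrix (continuous values for the g(V),
    g(R) covariates); ``activity`` maps modality -> ActivityMatrix (the
    per-cancer-type tertile states defining the pair-state indicators).
    Four fits per pair (rescued / non-rescued x mRNA / SCNA); BH within
    each (state, modality) family.  Pass requires beta1 > 0 with q < fdr
    for rescued AND beta1 < 0 with q < fdr for non-rescued, in both
    modalities.  Pairs whose state count is below ``min_state_samples``
    are skipped with a reason.
    """
    sr_type = SRType(sr_type)
    candidates = list(candidates)
    if not candidates:
        return pd.DataFrame(columns=["pass_step3", "rep_p"])
    samples = clinical.data.index
    strata = (clinical.data["cancer_type"].astype(str) + "|" +
              clinical.data["race"].astype(str) + "|" +
              clinical.data["sex"].astype(str))

    modalities = [m for m in (Modality.MRNA, Modality.SCNA) if m in activity and m in expr]
    states = (PairState.RESCUED, PairState.NON_RESCUED)
    records = {}
    for pair in candidates:
        v, r = pair[0], pair[1]
        rec: dict = {"skip": None}
        for mod in modalities:
            act, gm = activity[mod], expr[mod]
            if v not in act.states.index or r not in act.states.index:
                rec["skip"] = f"gene missing from {mod.value} activity"
                continue
            st = pair_states(act.states.loc[v, samples], act.states.loc[r, samples], sr_type)
            cov = _clinical_covariates(clinical, gm.values.loc[v, samples],
                                       gm.values.loc[r, samples], purity_columns)
            for state in states:
                key = f"{state.value}_{mod.value}"
                ind = (st == state.value).astype(float)
                if ind.sum() < min_state_samples:
                    rec[f"skip_{key}"] = f"only {int(ind.sum())} samples in state"
                    continue
                fit = fit_stratified_cox(ind, clinical.data["time_days"],
                                         clinical.data["event"], cov, strata)
                rec[f"beta_{key}"] = fit.beta1
                rec[f"p_{key}"] = fit.p_lrt
                rec[f"wald_{key}"] = fit.p_wald
        records[(v, r)] = rec
    df = pd.DataFrame.from_dict(records, orient="index")
    df.index = pd.MultiIndex.from_tuples(df.index, names=["V", "R"])

    pass_flags = pd.Series(True, index=df.index)
    rep = pd.Series(0.0, index=df.index)
    for mod in modalities:
        for state in states:
            key = f"{state.value}_{mod.value}"
            pcol, bcol = f"p_{key}", f"beta_{key}"
            if pcol not in df.columns:
                df[pcol] = np.nan
                df[bcol] = np.nan
            tested = df[pcol].notna()
            q = pd.Series(np.nan, index=df.index)
            if tested.any():
                q[tested] = bh_fdr(df.loc[tested, pcol].to_numpy())
            df[f"q_{key}"] = q
            sign_ok = df[bcol] > 0 if state is PairState.RESCUED else df[bcol] < 0
            pass_flags &= tested & (q < fdr) & sign_ok
            # sign-gated representative p: wrong sign counts as p = 1
            gated = df[pcol].where(sign_ok, 1.0)
            rep = np.fmax(rep, gated.fillna(1.0))
    df["pass_step3"] = pass_flags
    df["rep_p"] = rep
    return df
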