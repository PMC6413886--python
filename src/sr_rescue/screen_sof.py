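"""Screen 2: molecular "survival of the fittest" (SoF) in tumor cohorts.

Tumors in the rescued state (V underactive, R in its rescuing state) gain
fitness, so under positive selection they should be over-represented among
sequenced tumors; tumors in the non-rescued state (V underactive without
the rescue) lose fitness and should be depleted.  Both are tested with
one-tailed hypergeometric tests on the joint state count against the
single-gene marginals, separately in mRNA and SCNA, and a pair passes only
if rescued-state enrichment AND non-rescued-state depletion are significant
(BH FDR < 0.05 by default) in BOTH modalities.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from ._fdr import bh_fdr
from .cohort import OVER, UNDER, ActivityMatrix, Modality, SRType

__all__ = ["hypergeom_tail", "sof_test_pair", "step2_screen"]

MIN_SAMPLES = 30


def hypergeom_tail(k: int, n1: int, N: int, n2: int, tail: str) -> float:
    """Tail probability of the hypergeometric overlap count.

    X ~ Hypergeom(population N, successes n1, draws n2); 'enrich' returns
    P(X >= k), 'deplete' returns P(X <= k).
    """
    if not (0 <= k <= min(n1, n2) <= N) or n1 > N or n2 > N:
        raise ValueError(f"inconsistent counts k={k}, n1={n1}, N={N}, n2={n2}")
    if tail == "enrich":
        return float(hypergeom.sf(k - 1, N, n1, n2))
    if tail == "deplete":
        return float(hypergeom.cdf(k, N, n1, n2))
    raise ValueError(f"unknown tail {tail!r}")


def sof_test_pair(actV, actR, sr_type: SRType | str) -> dict:
    """Enrichment/depletion p-values for one pair in one modality.

    Marginals come from the single-gene states (n2 = samples with V
    underactive; n1 = samples with R in the relevant R-condition); k is the
    joint count.  Degenerate margins give p = 1 with a flag.
    """
    sr_type = SRType(sr_type)
    v = np.asarray(actV)
    r = np.asarray(actR)
    if v.shape != r.shape:
        raise ValueError("activity vectors differ in length")
    N = v.size
    if N < MIN_SAMPLES:
        raise ValueError(f"need >= {MIN_SAMPLES} samples, got {N}")
    rescue_state = OVER if sr_type is SRType.DU else UNDER
    under_v = v == UNDER
    r_resc = r == rescue_state

    n2 = int(under_v.sum())
    out: dict = {"N": N, "n2": n2, "degenerate": False}

    # rescued state: V under AND R rescuing
    n1_res = int(r_resc.sum())
    k_res = int((under_v & r_resc).sum())
    out.update(n1_rescued=n1_res, k_rescued=k_res)
    # non-rescued state: V under AND R not rescuing
    n1_non = int((~r_resc).sum())
    k_non = int((under_v & ~r_resc).sum())
    out.update(n1_nonrescued=n1_non, k_nonrescued=k_non)

    if n2 == 0 or n1_res == 0 or n1_non == 0:
        out.update(p_enrich_rescued=1.0, p_deplete_nonrescued=1.0, degenerate=True)
        return out
    out["p_enrich_rescued"] = hypergeom_tail(k_res, n1_res, N, n2, "enrich")
    out["p_deplete_nonrescued"] = hypergeom_tail(k_non, n1_non, N, n2, "deplete")
    return out


def step2_screen(activity_mrna: ActivityMatrix, activity_scna: ActivityMatrix | None,
                 candidates, sr_type: SRType | str = SRType.DU,
                 fdr: float = 0.05, require_both_modalities: bool = True) -> pd.DataFrame:
    """Run the SoF screen over candidate pairs.

    BH adjustment is applied within each of the four test families
    (2 states x 2 modalities).  A pair passes when all four q-values are
    below ``fdr``; with ``require_both_modalities=False`` (mRNA-only mode)
    only the two mRNA families are required.

    Returns a DataFrame indexed by (V, R) with p/q per family, the
    ``pass_step2`` flag, and ``rep_p`` = worst of the required p-values.
    """
    sr_type = SRType(sr_type)
    candidates = list(candidates)
    cols = ["p_enrich_rescued", "p_deplete_nonrescued"]
    if not candidates:
        return pd.DataFrame(columns=["pass_step2", "rep_p"])
    if activity_scna is None and require_both_modalities:
        raise ValueError("SCNA activity required; pass require_both_modalities=False "
                         "for mRNA-only mode")

    modalities = [(Modality.MRNA, activity_mrna)]
    if activity_scna is not None:
        modalities.append((Modality.SCNA, activity_scna))

    records = {}
    for pair in candidates:
        v, r = pair[0], pair[1]
        rec: dict = {}
        for mod, act in modalities:
            if v not in act.states.index or r not in act.states.index:
                continue
            res = sof_test_pair(act.states.loc[v].to_numpy(),
                                act.states.loc[r].to_numpy(), sr_type)
            for c in cols:
                rec[f"{c}_{mod.value}"] = res[c]
        records[(v, r)] = rec
    df = pd.DataFrame.from_dict(records, orient="index")
    df.index = pd.MultiIndex.from_tuples(df.index, names=["V", "R"])

    required = []
    for mod, _ in modalities:
        for c in cols:
            pc = f"{c}_{mod.value}"
            if pc not in df.columns:
                df[pc] = np.nan
            qc = f"q{c[1:]}_{mod.value}"
            tested = df[pc].notna()
            q = pd.Series(np.nan, index=df.index)
            if tested.any():
                q[tested] = bh_fdr(df.loc[tested, pc].to_numpy())
            df[qc] = q
            if mod is Modality.MRNA or require_both_modalities:
                required.append((pc, qc))

    pass_flags = pd.Series(True, index=df.index)
    rep = pd.Series(0.0, index=df.index)
    for pc, qc in required:
        pass_flags &= df[qc].notna() & (df[qc] < fdr)
        rep = np.fmax(rep, df[pc])
    df["pass_step2"] = pass_flags
    df["rep_p"] = rep
    return df
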