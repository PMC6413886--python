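"""Screen 1: conditional essentiality in cell-line perturbation panels.

A candidate DU pair (vulnerable V, rescuer R) is supported in vitro when
(i) knocking down V costs less fitness in cell lines where R is highly
expressed (rescue in action), and (ii) knocking down R is lethal in cell
lines where V is lowly expressed (the rescue is load-bearing).  Both
conditions are tested with a linear mixed-effects model of the
quantile-normalized fitness readout on the partner gene's molecular level,
with cancer type as a random intercept:

    y ~ g + (1 | cancer_type)

The fixed-effect p-value comes from a 1-df likelihood-ratio test (ANOVA
against the model without g); with a single cancer type the fit degrades to
ordinary least squares.  For DD pairs condition (i) flips sign (growth
increases when R is *down*) and condition (ii) is a one-sided Wilcoxon
rank-sum test comparing V-knockdown fitness between R-low and R-high
cell-line tertiles.

P-values are Fisher-combined across panels, Benjamini-Hochberg adjusted
within each modality, and a pair passes at FDR < 0.2 (default) if it is
significant in mRNA OR SCNA.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._lmm import lrt_random_intercept
from .cohort import GeneMatrix, Modality, SRType, inverse_normal_transform
from ._fdr import bh_fdr

__all__ = [
    "ScreenPanel",
    "read_screen_panel",
    "expand_drug_readouts",
    "fit_conditional_essentiality",
    "test_du_pair_invitro",
    "combine_fisher",
    "step1_screen",
]

MIN_CELL_LINES = 10
_P_FLOOR = 1e-300


@dataclass
class ScreenPanel:
    """One perturbation screen: per-cell-line fitness readouts per perturbed
    gene, plus the cell lines' molecular profiles and cancer-type labels.

    ``readouts`` is a DataFrame (perturbed gene x cell line); higher values
    mean more growth (log-IC50 readouts from drug screens satisfy this:
    resistant lines grow more).
    """

    readouts: pd.DataFrame
    cancer_types: pd.Series
    profiles_mrna: GeneMatrix
    profiles_scna: GeneMatrix | None = None
    readout_kind: str = "shRNA_essentiality"
    name: str = "panel"

    def __post_init__(self) -> None:
        cells = pd.Index(self.readouts.columns)
        if not cells.isin(self.cancer_types.index).all():
            raise ValueError("every readout cell line needs a cancer-type label")
        for gm in (self.profiles_mrna, self.profiles_scna):
            if gm is not None and not cells.isin(gm.values.columns).all():
                missing = cells.difference(gm.values.columns).tolist()
                raise ValueError(f"cell lines missing from profiles: {missing}")

    @property
    def cell_line_ids(self) -> list[str]:
        return list(self.readouts.columns)

    def profile(self, modality: Modality | str) -> GeneMatrix | None:
        return self.profiles_mrna if Modality(modality) is Modality.MRNA else self.profiles_scna


def read_screen_panel(readout_path, mrna: GeneMatrix, scna: GeneMatrix | None = None,
                      name: str = "panel") -> ScreenPanel:
    """Read a long-format readout TSV with columns
    cell_line, cancer_type, perturbed_gene, readout_kind, value."""
    long = pd.read_csv(readout_path, sep="\t")
    required = {"cell_line", "cancer_type", "perturbed_gene", "readout_kind", "value"}
    if not required.issubset(long.columns):
        raise ValueError(f"{readout_path}: missing columns {required - set(long.columns)}")
    kinds = long["readout_kind"].unique()
    if len(kinds) != 1:
        raise ValueError(f"{readout_path}: mixed readout kinds {kinds}")
    readouts = long.pivot_table(index="perturbed_gene", columns="cell_line",
                                values="value", aggfunc="mean")
    ctypes = long.drop_duplicates("cell_line").set_index("cell_line")["cancer_type"]
    return ScreenPanel(readouts, ctypes, mrna, scna, readout_kind=kinds[0], name=name)


def expand_drug_readouts(drug_readouts: pd.DataFrame, drug_targets: dict) -> pd.DataFrame:
    """Map drug-response readouts (drug x cell line) to gene-level readouts.

    A drug with several targets contributes its readout to each target gene;
    a gene hit by several drugs gets the per-cell-line mean.
    """
    rows, index = [], []
    for drug, targets in drug_targets.items():
        if drug not in drug_readouts.index:
            continue
        for gene in targets:
            rows.append(drug_readouts.loc[drug])
            index.append(gene)
    if not rows:
        return pd.DataFrame(columns=drug_readouts.columns)
    df = pd.DataFrame(rows, index=index)
    return df.groupby(level=0).mean()


def fit_conditional_essentiality(y, g, cancer_type):
    """Fit y ~ g + (1|cancer_type) and return (slope, LRT p-value).

    y is quantile-normalized to N(0,1) before fitting.  Missing values are
    dropped pairwise; fewer than MIN_CELL_LINES complete observations is an
    error.  A singular fit is reported as p = 1 with a warning.
    """
    y = np.asarray(y, dtype=float)
    g = np.asarray(g, dtype=float)
    ct = np.asarray(cancer_type)
    mask = ~(np.isnan(y) | np.isnan(g))
    y, g, ct = y[mask], g[mask], ct[mask]
    if y.size < MIN_CELL_LINES:
        raise ValueError(f"need >= {MIN_CELL_LINES} cell lines, got {y.size}")
    if np.all(g == g[0]):
        raise ValueError("constant covariate g: slope undefined")
    yn = inverse_normal_transform(y)
    if len(np.unique(ct)) == 1:
        res = stats.linregress(g, yn)
        return float(res.slope), float(res.pvalue)
    try:
        return lrt_random_intercept(yn, g, ct)
    except np.linalg.LinAlgError:
        warnings.warn("singular mixed-model fit; reporting p = 1")
        return 0.0, 1.0


def _wilcoxon_tertile(y, g, alternative):
    """One-sided rank-sum on y between g-low and g-high tertile cell lines."""
    lo_thr, hi_thr = np.nanquantile(g, [1 / 3, 2 / 3])
    low, high = y[g < lo_thr], y[g > hi_thr]
    if low.size < 3 or high.size < 3:
        return 0.0, 1.0
    stat, p = stats.mannwhitneyu(low, high, alternative=alternative)
    effect = float(np.median(low) - np.median(high))
    return effect, float(p)


def test_du_pair_invitro(panel: ScreenPanel, pair, modality: Modality | str,
                         sr_type: SRType | str = SRType.DU) -> dict:
    """Test both rescue conditions for one pair in one panel and modality.

    Returns a dict with per-condition (beta, p, sign_ok); the gated p
    (``p_i``/``p_ii``) is the raw p when the effect sign supports rescue and
    1.0 otherwise.  Missing readouts skip the pair with a reason code.
    """
    v, r = pair[0], pair[1]
    sr_type = SRType(sr_type)
    prof = panel.profile(modality)
    if prof is None:
        return {"skip": f"no {Modality(modality).value} profiles"}
    out: dict = {"pair": (v, r), "modality": Modality(modality).value, "panel": panel.name}

    def _aligned(readout_gene, profile_gene):
        if readout_gene not in panel.readouts.index:
            return None
        if profile_gene not in prof.values.index:
            return None
        y = panel.readouts.loc[readout_gene]
        g = prof.values.loc[profile_gene, y.index]
        ct = panel.cancer_types.loc[y.index]
        return y.to_numpy(), g.to_numpy(), ct.to_numpy()

    # condition (i): V-knockdown fitness versus R's molecular level
    data = _aligned(v, r)
    if data is None:
        return {"skip": f"missing readout or profile for condition (i) of ({v},{r})"}
    try:
        beta_i, p_i = fit_conditional_essentiality(*data)
    except ValueError as err:
        return {"skip": str(err)}
    want_positive = sr_type is SRType.DU  # DD rescue: growth up when R is DOWN
    sign_ok_i = beta_i > 0 if want_positive else beta_i < 0
    out.update(beta_i=beta_i, p_i_raw=p_i, sign_ok_i=sign_ok_i,
               p_i=p_i if sign_ok_i else 1.0)

    # condition (ii)
    if sr_type is SRType.DU:
        data = _aligned(r, v)
        if data is None:
            return {"skip": f"missing readout or profile for condition (ii) of ({v},{r})"}
        try:
            beta_ii, p_ii = fit_conditional_essentiality(*data)
        except ValueError as err:
            return {"skip": str(err)}
        sign_ok_ii = beta_ii > 0  # R-KD lethal where V is low
    else:
        # DD: V-KD fitness higher in R-low than R-high tertile (one-sided)
        y, g, _ = _aligned(v, r)
        mask = ~(np.isnan(y) | np.isnan(g))
        beta_ii, p_ii = _wilcoxon_tertile(y[mask], g[mask], alternative="greater")
        sign_ok_ii = beta_ii > 0
    out.update(beta_ii=beta_ii, p_ii_raw=p_ii, sign_ok_ii=sign_ok_ii,
               p_ii=p_ii if sign_ok_ii else 1.0)
    return out


def combine_fisher(pvals) -> float:
    """Fisher's method: X = -2 sum(ln p) ~ chi-square with 2k df."""
    p = np.asarray(list(pvals), dtype=float)
    if p.size == 0:
        raise ValueError("no p-values to combine")
    if (p <= 0).any():
        warnings.warn("non-positive p-values clamped to 1e-300")
        p = np.clip(p, _P_FLOOR, None)
    if (p > 1).any():
        raise ValueError("p-values must be <= 1")
    x = -2.0 * np.sum(np.log(p))
    return float(stats.chi2.sf(x, df=2 * p.size))


def step1_screen(panels, candidates, sr_type: SRType | str = SRType.DU,
                 fdr: float = 0.2) -> pd.DataFrame:
    """Run the in-vitro screen over candidate pairs.

    Per modality the two condition p-values are Fisher-combined across
    panels, BH-adjusted over all tested pairs (separately per condition and
    modality), and the modality passes when both conditions reach
    q < ``fdr``.  A pair passes the screen if either modality passes.

    Returns a DataFrame indexed by (V, R) with per-modality q-values, a
    ``pass_step1`` flag, and ``rep_p`` (the representative p-value: worst of
    the two conditions in the best modality) used for rank scoring.
    """
    if not panels:
        raise ValueError("need at least one panel")
    sr_type = SRType(sr_type)
    candidates = list(candidates)
    if not candidates:
        return pd.DataFrame(columns=["pass_step1", "rep_p"])

    modalities = [Modality.MRNA]
    if any(p.profiles_scna is not None for p in panels):
        modalities.append(Modality.SCNA)

    records = {}
    for pair in candidates:
        rec: dict = {"skip": None}
        for mod in modalities:
            ps_i, ps_ii = [], []
            for panel in panels:
                res = test_du_pair_invitro(panel, pair, mod, sr_type)
                if "skip" in res and res["skip"]:
                    continue
                ps_i.append(res["p_i"])
                ps_ii.append(res["p_ii"])
            if ps_i:
                rec[f"p_i_{mod.value}"] = combine_fisher(ps_i)
                rec[f"p_ii_{mod.value}"] = combine_fisher(ps_ii)
        records[(pair[0], pair[1])] = rec

    df = pd.DataFrame.from_dict(records, orient="index")
    df.index = pd.MultiIndex.from_tuples(df.index, names=["V", "R"])

    pass_any = pd.Series(False, index=df.index)
    rep = pd.Series(np.nan, index=df.index)
    for mod in modalities:
        ci, cii = f"p_i_{mod.value}", f"p_ii_{mod.value}"
        if ci not in df.columns:
            continue
        tested = df[ci].notna() & df[cii].notna()
        qi = pd.Series(np.nan, index=df.index)
        qii = pd.Series(np.nan, index=df.index)
        qi[tested] = bh_fdr(df.loc[tested, ci].to_numpy())
        qii[tested] = bh_fdr(df.loc[tested, cii].to_numpy())
        df[f"q_i_{mod.value}"], df[f"q_ii_{mod.value}"] = qi, qii
        mod_pass = tested & (qi < fdr) & (qii < fdr)
        pass_any |= mod_pass
        worst = df[[ci, cii]].max(axis=1)
        rep = np.fmin(rep, worst.where(tested))
    df["pass_step1"] = pass_any
    df["rep_p"] = rep
    return df
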