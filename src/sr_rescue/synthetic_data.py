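"""Synthetic fixtures with planted synthetic-rescue structure.

Every generator is a pure function of its parameters and a seed, and plants
exactly the statistical structure the four screens assume:

* tumor cohorts with per-cancer-type location shifts, mRNA/SCNA correlation,
  rescued-state joint-frequency inflation (positive selection), and survival
  hazards raised in the rescued state and lowered in the non-rescued state;
* cell-line panels where knocking down a planted vulnerable gene costs less
  fitness when its rescuer is highly expressed, and knocking down the
  rescuer is lethal where the vulnerable gene is low;
* phylogenetic profiles built from a block model, with planted pairs sharing
  near-identical profiles;
* 1x5 dose-response grids generated under Bliss independence scaled by a
  chosen synergy level, with multiplicative log-normal count noise.

Defaults (1,000 samples, 500 genes, 3 cancer types, 20 DU + 10 DD planted
pairs, inflation 2.0, rescued-state log-hazard +0.7 / non-rescued -0.7,
in-vitro effect 0.8 SD) define the reference desk-scale conditions; see
docs/methods.md for rationale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import ClinicalTable, GeneMatrix, Modality, SRType
from .pipeline_core import CohortData
from .screen_invitro import ScreenPanel
from .screen_phylo import PhyloProfileMatrix
from .synergy_bliss import DoseResponseGrid

__all__ = [
    "PlantedTruth",
    "default_truth",
    "gene_names",
    "generate_cohort",
    "generate_screen_panel",
    "generate_phylo_profiles",
    "generate_dose_grids",
    "generate_response_tables",
    "candidate_universe",
]

# reference desk-scale conditions
DEFAULT_N_SAMPLES = 1000
DEFAULT_N_GENES = 500
DEFAULT_N_CANCER_TYPES = 3
DEFAULT_SOF_INFLATION = 2.0
DEFAULT_HAZARD_RESCUED = 0.7
DEFAULT_HAZARD_NONRESCUED = -0.7
DEFAULT_ESSENTIALITY_EFFECT = 0.8
DEFAULT_PROFILE_NOISE = 0.05

_MRNA_SCNA_RHO = 0.5
_SCNA_SCALE = 0.6
_BASELINE_MEDIAN_DAYS = 700.0


@dataclass
class PlantedTruth:
    """The planted pairs and their effect sizes; recorded in every artifact."""

    pairs: list  # of (V, R, sr_type)
    sof_inflation: float = DEFAULT_SOF_INFLATION
    hazard_rescued: float = DEFAULT_HAZARD_RESCUED
    hazard_nonrescued: float = DEFAULT_HAZARD_NONRESCUED
    essentiality_effect: float = DEFAULT_ESSENTIALITY_EFFECT
    profile_noise: float = DEFAULT_PROFILE_NOISE
    seed: int = 0

    def __post_init__(self) -> None:
        self.pairs = [(v, r, SRType(t).value) for v, r, t in self.pairs]
        genes = [g for v, r, _ in self.pairs for g in (v, r)]
        if len(set(genes)) != len(genes):
            raise ValueError("planted genes must be disjoint across pairs")
        if not np.isfinite([self.sof_inflation, self.hazard_rescued,
                            self.hazard_nonrescued, self.essentiality_effect,
                            self.profile_noise]).all():
            raise ValueError("effect sizes must be finite")
        if not (0.0 < self.sof_inflation <= 3.0):
            raise ValueError("infeasible inflation: joint frequency would exceed "
                             "a marginal (need 0 < inflation <= 3)")

    def pairs_of_type(self, sr_type: SRType | str) -> list:
        t = SRType(sr_type).value
        return [(v, r) for v, r, typ in self.pairs if typ == t]

    def to_tsv(self, path) -> None:
        pd.DataFrame(self.pairs, columns=["V", "R", "sr_type"]).to_csv(
            path, sep="\t", index=False)


def gene_names(n: int) -> list[str]:
    return [f"G{i + 1:04d}" for i in range(n)]


def default_truth(n_du: int = 20, n_dd: int = 10, seed: int = 0, **effects) -> PlantedTruth:
    """Planted pairs on reserved leading gene names: DU pairs take genes
    (G0001, G0002), (G0003, G0004), ...; DD pairs follow."""
    names = gene_names(2 * (n_du + n_dd))
    pairs = []
    for i in range(n_du):
        pairs.append((names[2 * i], names[2 * i + 1], "DU"))
    off = 2 * n_du
    for i in range(n_dd):
        pairs.append((names[off + 2 * i], names[off + 2 * i + 1], "DD"))
    return PlantedTruth(pairs, seed=seed, **effects)


def _rng(truth: PlantedTruth, seed, salt: int):
    base = truth.seed if seed is None else seed
    return np.random.default_rng(np.random.SeedSequence([int(base), salt]))


def _planted_states(truth: PlantedTruth, n_samples: int, rng):
    """Draw per-sample activity states for every planted gene.

    All planted pairs share one latent per-sample "rescue program": block 1
    (frequency inflation/9) is the rescued state of every planted pair,
    block 2 (1/3 - inflation/9) the non-rescued state, block 3 the rest.
    Within each block the vulnerable and rescuer states are drawn so every
    gene's tertile marginals stay exactly at 1/3, which plants the joint
    rescued-state inflation for each pair while keeping the survival effect
    a single bounded per-sample contrast (independent per-pair hazards would
    add ~30 random log-hazard terms per sample, and the resulting frailty
    attenuates every pair's marginal hazard ratio; see docs/methods.md).

    Returns (states dict, block labels in {1, 2, 3}).
    """
    f = truth.sof_inflation
    p1 = f / 9.0
    p2 = 1.0 / 3.0 - p1
    block = rng.choice([1, 2, 3], size=n_samples, p=[p1, p2, 2.0 / 3.0])
    b1, b2, b3 = block == 1, block == 2, block == 3
    n3 = int(b3.sum())
    # conditional R-state probabilities in block 3 preserving 1/3 marginals
    q_resc = (3.0 - f) / 6.0 / (2.0 / 3.0)  # P(R = rescue state | block 3)
    q_other = (1.0 - q_resc) / 2.0
    states: dict = {}
    for v, r, typ in truth.pairs:
        rescue_state = 1 if typ == "DU" else -1
        other = [s for s in (-1, 0, 1) if s != rescue_state]
        sv = np.empty(n_samples, dtype=np.int8)
        sv[b1 | b2] = -1
        sv[b3] = rng.choice([0, 1], size=n3)
        sr = np.empty(n_samples, dtype=np.int8)
        sr[b1] = rescue_state
        sr[b2] = rng.choice(other, size=int(b2.sum()))
        sr[b3] = rng.choice([rescue_state, other[0], other[1]], size=n3,
                            p=[q_resc, q_other, q_other])
        states[v] = sv
        states[r] = sr
    return states, block


def _values_matching_states(base_values: np.ndarray, states: np.ndarray,
                            type_codes: np.ndarray, rng) -> np.ndarray:
    """Reorder a gene's continuous draws within each cancer type so that the
    planted states occupy the correct tertile bands."""
    out = np.empty_like(base_values)
    for t in np.unique(type_codes):
        idx = np.flatnonzero(type_codes == t)
        vals = np.sort(base_values[idx])
        st = states[idx]
        pos = 0
        for s in (-1, 0, 1):
            members = idx[st == s]
            chunk = vals[pos:pos + members.size]
            out[members] = rng.permutation(chunk)
            pos += members.size
    return out


def generate_cohort(truth: PlantedTruth, n_samples: int = DEFAULT_N_SAMPLES,
                    n_genes: int = DEFAULT_N_GENES,
                    n_cancer_types: int = DEFAULT_N_CANCER_TYPES,
                    seed: int | None = None) -> tuple[CohortData, pd.DataFrame]:
    """Simulate a tumor cohort with the planted rescue structure.

    Returns ``(cohort, planted_state_table)`` where the second element is the
    per-sample true pair state (for generator self-checks).
    """
    if n_samples < 100:
        raise ValueError("need n_samples >= 100")
    rng = _rng(truth, seed, salt=1)
    genes = gene_names(n_genes)
    missing = [g for v, r, _ in truth.pairs for g in (v, r) if g not in genes]
    if missing:
        raise ValueError(f"planted genes outside the gene universe: {missing}")
    samples = [f"S{i + 1:05d}" for i in range(n_samples)]
    type_codes = np.arange(n_samples) % n_cancer_types
    ctypes = np.array([f"CT{c + 1}" for c in type_codes])

    planted, block = _planted_states(truth, n_samples, rng)

    mu = rng.normal(8.0, 2.0, size=n_genes)
    shift = rng.normal(0.0, 1.0, size=(n_genes, n_cancer_types))
    e1 = rng.normal(0.0, 1.0, size=(n_genes, n_samples))
    e2 = rng.normal(0.0, 1.0, size=(n_genes, n_samples))
    mrna = mu[:, None] + shift[:, type_codes] + e1
    scna = _SCNA_SCALE * (_MRNA_SCNA_RHO * e1 +
                          np.sqrt(1 - _MRNA_SCNA_RHO**2) * e2)

    gene_index = {g: i for i, g in enumerate(genes)}
    for g, st in planted.items():
        gi = gene_index[g]
        mrna[gi] = _values_matching_states(mrna[gi], st, type_codes, rng)
        scna[gi] = _values_matching_states(scna[gi], st, type_codes, rng)

    # survival: exponential baseline per cancer type; hazard multiplied by
    # exp(+hazard_rescued) for samples in the shared rescued block and by
    # exp(hazard_nonrescued) for the shared non-rescued block
    base_rate = (np.log(2.0) / _BASELINE_MEDIAN_DAYS) * \
        np.array([0.7, 1.0, 1.4] * (n_cancer_types // 3 + 1))[:n_cancer_types]
    log_hr = (truth.hazard_rescued * (block == 1) +
              truth.hazard_nonrescued * (block == 2))
    state_rows = []
    for v, r, typ in truth.pairs:
        rescue_state = 1 if typ == "DU" else -1
        rescued = (planted[v] == -1) & (planted[r] == rescue_state)
        nonrescued = (planted[v] == -1) & ~ (planted[r] == rescue_state)
        state_rows.append(pd.Series(
            np.where(rescued, "rescued", np.where(nonrescued, "non_rescued", "other")),
            index=samples, name=f"{v}->{r}"))
    rate = base_rate[type_codes] * np.exp(log_hr)
    t_death = rng.exponential(1.0 / rate)
    t_censor = rng.exponential(1.0 / (base_rate[type_codes] * 3.0 / 7.0))
    time = np.maximum(np.minimum(t_death, t_censor), 0.5)
    event = (t_death <= t_censor).astype(int)

    mrna_gm = GeneMatrix(pd.DataFrame(mrna, index=genes, columns=samples), Modality.MRNA)
    scna_gm = GeneMatrix(pd.DataFrame(scna, index=genes, columns=samples), Modality.SCNA)
    clinical = pd.DataFrame({
        "time_days": time,
        "event": event,
        "age": np.clip(rng.normal(60.0, 10.0, n_samples), 25, 90),
        "sex": rng.choice(["female", "male"], size=n_samples),
        "race": rng.choice(["groupA", "groupB", "groupC"], size=n_samples,
                           p=[0.7, 0.2, 0.1]),
        "cancer_type": ctypes,
        "tumor_purity": rng.beta(5.0, 2.0, size=n_samples),
    }, index=pd.Index(samples, name="sample_id"))
    clinical["gii"] = np.mean(np.abs(scna) > 1, axis=0)
    cohort = CohortData(mrna_gm, scna_gm, ClinicalTable(clinical))
    truth_states = pd.concat(state_rows, axis=1) if state_rows else pd.DataFrame(index=samples)
    return cohort, truth_states


def generate_screen_panel(truth: PlantedTruth, n_cell_lines: int = 100,
                          n_genes: int = DEFAULT_N_GENES,
                          n_cancer_types: int = DEFAULT_N_CANCER_TYPES,
                          seed: int | None = None, name: str = "sim_panel") -> ScreenPanel:
    """Simulate an shRNA-style essentiality panel (higher readout = more
    growth).  Planted DU pairs: V-knockdown fitness rises with R's level and
    R-knockdown fitness falls with V's level; planted DD pairs: V-knockdown
    fitness rises as R's level falls.  All other readouts are pure noise."""
    if n_cell_lines < 30:
        raise ValueError("need n_cell_lines >= 30")
    rng = _rng(truth, seed, salt=2)
    genes = gene_names(n_genes)
    cells = [f"CL{i + 1:03d}" for i in range(n_cell_lines)]
    type_codes = np.arange(n_cell_lines) % n_cancer_types
    ctypes = pd.Series([f"CT{c + 1}" for c in type_codes], index=cells)

    mu = rng.normal(8.0, 2.0, size=n_genes)
    shift = rng.normal(0.0, 1.0, size=(n_genes, n_cancer_types))
    e1 = rng.normal(0.0, 1.0, size=(n_genes, n_cell_lines))
    e2 = rng.normal(0.0, 1.0, size=(n_genes, n_cell_lines))
    mrna = mu[:, None] + shift[:, type_codes] + e1
    scna = _SCNA_SCALE * (_MRNA_SCNA_RHO * e1 +
                          np.sqrt(1 - _MRNA_SCNA_RHO**2) * e2)

    intercepts = rng.normal(0.0, 0.5, size=n_cancer_types)
    readouts = intercepts[type_codes][None, :] + rng.normal(0.0, 1.0, (n_genes, n_cell_lines))

    gene_index = {g: i for i, g in enumerate(genes)}

    def _z(row):
        return (row - row.mean()) / row.std()

    a = truth.essentiality_effect
    for v, r, typ in truth.pairs:
        vi, ri = gene_index[v], gene_index[r]
        if typ == "DU":
            readouts[vi] += a * _z(mrna[ri])   # rescue: growth up with R high
            readouts[ri] += a * _z(mrna[vi])   # R-KD lethal where V low
        else:
            readouts[vi] += -a * _z(mrna[ri])  # DD rescue: growth up with R low

    mrna_gm = GeneMatrix(pd.DataFrame(mrna, index=genes, columns=cells), Modality.MRNA)
    scna_gm = GeneMatrix(pd.DataFrame(scna, index=genes, columns=cells), Modality.SCNA)
    return ScreenPanel(pd.DataFrame(readouts, index=genes, columns=cells),
                       ctypes, mrna_gm, scna_gm, name=name)


def generate_phylo_profiles(truth: PlantedTruth, n_genes: int = DEFAULT_N_GENES,
                            n_species: int = 87, n_blocks: int = 10,
                            seed: int | None = None) -> PhyloProfileMatrix:
    """Block-structured non-negative conservation scores; planted pairs get
    near-identical profiles (correlated evolution)."""
    if n_species < 10:
        raise ValueError("need n_species >= 10")
    rng = _rng(truth, seed, salt=3)
    genes = gene_names(n_genes)
    signatures = rng.gamma(2.0, 1.0, size=(n_blocks, n_species))
    blocks = np.arange(n_genes) % n_blocks
    scale = rng.uniform(0.5, 1.5, size=n_genes)
    profiles = scale[:, None] * signatures[blocks] + \
        0.3 * np.abs(rng.normal(0.0, 1.0, size=(n_genes, n_species)))
    gene_index = {g: i for i, g in enumerate(genes)}
    for v, r, _ in truth.pairs:
        vi, ri = gene_index[v], gene_index[r]
        profiles[ri] = profiles[vi] * (1.0 + truth.profile_noise *
                                       rng.normal(0.0, 1.0, size=n_species))
        profiles[ri] = np.clip(profiles[ri], 0.0, None)
    return PhyloProfileMatrix(pd.DataFrame(profiles, index=genes,
                                           columns=[f"sp{j + 1:02d}" for j in range(n_species)]))


_SINGLE_AGENT_FRACS = (0.95, 0.85, 0.7, 0.55, 0.4)  # five-dose dilution series
_PRIMARY_FRAC = 0.5
_UNTREATED_COUNT = 1000.0


def generate_dose_grids(n_grids: int, synergy_level: float = 1.0, seed: int = 0,
                        noise_sd: float = 0.05,
                        primary_drug: str = "primary") -> list[DoseResponseGrid]:
    """1x5 combination grids under Bliss independence scaled by
    ``synergy_level`` (1 = independent, >1 synergy, <1 antagonism), with
    multiplicative log-normal noise on every count."""
    if synergy_level <= 0:
        raise ValueError("synergy level must be positive")
    rng = np.random.default_rng(seed)

    def noisy(expected, n):
        return expected * np.exp(rng.normal(0.0, noise_sd, size=n))

    grids = []
    for i in range(n_grids):
        single = {d + 1: noisy(_UNTREATED_COUNT * f, 2)
                  for d, f in enumerate(_SINGLE_AGENT_FRACS)}
        combo = {d + 1: noisy(_UNTREATED_COUNT * _PRIMARY_FRAC * f / synergy_level, 2)
                 for d, f in enumerate(_SINGLE_AGENT_FRACS)}
        grids.append(DoseResponseGrid(
            cell_line=f"CL{i + 1:03d}", primary_drug=primary_drug,
            rescuer=f"Ri{i + 1:03d}",
            untreated=noisy(_UNTREATED_COUNT, 5),
            primary=noisy(_UNTREATED_COUNT * _PRIMARY_FRAC, 5),
            single=single, combo=combo))
    return grids


def generate_response_tables(scores: pd.Series, drug: str, effect: float = 2.0,
                             seed: int = 0) -> pd.DataFrame:
    """RECIST-style response labels where the probability of responding
    decreases with the SR score C (logistic link with slope ``-effect``)."""
    rng = np.random.default_rng(seed)
    z = (scores - scores.mean()) / (scores.std() if scores.std() > 0 else 1.0)
    p_resp = 1.0 / (1.0 + np.exp(effect * z))
    responder = rng.random(len(scores)) < p_resp
    labels = np.where(responder,
                      rng.choice(["CR", "PR"], size=len(scores)),
                      rng.choice(["SD", "PD"], size=len(scores)))
    return pd.DataFrame({"sample_id": scores.index, "drug": drug,
                         "response": labels})


def candidate_universe(truth: PlantedTruth, n_candidates: int,
                       n_genes: int = DEFAULT_N_GENES,
                       sr_type: SRType | str = SRType.DU,
                       seed: int | None = None) -> list:
    """Candidate pair list: all planted pairs of the requested type plus
    random non-planted ordered pairs, up to ``n_candidates`` total."""
    sr_type = SRType(sr_type)
    rng = _rng(truth, seed, salt=4)
    genes = gene_names(n_genes)
    planted = truth.pairs_of_type(sr_type)
    planted_any = {(v, r) for v, r, _ in truth.pairs}
    pairs = list(planted)
    seen = set(planted) | planted_any
    while len(pairs) < n_candidates:
        v, r = rng.choice(genes, size=2, replace=False)
        if (v, r) in seen:
            continue
        seen.add((v, r))
        pairs.append((str(v), str(r)))
    return pairs
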