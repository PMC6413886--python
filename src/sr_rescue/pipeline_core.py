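"""Pipeline orchestration: the four screens run sequentially, each consuming
the survivors of the previous one, and every candidate pair is scored by the
sum of its four rank-normalized screen significances (0 = most significant
per screen, so LOWER interaction scores mean stronger rescue evidence).

Modes: ``standard`` runs screens 1-4; ``ICB`` (immune-checkpoint blockade)
drops the in-vitro screen, whose cell-line data lack an immune compartment,
and rescales the score by 4/3 to keep the [0, 4] range comparable.

Also provides the control-network generators used for enrichment baselines:
a degree-preserving shuffle of rescuer endpoints, and a random network with
matched degree structure drawn from a larger gene universe.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import rankdata

from ._fdr import bh_fdr
from .cohort import ClinicalTable, GeneMatrix, Modality, SRType, call_activity
from .screen_clinical import step3_screen
from .screen_phylo import (PhyloProfileMatrix, background_distances,
                           nmf_membership, phylo_distance, step4_screen)
from .screen_sof import step2_screen

__all__ = [
    "CohortData",
    "SRNetwork",
    "rank_normalize",
    "interaction_score",
    "bh_fdr",
    "run_pipeline",
    "shuffle_network",
    "random_degree_matched_network",
]


@dataclass
class CohortData:
    """A tumor cohort: paired molecular matrices plus the clinical table."""

    mrna: GeneMatrix
    scna: GeneMatrix
    clinical: ClinicalTable

    def __post_init__(self) -> None:
        samples = set(self.clinical.sample_ids)
        for gm in (self.mrna, self.scna):
            if not samples.issubset(gm.values.columns):
                raise ValueError("clinical samples missing from molecular matrices")

    def ensure_gii(self) -> "CohortData":
        if "gii" in self.clinical.data.columns and self.clinical.data["gii"].notna().all():
            return self
        return CohortData(self.mrna, self.scna, self.clinical.with_gii(self.scna))


@dataclass
class SRNetwork:
    """Directed vulnerable -> rescuer edge list with interaction scores."""

    edges: pd.DataFrame  # columns: V, R, sr_type, interaction_score, ...
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for col in ("V", "R", "sr_type"):
            if col not in self.edges.columns:
                raise ValueError(f"edge table missing column {col!r}")
        if self.edges.duplicated(["V", "R", "sr_type"]).any():
            raise ValueError("duplicate edges in network")

    @property
    def genes(self) -> set:
        return set(self.edges["V"]) | set(self.edges["R"])

    def __len__(self) -> int:
        return len(self.edges)

    def to_tsv(self, path) -> None:
        self.edges.to_csv(path, sep="\t", index=False)

    def to_graphml(self, path) -> None:
        g = nx.DiGraph()
        for _, row in self.edges.iterrows():
            g.add_edge(row["V"], row["R"], sr_type=str(row["sr_type"]),
                       interaction_score=float(row.get("interaction_score", np.nan)))
        nx.write_graphml(g, path)

    @classmethod
    def from_tsv(cls, path) -> "SRNetwork":
        return cls(pd.read_csv(path, sep="\t"))


def rank_normalize(pvalues) -> np.ndarray:
    """Map significance levels linearly in rank to [0, 1]: the most
    significant pair gets 0, the least significant 1, ties the average."""
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        raise ValueError("nothing to rank-normalize")
    if p.size == 1:
        return np.zeros(1)
    ranks = rankdata(p, method="average")
    return (ranks - 1.0) / (p.size - 1.0)


def interaction_score(r1: float, r2: float, r3: float, r4: float) -> float:
    """Sum of the four rank-normalized screen scores; lower = stronger."""
    rs = np.array([r1, r2, r3, r4], dtype=float)
    if ((rs < 0) | (rs > 1)).any():
        raise ValueError("rank-normalized scores must lie in [0, 1]")
    return float(rs.sum())


def _candidate_key(pair):
    return (pair[0], pair[1])


def run_pipeline(cohort: CohortData, panels, profiles: PhyloProfileMatrix | None,
                candidates, sr_type: SRType | str = SRType.DU, mode: str = "standard",
                fdr_step1: float = 0.2, fdr_step2: float = 0.05, fdr_step3: float = 0.05,
                phylo_quantile: float = 0.05, nmf_rank: int = 20,
                min_type_size: int = 10, seed: int = 0, stop_after: int = 4):
    """Run the sequential screening pipeline and assemble the SR network.

    Returns ``(network, audit)`` where ``audit`` is a per-candidate table of
    representative p-values, pass flags, rank scores and the interaction
    score for pairs reaching the final step.  ``stop_after`` truncates the
    pipeline (1-4) for inspection; the returned network then contains the
    survivors of the last executed step.
    """
    sr_type = SRType(sr_type)
    if mode not in ("standard", "ICB"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "standard" and not panels:
        raise ValueError("standard mode requires at least one screen panel")
    if stop_after >= 4 and profiles is None:
        raise ValueError("phylogenetic profiles required to run step 4")
    candidates = [_candidate_key(p) for p in candidates]
    if len(set(candidates)) != len(candidates):
        raise ValueError("duplicate candidate pairs")
    cohort = cohort.ensure_gii()

    audit = pd.DataFrame(index=pd.MultiIndex.from_tuples(candidates, names=["V", "R"]))
    steps_used: list[int] = []

    # --- step 1: in-vitro conditional essentiality ---
    if mode == "ICB":
        survivors = list(candidates)
    else:
        from .screen_invitro import step1_screen  # deferred: avoids import cycle
        res1 = step1_screen(panels, candidates, sr_type, fdr_step1)
        audit["p1"] = res1["rep_p"]
        audit["pass_step1"] = res1["pass_step1"].reindex(audit.index).eq(True)
        survivors = [p for p in candidates if audit.loc[p, "pass_step1"]]
        steps_used.append(1)
    if stop_after <= 1:
        return _assemble(audit, survivors, sr_type, mode, seed, steps_used), audit

    # --- activity calls shared by steps 2-3 ---
    labels = cohort.clinical.data["cancer_type"]
    samples = list(cohort.clinical.sample_ids)
    act = {
        Modality.MRNA: call_activity(
            GeneMatrix(cohort.mrna.values[samples], Modality.MRNA), labels,
            min_type_size=min_type_size),
        Modality.SCNA: call_activity(
            GeneMatrix(cohort.scna.values[samples], Modality.SCNA), labels,
            min_type_size=min_type_size),
    }

    # --- step 2: molecular survival of the fittest ---
    res2 = step2_screen(act[Modality.MRNA], act[Modality.SCNA], survivors,
                        sr_type, fdr_step2)
    audit["p2"] = res2["rep_p"]
    audit["pass_step2"] = res2["pass_step2"].reindex(audit.index).eq(True)
    survivors = [p for p in survivors if audit.loc[p, "pass_step2"]]
    steps_used.append(2)
    if stop_after <= 2:
        return _assemble(audit, survivors, sr_type, mode, seed, steps_used), audit

    # --- step 3: stratified Cox survival screen ---
    expr = {Modality.MRNA: cohort.mrna, Modality.SCNA: cohort.scna}
    res3 = step3_screen(cohort.clinical, expr, act, survivors, sr_type, fdr_step3)
    audit["p3"] = res3["rep_p"]
    audit["pass_step3"] = res3["pass_step3"].reindex(audit.index).eq(True)
    survivors = [p for p in survivors if audit.loc[p, "pass_step3"]]
    steps_used.append(3)
    if stop_after <= 3:
        return _assemble(audit, survivors, sr_type, mode, seed, steps_used), audit

    # --- step 4: phylogenetic similarity ---
    memberships = nmf_membership(profiles, nmf_rank, seed)
    distances = {}
    for pair in candidates:
        try:
            distances[pair] = phylo_distance(memberships, pair)
        except KeyError:
            distances[pair] = np.nan
    dist = pd.Series(distances)
    background = background_distances(memberships, seed=seed)
    # empirical p: percentile of the pair's distance within the background
    audit["p4"] = [(np.count_nonzero(background <= d) + 1) / (background.size + 1)
                   if np.isfinite(d) else np.nan for d in dist]
    tested4 = dist.dropna()
    # the 5% cap is taken over the full tested candidate universe (see docs)
    passing4 = set(step4_screen(tested4, background, phylo_quantile,
                                cap_universe_size=len(candidates)))
    audit["pass_step4"] = [p in passing4 for p in audit.index]
    survivors = [p for p in survivors if p in passing4]
    steps_used.append(4)
    return _assemble(audit, survivors, sr_type, mode, seed, steps_used), audit


def _assemble(audit: pd.DataFrame, survivors, sr_type: SRType, mode: str,
              seed: int, steps_used) -> SRNetwork:
    """Rank-normalize per-screen significances, compute interaction scores,
    and build the network from the surviving pairs."""
    r_cols = []
    for k in steps_used:
        pcol, rcol = f"p{k}", f"r{k}"
        if pcol not in audit.columns:
            continue
        tested = audit[pcol].notna()
        audit[rcol] = np.nan
        if tested.any():
            audit.loc[tested, rcol] = rank_normalize(audit.loc[tested, pcol].to_numpy())
        r_cols.append(rcol)
    if r_cols:
        score = audit[r_cols].sum(axis=1, min_count=len(r_cols))
        if mode == "ICB":
            score = score * (4.0 / 3.0)
        audit["interaction_score"] = score

    rows = []
    for pair in survivors:
        rows.append({"V": pair[0], "R": pair[1], "sr_type": sr_type.value,
                     "interaction_score": float(audit.loc[pair, "interaction_score"])
                     if "interaction_score" in audit.columns else np.nan})
    edges = pd.DataFrame(rows, columns=["V", "R", "sr_type", "interaction_score"])
    provenance = {"sr_type": sr_type.value, "mode": mode, "seed": int(seed),
                  "steps": list(steps_used), "n_candidates": int(len(audit)),
                  "config_hash": _config_hash(sr_type, mode, seed, steps_used, len(audit))}
    return SRNetwork(edges, provenance)


def _config_hash(*parts) -> str:
    import hashlib

    blob = json.dumps([str(p) for p in parts]).encode()
    return hashlib.sha1(blob).hexdigest()[:12]


def shuffle_network(network: SRNetwork, seed: int = 0, max_retries: int = 1000) -> SRNetwork:
    """Permute rescuer endpoints across edges, preserving every node's
    degree; no self-pairs, no edge left attached to its original rescuer."""
    edges = network.edges
    if len(edges) < 2:
        raise ValueError("need at least two edges to shuffle")
    rng = np.random.default_rng(seed)
    V = edges["V"].to_numpy()
    R = edges["R"].to_numpy()
    for _ in range(max_retries):
        perm = rng.permutation(len(R))
        newR = R[perm]
        if (newR == V).any() or (newR == R).any():
            continue
        if pd.DataFrame({"V": V, "R": newR}).duplicated().any():
            continue
        out = edges.copy()
        out["R"] = newR
        return SRNetwork(out, {**network.provenance, "shuffled_seed": int(seed)})
    raise RuntimeError(f"no valid degree-preserving shuffle in {max_retries} tries")


def random_degree_matched_network(network: SRNetwork, gene_universe,
                                  seed: int = 0) -> SRNetwork:
    """Random network with the same edge count and degree structure: each
    distinct node is relabeled with a gene drawn from the universe."""
    universe = list(gene_universe)
    nodes = sorted(network.genes)
    if len(universe) <= len(nodes):
        raise ValueError("gene universe must be larger than the network's gene set")
    rng = np.random.default_rng(seed)
    relabel = dict(zip(nodes, rng.choice(universe, size=len(nodes), replace=False)))
    out = network.edges.copy()
    out["V"] = out["V"].map(relabel)
    out["R"] = out["R"].map(relabel)
    return SRNetwork(out, {**network.provenance, "randomized_seed": int(seed)})
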