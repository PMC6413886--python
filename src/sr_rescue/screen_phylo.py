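"""Screen 4: phylogenetic-profile similarity filter.

Functionally interacting genes co-evolve, so true rescue pairs should have
similar phylogenetic profiles (per-species conservation scores across a
panel of divergent eukaryotes, 87 species in the reference setting).  The
gene x species score matrix is clustered by non-negative matrix
factorization; each gene's cluster-membership row (the W factor,
L2-normalized) summarizes its evolutionary pattern, and pair similarity is
the Euclidean distance between membership rows.  Pairs pass when their
distance falls below the empirical 5% quantile of a seeded random-pair
background AND within the top-5% most similar candidates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from math import ceil

import numpy as np
import pandas as pd
from sklearn.decomposition import NMF

__all__ = [
    "PhyloProfileMatrix",
    "read_phylo_profiles",
    "nmf_membership",
    "phylo_distance",
    "background_distances",
    "step4_screen",
]

DEFAULT_RANK = 20
DEFAULT_BACKGROUND_PAIRS = 10_000


@dataclass
class PhyloProfileMatrix:
    """Gene x species matrix of non-negative phylogenetic conservation
    scores.  Negative inputs are shifted to zero-minimum on construction."""

    scores: pd.DataFrame

    def __post_init__(self) -> None:
        arr = self.scores.to_numpy(dtype=float)
        if np.isnan(arr).any():
            raise ValueError("phylogenetic profiles must be complete")
        mn = arr.min()
        if mn < 0:
            self.scores = self.scores - mn
            arr = self.scores.to_numpy()
        keep = arr.sum(axis=1) > 0
        if not keep.all():
            warnings.warn(f"dropping {int((~keep).sum())} all-zero gene rows")
            self.scores = self.scores.loc[keep]

    @property
    def gene_ids(self) -> list[str]:
        return list(self.scores.index)

    @property
    def n_species(self) -> int:
        return self.scores.shape[1]


def read_phylo_profiles(path) -> PhyloProfileMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        raise ValueError(f"{path}: duplicated gene rows")
    return PhyloProfileMatrix(df.astype(float))


def nmf_membership(profiles: PhyloProfileMatrix, k: int = DEFAULT_RANK,
                   seed: int = 0) -> pd.DataFrame:
    """NMF cluster memberships: the W factor with L2-normalized rows.

    Multiplicative-update solver, 500 iterations, tolerance 1e-6;
    deterministic for a fixed seed.
    """
    n_genes, n_species = profiles.scores.shape
    if k < 1:
        raise ValueError("rank k must be >= 1")
    if k >= min(n_genes, n_species) and k != 1:
        raise ValueError(f"rank k={k} must be below min(matrix dims)={min(n_genes, n_species)}")
    model = NMF(n_components=k, init="nndsvda" if k > 1 else "random",
                solver="mu", max_iter=500, tol=1e-6, random_state=seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        W = model.fit_transform(profiles.scores.to_numpy())
    norms = np.linalg.norm(W, axis=1, keepdims=True)
    W = np.divide(W, norms, out=np.zeros_like(W), where=norms > 0)
    return pd.DataFrame(W, index=profiles.scores.index,
                        columns=[f"c{i}" for i in range(k)])


def phylo_distance(memberships: pd.DataFrame, pair) -> float:
    """Euclidean distance between the two genes' membership rows."""
    v, r = pair[0], pair[1]
    missing = [g for g in (v, r) if g not in memberships.index]
    if missing:
        raise KeyError(f"genes missing from profile matrix: {missing}")
    return float(np.linalg.norm(memberships.loc[v].to_numpy() -
                                memberships.loc[r].to_numpy()))


def background_distances(memberships: pd.DataFrame,
                         n_pairs: int = DEFAULT_BACKGROUND_PAIRS,
                         seed: int = 0) -> np.ndarray:
    """Distances of random gene pairs from the profile universe (the
    empirical null for the similarity threshold)."""
    rng = np.random.default_rng(seed)
    n = len(memberships)
    if n < 2:
        raise ValueError("need at least two profiled genes")
    i = rng.integers(0, n, size=n_pairs)
    j = rng.integers(0, n - 1, size=n_pairs)
    j = np.where(j >= i, j + 1, j)  # never a self-pair
    W = memberships.to_numpy()
    return np.linalg.norm(W[i] - W[j], axis=1)


def step4_screen(similarities: pd.Series, background: np.ndarray,
                 quantile: float = 0.05, cap_universe_size: int | None = None):
    """Select phylogenetically similar pairs.

    ``similarities`` maps (V, R) -> membership distance; pairs pass when
    their distance is below the ``quantile`` of the random-pair background
    AND within the ceil(quantile * n) most-similar pairs (ties broken by
    stable pair ordering).  ``cap_universe_size`` overrides n when the cap
    should be taken over a larger tested universe than the pairs given.
    Fewer than 20 candidates passes everything through with a warning.
    """
    sim = pd.Series(similarities).astype(float)
    if len(sim) < 20:
        warnings.warn(f"only {len(sim)} candidates; phylogenetic filter passed through")
        return list(sim.index)
    threshold = float(np.quantile(np.asarray(background, dtype=float), quantile))
    n = cap_universe_size if cap_universe_size is not None else len(sim)
    cap = ceil(quantile * n)
    order = sorted(range(len(sim)), key=lambda i: (sim.iloc[i], sim.index[i]))
    top = set(sim.index[i] for i in order[:cap])
    return [p for p in sim.index if sim[p] < threshold and p in top]
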