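"""Bliss-independence synergy scoring for a sparse 1x5 combination design.

One dose of a primary drug (several replicates) is combined with five doses
of a rescuer-targeting inhibitor (two replicates each).  For each dose/
replicate point,

    Ratio(X) = count(primary + R at dose c) / count(primary alone)
    Ratio(Y) = count(R at dose c alone)     / count(untreated)
    Synergism = Ratio(Y) / Ratio(X)

Under Bliss independence the combination's surviving fraction equals the
product of the single-agent fractions, so Synergism = 1; values above 1
mean the combination kills more than expected (synergy), below 1 less
(antagonism).  A rescuer's final synergism is the median over the 10 points
and its significance a rank-sum test of Ratio(Y) vs Ratio(X); across a
screen, BH correction is applied and calls use Synergism > 1.25 (synergy)
or < 0.75 (antagonism) at FDR < 0.05.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._fdr import bh_fdr

__all__ = [
    "DoseResponseGrid",
    "SynergyCall",
    "read_dose_grids",
    "bliss_point",
    "grid_synergy",
    "synergy_call",
    "call_synergies",
]

SYNERGY_THRESHOLD = 1.25
ANTAGONISM_THRESHOLD = 0.75
MIN_VALID_POINTS = 6
RATIO_CAP = 100.0


@dataclass
class DoseResponseGrid:
    """Raw cell counts for one (cell line, rescuer inhibitor) combination."""

    cell_line: str
    primary_drug: str
    rescuer: str
    untreated: np.ndarray          # counts, >= 1 replicate
    primary: np.ndarray            # primary drug alone, >= 1 replicate
    single: dict = field(default_factory=dict)  # dose -> counts (R alone)
    combo: dict = field(default_factory=dict)   # dose -> counts (primary + R)

    def __post_init__(self) -> None:
        self.untreated = np.asarray(self.untreated, dtype=float)
        self.primary = np.asarray(self.primary, dtype=float)
        for name, arr in (("untreated", self.untreated), ("primary", self.primary)):
            if arr.size == 0 or (arr < 0).any():
                raise ValueError(f"{name} counts must be non-empty and non-negative")
            if arr.mean() <= 0:
                raise ValueError(f"{name} counts must be positive on average")
        self.single = {d: np.asarray(v, dtype=float) for d, v in self.single.items()}
        self.combo = {d: np.asarray(v, dtype=float) for d, v in self.combo.items()}
        if set(self.single) != set(self.combo):
            raise ValueError("single-agent and combination doses must match")

    @property
    def doses(self) -> list:
        return sorted(self.single)


@dataclass
class SynergyCall:
    cell_line: str
    rescuer: str
    synergism: float
    p: float
    q: float = np.nan
    call: str = "neither"
    n_points: int = 0


def read_dose_grids(path) -> list[DoseResponseGrid]:
    """Read grids from a long TSV: cell_line, primary_drug,
    rescuer_inhibitor, condition in {untreated, primary, single, combo},
    dose_index, replicate, cell_count."""
    df = pd.read_csv(path, sep="\t")
    grids = []
    for (cl, pdrug, resc), sub in df.groupby(["cell_line", "primary_drug",
                                              "rescuer_inhibitor"]):
        single, combo = {}, {}
        for cond, block in sub.groupby("condition"):
            if cond in ("single", "combo"):
                target = single if cond == "single" else combo
                for dose, rows in block.groupby("dose_index"):
                    target[int(dose)] = rows["cell_count"].to_numpy(dtype=float)
        grids.append(DoseResponseGrid(
            cl, pdrug, resc,
            untreated=sub.loc[sub["condition"] == "untreated", "cell_count"].to_numpy(),
            primary=sub.loc[sub["condition"] == "primary", "cell_count"].to_numpy(),
            single=single, combo=combo))
    return grids


def _ratios(grid: DoseResponseGrid, cap: float = RATIO_CAP):
    """Per-point (Ratio(Y), Ratio(X)) arrays over all dose/replicate points.

    The primary-alone and untreated denominators use the mean of their
    replicates.  Points with a zero combination count are capped at ``cap``
    on the synergism scale (flagged via a warning) rather than infinite.
    """
    primary_ref = float(grid.primary.mean())
    untreated_ref = float(grid.untreated.mean())
    ys, xs = [], []
    for dose in grid.doses:
        single = grid.single[dose]
        combo = grid.combo[dose]
        if single.size != combo.size:
            raise ValueError(f"replicate mismatch at dose {dose}")
        for s, c in zip(single, combo):
            y = s / untreated_ref
            x = c / primary_ref
            if x <= 0:
                if y / cap <= 0:
                    warnings.warn("degenerate zero point excluded")
                    continue
                warnings.warn("zero combination count; synergism capped")
                x = y / cap
            ys.append(y)
            xs.append(x)
    return np.array(ys), np.array(xs)


def bliss_point(grid: DoseResponseGrid, dose: int, replicate: int,
                cap: float = RATIO_CAP) -> float:
    """Synergism Ratio(Y)/Ratio(X) for a single dose/replicate point."""
    s = float(grid.single[dose][replicate])
    c = float(grid.combo[dose][replicate])
    y = s / float(grid.untreated.mean())
    x = c / float(grid.primary.mean())
    if x <= 0:
        warnings.warn("zero combination count; synergism capped")
        return cap
    return min(y / x, cap)


def grid_synergy(grid: DoseResponseGrid):
    """Median synergism over all points plus the two-sided rank-sum p-value
    comparing Ratio(Y) against Ratio(X).  Fewer than MIN_VALID_POINTS valid
    points returns (nan, 1.0, n)."""
    ys, xs = _ratios(grid)
    n = ys.size
    if n < MIN_VALID_POINTS:
        return np.nan, 1.0, n
    synergism = float(np.median(ys / xs))
    if np.allclose(ys, xs):
        return synergism, 1.0, n
    _, p = stats.mannwhitneyu(ys, xs, alternative="two-sided")
    return synergism, float(p), n


def synergy_call(grid: DoseResponseGrid, q: float | None = None,
                 fdr: float = 0.05) -> SynergyCall:
    """Call one grid; ``q`` is the screen-level BH-adjusted p (defaults to
    the raw p when the grid is judged alone)."""
    synergism, p, n = grid_synergy(grid)
    qv = p if q is None else q
    call = "neither"
    if n >= MIN_VALID_POINTS and qv < fdr and np.isfinite(synergism):
        if synergism > SYNERGY_THRESHOLD:
            call = "synergistic"
        elif synergism < ANTAGONISM_THRESHOLD:
            call = "antagonistic"
    return SynergyCall(grid.cell_line, grid.rescuer, synergism, p, qv, call, n)


def call_synergies(grids, fdr: float = 0.05) -> pd.DataFrame:
    """Screen-level calls: BH across all (cell line, rescuer) grids."""
    prelim = [grid_synergy(g) for g in grids]
    ps = np.array([p for _, p, _ in prelim])
    qs = bh_fdr(np.clip(ps, 1e-300, 1.0))
    rows = []
    for g, (syn, p, n), q in zip(grids, prelim, qs):
        call = "neither"
        if n >= MIN_VALID_POINTS and q < fdr and np.isfinite(syn):
            if syn > SYNERGY_THRESHOLD:
                call = "synergistic"
            elif syn < ANTAGONISM_THRESHOLD:
                call = "antagonistic"
        rows.append({"cell_line": g.cell_line, "rescuer": g.rescuer,
                     "synergism": syn, "p": p, "q": q, "call": call,
                     "n_points": n})
    return pd.DataFrame(rows)
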