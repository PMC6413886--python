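"""Tumor-cohort data model.

Gene-by-sample molecular matrices (mRNA expression in log scale, somatic
copy-number alteration as log ratio versus matched normal), per-sample
clinical covariates, per-cancer-type tertile activity calls, the genomic
instability index (GII), and the rank-based inverse-normal transform used
to normalize continuous covariates before model fitting.

Activity calling follows the tertile convention: within each cancer type a
gene is *underactive* (-1) in samples where its value is strictly below the
33rd percentile of that type, *overactive* (+1) strictly above the 67th
percentile, and *normal* (0) otherwise.  Quantiles use linear interpolation;
values equal to a threshold, constant genes, and missing entries are all
assigned the normal state.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import ndtri
from scipy.stats import rankdata

__all__ = [
    "Modality",
    "SRType",
    "PairState",
    "GeneMatrix",
    "ClinicalTable",
    "ActivityMatrix",
    "read_gene_matrix",
    "write_gene_matrix",
    "read_clinical_table",
    "compute_gii",
    "call_activity",
    "pair_states",
    "inverse_normal_transform",
]


class Modality(str, enum.Enum):
    MRNA = "mRNA"
    SCNA = "SCNA"


class SRType(str, enum.Enum):
    """Rescue polarity: rescuer Up- or Down-regulation after vulnerable-gene loss."""

    DU = "DU"
    DD = "DD"


class PairState(str, enum.Enum):
    RESCUED = "rescued"
    NON_RESCUED = "non_rescued"
    OTHER = "other"


UNDER, NORMAL, OVER = -1, 0, 1

#: Tertile boundaries used for activity calling.
LOWER_PERCENTILE = 0.33
UPPER_PERCENTILE = 0.67


@dataclass
class GeneMatrix:
    """Gene x sample numeric matrix tagged with its molecular modality.

    ``values`` is a pandas DataFrame (rows = gene symbols, columns = sample
    identifiers).  Missing measurements are NaN and are excluded from
    quantile computations.
    """

    values: pd.DataFrame
    modality: Modality

    def __post_init__(self) -> None:
        self.modality = Modality(self.modality)
        if self.values.index.duplicated().any():
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene ids: {dups}")
        if self.values.columns.duplicated().any():
            dups = self.values.columns[self.values.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dups}")
        if not all(np.issubdtype(dt, np.number) for dt in self.values.dtypes):
            bad = [c for c, dt in self.values.dtypes.items() if not np.issubdtype(dt, np.number)]
            raise ValueError(f"non-numeric columns: {bad}")
        with np.errstate(invalid="ignore"):
            arr = self.values.to_numpy(dtype=float)
        if np.isinf(arr).any():
            raise ValueError("gene matrix contains infinite values")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


CLINICAL_COLUMNS = [
    "time_days",
    "event",
    "age",
    "sex",
    "race",
    "cancer_type",
    "tumor_purity",
]


@dataclass
class ClinicalTable:
    """Per-sample survival and covariate table, indexed by sample id.

    Required columns: time_days (>0), event (0 censored / 1 death), age,
    sex, race, cancer_type, tumor_purity in [0,1].  The genomic instability
    index ``gii`` is computed from SCNA unless already present.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        missing = [c for c in CLINICAL_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"clinical table missing columns: {missing}")
        if df.index.duplicated().any():
            raise ValueError("duplicate sample ids in clinical table")
        if (df["time_days"] <= 0).any():
            raise ValueError("survival times must be positive")
        if not df["event"].isin([0, 1]).all():
            raise ValueError("event must be 0 or 1")
        purity = df["tumor_purity"].dropna()
        if ((purity < 0) | (purity > 1)).any():
            raise ValueError("tumor_purity must lie in [0,1]")
        if "gii" in df.columns:
            gii = df["gii"].dropna()
            if ((gii < 0) | (gii > 1)).any():
                raise ValueError("gii must lie in [0,1]")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    def with_gii(self, scna: GeneMatrix) -> "ClinicalTable":
        """Return a copy with the GII column computed from an SCNA matrix."""
        df = self.data.copy()
        common = [s for s in df.index if s in scna.values.columns]
        gii = scna.values[common].apply(lambda col: compute_gii(col.to_numpy()), axis=0)
        df.loc[common, "gii"] = gii
        return ClinicalTable(df)


@dataclass
class ActivityMatrix:
    """Discrete activity states in {-1, 0, +1} per gene and sample."""

    states: pd.DataFrame
    modality: Modality
    thresholds: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self.modality = Modality(self.modality)
        if not self.states.isin([UNDER, NORMAL, OVER]).all().all():
            raise ValueError("activity states must be in {-1, 0, 1}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.states.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.states.columns)


def read_gene_matrix(path, modality: Modality | str) -> GeneMatrix:
    """Read a tab-separated gene x sample matrix (first column = gene ids,
    header row = sample ids, 'NA' for missing)."""
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicated gene rows {dups}")
    for col in df.columns:
        if not np.issubdtype(df[col].dtype, np.number):
            bad = df[col][pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()]
            row = bad.index[0] if len(bad) else "?"
            raise ValueError(f"{path}: non-numeric cell at gene {row!r}, sample {col!r}")
    return GeneMatrix(df.astype(float), Modality(modality))


def write_gene_matrix(matrix: GeneMatrix, path) -> None:
    matrix.values.to_csv(path, sep="\t", na_rep="NA")


def read_clinical_table(path) -> ClinicalTable:
    df = pd.read_csv(path, sep="\t")
    if "sample_id" not in df.columns:
        raise ValueError(f"{path}: missing sample_id column")
    return ClinicalTable(df.set_index("sample_id"))


def compute_gii(scna_profile) -> float:
    """Genomic instability index: fraction of genes with |log SCNA ratio| > 1.

    Strict inequality; missing entries are excluded from the denominator.
    """
    arr = np.asarray(scna_profile, dtype=float)
    arr = arr[~np.isnan(arr)]
    if arr.size == 0:
        raise ValueError("empty SCNA profile")
    return float(np.mean(np.abs(arr) > 1))


def call_activity(
    matrix: GeneMatrix,
    cancer_type_labels,
    lower: float = LOWER_PERCENTILE,
    upper: float = UPPER_PERCENTILE,
    min_type_size: int = 10,
) -> ActivityMatrix:
    """Call tertile activity states per gene, recomputing the quantile
    thresholds independently within each cancer type.

    Cancer types with fewer than ``min_type_size`` samples get all-normal
    states (with a warning).  Constant genes and boundary-equal values map
    to the normal state; missing values are excluded from the quantile
    estimate and assigned state 0.
    """
    labels = pd.Series(cancer_type_labels)
    if not labels.index.equals(pd.Index(matrix.values.columns)):
        labels = pd.Series(np.asarray(cancer_type_labels), index=matrix.values.columns)
    if labels.isna().any():
        raise ValueError("every sample needs a cancer-type label")

    states = pd.DataFrame(
        NORMAL, index=matrix.values.index, columns=matrix.values.columns, dtype=np.int8
    )
    thresholds: dict = {}
    for ctype, cols in labels.groupby(labels).groups.items():
        sub = matrix.values.loc[:, list(cols)]
        if sub.shape[1] < min_type_size:
            warnings.warn(
                f"cancer type {ctype!r} has {sub.shape[1]} samples "
                f"(< {min_type_size}); states set to normal"
            )
            continue
        arr = sub.to_numpy(dtype=float)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN rows
            lo = np.nanquantile(arr, lower, axis=1, method="linear")
            hi = np.nanquantile(arr, upper, axis=1, method="linear")
        st = np.zeros_like(arr, dtype=np.int8)
        st[arr < lo[:, None]] = UNDER
        st[arr > hi[:, None]] = OVER
        st[np.isnan(arr)] = NORMAL
        states.loc[:, list(cols)] = st
        thresholds[ctype] = (lo, hi)
    return ActivityMatrix(states, matrix.modality, thresholds)


def pair_states(actV, actR, sr_type: SRType | str):
    """Classify samples into rescued / non-rescued / other for a (V, R) pair.

    DU: rescued = (V underactive and R overactive); DD: rescued =
    (V underactive and R underactive).  Non-rescued = V underactive with R
    not in its rescuing state; everything else is 'other'.
    """
    sr_type = SRType(sr_type)
    v = np.asarray(actV)
    r = np.asarray(actR)
    if v.shape != r.shape:
        raise ValueError(f"activity vectors differ in length: {v.shape} vs {r.shape}")
    rescue_state = OVER if sr_type is SRType.DU else UNDER
    out = np.full(v.shape, PairState.OTHER.value, dtype=object)
    under_v = v == UNDER
    out[under_v & (r == rescue_state)] = PairState.RESCUED.value
    out[under_v & (r != rescue_state)] = PairState.NON_RESCUED.value
    if isinstance(actV, pd.Series):
        return pd.Series(out, index=actV.index)
    return out


def inverse_normal_transform(x) -> np.ndarray:
    """Rank-based inverse-normal (Blom) scores: Phi^-1((r - 3/8)/(n + 1/4)).

    Ties get the average rank; NaN entries are ignored in ranking and stay
    NaN in the output.  Raises on vectors shorter than 2 or all-equal input.
    """
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise ValueError("expected a 1-D vector")
    mask = ~np.isnan(arr)
    vals = arr[mask]
    if vals.size < 2:
        raise ValueError("need at least two non-missing values")
    if np.all(vals == vals[0]):
        raise ValueError("cannot normalize a constant vector")
    ranks = rankdata(vals, method="average")
    scores = ndtri((ranks - 3.0 / 8.0) / (vals.size + 0.25))
    out = np.full(arr.shape, np.nan)
    out[mask] = scores
    return out
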