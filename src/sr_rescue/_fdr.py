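"""Benjamini-Hochberg step-up q-values (shared by all screens)."""

from __future__ import annotations

import numpy as np
from statsmodels.stats.multitest import multipletests

__all__ = ["bh_fdr"]


def bh_fdr(pvals) -> np.ndarray:
    """Standard BH step-up adjusted p-values (q-values)."""
    p = np.asarray(list(pvals), dtype=float)
    if p.size == 0:
        return p
    if np.isnan(p).any() or (p <= 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]
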