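"""Shared statistical helpers (multiple-testing correction, size factors)."""

from __future__ import annotations

import numpy as np
from statsmodels.stats.multitest import multipletests


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values for a vector of p-values."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def median_of_ratios_size_factors(counts: np.ndarray) -> np.ndarray:
    """DESeq-style size factors for a units x samples count matrix.

    Rows with any zero are excluded from the geometric-mean reference (they
    would zero the log-mean); at least one all-positive row is required.
    """
    c = np.asarray(counts, dtype=float)
    if c.ndim != 2 or c.shape[1] < 2:
        raise ValueError("need a units x samples matrix with >= 2 samples")
    if (c.sum(axis=0) == 0).any():
        raise ValueError("a sample has all-zero counts; size factor undefined")
    positive = (c > 0).all(axis=1)
    if not positive.any():
        raise ValueError("no row with all-positive counts; cannot form reference")
    logc = np.log(c[positive])
    log_ref = logc.mean(axis=1, keepdims=True)
    return np.exp(np.median(logc - log_ref, axis=0))
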