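"""Benjamini-Hochberg false-discovery-rate adjustment, shared by the
methylation and count differential tests."""

from __future__ import annotations

import numpy as np
from statsmodels.stats.multitest import multipletests


def benjamini_hochberg(p) -> np.ndarray:
    """Step-up BH adjusted p-values, returned in the input order.

    padj_i = min_{k: p_(k) >= p_i} m * p_(k) / k, capped at 1, with the
    usual monotonicity enforcement; equals ``p`` itself for a single test.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("p must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.any(np.isnan(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
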