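"""Shared statistical helpers: BH FDR and Fisher's combined probability."""

from __future__ import annotations

import numpy as np
from scipy import stats


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values with monotonicity enforcement.

    NaN p-values are propagated as NaN and excluded from the family size.
    """
    p = np.asarray(p_values, dtype=float)
    q = np.full(p.shape, np.nan)
    mask = ~np.isnan(p)
    pv = p[mask]
    if pv.size == 0:
        return q
    if np.any((pv < 0) | (pv > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = pv.size
    order = np.argsort(pv, kind="mergesort")
    ranked = pv[order] * m / np.arange(1, m + 1)
    # enforce monotone non-decreasing q along increasing p
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(ranked, 1.0)
    q[mask] = out
    return q


def fisher_combined(p_values) -> tuple[float, int, float]:
    """Fisher's combined probability test.

    Returns (X2, df, combined p) with X2 = -2 * sum(ln p_i) and df = 2k.
    Zero p-values are clamped to the smallest positive float.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("no p-values to combine")
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    x2 = float(-2.0 * np.sum(np.log(p)))
    df = 2 * p.size
    return x2, df, float(stats.chi2.sf(x2, df))
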