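"""Aggregated-cell peak matrix drawn from a known block precision structure.

The true precision matrix is the identity plus -partial_corr entries on every
within-block pair, so partial correlations are exactly the configured value
inside blocks and zero outside.  The ledger records the matrix itself, making
every downstream recovery statement checkable by direct inversion.
"""

from __future__ import annotations

import numpy as np

from .config import SyntheticConfig


def true_precision(config: SyntheticConfig) -> np.ndarray:
    theta = np.eye(config.n_peaks)
    for blk in config.ccan_blocks:
        idx = list(blk.peak_indices)
        k = len(idx)
        for a in range(k):
            for b in range(a + 1, k):
                theta[idx[a], idx[b]] = theta[idx[b], idx[a]] = -blk.partial_corr
        if blk.partial_corr * (k - 1) >= 1.0:
            raise ValueError(
                f"block partial correlation {blk.partial_corr} with {k} peaks "
                "is not positive definite"
            )
    return theta


def generate_coaccessible_counts(
    config: SyntheticConfig, n_samples: int | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """(samples x peaks Gaussian draw, true precision matrix)."""
    theta = true_precision(config)
    n = n_samples if n_samples is not None else config.n_coaccess_samples
    rng = config.rng(3)
    cov = np.linalg.inv(theta)
    chol = np.linalg.cholesky(cov)
    z = rng.standard_normal((n, config.n_peaks))
    return z @ chol.T, theta
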