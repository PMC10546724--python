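"""Windowed Poisson peak calling with dynamic local background, and
multi-sample consensus via Fisher's combined probability test."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .intervals import GenomicInterval
from .stats import bh_fdr, fisher_combined


@dataclass(frozen=True)
class CalledPeak:
    interval: GenomicInterval
    sample: str
    cluster: str
    p: float
    summit_count: int


def call_peaks(
    midpoints: dict[str, np.ndarray],
    chrom_lengths: dict[str, int],
    sample: str = "sample",
    cluster: str = "cluster",
    window: int = 200,
    step: int = 100,
    lambda_scales: tuple[int, ...] = (1000, 5000, 10000),
    p_threshold: float = 1e-5,
) -> list[CalledPeak]:
    """Call enriched windows against a dynamic Poisson background.

    For every sliding window the local rate is the maximum of the genome-wide
    fragment rate and the rates measured in centered spans at each
    ``lambda_scales`` width, all rescaled to the window size; the window count
    is tested against the upper Poisson tail.  Significant (p <= threshold)
    windows that touch or overlap are merged; a merged peak takes the minimum
    member p and the maximum member count as its summit count.
    """
    genome_size = sum(chrom_lengths.values())
    total = sum(len(v) for v in midpoints.values())
    if total == 0 or genome_size == 0:
        return []
    lam_genome = total * window / genome_size
    peaks: list[CalledPeak] = []
    for chrom, mids in sorted(midpoints.items()):
        clen = chrom_lengths.get(chrom)
        if clen is None:
            raise ValueError(f"no length for chromosome {chrom}")
        if len(mids) == 0:
            continue
        mids = np.sort(np.asarray(mids))
        starts = np.arange(0, max(clen - window, 0) + 1, step)
        counts = np.searchsorted(mids, starts + window) - np.searchsorted(mids, starts)
        lam = np.full(starts.shape, lam_genome)
        centers = starts + window / 2
        for scale in lambda_scales:
            lo = np.searchsorted(mids, centers - scale / 2)
            hi = np.searchsorted(mids, centers + scale / 2)
            lam = np.maximum(lam, (hi - lo) * window / scale)
        pvals = stats.poisson.sf(counts - 1, lam)
        sig = np.nonzero(pvals <= p_threshold)[0]
        if sig.size == 0:
            continue
        # merge windows whose spans touch or overlap
        run_start = sig[0]
        prev = sig[0]
        runs = []
        for i in sig[1:]:
            if starts[i] <= starts[prev] + window:
                prev = i
            else:
                runs.append((run_start, prev))
                run_start = prev = i
        runs.append((run_start, prev))
        for a, b in runs:
            members = sig[(sig >= a) & (sig <= b)]
            peaks.append(
                CalledPeak(
                    GenomicInterval(chrom, int(starts[a]), int(min(starts[b] + window, clen))),
                    sample,
                    cluster,
                    float(pvals[members].min()),
                    int(counts[members].max()),
                )
            )
    return peaks


def consensus_peaks(
    sample_peaks: dict[str, list[CalledPeak]],
    min_samples: int = 2,
    fdr: float = 0.05,
) -> pd.DataFrame:
    """Fisher-method consensus across samples.

    Peaks from all samples are grouped by single-linkage interval overlap;
    each group combines its member p-values with Fisher's method (X2 =
    -2 sum ln p, df = 2k).  Groups supported by at least ``min_samples``
    distinct samples and passing BH FDR <= ``fdr`` are reported with their
    union-span coordinates.
    """
    if len(sample_peaks) < 2:
        raise ValueError("consensus requires >= 2 samples")
    records = []
    for sample in sorted(sample_peaks):
        for pk in sample_peaks[sample]:
            records.append((pk.interval.chrom, pk.interval.start, pk.interval.end, sample, pk.p))
    if not records:
        return pd.DataFrame(
            columns=["chrom", "start", "end", "n_samples", "x2", "df", "p_combined", "fdr"]
        )
    rec = sorted(records)
    groups: list[list[tuple]] = []
    cur = [rec[0]]
    cur_chrom, cur_end = rec[0][0], rec[0][2]
    for r in rec[1:]:
        if r[0] == cur_chrom and r[1] < cur_end:
            cur.append(r)
            cur_end = max(cur_end, r[2])
        else:
            groups.append(cur)
            cur = [r]
            cur_chrom, cur_end = r[0], r[2]
    groups.append(cur)
    rows = []
    for g in groups:
        samples = {r[3] for r in g}
        x2, df, p = fisher_combined([r[4] for r in g])
        rows.append(
            {
                "chrom": g[0][0],
                "start": min(r[1] for r in g),
                "end": max(r[2] for r in g),
                "n_samples": len(samples),
                "x2": x2,
                "df": df,
                "p_combined": p,
            }
        )
    df_out = pd.DataFrame(rows)
    df_out["fdr"] = bh_fdr(df_out["p_combined"])
    keep = (df_out["n_samples"] >= min_samples) & (df_out["fdr"] <= fdr)
    return df_out[keep].reset_index(drop=True)
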