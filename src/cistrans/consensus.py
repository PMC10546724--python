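"""Cross-study consensus for differential genes and peaks.

DEGs match by gene identity within a cell type, requiring |log2FC| above a
threshold and the same sign across studies; DAPs match by interval overlap,
requiring >= 200 bp of overlap, interval Jaccard >= 0.25, and the same sign.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .intervals import GenomicInterval, overlap_pairs


def consensus_degs(
    tables: dict[str, pd.DataFrame],
    min_abs_lfc: float = 0.2,
) -> pd.DataFrame:
    """Tiered DEG consensus across studies.

    Each table needs gene, celltype, log2fc columns.  Per (celltype, gene):
    studies where |log2fc| > threshold are collected; genes present with the
    same sign in >= 2 studies form the 2-study tier, in all studies the
    all-study tier.  Genes with conflicting signs are excluded.
    """
    n_studies = len(tables)
    frames = []
    for study, df in tables.items():
        sub = df[df["log2fc"].abs() > min_abs_lfc][["gene", "celltype", "log2fc"]].copy()
        sub["study"] = study
        frames.append(sub)
    frames = [f for f in frames if not f.empty]
    if not frames:
        return pd.DataFrame(
            columns=["gene", "celltype", "direction", "studies", "n_studies", "all_studies"]
        )
    allf = pd.concat(frames, ignore_index=True)
    rows = []
    for (ct, gene), grp in allf.groupby(["celltype", "gene"]):
        signs = set(np.sign(grp["log2fc"]))
        if len(signs) > 1:
            continue
        k = grp["study"].nunique()
        if k < 2:
            continue
        rows.append(
            {
                "gene": gene,
                "celltype": ct,
                "direction": "+" if signs == {1.0} else "-",
                "studies": ",".join(sorted(grp["study"])),
                "n_studies": k,
                "all_studies": k == n_studies,
            }
        )
    return pd.DataFrame(
        rows, columns=["gene", "celltype", "direction", "studies", "n_studies", "all_studies"]
    )


@dataclass(frozen=True)
class ConsensusMatch:
    peak_a: GenomicInterval
    peak_b: GenomicInterval
    overlap_bp: int
    jaccard: float
    direction: str


def match_daps(
    peaks_a: list[GenomicInterval],
    lfc_a,
    peaks_b: list[GenomicInterval],
    lfc_b,
    min_overlap: int = 200,
    min_jaccard: float = 0.25,
) -> list[ConsensusMatch]:
    """Interval-overlap DAP matching between two studies.

    For every overlapping pair: overlap width >= min_overlap AND interval
    Jaccard (intersection / merged span) >= min_jaccard AND same log2fc sign.
    A peak is consensus if it appears in at least one kept match.
    """
    lfc_a = np.asarray(lfc_a, dtype=float)
    lfc_b = np.asarray(lfc_b, dtype=float)
    out = []
    for i, j in overlap_pairs(peaks_a, peaks_b):
        a, b = peaks_a[i], peaks_b[j]
        ov = a.overlap_bp(b)
        if ov < min_overlap:
            continue
        jac = a.jaccard(b)
        if jac < min_jaccard:
            continue
        if np.sign(lfc_a[i]) != np.sign(lfc_b[j]):
            continue
        out.append(ConsensusMatch(a, b, ov, jac, "+" if lfc_a[i] > 0 else "-"))
    return out


def consensus_dap_set(matches: list[ConsensusMatch], side: str = "a") -> set:
    """Distinct consensus peaks on one side of a match list."""
    attr = "peak_a" if side == "a" else "peak_b"
    return {getattr(m, attr) for m in matches}
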