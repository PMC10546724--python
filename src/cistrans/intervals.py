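"""Genomic interval primitives.

Coordinates are 0-based, half-open throughout the package; readers for 1-based
formats convert at the boundary.  The promoter convention used everywhere is
[TSS - 2000 bp, TSS + 200 bp), oriented by gene strand.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

PROMOTER_UPSTREAM = 2000
PROMOTER_DOWNSTREAM = 200


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A chrom/start/end interval with optional strand.

    ``start`` is inclusive, ``end`` exclusive.  Strand is '+', '-' or '.'.
    """

    chrom: str
    start: int
    end: int
    strand: str = field(default=".", compare=False)

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"empty interval {self.chrom}:{self.start}-{self.end}")
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"bad strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def overlap_bp(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def union_bp(self, other: "GenomicInterval") -> int:
        """Width of the merged span of two overlapping intervals."""
        if self.chrom != other.chrom:
            raise ValueError("union of intervals on different chromosomes")
        return max(self.end, other.end) - min(self.start, other.start)

    def jaccard(self, other: "GenomicInterval") -> float:
        """Intersection width over merged-region width."""
        inter = self.overlap_bp(other)
        if inter == 0:
            return 0.0
        return inter / self.union_bp(other)

    def distance(self, other: "GenomicInterval") -> float:
        """Gap between intervals; 0 if overlapping, inf across chromosomes."""
        if self.chrom != other.chrom:
            return float("inf")
        if self.overlaps(other):
            return 0.0
        return float(max(self.start, other.start) - min(self.end, other.end) + 1) - 1.0

    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    @property
    def name(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"


def promoter_interval(
    chrom: str,
    tss: int,
    strand: str,
    upstream: int = PROMOTER_UPSTREAM,
    downstream: int = PROMOTER_DOWNSTREAM,
) -> GenomicInterval:
    """Promoter window around a TSS, strand-oriented.

    '+' strand: [tss - upstream, tss + downstream);
    '-' strand: [tss - downstream, tss + upstream).
    """
    if strand == "+":
        return GenomicInterval(chrom, tss - upstream, tss + downstream, "+")
    if strand == "-":
        return GenomicInterval(chrom, tss - downstream, tss + upstream, "-")
    raise ValueError(f"promoter requires stranded gene, got {strand!r}")


def intervals_to_frame(intervals: Sequence[GenomicInterval]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": [iv.chrom for iv in intervals],
            "start": [iv.start for iv in intervals],
            "end": [iv.end for iv in intervals],
            "strand": [iv.strand for iv in intervals],
        }
    )


def frame_to_intervals(df: pd.DataFrame) -> list[GenomicInterval]:
    strands = df["strand"] if "strand" in df.columns else ["."] * len(df)
    return [
        GenomicInterval(c, int(s), int(e), st)
        for c, s, e, st in zip(df["chrom"], df["start"], df["end"], strands)
    ]


def overlap_pairs(
    a: Sequence[GenomicInterval], b: Sequence[GenomicInterval]
) -> list[tuple[int, int]]:
    """All (i, j) index pairs with a[i] overlapping b[j].

    Sweep over per-chromosome sorted lists; adequate for the peak-set sizes
    this package handles (tens of thousands).
    """
    by_chrom: dict[str, list[tuple[int, int, int]]] = {}
    for j, iv in enumerate(b):
        by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end, j))
    for lst in by_chrom.values():
        lst.sort()
    out: list[tuple[int, int]] = []
    for i, iv in enumerate(a):
        cand = by_chrom.get(iv.chrom)
        if not cand:
            continue
        starts = [c[0] for c in cand]
        lo = np.searchsorted(starts, iv.end)
        for s, e, j in cand[:lo]:
            if e > iv.start:
                out.append((i, j))
    return out


def any_overlap(query: GenomicInterval, targets: Iterable[GenomicInterval]) -> bool:
    return any(query.overlaps(t) for t in targets)


def within_window(
    iv: GenomicInterval, chrom: str, pos: int, window: int = 500_000
) -> bool:
    """True iff any coordinate of ``iv`` lies within ±window of pos (inclusive)."""
    if iv.chrom != chrom:
        return False
    # closest point of the half-open interval to pos
    nearest = min(max(pos, iv.start), iv.end - 1)
    return abs(nearest - pos) <= window
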