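"""Gene annotation container: genes, exons, promoters and first introns."""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .intervals import GenomicInterval, promoter_interval


@dataclass
class GeneAnnotation:
    """Gene models with the derived features the pipeline anchors on.

    ``genes``: DataFrame indexed by gene_id with columns chrom, start, end,
    strand, tss.  ``exons``: DataFrame with gene_id, chrom, start, end and an
    exon_number counted in transcription order (1 = first exon).
    """

    genes: pd.DataFrame
    exons: pd.DataFrame

    def __post_init__(self) -> None:
        need = {"chrom", "start", "end", "strand", "tss"}
        if not need <= set(self.genes.columns):
            raise ValueError(f"genes frame needs columns {sorted(need)}")
        if not {"gene_id", "chrom", "start", "end", "exon_number"} <= set(self.exons.columns):
            raise ValueError("exons frame needs gene_id, chrom, start, end, exon_number")

    def promoter(self, gene_id: str) -> GenomicInterval:
        g = self.genes.loc[gene_id]
        return promoter_interval(g["chrom"], int(g["tss"]), g["strand"])

    def promoters(self) -> dict[str, GenomicInterval]:
        return {gid: self.promoter(gid) for gid in self.genes.index}

    def intron1(self, gene_id: str) -> GenomicInterval | None:
        """First intron in transcription order; None for single-exon genes."""
        ex = self.exons[self.exons["gene_id"] == gene_id].sort_values("exon_number")
        if len(ex) < 2:
            return None
        strand = self.genes.loc[gene_id, "strand"]
        e1, e2 = ex.iloc[0], ex.iloc[1]
        if strand == "+":
            start, end = int(e1["end"]), int(e2["start"])
        else:
            start, end = int(e2["end"]), int(e1["start"])
        if end <= start:
            return None
        return GenomicInterval(e1["chrom"], start, end, strand)

    def exon_intervals(self) -> list[GenomicInterval]:
        return [
            GenomicInterval(r.chrom, int(r.start), int(r.end))
            for r in self.exons.itertuples()
        ]
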