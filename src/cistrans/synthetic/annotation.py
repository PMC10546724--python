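"""Synthetic genome annotation: genes, exons, peaks, tag SNPs, blacklist.

Layout is deterministic given the config seed.  Co-accessibility block peaks
are placed in compact loci (well within the 500 kb co-accessibility limit);
each causal block's first peak hosts the promoter of its anchor gene, its
second peak stays distal and noncoding so it can act as a cCRE.  A stated
fraction of the remaining peaks overlap promoters or first introns of filler
genes; the rest are distal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..annotation import GeneAnnotation
from ..intervals import GenomicInterval
from .config import SyntheticConfig

BLOCK_SPACING = 8_000  # between peaks of one block
BLOCK_STRIDE = 2_500_000  # between block loci on one chromosome
GENE_BODY = 20_000
EXON1_LEN = 300
INTRON1_LEN = 2_000
EXON2_LEN = 500


@dataclass
class AnnotationBundle:
    annotation: GeneAnnotation
    peaks: list  # GenomicInterval
    peak_ids: list
    tag_snps: pd.DataFrame  # chrom, pos
    blacklist: list
    anchor_genes: dict = field(default_factory=dict)  # block index -> gene_id


def _gene_records(gene_id: str, chrom: str, tss: int, strand: str):
    """Gene + two exons defining a first intron, strand-oriented."""
    if strand == "+":
        gene = {"gene_id": gene_id, "chrom": chrom, "start": tss, "end": tss + GENE_BODY,
                "strand": "+", "tss": tss}
        e1 = {"gene_id": gene_id, "chrom": chrom, "start": tss, "end": tss + EXON1_LEN,
              "exon_number": 1}
        e2s = tss + EXON1_LEN + INTRON1_LEN
        e2 = {"gene_id": gene_id, "chrom": chrom, "start": e2s, "end": e2s + EXON2_LEN,
              "exon_number": 2}
    else:
        gene = {"gene_id": gene_id, "chrom": chrom, "start": tss + 1 - GENE_BODY,
                "end": tss + 1, "strand": "-", "tss": tss}
        e1 = {"gene_id": gene_id, "chrom": chrom, "start": tss + 1 - EXON1_LEN,
              "end": tss + 1, "exon_number": 1}
        e2e = tss + 1 - EXON1_LEN - INTRON1_LEN
        e2 = {"gene_id": gene_id, "chrom": chrom, "start": e2e - EXON2_LEN, "end": e2e,
              "exon_number": 2}
    return gene, [e1, e2]


def generate_annotation(config: SyntheticConfig) -> AnnotationBundle:
    chroms = sorted(config.chrom_lengths)
    if not chroms:
        raise ValueError("chrom_lengths must not be empty")
    if config.n_genes <= 0 or config.n_peaks <= 0:
        raise ValueError("n_genes and n_peaks must be positive")
    rng = config.rng(1)
    peak_w = config.peak_width
    peaks: list[GenomicInterval | None] = [None] * config.n_peaks

    # 1. block peaks at compact loci, round-robin over chromosomes
    block_locus: dict[int, tuple[str, int]] = {}
    for b, blk in enumerate(config.ccan_blocks):
        chrom = chroms[b % len(chroms)]
        locus = 1_000_000 + (b // len(chroms)) * BLOCK_STRIDE
        span = (len(blk.peak_indices) - 1) * BLOCK_SPACING + peak_w
        if locus + span + GENE_BODY > config.chrom_lengths[chrom]:
            raise ValueError(
                f"chromosome {chrom} too short ({config.chrom_lengths[chrom]} bp) "
                f"for co-accessibility block {b}"
            )
        if span > 500_000:
            raise ValueError(f"block {b} spans {span} bp, beyond the 500 kb limit")
        block_locus[b] = (chrom, locus)
        for i, pidx in enumerate(blk.peak_indices):
            start = locus + i * BLOCK_SPACING
            peaks[pidx] = GenomicInterval(chrom, start, start + peak_w)

    # 2. remaining peaks on a coarse grid in the second half of each chromosome
    free = [i for i, p in enumerate(peaks) if p is None]
    grid_step = 40_000
    slot = 0
    for i in free:
        chrom = chroms[slot % len(chroms)]
        start = 5_000_000 + (slot // len(chroms)) * grid_step + int(rng.integers(0, 1000))
        if start + peak_w > config.chrom_lengths[chrom]:
            raise ValueError(f"chromosome {chrom} too short to host {config.n_peaks} peaks")
        peaks[i] = GenomicInterval(chrom, start, start + peak_w)
        slot += 1
    peak_ids = [p.name for p in peaks]

    # 3. anchor genes: promoter overlapping each block's first peak
    genes, exons = [], []
    anchor_genes: dict[int, str] = {}
    for b, blk in enumerate(config.ccan_blocks):
        if b >= config.n_genes:
            break
        gid = f"gene{b}"
        anchor = peaks[blk.peak_indices[0]]
        g, ex = _gene_records(gid, anchor.chrom, anchor.start + peak_w // 2, "+")
        genes.append(g)
        exons.extend(ex)
        anchor_genes[b] = gid

    # 4. a stated fraction of non-block peaks get promoter/intron-1 genes
    block_peaks = {i for blk in config.ccan_blocks for i in blk.peak_indices}
    distal = [i for i in range(config.n_peaks) if i not in block_peaks]
    n_promoter_peaks = int(round(config.promoter_peak_fraction * config.n_peaks))
    next_gene = len(genes)
    for k, pidx in enumerate(distal[:n_promoter_peaks]):
        if next_gene >= config.n_genes:
            break
        gid = f"gene{next_gene}"
        pk = peaks[pidx]
        strand = "+" if k % 2 == 0 else "-"
        g, ex = _gene_records(gid, pk.chrom, pk.midpoint(), strand)
        genes.append(g)
        exons.extend(ex)
        next_gene += 1

    # 5. filler genes in unoccupied space
    slot = 0
    while next_gene < config.n_genes:
        chrom = chroms[slot % len(chroms)]
        tss = 8_200_000 + (slot // len(chroms)) * 35_000
        if tss + GENE_BODY > config.chrom_lengths[chrom]:
            raise ValueError(f"chromosome {chrom} too short to host {config.n_genes} genes")
        g, ex = _gene_records(f"gene{next_gene}", chrom, tss, "+")
        genes.append(g)
        exons.extend(ex)
        next_gene += 1
        slot += 1

    annotation = GeneAnnotation(
        genes=pd.DataFrame(genes).set_index("gene_id"),
        exons=pd.DataFrame(exons),
    )

    # 6. tag SNPs: "auto" sentinels resolve to 100 kb beyond their block locus
    tag_rows = []
    for chrom, pos in config.gwas_tags:
        if chrom == "auto":
            b = int(pos)
            if b in block_locus:
                c, locus = block_locus[b]
                tag_rows.append({"chrom": c, "pos": locus + 100_000})
        else:
            tag_rows.append({"chrom": chrom, "pos": int(pos)})
    tag_snps = pd.DataFrame(tag_rows, columns=["chrom", "pos"])

    blacklist = [
        GenomicInterval(chroms[0], 9_900_000, 9_950_000),
    ]
    return AnnotationBundle(annotation, peaks, peak_ids, tag_snps, blacklist, anchor_genes)
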