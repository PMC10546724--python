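"""Readers and writers for the plain-text formats the pipeline exchanges.

Matrices travel as MatrixMarket (.mtx) with row/column TSVs; intervals as
BED; gene models as GTF; sequences as FASTA (Bio.SeqIO); motifs as JASPAR
PFM text (Bio.motifs); SNPs as a minimal VCF with an AF INFO field; gene
sets as GMT.  All genomic coordinates are converted to 0-based half-open at
this boundary (BED already is; GTF and VCF are 1-based).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO, motifs as bio_motifs
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from scipy import io as spio, sparse

from .annotation import GeneAnnotation
from .intervals import GenomicInterval
from .pwm import PWM, MarkovBackground, build_pwm


def write_mtx(path, matrix, row_ids, col_ids) -> None:
    path = Path(path)
    spio.mmwrite(str(path), sparse.csr_matrix(matrix))
    pd.Series(row_ids).to_csv(path.with_suffix(".rows.tsv"), sep="\t", index=False, header=False)
    pd.Series(col_ids).to_csv(path.with_suffix(".cols.tsv"), sep="\t", index=False, header=False)


def read_mtx(path):
    path = Path(path)
    mat = spio.mmread(str(path)).tocsr()
    rows = pd.read_csv(path.with_suffix(".rows.tsv"), sep="\t", header=None)[0].tolist()
    cols = pd.read_csv(path.with_suffix(".cols.tsv"), sep="\t", header=None)[0].tolist()
    return mat, rows, cols


def write_bed(path, intervals: list[GenomicInterval], names=None, scores=None) -> None:
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            name = names[i] if names is not None else iv.name
            score = scores[i] if scores is not None else 0
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{score}\t{iv.strand}\n")


def read_bed(path) -> list[GenomicInterval]:
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.rstrip("\n").split("\t")
            strand = f[5] if len(f) > 5 else "."
            out.append(GenomicInterval(f[0], int(f[1]), int(f[2]), strand))
    return out


def write_gtf(path, annotation: GeneAnnotation) -> None:
    """GTF (1-based inclusive) with gene and exon features."""
    with open(path, "w") as fh:
        for gid, g in annotation.genes.iterrows():
            attrs = f'gene_id "{gid}";'
            fh.write(
                f"{g['chrom']}\tcistrans\tgene\t{int(g['start']) + 1}\t{int(g['end'])}\t.\t{g['strand']}\t.\t{attrs}\n"
            )
            ex = annotation.exons[annotation.exons["gene_id"] == gid].sort_values("exon_number")
            for e in ex.itertuples():
                ea = f'gene_id "{gid}"; exon_number "{int(e.exon_number)}";'
                fh.write(
                    f"{e.chrom}\tcistrans\texon\t{int(e.start) + 1}\t{int(e.end)}\t.\t{g['strand']}\t.\t{ea}\n"
                )


def read_gtf(path) -> GeneAnnotation:
    genes, exons = [], []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            attrs = dict(
                kv.strip().split(" ", 1) for kv in f[8].strip().strip(";").split(";") if kv.strip()
            )
            gid = attrs["gene_id"].strip('"')
            start, end = int(f[3]) - 1, int(f[4])
            if f[2] == "gene":
                tss = start if f[6] == "+" else end - 1
                genes.append(
                    {"gene_id": gid, "chrom": f[0], "start": start, "end": end, "strand": f[6], "tss": tss}
                )
            elif f[2] == "exon":
                exons.append(
                    {
                        "gene_id": gid,
                        "chrom": f[0],
                        "start": start,
                        "end": end,
                        "exon_number": int(attrs.get("exon_number", "0").strip('"')),
                    }
                )
    gdf = pd.DataFrame(genes).set_index("gene_id")
    return GeneAnnotation(genes=gdf, exons=pd.DataFrame(exons))


def write_fasta(path, sequences: dict[str, str]) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_vcf(path, snps: pd.DataFrame, contigs: dict[str, int] | None = None) -> None:
    """Minimal sites-only VCF; ``snps`` has id, chrom, pos (0-based), ref,
    alt, maf.  Positions are written 1-based; MAF goes to the AF INFO key."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=AF,Number=A,Type=Float,Description="Allele Frequency">\n')
        for c, ln in (contigs or {}).items():
            fh.write(f"##contig=<ID={c},length={ln}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for r in snps.sort_values(["chrom", "pos"]).itertuples():
            fh.write(
                f"{r.chrom}\t{int(r.pos) + 1}\t{r.id}\t{r.ref}\t{r.alt}\t.\tPASS\tAF={r.maf:.6g}\n"
            )


def read_vcf(path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            info = dict(kv.split("=", 1) for kv in f[7].split(";") if "=" in kv)
            afs = info.get("AF", "0").split(",")
            for alt, af in zip(f[4].split(","), afs):
                rows.append(
                    {
                        "id": f[2],
                        "chrom": f[0],
                        "pos": int(f[1]) - 1,
                        "ref": f[3],
                        "alt": alt,
                        "maf": float(af),
                    }
                )
    return pd.DataFrame(rows, columns=["id", "chrom", "pos", "ref", "alt", "maf"])


def write_jaspar_pfms(path, pwms: list[PWM], counts: dict[str, np.ndarray]) -> None:
    """JASPAR-format PFM text from the original count matrices."""
    with open(path, "w") as fh:
        for pwm in pwms:
            c = counts[pwm.tf]
            if c.shape[0] != 4:
                c = c.T
            fh.write(f">{pwm.tf}\t{pwm.tf}\n")
            for base, row in zip("ACGT", c):
                vals = " ".join(f"{v:.0f}" for v in row)
                fh.write(f"{base}  [ {vals} ]\n")


def read_jaspar_pfms(
    path, background: MarkovBackground | None = None, pseudocount: float = 0.8
) -> list[PWM]:
    with open(path) as fh:
        records = bio_motifs.parse(fh, "jaspar")
    out = []
    for m in records:
        counts = np.array([m.counts[b] for b in "ACGT"], dtype=float)
        out.append(build_pwm(counts, background=background, tf=m.matrix_id or m.name, pseudocount=pseudocount))
    return out


def write_gmt(path, gene_sets: dict[str, set]) -> None:
    with open(path, "w") as fh:
        for term, genes in gene_sets.items():
            fh.write("\t".join([term, term] + sorted(genes)) + "\n")


def read_gmt(path) -> dict[str, set]:
    out = {}
    with open(path) as fh:
        for line in fh:
            f = line.rstrip("\n").split("\t")
            if len(f) >= 3:
                out[f[0]] = set(f[2:])
    return out


def write_json(path, obj) -> None:
    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        raise TypeError(f"not JSON serializable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True, default=default)


def read_json(path):
    with open(path) as fh:
        return json.load(fh)
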