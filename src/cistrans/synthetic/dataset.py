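"""Assemble and serialize the full synthetic dataset with its truth ledger."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .. import io as ctio
from .annotation import AnnotationBundle, generate_annotation
from .coaccess import generate_coaccessible_counts
from .config import SyntheticConfig, default_config
from .counts import CountsBundle, generate_counts
from .sequences import SequenceBundle, generate_sequences_snps_motifs


@dataclass
class SyntheticDataset:
    config: SyntheticConfig
    annotation: AnnotationBundle
    counts: CountsBundle
    sequences: SequenceBundle
    coaccess_samples: np.ndarray
    true_precision: np.ndarray
    truth: dict


def _truth_ledger(
    config: SyntheticConfig,
    ann: AnnotationBundle,
    counts: CountsBundle,
    seqs: SequenceBundle,
    theta: np.ndarray,
) -> dict:
    deg = {}
    dap = {}
    for eff in config.gene_effects:
        gid = ann.annotation.genes.index[eff.feature]
        deg.setdefault(str(eff.cluster), {})[gid] = eff.log2fc
    for eff in config.peak_effects:
        dap.setdefault(str(eff.cluster), {})[ann.peak_ids[eff.feature]] = eff.log2fc
    blocks = [
        {"peaks": [ann.peak_ids[i] for i in blk.peak_indices], "partial_corr": blk.partial_corr}
        for blk in config.ccan_blocks
    ]
    anchor = {str(b): gid for b, gid in ann.anchor_genes.items()}
    # causal SNP-motif pairs: planted SNPs with MAF >= 1% inside a causal
    # (GWAS-tagged) block
    tagged_peaks = set()
    tags = seqs.tag_snps
    for blk in blocks:
        near = False
        for pid in blk["peaks"]:
            chrom, span = pid.rsplit(":", 1)
            start, end = (int(x) for x in span.split("-"))
            for t in tags.itertuples():
                if t.chrom == chrom and min(abs(int(t.pos) - start), abs(int(t.pos) - (end - 1))) <= 500_000:
                    near = True
        if near:
            tagged_peaks.update(blk["peaks"])
    causal = [
        s for s in seqs.truth["snps"]
        if s["effect"] in ("gain", "loss") and not s["maf_excluded"] and s["peak"] in tagged_peaks
    ]
    # each synthetic TF is "encoded" by one broadly expressed filler gene so
    # the >=10% TF-expression filters have something real to measure
    genes_idx = list(ann.annotation.genes.index)
    tf_genes = {tf: genes_idx[-(k + 1)] for k, tf in enumerate(config.pfm_counts)}
    return {
        "tf_genes": tf_genes,
        "deg": deg,
        "dap": dap,
        "ccan_blocks": blocks,
        "anchor_genes": anchor,
        "true_precision": theta,
        "motifs": seqs.truth["motifs"],
        "snps": seqs.truth["snps"],
        "causal_snps": [s["id"] for s in causal],
        "hybrid_rna": counts.rna_scores.index[counts.rna_scores["is_hybrid"]].tolist(),
        "hybrid_atac": counts.atac_scores.index[counts.atac_scores["is_hybrid"]].tolist(),
        "donors": counts.donors.reset_index().to_dict(orient="records"),
        "proportion_shift": {
            "cluster": config.proportion_shift_cluster,
            "factor": config.proportion_shift_factor,
        },
    }


def generate_all(config: SyntheticConfig | None = None, seed: int | None = None) -> SyntheticDataset:
    """Generate every pipeline input plus the planted-truth ledger."""
    if config is None:
        config = default_config(seed=seed if seed is not None else 0)
    elif seed is not None and seed != config.seed:
        raise ValueError("pass the seed through the config")
    ann = generate_annotation(config)
    counts = generate_counts(config, ann)
    seqs = generate_sequences_snps_motifs(config, ann)
    samples, theta = generate_coaccessible_counts(config)
    truth = _truth_ledger(config, ann, counts, seqs, theta)
    return SyntheticDataset(config, ann, counts, seqs, samples, theta, truth)


def write_dataset(ds: SyntheticDataset, outdir) -> None:
    """Serialize to the on-disk formats the pipeline consumes."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    ctio.write_mtx(out / "rna_counts.mtx", ds.counts.rna_counts,
                   list(ds.annotation.annotation.genes.index), list(ds.counts.rna_meta.index))
    ctio.write_mtx(out / "atac_counts.mtx", ds.counts.atac_counts,
                   ds.annotation.peak_ids, list(ds.counts.atac_meta.index))
    ds.counts.rna_meta.to_csv(out / "rna_metadata.tsv", sep="\t")
    ds.counts.atac_meta.to_csv(out / "atac_metadata.tsv", sep="\t")
    ds.counts.rna_scores.to_csv(out / "rna_prediction_scores.tsv", sep="\t")
    ds.counts.atac_scores.to_csv(out / "atac_prediction_scores.tsv", sep="\t")
    ds.counts.donors.to_csv(out / "donors.tsv", sep="\t")
    np.savetxt(out / "rna_embedding.tsv", ds.counts.rna_embedding, delimiter="\t")
    np.savetxt(out / "atac_embedding.tsv", ds.counts.atac_embedding, delimiter="\t")
    ctio.write_gtf(out / "genes.gtf", ds.annotation.annotation)
    ctio.write_bed(out / "peaks.bed", ds.annotation.peaks, names=ds.annotation.peak_ids)
    ctio.write_bed(out / "blacklist.bed", ds.annotation.blacklist)
    ctio.write_fasta(out / "peaks.fasta", ds.sequences.peak_sequences)
    ctio.write_vcf(out / "snps.vcf", ds.sequences.snps, contigs=ds.config.chrom_lengths)
    ds.sequences.tag_snps.to_csv(out / "gwas_tags.tsv", sep="\t", index=False)
    counts_by_tf = {tf: np.asarray(c) for tf, c in ds.config.pfm_counts.items()}
    ctio.write_jaspar_pfms(out / "motifs.pfm", ds.sequences.pwms, counts_by_tf)
    np.savetxt(out / "coaccess_samples.tsv", ds.coaccess_samples, delimiter="\t")
    gene_sets = {
        "planted_module": {g for cl in ds.truth["deg"].values() for g in cl},
        "random_set": set(list(ds.annotation.annotation.genes.index)[::7]),
    }
    ctio.write_gmt(out / "gene_sets.gmt", gene_sets)
    ctio.write_json(out / "truth.json", ds.truth)
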