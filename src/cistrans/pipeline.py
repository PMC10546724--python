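"""End-to-end driver chaining every stage on a synthetic (or user) dataset.

simulate -> QC filtering -> cluster linking -> proportion testing ->
covariate selection -> differential expression/accessibility -> CCANs ->
cCRE linking -> motif scanning/enrichment -> SNP candidates -> affinity
tests -> flagship prioritization table, with a run manifest recording config
hash and seeds so reruns are reproducible and cached results verifiable.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as ctio
from .affinity import affinity_test
from .candidates import candidate_pairs, flagship_filter
from .ccan import aggregate_knn, classify_ccan, coaccessibility, extract_ccans, gwas_window_overlap, link_ccres
from .cohort import bootstrap_wilcoxon_proportions
from .covariates import donor_pseudobulk, iterative_pc_selection
from .differential import da_cluster, de_cluster
from .enrichment import motif_enrichment
from .qc import QCThresholds, filter_nuclei, link_clusters
from .synthetic import SyntheticDataset, default_config, generate_all


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    stage_seconds: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "config_hash": self.config_hash,
            "seed": self.seed,
            "stage_seconds": self.stage_seconds,
            "outputs": self.outputs,
        }


@dataclass
class PipelineResult:
    manifest: RunManifest
    dataset: SyntheticDataset
    qc_rna: object
    qc_atac: object
    links: list
    proportions: pd.DataFrame
    selected_covariates: list
    deg_tables: dict  # cluster -> DataFrame
    dap_tables: dict
    ccans: dict  # cluster -> list[CCAN]
    ccre_links: dict
    enrichment: dict
    candidates: pd.DataFrame
    affinity: pd.DataFrame
    flagship: pd.DataFrame


def _config_hash(config) -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _sig_table(df: pd.DataFrame, max_fdr: float = 0.05) -> pd.DataFrame:
    sig = df[df["fdr"] <= max_fdr].copy()
    return sig.set_index("feature")[["log2fc", "fdr"]]


def run_pipeline(
    config=None,
    seed: int = 0,
    outdir=None,
    n_affinity_runs: int = 1000,
    de_mixed: bool = True,
    max_de_fdr: float = 0.05,
) -> PipelineResult:
    """Run every stage on a synthetic dataset generated from ``config``.

    ``seed`` is used when no config is given; all stage seeds derive from the
    config seed so the whole run is reproducible.
    """
    if config is None:
        config = default_config(seed=seed)
    manifest = RunManifest(config_hash=_config_hash(config), seed=config.seed)
    t0 = time.time()
    ds = generate_all(config)
    manifest.stage_seconds["simulate"] = round(time.time() - t0, 2)

    # ---- QC ----
    t0 = time.time()
    qc_rna = filter_nuclei(ds.counts.rna_meta, ds.counts.rna_scores, "rna")
    qc_atac = filter_nuclei(ds.counts.atac_meta, ds.counts.atac_scores, "atac",
                            QCThresholds())
    manifest.stage_seconds["qc"] = round(time.time() - t0, 2)

    # ---- cluster linking ----
    score_cols = [c for c in ds.counts.atac_scores.columns if c.startswith("c")]
    links = link_clusters(
        ds.counts.atac_scores.loc[qc_atac.kept, score_cols],
        ds.counts.atac_meta.loc[qc_atac.kept, "cluster"],
    )

    # ---- proportions ----
    t0 = time.time()
    nuc = ds.counts.rna_meta.loc[qc_rna.kept, ["donor", "diagnosis", "cluster"]].rename(
        columns={"cluster": "unit"}
    )
    proportions = bootstrap_wilcoxon_proportions(nuc, seed=config.seed)
    manifest.stage_seconds["proportions"] = round(time.time() - t0, 2)

    # ---- covariate selection on donor pseudobulk ----
    t0 = time.time()
    kept_meta = ds.counts.rna_meta.loc[qc_rna.kept]
    pseudo = donor_pseudobulk(
        ds.counts.rna_counts[:, ds.counts.rna_meta.index.isin(qc_rna.kept)],
        kept_meta,
        feature_ids=list(ds.annotation.annotation.genes.index),
    )
    donor_meta = ds.counts.donors.loc[pseudo.index, ["age", "sex", "pmi", "seq_saturation"]]
    selected, _ = iterative_pc_selection(pseudo, donor_meta)
    manifest.stage_seconds["covariates"] = round(time.time() - t0, 2)

    # ---- differential expression / accessibility per cluster ----
    t0 = time.time()
    donors = ds.counts.donors
    deg_tables, dap_tables = {}, {}
    gene_ids = list(ds.annotation.annotation.genes.index)
    for cl in range(config.n_clusters):
        mask = (kept_meta["cluster"] == cl).to_numpy()
        sub_meta = kept_meta[mask]
        cols = ds.counts.rna_meta.index.isin(sub_meta.index)
        counts_cl = ds.counts.rna_counts[:, cols]
        diag = (sub_meta["diagnosis"] == "LOAD").to_numpy().astype(int)
        # per-donor proportion of this cluster among the donor's kept nuclei
        prop = (
            kept_meta.groupby("donor")["cluster"].apply(lambda s: (s == cl).mean())
        )
        cov = pd.DataFrame({"cluster_proportion": sub_meta["donor"].map(prop).to_numpy()})
        for var in selected:
            vals = sub_meta["donor"].map(donors[var])
            cov[var] = pd.factorize(vals)[0] if vals.dtype == object else vals.to_numpy()
        deg_tables[cl] = de_cluster(
            counts_cl, gene_ids, diag, sub_meta["donor"].to_numpy(), cov,
            cluster=str(cl), mixed=de_mixed,
        )
        amask = (ds.counts.atac_meta["cluster"] == cl) & ds.counts.atac_meta.index.isin(qc_atac.kept)
        a_meta = ds.counts.atac_meta[amask]
        a_counts = ds.counts.atac_counts[:, amask.to_numpy()]
        a_diag = (a_meta["diagnosis"] == "LOAD").to_numpy().astype(int)
        aprop = ds.counts.atac_meta.loc[qc_atac.kept].groupby("donor")["cluster"].apply(
            lambda s: (s == cl).mean()
        )
        a_cov = pd.DataFrame(
            {
                "peak_region_fragments": a_meta["peak_region_fragments"].to_numpy(),
                "pct_fragments_in_targets": a_meta["pct_fragments_in_targets"].to_numpy(),
                "cluster_proportion": a_meta["donor"].map(aprop).to_numpy(),
                "age": a_meta["donor"].map(donors["age"]).to_numpy(),
                "sex": pd.factorize(a_meta["donor"].map(donors["sex"]))[0],
                "pmi": a_meta["donor"].map(donors["pmi"]).to_numpy(),
            }
        )
        dap_tables[cl] = da_cluster(
            a_counts, ds.annotation.peak_ids, a_diag, a_cov, cluster=str(cl)
        )
    manifest.stage_seconds["differential"] = round(time.time() - t0, 2)

    # ---- CCANs per cluster (disease nuclei only) ----
    t0 = time.time()
    ccans_by_cluster, links_by_cluster = {}, {}
    annotation = ds.annotation.annotation
    for cl in range(config.n_clusters):
        amask = (
            (ds.counts.atac_meta["cluster"] == cl)
            & (ds.counts.atac_meta["diagnosis"] == "LOAD")
            & ds.counts.atac_meta.index.isin(qc_atac.kept)
        ).to_numpy()
        nuc_counts = ds.counts.atac_counts[:, amask].T  # nuclei x peaks
        emb = ds.counts.atac_embedding[amask]
        agg, _ = aggregate_knn(nuc_counts, emb, k=min(50, max(2, nuc_counts.shape[0] // 4)),
                               seed=config.seed)
        edges = coaccessibility(agg, ds.annotation.peaks, ds.annotation.peak_ids)
        ccans = extract_ccans(edges, seed=config.seed)
        dap_sig = _sig_table(dap_tables[cl])
        deg_sig = _sig_table(deg_tables[cl])
        for c in ccans:
            classify_ccan(c, dap_sig, deg_sig, annotation)
        gwas_window_overlap(ccans, ds.sequences.tag_snps)
        ccans_by_cluster[cl] = ccans
        links_by_cluster[cl] = link_ccres(ccans, dap_sig, deg_sig, annotation)
    manifest.stage_seconds["ccan"] = round(time.time() - t0, 2)

    # ---- motif enrichment within CCAN peaks ----
    t0 = time.time()
    tf_genes = ds.truth.get("tf_genes", {})
    enrich = {}
    candidate_frames = []
    for cl in range(config.n_clusters):
        ccans = ccans_by_cluster[cl]
        target_peaks = {
            p for c in ccans if c.klass in ("unidirectional", "mixed") for p in c.peaks
        }
        if target_peaks:
            target_seqs = {p: ds.sequences.peak_sequences[p] for p in target_peaks}
            bg_seqs = {
                p: s for p, s in ds.sequences.peak_sequences.items() if p not in target_peaks
            }
            expr = {}
            mask = (ds.counts.rna_meta["cluster"] == cl).to_numpy()
            for tf, gene in tf_genes.items():
                gi = gene_ids.index(gene)
                expr[tf] = float((ds.counts.rna_counts[gi, mask] > 0).mean())
            enrich[cl] = motif_enrichment(
                target_seqs, bg_seqs, ds.sequences.pwms, expr or None,
                seed=config.seed, dists=ds.sequences.dists,
            )
        # SNP candidates for this cluster
        cand = candidate_pairs(
            ds.sequences.snps,
            ccans,
            _sig_table(dap_tables[cl]),
            _sig_table(deg_tables[cl]),
            ds.sequences.peak_sequences,
            ds.sequences.pwms,
            dists=ds.sequences.dists,
        )
        if not cand.empty:
            cand.insert(0, "cluster", cl)
            candidate_frames.append(cand)
    candidates = (
        pd.concat(candidate_frames, ignore_index=True)
        if candidate_frames
        else pd.DataFrame(columns=["cluster", "snp", "tf", "peak", "ccan", "context",
                                   "ref", "alt", "maf", "target_deg", "target_log2fc"])
    )
    candidates = candidates.drop_duplicates(subset=["snp", "tf", "peak"])
    manifest.stage_seconds["motifs_candidates"] = round(time.time() - t0, 2)

    # ---- affinity tests ----
    t0 = time.time()
    pwm_by_tf = {p.tf: p for p in ds.sequences.pwms}
    rows = []
    for i, r in enumerate(candidates.itertuples()):
        res = affinity_test(
            pwm_by_tf[r.tf], r.context, r.ref, r.alt, snp_id=r.snp,
            n_runs=n_affinity_runs, seed=int(np.random.default_rng([config.seed, 7, i]).integers(2**31)),
        )
        rows.append(
            {
                "snp": r.snp, "tf": r.tf, "peak": r.peak, "cluster": r.cluster,
                "target_deg": r.target_deg, "target_log2fc": r.target_log2fc,
                "effect": res.effect, "score_ref": res.best_score_ref,
                "score_alt": res.best_score_alt, "p_mean": res.p_mean,
                "p_var": res.p_var, "p_min": res.p_min, "p_max": res.p_max,
            }
        )
    affinity = pd.DataFrame(
        rows, columns=["snp", "tf", "peak", "cluster", "target_deg", "target_log2fc",
                       "effect", "score_ref", "score_alt", "p_mean", "p_var", "p_min", "p_max"],
    )
    if not affinity.empty:
        expr_all = {}
        for tf, gene in tf_genes.items():
            gi = gene_ids.index(gene)
            expr_all[tf] = float((ds.counts.rna_counts[gi] > 0).mean())
        flagship = flagship_filter(affinity, expr_all or {tf: 1.0 for tf in pwm_by_tf})
    else:
        flagship = affinity.assign(fdr=[], flagship=[])
    manifest.stage_seconds["affinity"] = round(time.time() - t0, 2)

    result = PipelineResult(
        manifest, ds, qc_rna, qc_atac, links, proportions, selected,
        deg_tables, dap_tables, ccans_by_cluster, links_by_cluster, enrich,
        candidates, affinity, flagship,
    )
    if outdir is not None:
        _write_outputs(result, outdir)
    return result


def _write_outputs(result: PipelineResult, outdir) -> None:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    pd.concat(result.deg_tables.values()).to_csv(out / "deg.tsv", sep="\t", index=False)
    pd.concat(result.dap_tables.values()).to_csv(out / "dap.tsv", sep="\t", index=False)
    result.proportions.drop(columns=["p_iterations"]).to_csv(out / "proportions.tsv", sep="\t")
    result.candidates.to_csv(out / "snp_candidates.tsv", sep="\t", index=False)
    result.flagship.to_csv(out / "flagship.tsv", sep="\t", index=False)
    ccan_dump = {
        str(cl): [
            {"id": c.id, "peaks": c.peaks, "class": c.klass, "gwas": c.gwas_overlap}
            for c in ccans
        ]
        for cl, ccans in result.ccans.items()
    }
    ctio.write_json(out / "ccans.json", ccan_dump)
    ctio.write_json(out / "manifest.json", result.manifest.to_dict())
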