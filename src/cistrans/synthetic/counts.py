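"""Synthetic count matrices, nucleus metadata, prediction scores, embeddings.

Gene counts are negative binomial around cluster/donor/diagnosis-dependent
means; planted differential genes get a multiplicative 2^log2FC shift in
disease nuclei of their cluster, and every (gene, donor) pair carries a
log2-scale random intercept so donor pseudoreplication is a real feature of
the data.  Peak fragment counts are Bernoulli-thinned Poisson, with planted
differential peaks shifted the same way and per-nucleus latent block factors
inducing the planted co-accessibility structure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .annotation import AnnotationBundle
from .config import SyntheticConfig

NB_DISPERSION = 2.0  # negative binomial size parameter
THIN_P = 0.5  # Bernoulli thinning of peak fragments


@dataclass
class CountsBundle:
    rna_counts: np.ndarray  # genes x nuclei
    atac_counts: np.ndarray  # peaks x nuclei
    rna_meta: pd.DataFrame
    atac_meta: pd.DataFrame
    rna_scores: pd.DataFrame  # barcode-indexed; per-cluster scores + x1/x2
    atac_scores: pd.DataFrame
    rna_embedding: np.ndarray
    atac_embedding: np.ndarray
    donors: pd.DataFrame


def _donor_table(config: SyntheticConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = config.n_donors
    rows = []
    for d in range(n):
        diagnosis = "LOAD" if d < n // 2 else "Normal"
        rows.append(
            {
                "donor": f"D{d:02d}",
                "diagnosis": diagnosis,
                "sex": "F" if d % 2 == 0 else "M",
                "age": float(np.round(rng.normal(80, 8), 1)),
                "pmi": float(np.round(np.abs(rng.normal(9, 5)), 1)),
                "seq_saturation": float(np.round(rng.uniform(0.4, 0.9), 3)),
            }
        )
    return pd.DataFrame(rows).set_index("donor")


def _cluster_assignments(
    config: SyntheticConfig,
    donors: pd.DataFrame,
    rng: np.random.Generator,
    n_per: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-nucleus donor index and cluster label, with the configured
    disease-group proportion shift in one cluster."""
    if n_per is None:
        n_per = config.nuclei_per_donor
    donor_idx = np.repeat(np.arange(len(donors)), n_per)
    clusters = np.empty(donor_idx.size, dtype=int)
    base = np.ones(config.n_clusters)
    for d in range(len(donors)):
        w = base.copy()
        if (
            config.proportion_shift_cluster is not None
            and donors.iloc[d]["diagnosis"] == "LOAD"
        ):
            w[config.proportion_shift_cluster] *= config.proportion_shift_factor
        w = w / w.sum()
        sl = slice(d * n_per, (d + 1) * n_per)
        clusters[sl] = rng.choice(config.n_clusters, size=n_per, p=w)
    return donor_idx, clusters


def _prediction_scores(
    barcodes: list[str],
    clusters: np.ndarray,
    n_labels: int,
    hybrid_fraction: float,
    low_score_fraction: float,
    rng: np.random.Generator,
) -> pd.DataFrame:
    n = len(barcodes)
    hybrid = rng.random(n) < hybrid_fraction
    low = (~hybrid) & (rng.random(n) < low_score_fraction)
    x1 = rng.uniform(0.7, 0.95, size=n)
    x1[low] = rng.uniform(0.2, 0.45, size=int(low.sum()))
    # hybrids: runner-up within 20% of the top score; others well separated
    ratio = np.where(hybrid, rng.uniform(0.85, 0.99, size=n), rng.uniform(0.1, 0.7, size=n))
    x2 = x1 * ratio
    mat = np.zeros((n, n_labels))
    rows = np.arange(n)
    mat[rows, clusters] = x1
    runner = (clusters + 1 + rng.integers(0, n_labels - 1, size=n)) % n_labels
    runner = np.where(runner == clusters, (clusters + 1) % n_labels, runner)
    mat[rows, runner] = x2
    rest = np.clip(1.0 - x1 - x2, 0.0, None)
    others = n_labels - 2
    if others > 0:
        fill = rest / others
        for lbl in range(n_labels):
            untouched = (clusters != lbl) & (runner != lbl)
            mat[untouched, lbl] = fill[untouched]
    df = pd.DataFrame(mat, index=pd.Index(barcodes, name="barcode"),
                      columns=[f"c{k}" for k in range(n_labels)])
    df["x1"] = x1
    df["x2"] = x2
    df["is_hybrid"] = hybrid
    df["is_low_score"] = low
    return df


def _embedding(
    clusters: np.ndarray, n_clusters: int, rng: np.random.Generator, dim: int = 10
) -> np.ndarray:
    centroids = rng.normal(0, 5, size=(n_clusters, dim))
    return centroids[clusters] + rng.normal(0, 1.0, size=(clusters.size, dim))


def generate_counts(config: SyntheticConfig, bundle: AnnotationBundle) -> CountsBundle:
    if len(bundle.peaks) != config.n_peaks:
        raise ValueError("annotation bundle does not match config (peak count)")
    if len(bundle.annotation.genes) != config.n_genes:
        raise ValueError("annotation bundle does not match config (gene count)")
    rng = config.rng(2)
    donors = _donor_table(config, rng)
    is_load = (donors["diagnosis"] == "LOAD").to_numpy()

    # ---- RNA ----
    donor_idx, clusters = _cluster_assignments(config, donors, rng)
    n_nuc = donor_idx.size
    barcodes = [f"rna_{i:05d}" for i in range(n_nuc)]
    base_mu = rng.lognormal(mean=0.0, sigma=0.8, size=config.n_genes)  # per-gene scale
    # differential genes are drawn from the expressed part of the spectrum,
    # as disease-effect genes must clear the 10% detection filter anyway
    for eff in config.gene_effects:
        base_mu[eff.feature] = max(base_mu[eff.feature], 1.0)
    log2mu = np.tile(np.log2(base_mu)[:, None], (1, n_nuc))
    donor_intercepts = rng.normal(0, config.donor_sd, size=(config.n_genes, config.n_donors))
    log2mu += donor_intercepts[:, donor_idx]
    for eff in config.gene_effects:
        sel = (clusters == eff.cluster) & is_load[donor_idx]
        log2mu[eff.feature, sel] += eff.log2fc
    mu = 2.0**log2mu
    p_nb = NB_DISPERSION / (NB_DISPERSION + mu)
    rna_counts = rng.negative_binomial(NB_DISPERSION, p_nb)

    rna_meta = pd.DataFrame(
        {
            "barcode": barcodes,
            "donor": donors.index[donor_idx],
            "diagnosis": donors["diagnosis"].to_numpy()[donor_idx],
            "cluster": clusters,
        }
    ).set_index("barcode")
    # QC columns: mostly passing, a configured fraction violating each rule
    n_feat = (rna_counts > 0).sum(axis=0) + rng.integers(300, 2000, size=n_nuc)
    pct_mito = rng.uniform(0.0, 0.12, size=n_nuc)
    viol_feat = rng.random(n_nuc) < config.qc_violation_fraction
    n_feat = np.where(viol_feat, rng.integers(10, 199, size=n_nuc), n_feat)
    viol_mito = (~viol_feat) & (rng.random(n_nuc) < config.qc_violation_fraction)
    pct_mito = np.where(viol_mito, rng.uniform(0.18, 0.6, size=n_nuc), pct_mito)
    rna_meta["n_features"] = n_feat
    rna_meta["pct_mito"] = pct_mito
    rna_meta["qc_violation"] = np.select(
        [viol_feat, viol_mito], ["n_features", "pct_mito"], ""
    )
    rna_scores = _prediction_scores(
        barcodes, clusters, config.n_clusters, config.hybrid_fraction,
        config.qc_violation_fraction, rng,
    )
    rna_embedding = _embedding(clusters, config.n_clusters, rng)

    # ---- ATAC ----
    a_donor_idx, a_clusters = _cluster_assignments(
        config, donors, rng, n_per=config.atac_nuclei_per_donor
    )
    n_anuc = a_donor_idx.size
    a_barcodes = [f"atac_{i:05d}" for i in range(n_anuc)]
    base_lam = rng.uniform(0.5, 2.0, size=config.n_peaks)
    # co-accessibility block peaks are open regulatory chromatin; keep them
    # out of the barely-detectable regime so their correlation structure is
    # not drowned by Poisson noise
    for blk in config.ccan_blocks:
        for pidx in blk.peak_indices:
            base_lam[pidx] = max(base_lam[pidx], 2.0)
    log2lam = np.tile(np.log2(base_lam)[:, None], (1, n_anuc))
    a_intercepts = rng.normal(0, config.atac_donor_sd, size=(config.n_peaks, config.n_donors))
    log2lam += a_intercepts[:, a_donor_idx]
    for eff in config.peak_effects:
        sel = (a_clusters == eff.cluster) & is_load[a_donor_idx]
        log2lam[eff.feature, sel] += eff.log2fc
    # latent per-nucleus Gaussian vectors with a chain precision induce the
    # within-block co-accessibility: adjacent block peaks get strong partial
    # correlations (a clique through one shared factor would spread the
    # dependence too thin for pairwise partial correlations to survive)
    for blk in config.ccan_blocks:
        k = len(blk.peak_indices)
        prec = np.eye(k)
        for a in range(k - 1):
            prec[a, a + 1] = prec[a + 1, a] = -0.5
        chol = np.linalg.cholesky(np.linalg.inv(prec))
        z = rng.standard_normal((n_anuc, k)) @ chol.T
        for j, pidx in enumerate(blk.peak_indices):
            log2lam[pidx] += config.block_factor_weight * z[:, j]
    lam = 2.0**log2lam
    atac_counts = rng.binomial(rng.poisson(lam / THIN_P), THIN_P)

    atac_meta = pd.DataFrame(
        {
            "barcode": a_barcodes,
            "donor": donors.index[a_donor_idx],
            "diagnosis": donors["diagnosis"].to_numpy()[a_donor_idx],
            "cluster": a_clusters,
        }
    ).set_index("barcode")
    prf = atac_counts.sum(axis=0)
    atac_meta["peak_region_fragments"] = np.maximum(prf + rng.integers(1000, 4000, size=n_anuc), 1001)
    atac_meta["pct_fragments_in_targets"] = rng.uniform(0.3, 0.8, size=n_anuc)
    ns = rng.uniform(0.2, 2.5, size=n_anuc)
    viol_ns = rng.random(n_anuc) < config.qc_violation_fraction
    ns = np.where(viol_ns, rng.uniform(4.5, 8.0, size=n_anuc), ns)
    tss = rng.uniform(2.5, 8.0, size=n_anuc)
    viol_tss = (~viol_ns) & (rng.random(n_anuc) < config.qc_violation_fraction)
    tss = np.where(viol_tss, rng.uniform(0.1, 1.9, size=n_anuc), tss)
    atac_meta["nucleosome_signal"] = ns
    atac_meta["tss_enrichment"] = tss
    atac_meta["pct_reads_in_peaks"] = rng.uniform(0.2, 0.8, size=n_anuc)
    atac_meta["blacklist_ratio"] = rng.uniform(0.0, 0.04, size=n_anuc)
    atac_meta["sample"] = atac_meta["donor"]
    atac_meta["qc_violation"] = np.select(
        [viol_ns, viol_tss], ["nucleosome_signal", "tss_enrichment"], ""
    )
    atac_scores = _prediction_scores(
        a_barcodes, a_clusters, config.n_clusters, config.hybrid_fraction,
        config.qc_violation_fraction, rng,
    )
    atac_embedding = _embedding(a_clusters, config.n_clusters, rng)

    return CountsBundle(
        rna_counts=rna_counts,
        atac_counts=atac_counts,
        rna_meta=rna_meta,
        atac_meta=atac_meta,
        rna_scores=rna_scores,
        atac_scores=atac_scores,
        rna_embedding=rna_embedding,
        atac_embedding=atac_embedding,
        donors=donors,
    )
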