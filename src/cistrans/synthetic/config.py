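"""Configuration and planted ground truth for the synthetic cohort.

The default configuration emulates the study design the pipeline targets:
24 donors split evenly between disease (LOAD) and control, paired snRNA-seq
and snATAC-seq per donor, a small two-chromosome genome, per-cluster planted
differential genes and peaks, block-structured peak co-accessibility,
motif instances in peak sequences, and affinity-changing SNP alleles — each
with a machine-readable truth ledger entry.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np


@dataclass(frozen=True)
class EffectPlant:
    """One planted differential feature (gene or peak) in one cluster."""

    feature: int  # index into genes or peaks
    cluster: int
    log2fc: float  # sign: positive = up in disease


@dataclass(frozen=True)
class CCANBlock:
    peak_indices: tuple[int, ...]
    partial_corr: float = 0.2


@dataclass(frozen=True)
class MotifPlant:
    tf: str
    peak_index: int
    offset: int  # within the peak sequence
    strand: str = "+"


@dataclass(frozen=True)
class SNPPlant:
    snp_id: str
    peak_index: int
    motif_tf: str
    column: int  # motif column carrying the SNP
    maf: float
    effect: str  # "gain" | "loss"


@dataclass
class SyntheticConfig:
    n_donors: int = 24
    n_clusters: int = 3
    n_genes: int = 60
    n_peaks: int = 120
    chrom_lengths: dict = field(
        default_factory=lambda: {"chr1": 10_000_000, "chr2": 10_000_000}
    )
    nuclei_per_donor: int = 200
    atac_nuclei_per_donor: int = 800  # k-NN aggregation needs n >> k per cluster
    peak_width: int = 500
    gene_effects: list = field(default_factory=list)
    peak_effects: list = field(default_factory=list)
    ccan_blocks: list = field(default_factory=list)
    motif_plants: list = field(default_factory=list)
    snp_plants: list = field(default_factory=list)
    pfm_counts: dict = field(default_factory=dict)  # tf -> (4, L) count array
    gwas_tags: list = field(default_factory=list)  # (chrom, pos)
    decoy_snps: list = field(default_factory=list)  # SNPPlant with maf < 1%
    max_abs_lfc: float = 2.0
    donor_sd: float = 0.2  # log2-scale donor random intercept SD (gene means)
    atac_donor_sd: float = 0.0  # peaks: the binomial DA test has no donor term
    hybrid_fraction: float = 0.05
    qc_violation_fraction: float = 0.02
    promoter_peak_fraction: float = 0.3
    block_factor_weight: float = 1.2
    proportion_shift_cluster: int | None = None
    proportion_shift_factor: float = 2.0
    snp_margin: float = 1.0  # minimum |score change| in bits for planted SNPs
    n_coaccess_samples: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_donors % 2:
            raise ValueError("n_donors must split evenly into case/control")
        for eff in list(self.gene_effects) + list(self.peak_effects):
            if abs(eff.log2fc) > self.max_abs_lfc:
                raise ValueError(f"planted |log2fc| {eff.log2fc} exceeds max {self.max_abs_lfc}")
        for blk in self.ccan_blocks:
            bad = [i for i in blk.peak_indices if not 0 <= i < self.n_peaks]
            if bad:
                raise ValueError(f"ccan block references invalid peak indices {bad}")

    def rng(self, stream: int) -> np.random.Generator:
        """Named deterministic random stream derived from the config seed."""
        return np.random.default_rng([self.seed, stream])

    def to_dict(self) -> dict:
        d = asdict(self)
        d["pfm_counts"] = {k: np.asarray(v).tolist() for k, v in self.pfm_counts.items()}
        return d


def _informative_pfm(rng: np.random.Generator, length: int, total: int = 100) -> np.ndarray:
    """A (4, L) count matrix with one dominant base per column (high
    information content, so exact thresholds at 5e-5 are attainable)."""
    counts = np.zeros((4, length))
    for j in range(length):
        dominant = rng.integers(0, 4)
        counts[dominant, j] = total - 15
        others = [b for b in range(4) if b != dominant]
        split = rng.multinomial(15, [1 / 3] * 3)
        for b, c in zip(others, split):
            counts[b, j] = c
    return counts


def default_config(seed: int = 0, **overrides) -> SyntheticConfig:
    """The study-condition configuration with coherent planted modules.

    Three causal regulatory modules are planted (clusters 0-2): a 5-peak
    co-accessibility block whose first peak is the promoter anchor of a
    disease-upregulated gene (+0.75 log2FC), whose second peak is a distal
    noncoding disease DAP carrying a motif instance with a common (MAF >= 1 %)
    loss-of-affinity SNP, and a GWAS tag SNP within 500 kb.  Decoys violate
    individual candidate criteria: a block with no nearby tag SNP, a rare
    (MAF < 1 %) SNP, and null genes/peaks everywhere else.
    """
    rng = np.random.default_rng([seed, 999])
    n_clusters = overrides.pop("n_clusters", 3)
    n_genes = overrides.pop("n_genes", 60)
    n_peaks = overrides.pop("n_peaks", 120)
    motif_len = 8
    tfs = [f"TF{i}" for i in range(3)]
    pfms = {tf: _informative_pfm(rng, motif_len) for tf in tfs}

    blocks = []
    gene_effects = []
    peak_effects = []
    motif_plants = []
    snp_plants = []
    gwas_tags = []
    # causal modules: peaks 0-4 (cluster 0), 5-9 (cluster 1), 10-14 (cluster 2)
    for m in range(3):
        cluster = m % n_clusters
        idx = tuple(range(5 * m, 5 * m + 5))
        blocks.append(CCANBlock(peak_indices=idx, partial_corr=0.2))
        # causal anchor genes carry a strong disease effect, as the flagship
        # cCRE-linked genes do; the +0.5 power analyses use their own fixtures
        gene_effects.append(EffectPlant(feature=m, cluster=cluster, log2fc=0.75))
        peak_effects.append(EffectPlant(feature=idx[0], cluster=cluster, log2fc=1.0))
        peak_effects.append(EffectPlant(feature=idx[1], cluster=cluster, log2fc=1.0))
        tf = tfs[m]
        motif_plants.append(MotifPlant(tf=tf, peak_index=idx[1], offset=200))
        snp_plants.append(
            SNPPlant(
                snp_id=f"rs_causal_{m}",
                peak_index=idx[1],
                motif_tf=tf,
                column=3,
                maf=0.25,
                effect="loss" if m % 2 == 0 else "gain",
            )
        )
    # decoy block (peaks 15-19): differential and motif-bearing but no GWAS
    # tag within 500 kb, so criterion (c) must exclude its SNP
    decoy_idx = tuple(range(15, 20))
    blocks.append(CCANBlock(peak_indices=decoy_idx, partial_corr=0.2))
    gene_effects.append(EffectPlant(feature=3, cluster=0, log2fc=0.75))
    peak_effects.append(EffectPlant(feature=decoy_idx[0], cluster=0, log2fc=1.0))
    peak_effects.append(EffectPlant(feature=decoy_idx[1], cluster=0, log2fc=1.0))
    motif_plants.append(MotifPlant(tf=tfs[0], peak_index=decoy_idx[1], offset=150))
    snp_plants.append(
        SNPPlant(
            snp_id="rs_no_gwas",
            peak_index=decoy_idx[1],
            motif_tf=tfs[0],
            column=3,
            maf=0.2,
            effect="loss",
        )
    )
    # rare-allele decoy inside the first causal module's motif
    decoys = [
        SNPPlant(
            snp_id="rs_rare",
            peak_index=1,
            motif_tf=tfs[0],
            column=5,
            maf=0.005,
            effect="loss",
        )
    ]
    # additional planted DEGs so each cluster carries a handful of true
    # effects in both directions, as disease clusters do
    for g in range(4, 16):
        sign = 1.0 if g % 2 == 0 else -1.0
        gene_effects.append(EffectPlant(feature=g, cluster=(g % n_clusters), log2fc=0.5 * sign))
    # tag SNPs are placed by the annotation generator near causal blocks;
    # sentinel entries here mark how many are wanted
    gwas_tags = [("auto", m) for m in range(3)] + [("chr2", 9_500_000)]
    return SyntheticConfig(
        n_clusters=n_clusters,
        n_genes=n_genes,
        n_peaks=n_peaks,
        gene_effects=gene_effects,
        peak_effects=peak_effects,
        ccan_blocks=blocks,
        motif_plants=motif_plants,
        snp_plants=snp_plants,
        pfm_counts=pfms,
        gwas_tags=gwas_tags,
        decoy_snps=decoys,
        proportion_shift_cluster=None,
        seed=seed,
        **overrides,
    )
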