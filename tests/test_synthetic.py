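import hashlib
import io

import numpy as np
import pytest
from scipy import stats as sps

from cistrans import io as ctio
from cistrans.affinity import score_change
from cistrans.intervals import GenomicInterval, within_window
from cistrans.pwm import build_pwm, MarkovBackground
from cistrans.synthetic import (
    default_config,
    generate_all,
    generate_annotation,
    generate_coaccessible_counts,
    generate_counts,
    true_precision,
)


def _file_hash(write_fn) -> str:
    import tempfile, pathlib

    with tempfile.TemporaryDirectory() as d:
        path = pathlib.Path(d) / "x"
        write_fn(path)
        return hashlib.sha256(path.read_bytes()).hexdigest()


class TestDeterminism:
    def test_annotation_bytes_identical(self):
        cfg = default_config(seed=1)
        h = []
        for _ in range(2):
            ann = generate_annotation(cfg)
            h.append(
                (
                    _file_hash(lambda p, a=ann: ctio.write_gtf(p, a.annotation)),
                    _file_hash(lambda p, a=ann: ctio.write_bed(p, a.peaks)),
                )
            )
        assert h[0] == h[1]

    def test_count_matrices_identical(self):
        cfg = default_config(seed=3)
        ann = generate_annotation(cfg)
        c1 = generate_counts(cfg, ann)
        c2 = generate_counts(cfg, ann)
        assert np.array_equal(c1.rna_counts, c2.rna_counts)
        assert np.array_equal(c1.atac_counts, c2.atac_counts)

    def test_coaccess_matrix_identical(self):
        cfg = default_config(seed=2)
        s1, t1 = generate_coaccessible_counts(cfg)
        s2, t2 = generate_coaccessible_counts(cfg)
        assert np.array_equal(s1, s2) and np.array_equal(t1, t2)


class TestAnnotation:
    def test_promoter_fraction_of_peaks(self, synthetic_dataset):
        ds = synthetic_dataset
        promoters = list(ds.annotation.annotation.promoters().values())
        intron1 = [
            iv
            for g in ds.annotation.annotation.genes.index
            if (iv := ds.annotation.annotation.intron1(g)) is not None
        ]
        n_anchor = sum(
            any(p.overlaps(t) for t in promoters + intron1) for p in ds.annotation.peaks
        )
        frac = n_anchor / len(ds.annotation.peaks)
        assert frac >= ds.config.promoter_peak_fraction * 0.8

    def test_coordinates_within_chromosomes(self, synthetic_dataset):
        ds = synthetic_dataset
        lens = ds.config.chrom_lengths
        for p in ds.annotation.peaks:
            assert 0 <= p.start < p.end <= lens[p.chrom]
        for _, g in ds.annotation.annotation.genes.iterrows():
            assert 0 <= g["start"] < g["end"] <= lens[g["chrom"]]

    def test_every_gene_has_first_intron(self, synthetic_dataset):
        ann = synthetic_dataset.annotation.annotation
        for g in ann.genes.index:
            assert ann.intron1(g) is not None

    def test_chrom_too_short_errors(self):
        with pytest.raises(ValueError, match="chr"):
            generate_annotation(default_config(seed=0, chrom_lengths={"chrX": 50_000}))


class TestCounts:
    def test_planted_effect_sign_at_generation(self, synthetic_dataset):
        ds = synthetic_dataset
        y = np.log2(ds.counts.rna_counts + 1.0)
        meta = ds.counts.rna_meta
        for eff in ds.config.gene_effects:
            m = (meta["cluster"] == eff.cluster).to_numpy()
            load = m & (meta["diagnosis"] == "LOAD").to_numpy()
            norm = m & (meta["diagnosis"] == "Normal").to_numpy()
            diff = y[eff.feature, load].mean() - y[eff.feature, norm].mean()
            assert np.sign(diff) == np.sign(eff.log2fc)

    def test_hybrid_fraction_binomial(self, synthetic_dataset):
        ds = synthetic_dataset
        scores = ds.counts.rna_scores
        x1, x2 = scores["x1"].to_numpy(), scores["x2"].to_numpy()
        n_hybrid = int(((x1 - x2) / x1 < 0.2).sum())
        n = len(scores)
        p = ds.config.hybrid_fraction + ds.config.qc_violation_fraction * 0  # hybrids only
        lo, hi = sps.binom.interval(0.999, n, ds.config.hybrid_fraction)
        # low-score nuclei can also fall under the threshold; allow one-sided slack
        assert lo <= n_hybrid <= hi * 1.5

    def test_counts_nonnegative_integers(self, synthetic_dataset):
        ds = synthetic_dataset
        assert ds.counts.rna_counts.min() >= 0
        assert np.issubdtype(ds.counts.rna_counts.dtype, np.integer)
        assert ds.counts.atac_counts.min() >= 0

    def test_embedding_separates_clusters(self, synthetic_dataset):
        ds = synthetic_dataset
        emb = ds.counts.rna_embedding
        cl = ds.counts.rna_meta["cluster"].to_numpy()
        centroids = np.stack([emb[cl == k].mean(axis=0) for k in range(ds.config.n_clusters)])
        within = np.mean([np.linalg.norm(emb[cl == k] - centroids[k], axis=1).mean()
                          for k in range(ds.config.n_clusters)])
        between = np.mean([np.linalg.norm(centroids[i] - centroids[j])
                           for i in range(3) for j in range(i + 1, 3)])
        assert between > 2 * within


class TestCoaccessibleCounts:
    def test_precision_support_matches_blocks(self):
        cfg = default_config(seed=5)
        theta = true_precision(cfg)
        in_block = np.zeros_like(theta, dtype=bool)
        for blk in cfg.ccan_blocks:
            for a in blk.peak_indices:
                for b in blk.peak_indices:
                    if a != b:
                        in_block[a, b] = True
        off = ~np.eye(len(theta), dtype=bool)
        assert np.all(theta[off & ~in_block] == 0)
        assert np.all(theta[in_block] != 0)

    def test_empirical_partial_correlation_recovers_blocks(self):
        cfg = default_config(seed=5)
        samples, theta = generate_coaccessible_counts(cfg, n_samples=500)
        emp_prec = np.linalg.inv(np.cov(samples, rowvar=False))
        d = np.sqrt(np.diag(emp_prec))
        pc = -emp_prec / np.outer(d, d)
        in_vals, out_vals = [], []
        tri = np.triu_indices(len(theta), 1)
        for i, j in zip(*tri):
            (in_vals if theta[i, j] != 0 else out_vals).append(abs(pc[i, j]))
        assert np.median(in_vals) > np.quantile(out_vals, 0.95)

    def test_block_beyond_limit_rejected(self):
        from cistrans.synthetic import CCANBlock

        cfg = default_config(seed=0)
        cfg.ccan_blocks = [CCANBlock(peak_indices=tuple(range(80)), partial_corr=0.01)]
        with pytest.raises(ValueError, match="500 kb|beyond"):
            generate_annotation(cfg)


class TestSequencesSnps:
    def test_planted_motifs_pass_their_threshold(self, synthetic_dataset):
        for m in synthetic_dataset.truth["motifs"]:
            assert m["score"] >= m["threshold"] - 0.01

    def test_loss_snp_reduces_best_window_score(self, synthetic_dataset):
        ds = synthetic_dataset
        pwms = {p.tf: p for p in ds.sequences.pwms}
        for s in ds.truth["snps"]:
            if s["effect"] not in ("gain", "loss"):
                continue
            pwm = pwms[s["tf"]]
            pid = s["peak"]
            peak = ds.annotation.peaks[ds.annotation.peak_ids.index(pid)]
            off = s["pos"] - peak.start
            seq = ds.sequences.peak_sequences[pid]
            ctx = seq[off - (pwm.length - 1) : off + pwm.length]
            _, _, d = score_change(ctx, s["ref"], s["alt"], pwm)
            assert np.sign(d) == s["expected_change_sign"]
            assert abs(d) >= ds.config.snp_margin

    def test_rare_snp_marked_filter_excluded(self, synthetic_dataset):
        snps = synthetic_dataset.sequences.snps
        rare = snps[snps["maf"] < 0.01]
        assert len(rare) >= 1 and rare["maf_excluded"].all()
        assert not snps[snps["maf"] >= 0.01]["maf_excluded"].any()

    def test_gwas_window_tagging(self, synthetic_dataset):
        ds = synthetic_dataset
        tags = ds.sequences.tag_snps
        causal_peaks = {
            s["peak"] for s in ds.truth["snps"] if s["id"].startswith("rs_causal")
        }
        for pid in causal_peaks:
            peak = ds.annotation.peaks[ds.annotation.peak_ids.index(pid)]
            assert any(
                within_window(peak, t.chrom, int(t.pos), 500_000) for t in tags.itertuples()
            )

    def test_sequence_alphabet_and_length(self, synthetic_dataset):
        ds = synthetic_dataset
        for pid, seq in ds.sequences.peak_sequences.items():
            assert set(seq) <= set("ACGT")
            peak = ds.annotation.peaks[ds.annotation.peak_ids.index(pid)]
            assert len(seq) == len(peak)


class TestRoundTrips:
    def test_disk_round_trip(self, synthetic_dataset, tmp_path):
        from cistrans.synthetic import write_dataset

        ds = synthetic_dataset
        write_dataset(ds, tmp_path)
        mat, rows, cols = ctio.read_mtx(tmp_path / "rna_counts.mtx")
        assert mat.shape == ds.counts.rna_counts.shape
        assert rows == list(ds.annotation.annotation.genes.index)
        ann = ctio.read_gtf(tmp_path / "genes.gtf")
        assert list(ann.genes.index) == list(ds.annotation.annotation.genes.index)
        for g in list(ann.genes.index)[:5]:
            assert ann.promoter(g) == ds.annotation.annotation.promoter(g)
        snps = ctio.read_vcf(tmp_path / "snps.vcf")
        orig = ds.sequences.snps
        assert len(snps) == len(orig)
        merged = snps.merge(orig, on="id", suffixes=("", "_o"))
        assert (merged["pos"] == merged["pos_o"]).all()
        assert np.allclose(merged["maf"], merged["maf_o"], atol=1e-6)
        pwms = ctio.read_jaspar_pfms(tmp_path / "motifs.pfm")
        assert {p.tf for p in pwms} == {p.tf for p in ds.sequences.pwms}
        seqs = ctio.read_fasta(tmp_path / "peaks.fasta")
        assert seqs == ds.sequences.peak_sequences
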