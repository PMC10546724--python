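import itertools

import numpy as np
import pandas as pd
import pytest

from cistrans.annotation import GeneAnnotation
from cistrans.ccan import (
    CCAN,
    aggregate_knn,
    classify_ccan,
    coaccessibility,
    extract_ccans,
    go_enrichment,
    gwas_window_overlap,
    link_ccres,
)
from cistrans.glasso import graphical_lasso_penalized, partial_correlations
from cistrans.intervals import GenomicInterval


class TestAggregateKnn:
    def test_k_one_is_depth_normalized_identity(self):
        rng = np.random.default_rng(0)
        counts = rng.poisson(3.0, (20, 6)).astype(float) + 1
        emb = rng.normal(size=(20, 2))
        agg, members = aggregate_knn(counts, emb, k=1, max_overlap=0.0, seed=0)
        for vec, m in zip(agg, members):
            expected = counts[m[0]] / counts[m[0]].sum() * 1e4
            np.testing.assert_allclose(vec, expected)

    def test_identical_nuclei_give_identical_groups(self):
        counts = np.tile([2.0, 4.0, 6.0], (60, 1))
        emb = np.zeros((60, 2))
        agg, _ = aggregate_knn(counts, emb, k=10, max_overlap=1.0, seed=1)
        assert agg.shape[1] == 3
        assert np.allclose(agg, agg[0])

    def test_cluster_smaller_than_k(self):
        with pytest.raises(ValueError, match="fewer than k"):
            aggregate_knn(np.ones((5, 3)), np.ones((5, 2)), k=10)


class TestGlasso:
    def test_identity_precision_gives_no_strong_edges(self):
        rng = np.random.default_rng(0)
        total = 0
        for _ in range(5):
            X = rng.standard_normal((300, 8))
            S = np.corrcoef(X, rowvar=False)
            _, theta = graphical_lasso_penalized(S, np.full((8, 8), 0.1))
            pc = partial_correlations(theta)
            total += (np.abs(pc[np.triu_indices(8, 1)]) >= 0.2).sum()
        assert total == 0

    def test_partial_correlations_bounded_and_symmetric(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((200, 6))
        S = np.cov(X, rowvar=False)
        _, theta = graphical_lasso_penalized(S, np.zeros((6, 6)))
        pc = partial_correlations(theta)
        assert np.all(np.abs(pc) <= 1 + 1e-12)
        np.testing.assert_allclose(pc, pc.T, atol=1e-8)


def _grid_peaks(n, chrom="chr1", start=1_000_000, spacing=10_000, width=500):
    return [GenomicInterval(chrom, start + i * spacing, start + i * spacing + width) for i in range(n)]


class TestCoaccessibility:
    def test_distance_rule_blocks_far_pairs(self):
        rng = np.random.default_rng(1)
        peaks = [
            GenomicInterval("chr1", 1_000_000, 1_000_500),
            GenomicInterval("chr1", 1_600_000, 1_600_500),
        ]
        x = rng.standard_normal(200)
        data = np.column_stack([x, x + rng.normal(0, 0.01, 200)])  # near-perfect corr
        edges = coaccessibility(data, peaks, max_dist=500_000)
        assert edges.empty

    def test_planted_block_ranks_above_background(self, synthetic_dataset):
        ds = synthetic_dataset
        cfg = ds.config
        edges = coaccessibility(ds.coaccess_samples, ds.annotation.peaks, ds.annotation.peak_ids)
        blocks = [set(b.peak_indices) for b in cfg.ccan_blocks]
        idx = {p: i for i, p in enumerate(ds.annotation.peak_ids)}
        inb, outb = [], []
        for r in edges.itertuples():
            i, j = idx[r.peak_a], idx[r.peak_b]
            (inb if any(i in b and j in b for b in blocks) else outb).append(abs(r.score))
        inb, outb = np.array(inb), np.array(outb)
        auroc = (inb[:, None] > outb[None, :]).mean()
        assert auroc >= 0.95


class TestExtractCcans:
    def _clique_edges(self, names, score):
        rows = [
            {"peak_a": a, "peak_b": b, "score": score, "distance": 1000}
            for a, b in itertools.combinations(names, 2)
        ]
        return pd.DataFrame(rows)

    def test_two_disjoint_cliques(self):
        e = pd.concat(
            [
                self._clique_edges([f"chr1:{i}00-{i}50" for i in range(1, 6)], 0.5),
                self._clique_edges([f"chr2:{i}00-{i}50" for i in range(1, 6)], 0.5),
            ]
        )
        ccans = extract_ccans(e)
        assert len(ccans) == 2
        assert sorted(len(c.peaks) for c in ccans) == [5, 5]

    def test_subthreshold_scores_yield_nothing(self):
        e = self._clique_edges(["a", "b", "c", "d"], 0.19)
        assert extract_ccans(e) == []

    def test_min_size_excludes_pairs(self):
        e = self._clique_edges(["a", "b"], 0.9)
        assert extract_ccans(e) == []


def _toy_annotation():
    """One gene per 100 kb slot; promoter covers peak p{i}a at the TSS."""
    genes, exons = [], []
    for i, tss in enumerate([1_000_250, 2_000_250, 3_000_250]):
        genes.append(
            {"gene_id": f"g{i}", "chrom": "chr1", "start": tss, "end": tss + 20_000,
             "strand": "+", "tss": tss}
        )
        exons.append({"gene_id": f"g{i}", "chrom": "chr1", "start": tss, "end": tss + 300,
                      "exon_number": 1})
        exons.append({"gene_id": f"g{i}", "chrom": "chr1", "start": tss + 2300,
                      "end": tss + 2800, "exon_number": 2})
    return GeneAnnotation(pd.DataFrame(genes).set_index("gene_id"), pd.DataFrame(exons))


def _ccan_fixture(dap_signs, deg_signs, coacc=0.5, anchors_as_daps=True):
    """CCAN with one anchor peak per DEG (at its promoter) and one distal DAP
    per entry of dap_signs, fully connected at the given score.

    With anchors_as_daps the anchor peaks are themselves differential (with
    their DEG's sign), as the cCRE linking criteria require; without it only
    the distal peaks are DAPs, isolating the pure sign taxonomy.
    """
    ann = _toy_annotation()
    anchors = [f"chr1:{1_000_000 + i * 1_000_000}-{1_000_500 + i * 1_000_000}" for i in range(len(deg_signs))]
    daps = [f"chr1:{1_500_000 + i * 10_000}-{1_500_500 + i * 10_000}" for i in range(len(dap_signs))]
    peaks = anchors + daps
    rows = [
        {"peak_a": a, "peak_b": b, "score": coacc, "distance": 1000}
        for a, b in itertools.combinations(peaks, 2)
    ]
    ccan = CCAN(id="c0", peaks=peaks, edges=pd.DataFrame(rows))
    lfc = [s * 1.0 for s in dap_signs]
    index = list(daps)
    if anchors_as_daps:
        lfc += [deg_signs[i] * 1.0 for i in range(len(deg_signs))]
        index += anchors
    dap_table = pd.DataFrame({"log2fc": lfc}, index=index)
    deg_table = pd.DataFrame(
        {"log2fc": [s * 0.5 for s in deg_signs]}, index=[f"g{i}" for i in range(len(deg_signs))]
    )
    return ccan, dap_table, deg_table, ann


class TestClassification:
    @pytest.mark.parametrize(
        "dap_signs, deg_signs, expected",
        [
            ((1, 1), (1,), "unidirectional"),
            ((1, -1), (1,), "mixed"),
            ((-1,), (1,), "bidirectional"),
        ],
    )
    def test_rule_examples(self, dap_signs, deg_signs, expected):
        ccan, dap, deg, ann = _ccan_fixture(dap_signs, deg_signs, anchors_as_daps=False)
        assert classify_ccan(ccan, dap, deg, ann).klass == expected

    def test_exhaustive_sign_patterns(self):
        # the taxonomy is a pure function of the sign pattern
        for n_dap in (1, 2, 3):
            for n_deg in (1, 2):
                for dap_signs in itertools.product((1, -1), repeat=n_dap):
                    for deg_signs in itertools.product((1, -1), repeat=n_deg):
                        ccan, dap, deg, ann = _ccan_fixture(
                            dap_signs, deg_signs, anchors_as_daps=False
                        )
                        got = classify_ccan(ccan, dap, deg, ann).klass
                        pairs = [d == g for d in dap_signs for g in deg_signs]
                        expected = (
                            "unidirectional" if all(pairs)
                            else "bidirectional" if not any(pairs)
                            else "mixed"
                        )
                        assert got == expected, (dap_signs, deg_signs)

    def test_no_dap_or_no_anchor_unclassified(self):
        ccan, dap, deg, ann = _ccan_fixture((1,), (1,))
        empty = pd.DataFrame({"log2fc": []})
        assert classify_ccan(ccan, empty, deg, ann).klass == "unclassified"


class TestLinkCcres:
    def test_compliant_module_yields_one_link(self):
        ccan, dap, deg, ann = _ccan_fixture((1,), (1,))
        classify_ccan(ccan, dap, deg, ann)
        links = link_ccres([ccan], dap, deg, ann)
        assert len(links) == 1
        assert links[0].target == "g0" and links[0].ccre.startswith("chr1:15")

    def test_anchor_not_dap_blocks_link(self):
        ccan, dap, deg, ann = _ccan_fixture((1,), (1,))
        classify_ccan(ccan, dap, deg, ann)
        dap_no_anchor = dap.loc[[i for i in dap.index if i.startswith("chr1:15")]]
        ccan.daps = {p: v for p, v in ccan.daps.items() if p in dap_no_anchor.index}
        assert link_ccres([ccan], dap_no_anchor, deg, ann) == []

    def test_small_effect_target_blocks_link(self):
        ccan, dap, deg, ann = _ccan_fixture((1,), (1,))
        deg.loc["g0", "log2fc"] = 0.10
        classify_ccan(ccan, dap, deg, ann)
        assert link_ccres([ccan], dap, deg, ann) == []

    def test_low_coaccessibility_blocks_link(self):
        ccan, dap, deg, ann = _ccan_fixture((1,), (1,), coacc=0.15)
        classify_ccan(ccan, dap, deg, ann)
        assert link_ccres([ccan], dap, deg, ann) == []

    def test_bidirectional_ccans_skipped(self):
        ccan, dap, deg, ann = _ccan_fixture((-1,), (1,), anchors_as_daps=False)
        classify_ccan(ccan, dap, deg, ann)
        assert ccan.klass == "bidirectional"
        assert link_ccres([ccan], dap, deg, ann) == []


class TestGwasOverlap:
    def test_interval_flags(self):
        tags = pd.DataFrame({"chrom": ["chr1"], "pos": [1_000_000]})
        ivs = [
            GenomicInterval("chr1", 1_400_000, 1_400_500),
            GenomicInterval("chr1", 1_500_001, 1_500_501),
            GenomicInterval("chr2", 1_000_000, 1_000_500),
        ]
        assert gwas_window_overlap(ivs, tags) == [True, False, False]

    def test_ccan_flag_set_in_place(self):
        tags = pd.DataFrame({"chrom": ["chr1"], "pos": [1_000_000]})
        ccan = CCAN("c", ["chr1:900000-900500", "chr1:5000000-5000500"], pd.DataFrame())
        assert gwas_window_overlap([ccan], tags) == [True]
        assert ccan.gwas_overlap


class TestGoEnrichment:
    def test_full_term_recovery(self):
        bg = {f"g{i}" for i in range(1000)}
        term = {f"g{i}" for i in range(10)}
        res = go_enrichment(term, bg, {"T": term})
        from scipy import stats as sps

        assert res.loc[0, "p"] == pytest.approx(sps.hypergeom.sf(9, 1000, 10, 10), rel=1e-9)

    def test_disjoint_target_not_reported(self):
        bg = {f"g{i}" for i in range(100)}
        res = go_enrichment({"g50", "g51", "g52"}, bg, {"T": {"g0", "g1", "g2", "g3"}})
        assert res.empty

    def test_min_gene_rule(self):
        bg = {f"g{i}" for i in range(1000)}
        res = go_enrichment({"g0", "g1"}, bg, {"T": {"g0", "g1"}})
        assert res.empty  # only 2 mapped genes, below the >=3 rule
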