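import numpy as np
import pandas as pd
import pytest

from cistrans.intervals import GenomicInterval
from cistrans.qc import (
    QCThresholds,
    compute_atac_qc,
    filter_nuclei,
    jaccard_validate,
    link_clusters,
)


def _fragments(records):
    return pd.DataFrame(records, columns=["chrom", "start", "end", "barcode"])


class TestAtacQcMetrics:
    def test_nucleosome_signal_ratio(self):
        rows = [("chr1", 0, 100, "bc")] * 100 + [("chr1", 0, 200, "bc")] * 500
        qc = compute_atac_qc(_fragments(rows), [], pd.DataFrame(columns=["chrom", "pos"]), [])
        assert qc.loc["bc", "nucleosome_signal"] == pytest.approx(5.0)

    def test_zero_free_fragments_give_inf(self):
        rows = [("chr1", 0, 200, "bc")] * 10
        qc = compute_atac_qc(_fragments(rows), [], pd.DataFrame(columns=["chrom", "pos"]), [])
        assert np.isinf(qc.loc["bc", "nucleosome_signal"])

    def test_all_fragments_in_peaks(self):
        peaks = [GenomicInterval("chr1", 0, 1000)]
        rows = [("chr1", i * 10, i * 10 + 80, "bc") for i in range(20)]
        qc = compute_atac_qc(_fragments(rows), peaks, pd.DataFrame(columns=["chrom", "pos"]), [])
        assert qc.loc["bc", "pct_reads_in_peaks"] == 1.0

    def test_blacklist_ratio(self):
        blacklist = [GenomicInterval("chr1", 0, 100)]
        rows = [("chr1", 10, 60, "bc")] * 3 + [("chr1", 5000, 5050, "bc")] * 97
        qc = compute_atac_qc(_fragments(rows), [], pd.DataFrame(columns=["chrom", "pos"]), blacklist)
        assert qc.loc["bc", "blacklist_ratio"] == pytest.approx(0.03)

    def test_tss_enrichment_center_vs_flanks(self):
        tss = pd.DataFrame({"chrom": ["chr1"], "pos": [10_000]})
        rows = [("chr1", 9_960, 10_040, "bc")] * 40  # midpoints at the TSS
        rows += [("chr1", 8_050, 8_090, "bc")] * 10  # left flank (1900-2000 upstream)
        qc = compute_atac_qc(_fragments(rows), [], tss, [])
        # 40 center mids over 200 bp vs 10 flank mids over 200 bp
        assert qc.loc["bc", "tss_enrichment"] == pytest.approx(4.0)


def _rna_tables():
    qc = pd.DataFrame(
        {
            "n_features": [150, 5000, 20_000, 3000, 3000, 3000],
            "pct_mito": [0.05, 0.05, 0.05, 0.30, 0.05, 0.05],
        },
        index=["low", "ok", "high", "mito", "hybrid", "unscored"],
    )
    scores = pd.DataFrame(
        {
            "x1": [0.9, 0.9, 0.9, 0.9, 0.9],
            "x2": [0.1, 0.1, 0.1, 0.1, 0.8],
        },
        index=["low", "ok", "high", "mito", "hybrid"],
    )
    return qc, scores


class TestFilterNuclei:
    def test_rna_rules_and_reasons(self):
        qc, scores = _rna_tables()
        res = filter_nuclei(qc, scores, "rna")
        assert list(res.kept) == ["ok"]
        reasons = res.removed["reasons"]
        assert reasons["low"] == "n_features"
        assert reasons["high"] == "n_features"
        assert reasons["mito"] == "pct_mito"
        assert reasons["hybrid"] == "hybrid"  # (0.9-0.8)/0.9 = 0.111 < 0.2
        assert reasons["unscored"] == "unscored"

    def test_hybrid_formula_boundary(self):
        qc = pd.DataFrame({"n_features": [3000, 3000], "pct_mito": [0.0, 0.0]},
                          index=["kept", "removed"])
        scores = pd.DataFrame({"x1": [0.9, 0.9], "x2": [0.45, 0.8]}, index=qc.index)
        res = filter_nuclei(qc, scores, "rna")
        assert "kept" in res.kept and "removed" not in res.kept

    def test_atac_rules(self):
        qc = pd.DataFrame(
            {
                "nucleosome_signal": [1.0, 5.0, 1.0],
                "tss_enrichment": [4.0, 4.0, 1.0],
                "pct_reads_in_peaks": [0.5, 0.5, 0.5],
                "peak_region_fragments": [2000, 2000, 2000],
                "blacklist_ratio": [0.01, 0.01, 0.01],
                "sample": ["s1", "s1", "s1"],
            },
            index=["ok", "ns", "tss"],
        )
        scores = pd.DataFrame({"x1": [0.9] * 3, "x2": [0.1] * 3}, index=qc.index)
        res = filter_nuclei(qc, scores, "atac")
        assert list(res.kept) == ["ok"]
        assert res.removed["reasons"]["ns"] == "nucleosome_signal"
        assert res.removed["reasons"]["tss"] == "tss_enrichment"

    def test_per_sample_fragment_cap(self):
        n = 200
        qc = pd.DataFrame(
            {
                "nucleosome_signal": 1.0,
                "tss_enrichment": 4.0,
                "pct_reads_in_peaks": 0.5,
                "peak_region_fragments": list(range(1500, 1500 + n - 1)) + [10_000_000],
                "blacklist_ratio": 0.0,
                "sample": "s1",
            },
            index=[f"b{i}" for i in range(n)],
        )
        scores = pd.DataFrame({"x1": [0.9] * n, "x2": [0.1] * n}, index=qc.index)
        res = filter_nuclei(qc, scores, "atac")
        assert f"b{n-1}" not in res.kept
        assert "peak_region_fragments" in res.removed["reasons"][f"b{n-1}"]

    def test_idempotent_and_order_invariant(self):
        qc, scores = _rna_tables()
        first = filter_nuclei(qc, scores, "rna")
        again = filter_nuclei(qc.loc[first.kept], scores, "rna")
        assert list(again.kept) == list(first.kept)
        shuffled = filter_nuclei(qc.iloc[::-1], scores, "rna")
        assert set(shuffled.kept) == set(first.kept)
        assert len(first.kept) + len(first.removed) == len(qc)


class TestLinkClusters:
    def _scores(self, rows, index):
        return pd.DataFrame(rows, index=index, columns=["A", "B"])

    def test_argmax_and_cluster_hybrid(self):
        scores = self._scores([[6.0, 3.0], [4.0, 2.0]], ["n1", "n2"])
        clusters = pd.Series(["x", "x"], index=["n1", "n2"])
        (link,) = link_clusters(scores, clusters)
        assert link.linked_rna_cluster == "A"
        assert link.cluster_hybrid_score == pytest.approx(0.5)  # (10-5)/10
        assert not link.tie

    def test_tie_breaks_to_lowest_id_with_flag(self):
        scores = self._scores([[7.0, 7.0]], ["n1"])
        (link,) = link_clusters(scores, pd.Series(["x"], index=["n1"]))
        assert link.linked_rna_cluster == "A" and link.tie

    def test_permutation_invariance(self):
        rng = np.random.default_rng(0)
        scores = pd.DataFrame(rng.random((30, 2)), columns=["A", "B"],
                              index=[f"n{i}" for i in range(30)])
        clusters = pd.Series(["x"] * 15 + ["y"] * 15, index=scores.index)
        l1 = link_clusters(scores, clusters)
        perm = rng.permutation(30)
        l2 = link_clusters(scores.iloc[perm], clusters.iloc[perm])
        assert [(l.atac_cluster, l.linked_rna_cluster) for l in l1] == [
            (l.atac_cluster, l.linked_rna_cluster) for l in l2
        ]

    def test_empty_cluster_errors(self):
        scores = self._scores([[1.0, 0.0]], ["n1"])
        with pytest.raises(ValueError, match="empty"):
            link_clusters(scores, pd.Series([], dtype=object))


class TestJaccardValidation:
    def _links(self, pairs):
        from cistrans.qc import ClusterLink

        return [ClusterLink(a, r, {}, 1.0, True, False) for a, r in pairs]

    def test_identical_partitions(self):
        assign = pd.Series(["0"] * 50 + ["1"] * 50, index=[f"b{i}" for i in range(100)])
        links, mean = jaccard_validate(self._links([("0", "0"), ("1", "1")]), assign, assign)
        assert all(l.jaccard == 1.0 for l in links) and mean == 1.0

    def test_half_overlap_set_arithmetic(self):
        atac = pd.Series(["0"] * 100, index=[f"b{i}" for i in range(100)])
        rna = pd.Series(["0"] * 150, index=[f"b{i}" for i in range(50, 200)])
        links, mean = jaccard_validate(self._links([("0", "0")]), atac, rna)
        assert mean == pytest.approx(50 / 200)

    def test_shuffled_labels_match_direct_recount(self):
        rng = np.random.default_rng(4)
        barcodes = [f"b{i}" for i in range(400)]
        truth = np.repeat([0, 1, 2, 3], 100)
        noisy = truth.copy()
        flip = rng.random(400) < 0.1
        noisy[flip] = rng.integers(0, 4, flip.sum())
        atac = pd.Series(truth.astype(str), index=barcodes)
        rna = pd.Series(noisy.astype(str), index=barcodes)
        links, mean = jaccard_validate(
            self._links([(str(k), str(k)) for k in range(4)]), atac, rna
        )
        direct = []
        for k in range(4):
            a = {b for b, v in zip(barcodes, truth) if v == k}
            r = {b for b, v in zip(barcodes, noisy) if v == k}
            direct.append(len(a & r) / len(a | r))
        assert mean == pytest.approx(np.mean(direct))
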