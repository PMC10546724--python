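"""Per-nucleus quality control, multiplet removal and cross-modality linking.

RNA nuclei are kept when 200 <= n_features <= 10,000, mitochondrial fraction
<= 17.4 %, maximum prediction score >= 0.5, and hybrid score
(x1 - x2)/x1 >= 0.2.  ATAC nuclei additionally require nucleosome signal <= 4,
TSS enrichment >= 2, >= 15 % of fragments in peaks, 1000 <= peak-region
fragments <= per-sample 99th percentile, and blacklist ratio <= 5 %.  ATAC
clusters are linked to RNA clusters by the argmax of nucleus prediction
scores summed per cluster, with a cluster-level hybrid score and an optional
Jaccard validation against shared-barcode assignments.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .intervals import GenomicInterval


@dataclass
class QCThresholds:
    min_features: int = 200
    max_features: int = 10_000
    max_pct_mito: float = 0.174
    max_nucleosome_signal: float = 4.0
    min_tss_enrichment: float = 2.0
    min_pct_reads_in_peaks: float = 0.15
    min_peak_region_fragments: int = 1000
    fragment_cap_quantile: float = 0.99  # per-sample upper cap
    max_blacklist_ratio: float = 0.05
    min_prediction_score: float = 0.5
    min_hybrid_score: float = 0.2
    label_droplist: tuple[str, ...] = ()


def _frac_overlapping(mids: np.ndarray, chroms: np.ndarray, targets: list[GenomicInterval]) -> np.ndarray:
    """Boolean per fragment: midpoint inside any target interval."""
    hit = np.zeros(mids.shape, dtype=bool)
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for t in targets:
        by_chrom.setdefault(t.chrom, []).append(t)
    for chrom, ivs in by_chrom.items():
        sel = chroms == chrom
        if not sel.any():
            continue
        starts = np.array(sorted(iv.start for iv in ivs))
        ends = np.array([iv.end for iv in sorted(ivs, key=lambda x: x.start)])
        pos = mids[sel]
        idx = np.searchsorted(starts, pos, side="right") - 1
        ok = idx >= 0
        ok[ok] &= pos[ok] < ends[idx[ok]]
        hit[sel] = ok
    return hit


def compute_atac_qc(
    fragments: pd.DataFrame,
    peaks: list[GenomicInterval],
    tss_reference: pd.DataFrame,
    blacklist: list[GenomicInterval],
    tss_window: int = 100,
    flank_offset: int = 1900,
    flank_width: int = 100,
) -> pd.DataFrame:
    """Per-barcode ATAC QC metrics from a fragment table.

    ``fragments`` needs chrom, start, end, barcode.  Nucleosome signal is the
    count ratio of mononucleosome (147-294 bp) to nucleosome-free (<147 bp)
    fragments; TSS enrichment compares per-bp fragment-midpoint signal in
    ±``tss_window`` bp of a TSS to two 100-bp flanks at ±1900-2000 bp;
    fraction-in-peaks and blacklist ratio count fragment midpoints.  A barcode
    with zero nucleosome-free fragments gets +inf signal; a barcode with zero
    fragments cannot occur (it has no rows).
    """
    frag = fragments.copy()
    frag["length"] = frag["end"] - frag["start"]
    frag["mid"] = (frag["start"] + frag["end"]) // 2
    mids = frag["mid"].to_numpy()
    chroms = frag["chrom"].to_numpy()
    frag["in_peak"] = _frac_overlapping(mids, chroms, peaks)
    frag["in_blacklist"] = _frac_overlapping(mids, chroms, blacklist)
    center_ivs, flank_ivs = [], []
    for r in tss_reference.itertuples():
        tss = int(r.pos)
        center_ivs.append(GenomicInterval(r.chrom, max(tss - tss_window, 0), tss + tss_window))
        flank_ivs.append(
            GenomicInterval(r.chrom, max(tss - flank_offset - flank_width, 0), max(tss - flank_offset, 1))
        )
        flank_ivs.append(GenomicInterval(r.chrom, tss + flank_offset, tss + flank_offset + flank_width))
    frag["in_tss"] = _frac_overlapping(mids, chroms, center_ivs)
    frag["in_flank"] = _frac_overlapping(mids, chroms, flank_ivs)
    center_bp = 2 * tss_window
    flank_bp = 2 * flank_width

    def per_barcode(g: pd.DataFrame) -> pd.Series:
        free = int((g["length"] < 147).sum())
        mono = int(((g["length"] >= 147) & (g["length"] <= 294)).sum())
        ns = mono / free if free > 0 else float("inf")
        tss_rate = g["in_tss"].sum() / center_bp
        flank_rate = g["in_flank"].sum() / flank_bp
        if flank_rate > 0:
            tss_enr = tss_rate / flank_rate
        else:
            tss_enr = float("inf") if tss_rate > 0 else 0.0
        n = len(g)
        return pd.Series(
            {
                "nucleosome_signal": ns,
                "tss_enrichment": tss_enr,
                "pct_reads_in_peaks": g["in_peak"].sum() / n,
                "peak_region_fragments": int(g["in_peak"].sum()),
                "blacklist_ratio": g["in_blacklist"].sum() / n,
                "n_fragments": n,
            }
        )

    qc = frag.groupby("barcode").apply(per_barcode, include_groups=False)
    return qc


@dataclass
class FilterResult:
    kept: pd.Index
    removed: pd.DataFrame  # barcode-indexed, column "reasons" (semicolon list)

    def reason_table(self) -> pd.DataFrame:
        return self.removed


def filter_nuclei(
    qc_table: pd.DataFrame,
    score_table: pd.DataFrame,
    modality: str,
    thresholds: QCThresholds | None = None,
) -> FilterResult:
    """Apply the per-nucleus QC and hybrid-score filters.

    ``score_table`` is barcode-indexed with columns x1 and x2 (top two
    prediction scores); barcodes missing from it are removed as "unscored".
    Every removed barcode lists all failed rules.
    """
    th = thresholds or QCThresholds()
    if modality not in ("rna", "atac"):
        raise ValueError("modality must be 'rna' or 'atac'")
    reasons: dict[str, list[str]] = {bc: [] for bc in qc_table.index}
    if modality == "rna":
        for bc, row in qc_table.iterrows():
            if not (th.min_features <= row["n_features"] <= th.max_features):
                reasons[bc].append("n_features")
            if row["pct_mito"] > th.max_pct_mito:
                reasons[bc].append("pct_mito")
    else:
        caps = (
            qc_table.groupby(qc_table["sample"])["peak_region_fragments"].quantile(
                th.fragment_cap_quantile
            )
            if "sample" in qc_table.columns
            else None
        )
        for bc, row in qc_table.iterrows():
            if row["nucleosome_signal"] > th.max_nucleosome_signal:
                reasons[bc].append("nucleosome_signal")
            if row["tss_enrichment"] < th.min_tss_enrichment:
                reasons[bc].append("tss_enrichment")
            if row["pct_reads_in_peaks"] < th.min_pct_reads_in_peaks:
                reasons[bc].append("pct_reads_in_peaks")
            cap = caps.loc[row["sample"]] if caps is not None else np.inf
            if not (th.min_peak_region_fragments <= row["peak_region_fragments"] <= cap):
                reasons[bc].append("peak_region_fragments")
            if row["blacklist_ratio"] > th.max_blacklist_ratio:
                reasons[bc].append("blacklist_ratio")
    for bc in qc_table.index:
        if bc not in score_table.index:
            reasons[bc].append("unscored")
            continue
        x1 = score_table.loc[bc, "x1"]
        x2 = score_table.loc[bc, "x2"]
        if x1 < th.min_prediction_score:
            reasons[bc].append("prediction_score")
        if x1 > 0 and (x1 - x2) / x1 < th.min_hybrid_score:
            reasons[bc].append("hybrid")
        if th.label_droplist and "label" in score_table.columns:
            if score_table.loc[bc, "label"] in th.label_droplist:
                reasons[bc].append("label_droplist")
    removed = {bc: r for bc, r in reasons.items() if r}
    kept = qc_table.index[~qc_table.index.isin(removed)]
    removed_df = pd.DataFrame(
        {"reasons": [";".join(removed[bc]) for bc in removed]}, index=pd.Index(removed, name="barcode")
    )
    return FilterResult(kept=kept, removed=removed_df)


@dataclass(frozen=True)
class ClusterLink:
    atac_cluster: str
    linked_rna_cluster: str
    summed_scores: dict
    cluster_hybrid_score: float
    celltype_concordant: bool
    tie: bool
    jaccard: float | None = None


def link_clusters(
    score_matrix: pd.DataFrame,
    atac_clusters: pd.Series,
    atac_celltypes: dict | None = None,
    rna_celltypes: dict | None = None,
) -> list[ClusterLink]:
    """Link each ATAC cluster to the RNA cluster with the largest summed
    prediction score; compute the cluster-level hybrid score (s1 - s2)/s1 on
    the summed scores.  Argmax ties break to the lowest cluster id and are
    flagged.
    """
    if len(atac_clusters) == 0:
        raise ValueError("empty cluster assignment")
    links = []
    for cl in sorted(atac_clusters.unique(), key=str):
        members = atac_clusters.index[atac_clusters == cl]
        if len(members) == 0:
            raise ValueError(f"empty ATAC cluster {cl}")
        summed = score_matrix.loc[members].sum(axis=0)
        best = summed.max()
        winners = sorted(summed.index[summed == best], key=str)
        linked = winners[0]
        tie = len(winners) > 1
        s_sorted = np.sort(summed.to_numpy())[::-1]
        hybrid = (s_sorted[0] - s_sorted[1]) / s_sorted[0] if len(s_sorted) > 1 and s_sorted[0] > 0 else 1.0
        concordant = True
        if atac_celltypes is not None and rna_celltypes is not None:
            concordant = atac_celltypes.get(cl) == rna_celltypes.get(linked)
        links.append(
            ClusterLink(str(cl), str(linked), summed.to_dict(), float(hybrid), concordant, tie)
        )
    return links


def jaccard_validate(
    links: list[ClusterLink],
    atac_assign: pd.Series,
    rna_assign: pd.Series,
) -> tuple[list[ClusterLink], float]:
    """Jaccard index of barcode compositions for each linked cluster pair.

    Both assignment series are barcode-indexed (a multiome-style fixture where
    each barcode carries both an ATAC and an RNA cluster).  Returns the links
    annotated with per-cluster J and the unweighted mean J.
    """
    out = []
    js = []
    for link in links:
        a = set(atac_assign.index[atac_assign.astype(str) == link.atac_cluster])
        r = set(rna_assign.index[rna_assign.astype(str) == link.linked_rna_cluster])
        union = a | r
        j = len(a & r) / len(union) if union else 0.0
        js.append(j)
        out.append(
            ClusterLink(
                link.atac_cluster,
                link.linked_rna_cluster,
                link.summed_scores,
                link.cluster_hybrid_score,
                link.celltype_concordant,
                link.tie,
                jaccard=float(j),
            )
        )
    return out, float(np.mean(js)) if js else 0.0
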