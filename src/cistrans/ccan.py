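"""Cis-co-accessibility networks and candidate cis-regulatory element linking.

Pipeline: disease-group nuclei of one cluster are aggregated into groups of
k nearest neighbors in the embedding; co-accessibility scores are regularized
partial correlations from a distance-penalized sparse inverse-covariance fit
over overlapping genomic windows; CCANs are Louvain communities of the
score >= 0.2 graph; each CCAN is classified by the log2FC sign concordance of
its (DAP, DEG-anchor) pairs; cCRE-DEG links are emitted for the pairs passing
the four linking criteria plus the noncoding requirement.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from sklearn.neighbors import NearestNeighbors

from .annotation import GeneAnnotation
from .glasso import graphical_lasso_penalized, partial_correlations
from .intervals import GenomicInterval, within_window


def aggregate_knn(
    counts: np.ndarray,
    embedding: np.ndarray,
    k: int = 50,
    max_overlap: float = 0.8,
    seed: int = 0,
) -> tuple[np.ndarray, list[np.ndarray]]:
    """Sum peak counts over groups of k nearest neighbors, depth-normalized.

    ``counts`` is nuclei x peaks; ``embedding`` nuclei x d.  Seed nuclei are
    drawn in random order and a group is kept only if it shares at most
    ``max_overlap`` of its members with every previously accepted group.
    Group vectors are divided by total group fragments and scaled by 1e4.
    Returns (groups x peaks matrix, list of member index arrays).
    """
    n = counts.shape[0]
    if n < k:
        raise ValueError(f"cluster has {n} nuclei, fewer than k={k}; merge or skip")
    nn = NearestNeighbors(n_neighbors=k).fit(embedding)
    _, neighbor_idx = nn.kneighbors(embedding)
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    member_sets: list[set[int]] = []
    members: list[np.ndarray] = []
    for i in order:
        group = neighbor_idx[i]
        gset = set(int(x) for x in group)
        if any(len(gset & prev) > max_overlap * k for prev in member_sets):
            continue
        member_sets.append(gset)
        members.append(np.sort(group))
    agg = np.stack([counts[m].sum(axis=0).astype(float) for m in members])
    depth = agg.sum(axis=1, keepdims=True)
    depth[depth == 0] = 1.0
    return agg / depth * 1e4, members


@dataclass(frozen=True)
class CoaccessEdge:
    peak_a: str
    peak_b: str
    score: float
    distance: int


def coaccessibility(
    aggregated: np.ndarray,
    peaks: list[GenomicInterval],
    peak_ids: list[str] | None = None,
    max_dist: int = 500_000,
    window: int = 1_000_000,
    rho0: float = 0.1,
    gamma: float = 0.5,
    min_groups: int = 10,
) -> pd.DataFrame:
    """Distance-penalized partial-correlation co-accessibility scores.

    Estimation runs per chromosome in overlapping genomic windows (50 %
    overlap); the L1 penalty on pair (i, j) is rho0 * (d_ij / max_dist)^gamma,
    and pairs beyond ``max_dist`` are excluded from the precision support
    entirely.  Scores of pairs seen in multiple windows are averaged.
    Returns a frame with peak_a, peak_b (canonically ordered), score, distance.
    """
    if peak_ids is None:
        peak_ids = [p.name for p in peaks]
    if aggregated.shape[0] < min_groups:
        raise ValueError(f"need >= {min_groups} aggregated groups, got {aggregated.shape[0]}")
    if aggregated.shape[1] != len(peaks):
        raise ValueError("aggregated matrix columns must match peaks")
    mids = np.array([p.midpoint() for p in peaks])
    chroms = np.array([p.chrom for p in peaks])
    acc: dict[tuple[int, int], list[float]] = {}
    for chrom in np.unique(chroms):
        cidx = np.nonzero(chroms == chrom)[0]
        cidx = cidx[np.argsort(mids[cidx], kind="mergesort")]
        cm = mids[cidx]
        start0 = int(cm.min())
        step = window // 2
        w0 = start0 - (start0 % step)
        while w0 <= cm.max():
            sel = cidx[(cm >= w0) & (cm < w0 + window)]
            w0 += step
            if sel.size < 2:
                continue
            sub = aggregated[:, sel]
            keep = sub.std(axis=0) > 0
            sel = sel[keep]
            if sel.size < 2:
                continue
            sub = sub[:, keep]
            S = np.corrcoef(sub, rowvar=False)
            d = np.abs(mids[sel][:, None] - mids[sel][None, :])
            allowed = d <= max_dist
            np.fill_diagonal(allowed, True)
            penalty = rho0 * (np.clip(d, 0, max_dist) / max_dist) ** gamma
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                _, theta = graphical_lasso_penalized(S, penalty, allowed)
            pc = partial_correlations(theta)
            for a in range(sel.size):
                for b in range(a + 1, sel.size):
                    if d[a, b] > max_dist:
                        continue
                    key = (int(min(sel[a], sel[b])), int(max(sel[a], sel[b])))
                    acc.setdefault(key, []).append(float(pc[a, b]))
    rows = []
    for (i, j), scores in sorted(acc.items()):
        rows.append(
            {
                "peak_a": peak_ids[i],
                "peak_b": peak_ids[j],
                "score": float(np.mean(scores)),
                "distance": int(abs(mids[i] - mids[j])),
            }
        )
    return pd.DataFrame(rows, columns=["peak_a", "peak_b", "score", "distance"])


@dataclass
class CCAN:
    """A cis-co-accessibility network: one Louvain community of peaks."""

    id: str
    peaks: list[str]
    edges: pd.DataFrame
    klass: str = "unclassified"
    daps: dict[str, float] = field(default_factory=dict)
    deg_anchors: list[tuple[str, str, str]] = field(default_factory=list)
    gwas_overlap: bool = False


def extract_ccans(
    edges: pd.DataFrame,
    min_score: float = 0.2,
    min_size: int = 3,
    seed: int = 0,
    resolution: float = 1.0,
) -> list[CCAN]:
    """Louvain communities (weighted by score) of the thresholded peak graph;
    communities with >= min_size peaks become CCANs."""
    strong = edges[edges["score"] >= min_score]
    if strong.empty:
        return []
    g = nx.Graph()
    for r in strong.itertuples():
        g.add_edge(r.peak_a, r.peak_b, weight=r.score)
    communities = nx.community.louvain_communities(
        g, weight="weight", resolution=resolution, seed=seed
    )
    out: list[CCAN] = []
    for comm in sorted(communities, key=lambda c: sorted(c)[0]):
        if len(comm) < min_size:
            continue
        sub = strong[strong["peak_a"].isin(comm) & strong["peak_b"].isin(comm)]
        out.append(CCAN(id=f"ccan_{len(out)}", peaks=sorted(comm), edges=sub.reset_index(drop=True)))
    return out


def _parse_peak_id(peak_id: str) -> GenomicInterval:
    chrom, span = peak_id.rsplit(":", 1)
    start, end = span.split("-")
    return GenomicInterval(chrom, int(start), int(end))


def _deg_anchors(
    ccan_peaks: list[str], deg_table: pd.DataFrame, annotation: GeneAnnotation
) -> list[tuple[str, str, str]]:
    """(gene, anchor peak id, 'promoter'|'intron1') triples for CCAN peaks
    overlapping a DEG's promoter or first intron."""
    anchors = []
    intervals = {pid: _parse_peak_id(pid) for pid in ccan_peaks}
    for gene in deg_table.index:
        if gene not in annotation.genes.index:
            continue
        prom = annotation.promoter(gene)
        intr = annotation.intron1(gene)
        for pid, iv in intervals.items():
            if iv.overlaps(prom):
                anchors.append((gene, pid, "promoter"))
            elif intr is not None and iv.overlaps(intr):
                anchors.append((gene, pid, "intron1"))
    return anchors


def classify_ccan(
    ccan: CCAN,
    dap_table: pd.DataFrame,
    deg_table: pd.DataFrame,
    annotation: GeneAnnotation,
) -> CCAN:
    """Assign the directionality class from all (DAP, DEG-anchor) sign pairs.

    ``dap_table`` is indexed by peak id with a log2fc column; ``deg_table``
    indexed by gene with a log2fc column (both already significance-filtered).
    All pairs same sign -> unidirectional; none -> bidirectional; otherwise
    mixed; CCANs lacking a DAP or a DEG anchor stay unclassified.
    """
    ccan.daps = {
        pid: float(dap_table.loc[pid, "log2fc"]) for pid in ccan.peaks if pid in dap_table.index
    }
    ccan.deg_anchors = _deg_anchors(ccan.peaks, deg_table, annotation)
    genes = {g for g, _, _ in ccan.deg_anchors}
    if not ccan.daps or not genes:
        ccan.klass = "unclassified"
        return ccan
    same = []
    for dap_lfc in ccan.daps.values():
        for g in genes:
            same.append(np.sign(dap_lfc) == np.sign(deg_table.loc[g, "log2fc"]))
    if all(same):
        ccan.klass = "unidirectional"
    elif not any(same):
        ccan.klass = "bidirectional"
    else:
        ccan.klass = "mixed"
    return ccan


@dataclass(frozen=True)
class CCRELink:
    ccre: str  # distal noncoding DAP peak id
    target: str  # DEG gene id
    anchor: str  # anchor peak id at the target's promoter/intron1
    anchor_kind: str
    coaccessibility: float
    target_log2fc: float
    ccan_id: str


def link_ccres(
    ccans: list[CCAN],
    dap_table: pd.DataFrame,
    deg_table: pd.DataFrame,
    annotation: GeneAnnotation,
    min_coacc: float = 0.2,
    min_abs_lfc: float = 0.15,
) -> list[CCRELink]:
    """cCRE-target links from unidirectional and mixed CCANs.

    A link requires: (1) cCRE-anchor co-accessibility >= min_coacc; (2) the
    anchor peak is itself a DAP; (3) cCRE DAP, anchor DAP and DEG share sign;
    (4) |DEG log2fc| >= min_abs_lfc; and the cCRE overlaps no annotated exon
    and no promoter of any gene (noncoding requirement).
    """
    promoters = list(annotation.promoters().values())
    exons = annotation.exon_intervals()

    def noncoding(pid: str) -> bool:
        iv = _parse_peak_id(pid)
        return not any(iv.overlaps(x) for x in promoters) and not any(
            iv.overlaps(x) for x in exons
        )

    links: list[CCRELink] = []
    for ccan in ccans:
        if ccan.klass not in ("unidirectional", "mixed"):
            continue
        edge_score = {}
        for r in ccan.edges.itertuples():
            edge_score[frozenset((r.peak_a, r.peak_b))] = r.score
        for dap, dap_lfc in ccan.daps.items():
            if not noncoding(dap):
                continue
            for gene, anchor, kind in ccan.deg_anchors:
                if anchor == dap:
                    continue
                score = edge_score.get(frozenset((dap, anchor)))
                if score is None or score < min_coacc:
                    continue
                if anchor not in dap_table.index:
                    continue
                anchor_lfc = float(dap_table.loc[anchor, "log2fc"])
                gene_lfc = float(deg_table.loc[gene, "log2fc"])
                if not (np.sign(dap_lfc) == np.sign(anchor_lfc) == np.sign(gene_lfc)):
                    continue
                if abs(gene_lfc) < min_abs_lfc:
                    continue
                links.append(
                    CCRELink(dap, gene, anchor, kind, float(score), gene_lfc, ccan.id)
                )
    return links


def gwas_window_overlap(
    entities,
    tag_snps: pd.DataFrame,
    window: int = 500_000,
):
    """Flag intervals/CCANs within ±window (inclusive) of any GWAS tag SNP.

    ``tag_snps`` has columns chrom, pos.  Accepts a list of GenomicInterval
    (returns a boolean list) or a list of CCANs (sets .gwas_overlap in place
    and returns the flags).
    """
    tags = [(r.chrom, int(r.pos)) for r in tag_snps.itertuples()]

    def flag_interval(iv: GenomicInterval) -> bool:
        return any(within_window(iv, c, p, window) for c, p in tags)

    flags = []
    for ent in entities:
        if isinstance(ent, CCAN):
            f = any(flag_interval(_parse_peak_id(pid)) for pid in ent.peaks)
            ent.gwas_overlap = f
        else:
            f = flag_interval(ent)
        flags.append(f)
    return flags


def go_enrichment(
    target_genes,
    background_genes,
    gene_sets: dict[str, set],
    max_p: float = 0.05,
    min_genes: int = 3,
) -> pd.DataFrame:
    """One-sided hypergeometric over-representation of gene sets.

    Background should be the genes expressed in >=10% of the cluster's cells.
    Terms are reported when p <= max_p and >= min_genes target genes map to
    the term; terms with no background overlap are skipped.
    """
    target = set(target_genes) & set(background_genes)
    bg = set(background_genes)
    rows = []
    for term, members in gene_sets.items():
        in_bg = members & bg
        if not in_bg:
            continue
        k = len(target & in_bg)
        p = float(stats.hypergeom.sf(k - 1, len(bg), len(in_bg), len(target)))
        rows.append(
            {"term": term, "n_target": k, "n_background": len(in_bg), "p": p}
        )
    df = pd.DataFrame(rows, columns=["term", "n_target", "n_background", "p"])
    keep = df[(df["p"] <= max_p) & (df["n_target"] >= min_genes)]
    return keep.sort_values("p", kind="mergesort").reset_index(drop=True)
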