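"""Candidate regulatory SNP x TFBS screening and flagship filtering.

A SNP-TFBS pair is tested for affinity change only when it passes all of:
(a) it lies within a differentially accessible peak (DAP); (b) that peak
belongs to a unidirectional or mixed CCAN; (c) the CCAN has at least one peak
within 500 kb of a GWAS tag SNP; (d) the DAP is co-accessible (score >= 0.2)
with a peak at a DEG's promoter or first intron in the linked cluster;
(e) DAP and DEG share log2FC sign; (f) the motif match has exact p <= 5e-5
for the major or the minor allele sequence; (g) the TFBS overlaps the SNP;
(h) the SNP's minor allele frequency is >= 1 % (multiallelic sites contribute
only alleles at >= 1 %).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .ccan import CCAN, _parse_peak_id
from .pwm import PWM, ScoreDistribution, _window_scores, encode
from .stats import bh_fdr


def _allele_windows_pass(
    seq: str, offset_in_peak: int, allele: str, pwm: PWM, threshold: float
) -> bool:
    """Does any window covering the SNP position reach the score threshold
    (either strand) after substituting ``allele`` at the SNP offset?"""
    codes = encode(seq)
    codes = codes.copy()
    codes[offset_in_peak] = encode(allele)[0]
    L = pwm.length
    lo = max(0, offset_in_peak - L + 1)
    hi = min(len(codes) - L, offset_in_peak)
    if hi < lo:
        return False
    window = codes[lo : hi + L]
    for m in (pwm.matrix, pwm.reverse_complement_matrix()):
        if _window_scores(window, m).max(initial=-np.inf) >= threshold - 1e-12:
            return True
    return False


def candidate_pairs(
    snps: pd.DataFrame,
    ccans: list[CCAN],
    dap_table: pd.DataFrame,
    deg_table: pd.DataFrame,
    peak_sequences: dict[str, str],
    pwms: list[PWM],
    min_coacc: float = 0.2,
    alpha: float = 5e-5,
    min_maf: float = 0.01,
    dists: dict[str, ScoreDistribution] | None = None,
) -> pd.DataFrame:
    """Screen SNP x motif pairs against criteria (a)-(h).

    ``snps`` has columns id, chrom, pos, ref, alt, maf (one row per alternate
    allele).  ``ccans`` must already be classified and GWAS-flagged;
    ``dap_table``/``deg_table`` are indexed by peak/gene with log2fc columns.
    Returns one row per passing pair with the 2L-1 context for the affinity
    test, plus the linked DEG of largest |log2fc| used by the flagship filter.
    """
    dists = dists or {}
    thresholds = {}
    for pwm in pwms:
        d = dists.get(pwm.tf) or ScoreDistribution(pwm)
        dists[pwm.tf] = d
        thresholds[pwm.tf] = d.threshold(alpha) - d.tol
    rows = []
    for ccan in ccans:
        if ccan.klass not in ("unidirectional", "mixed"):
            continue  # (b)
        if not ccan.gwas_overlap:
            continue  # (c)
        edge_score = {}
        for r in ccan.edges.itertuples():
            edge_score[frozenset((r.peak_a, r.peak_b))] = r.score
        anchors = ccan.deg_anchors
        for dap, dap_lfc in ccan.daps.items():  # (a): search only DAPs
            linked = []
            for gene, anchor, _ in anchors:
                if anchor == dap:
                    continue
                s = edge_score.get(frozenset((dap, anchor)))
                if s is None or s < min_coacc:
                    continue  # (d)
                gene_lfc = float(deg_table.loc[gene, "log2fc"])
                if np.sign(gene_lfc) != np.sign(dap_lfc):
                    continue  # (e)
                linked.append((gene, gene_lfc, s))
            if not linked:
                continue
            gene, gene_lfc, coacc = max(linked, key=lambda t: abs(t[1]))
            iv = _parse_peak_id(dap)
            seq = peak_sequences.get(dap)
            if seq is None:
                continue
            in_peak = snps[
                (snps["chrom"] == iv.chrom) & (snps["pos"] >= iv.start) & (snps["pos"] < iv.end)
            ]
            for snp in in_peak.itertuples():
                if snp.maf < min_maf:
                    continue  # (h)
                off = int(snp.pos) - iv.start
                for pwm in pwms:
                    L = pwm.length
                    if off - (L - 1) < 0 or off + (L - 1) >= len(seq):
                        continue  # context would leave the peak
                    thr = thresholds[pwm.tf]
                    passes = _allele_windows_pass(seq, off, snp.ref, pwm, thr) or _allele_windows_pass(
                        seq, off, snp.alt, pwm, thr
                    )  # (f), (g)
                    if not passes:
                        continue
                    context = seq[off - (L - 1) : off + L]
                    rows.append(
                        {
                            "snp": snp.id,
                            "tf": pwm.tf,
                            "peak": dap,
                            "ccan": ccan.id,
                            "chrom": iv.chrom,
                            "pos": int(snp.pos),
                            "ref": snp.ref,
                            "alt": snp.alt,
                            "maf": float(snp.maf),
                            "context": context,
                            "dap_log2fc": float(dap_lfc),
                            "target_deg": gene,
                            "target_log2fc": float(gene_lfc),
                            "coaccessibility": float(coacc),
                        }
                    )
    return pd.DataFrame(
        rows,
        columns=[
            "snp", "tf", "peak", "ccan", "chrom", "pos", "ref", "alt", "maf",
            "context", "dap_log2fc", "target_deg", "target_log2fc", "coaccessibility",
        ],
    )


def flagship_filter(
    results: pd.DataFrame,
    tf_expression_pct: dict[str, float],
    max_fdr: float = 0.01,
    min_expression_pct: float = 0.10,
    min_abs_target_lfc: float = 0.15,
) -> pd.DataFrame:
    """Apply the flagship criteria to affinity-test results.

    ``results`` needs p_mean, tf and target_log2fc columns; FDR is BH over
    p_mean across all tested pairs.  Flagship rows require FDR <= 0.01, TF
    expressed in >= 10 % of the cluster's cells, and |target DEG log2FC|
    >= 0.15.
    """
    out = results.copy()
    out["fdr"] = bh_fdr(out["p_mean"])
    expressed = out["tf"].map(lambda t: tf_expression_pct.get(t, 0.0) >= min_expression_pct)
    out["flagship"] = (
        (out["fdr"] <= max_fdr)
        & expressed
        & (out["target_log2fc"].abs() >= min_abs_target_lfc)
    )
    return out
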