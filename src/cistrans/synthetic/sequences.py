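"""Peak sequences with planted motif instances and affinity-changing SNPs.

Every peak gets a background-model sequence; motif plants insert an instance
sampled from the motif's column distributions (retried until it beats the
exact 5e-5 threshold, then an error).  Loss SNPs sit on a motif column whose
reference base is the column consensus and whose alternate allele is the
weakest base; gain SNPs plant the weak base in the reference sequence and use
the consensus as the alternate, so the best-window score moves by at least
the configured margin in the intended direction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..pwm import BASES, COMPLEMENT, PWM, MarkovBackground, ScoreDistribution, build_pwm, decode, encode
from .annotation import AnnotationBundle
from .config import SNPPlant, SyntheticConfig

MAX_RETRIES = 50


@dataclass
class SequenceBundle:
    peak_sequences: dict  # peak_id -> str
    pwms: list  # PWM
    dists: dict  # tf -> ScoreDistribution
    snps: pd.DataFrame  # id, chrom, pos, ref, alt, maf + plant metadata
    tag_snps: pd.DataFrame
    truth: dict = field(default_factory=dict)


def _sample_instance(
    pwm: PWM, dist: ScoreDistribution, rng: np.random.Generator, force: dict[int, int]
) -> np.ndarray:
    """Draw a motif instance above the 5e-5 threshold, with forced columns."""
    thr = dist.threshold(5e-5) - dist.tol
    cum = np.cumsum(pwm.probs, axis=1)
    for _ in range(MAX_RETRIES):
        u = rng.random(pwm.length)
        inst = (u[:, None] > cum).sum(axis=1)
        for col, base in force.items():
            inst[col] = base
        if pwm.score(inst) >= thr:
            return inst.astype(np.int8)
    # sharp motifs leave little room below the threshold: fall back to the
    # consensus instance (maximum-scoring, so it passes whenever s* exists)
    inst = np.argmax(pwm.probs, axis=1)
    for col, base in force.items():
        inst[col] = base
    if pwm.score(inst) >= thr:
        return inst.astype(np.int8)
    raise RuntimeError(
        f"could not sample an instance of {pwm.tf} above its exact threshold"
    )


def _snp_alleles(pwm: PWM, plant: SNPPlant, margin: float) -> tuple[int, int, int]:
    """(reference base planted in the sequence, alternate base, sign of the
    expected ref-alt score change)."""
    col = pwm.matrix[plant.column]
    strong = int(np.argmax(col))
    weak = int(np.argmin(col))
    if col[strong] - col[weak] < margin:
        raise ValueError(
            f"motif {pwm.tf} column {plant.column} is too uninformative for a "
            f"planted SNP with margin {margin}"
        )
    if plant.effect == "loss":
        return strong, weak, +1
    if plant.effect == "gain":
        return weak, strong, -1
    raise ValueError(f"unknown SNP effect {plant.effect!r}")


def generate_sequences_snps_motifs(
    config: SyntheticConfig, bundle: AnnotationBundle
) -> SequenceBundle:
    rng = config.rng(4)
    background = MarkovBackground.uniform()
    pwms = [
        build_pwm(np.asarray(counts), background=background, tf=tf)
        for tf, counts in config.pfm_counts.items()
    ]
    pwm_by_tf = {p.tf: p for p in pwms}
    dists = {p.tf: ScoreDistribution(p) for p in pwms}

    seqs = {
        pid: background.sample(1, len(peak), rng)[0]
        for pid, peak in zip(bundle.peak_ids, bundle.peaks)
    }
    plants_by_peak: dict[int, list] = {}
    for mp in config.motif_plants:
        plants_by_peak.setdefault(mp.peak_index, []).append(mp)

    # SNP plants constrain columns of their motif instance
    forced: dict[tuple[int, str], dict[int, int]] = {}
    snp_meta: list[dict] = []
    for plant in list(config.snp_plants) + list(config.decoy_snps):
        pwm = pwm_by_tf[plant.motif_tf]
        ref, alt, sign = _snp_alleles(pwm, plant, config.snp_margin)
        forced.setdefault((plant.peak_index, plant.motif_tf), {})[plant.column] = ref
        snp_meta.append({"plant": plant, "ref": ref, "alt": alt, "sign": sign})

    motif_truth = []
    for pidx, plants in plants_by_peak.items():
        for mp in plants:
            pwm = pwm_by_tf[mp.tf]
            force = dict(forced.get((pidx, mp.tf), {}))
            # a gain SNP's forced base may push the instance below threshold;
            # sample with the strong base, then substitute the weak one
            weak_subs = {}
            for m in snp_meta:
                p = m["plant"]
                if p.peak_index == pidx and p.motif_tf == mp.tf and p.effect == "gain":
                    force[p.column] = int(np.argmax(pwm.matrix[p.column]))
                    weak_subs[p.column] = m["ref"]
            inst = _sample_instance(pwm, dists[mp.tf], rng, force)
            score_clean = pwm.score(inst)
            for col, base in weak_subs.items():
                inst[col] = base
            if mp.strand == "-":
                inst = COMPLEMENT[inst][::-1]
            seq = seqs[bundle.peak_ids[pidx]]
            if mp.offset + pwm.length > len(seq):
                raise ValueError(f"motif {mp.tf} does not fit peak {pidx} at offset {mp.offset}")
            seq[mp.offset : mp.offset + pwm.length] = inst
            motif_truth.append(
                {
                    "tf": mp.tf,
                    "peak": bundle.peak_ids[pidx],
                    "offset": mp.offset,
                    "strand": mp.strand,
                    "score": float(score_clean),
                    "threshold": float(dists[mp.tf].threshold(5e-5)),
                }
            )

    peak_sequences = {pid: decode(s) for pid, s in seqs.items()}

    snp_rows = []
    for m in snp_meta:
        plant: SNPPlant = m["plant"]
        mp = next(
            x for x in config.motif_plants if x.peak_index == plant.peak_index and x.tf == plant.motif_tf
        )
        pwm = pwm_by_tf[plant.motif_tf]
        if mp.strand == "+":
            off = mp.offset + plant.column
            ref_b, alt_b = BASES[m["ref"]], BASES[m["alt"]]
        else:
            off = mp.offset + pwm.length - 1 - plant.column
            ref_b = BASES[int(COMPLEMENT[m["ref"]])]
            alt_b = BASES[int(COMPLEMENT[m["alt"]])]
        peak = bundle.peaks[plant.peak_index]
        snp_rows.append(
            {
                "id": plant.snp_id,
                "chrom": peak.chrom,
                "pos": peak.start + off,
                "ref": ref_b,
                "alt": alt_b,
                "maf": plant.maf,
                "peak": bundle.peak_ids[plant.peak_index],
                "tf": plant.motif_tf,
                "effect": plant.effect,
                "expected_change_sign": m["sign"],
                "maf_excluded": plant.maf < 0.01,
            }
        )
    # background decoy SNPs outside any motif, common alleles
    decoy_rng = config.rng(5)
    for k in range(5):
        pidx = int(decoy_rng.integers(0, config.n_peaks))
        if pidx in plants_by_peak:
            continue
        peak = bundle.peaks[pidx]
        off = int(decoy_rng.integers(0, len(peak)))
        ref_b = peak_sequences[bundle.peak_ids[pidx]][off]
        alt_b = BASES[(BASES.index(ref_b) + 1) % 4]
        snp_rows.append(
            {
                "id": f"rs_bg_{k}",
                "chrom": peak.chrom,
                "pos": peak.start + off,
                "ref": ref_b,
                "alt": alt_b,
                "maf": float(np.round(decoy_rng.uniform(0.05, 0.4), 3)),
                "peak": bundle.peak_ids[pidx],
                "tf": "",
                "effect": "none",
                "expected_change_sign": 0,
                "maf_excluded": False,
            }
        )
    snps = pd.DataFrame(snp_rows)

    # verify the planted sequences behave as promised
    from ..affinity import score_change

    for r in snps.itertuples():
        if r.effect in ("gain", "loss"):
            pwm = pwm_by_tf[r.tf]
            peak = bundle.peaks[bundle.peak_ids.index(r.peak)]
            off = int(r.pos) - peak.start
            seq = peak_sequences[r.peak]
            if off - (pwm.length - 1) < 0 or off + pwm.length - 1 >= len(seq):
                continue
            ctx = seq[off - (pwm.length - 1) : off + pwm.length]
            _, _, d = score_change(ctx, r.ref, r.alt, pwm)
            if np.sign(d) != r.expected_change_sign or abs(d) < config.snp_margin:
                raise RuntimeError(
                    f"planted SNP {r.id} does not change affinity as intended "
                    f"(change {d:+.2f} bits)"
                )

    truth = {
        "motifs": motif_truth,
        "snps": snps.to_dict(orient="records"),
    }
    return SequenceBundle(
        peak_sequences=peak_sequences,
        pwms=pwms,
        dists=dists,
        snps=snps,
        tag_snps=bundle.tag_snps,
        truth=truth,
    )
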