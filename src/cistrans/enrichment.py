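"""Motif enrichment in CCAN peaks against GC-matched background peaks."""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .pwm import PWM, ScoreDistribution, scan
from .stats import bh_fdr
from scipy import stats


def gc_fraction(seq: str) -> float:
    s = seq.upper()
    return (s.count("G") + s.count("C")) / max(len(s), 1)


def _gc_matched_background(
    target_seqs: dict[str, str],
    background_seqs: dict[str, str],
    rng: np.random.Generator,
    bin_width: float = 0.05,
) -> dict[str, str]:
    """Resample background peaks to match the target GC histogram (5% bins)."""
    tg = np.array([gc_fraction(s) for s in target_seqs.values()])
    bg_names = list(background_seqs)
    bg = np.array([gc_fraction(background_seqs[n]) for n in bg_names])
    bins = np.arange(0, 1 + bin_width, bin_width)
    t_hist, _ = np.histogram(tg, bins=bins)
    want = t_hist / t_hist.sum()
    chosen: list[str] = []
    n_target_total = len(bg_names)
    for k in range(len(bins) - 1):
        pool = [bg_names[i] for i in np.nonzero((bg >= bins[k]) & (bg < bins[k + 1]))[0]]
        need = int(round(want[k] * n_target_total))
        if need == 0 or not pool:
            continue
        idx = rng.choice(len(pool), size=min(need, len(pool)), replace=False)
        chosen.extend(pool[i] for i in idx)
    if not chosen:
        return dict(background_seqs)
    return {n: background_seqs[n] for n in chosen}


def motif_enrichment(
    target_seqs: dict[str, str],
    background_seqs: dict[str, str],
    pwms: list[PWM],
    tf_expression_pct: dict[str, float] | None = None,
    alpha: float = 5e-5,
    min_fold: float = 1.2,
    max_fdr: float = 0.05,
    min_expression_pct: float = 0.10,
    seed: int = 0,
    dists: dict[str, ScoreDistribution] | None = None,
) -> pd.DataFrame:
    """Binomial-test enrichment of motif hits in target vs background peaks.

    Background peaks are resampled to the target GC distribution first.  Per
    motif, k = number of target peaks with >= 1 hit at the exact p <= alpha
    threshold; the background hit fraction is the binomial null; fold = target
    fraction / background fraction.  The retained set additionally requires
    the TF expressed in >= ``min_expression_pct`` of the cluster's cells when
    an expression table is supplied.  Returns all motifs with a ``retained``
    flag so the filtering is auditable.
    """
    rng = np.random.default_rng(seed)
    bg = _gc_matched_background(target_seqs, background_seqs, rng)
    n_t, n_b = len(target_seqs), len(bg)
    rows = []
    for pwm in pwms:
        dist = dists.get(pwm.tf) if dists else None
        if dist is None:
            dist = ScoreDistribution(pwm)
        thr = dist.threshold(alpha)
        k = len({h.seq_name for h in scan(target_seqs, pwm, threshold=thr, dist=dist)})
        kb = len({h.seq_name for h in scan(bg, pwm, threshold=thr, dist=dist)})
        p_bg = kb / n_b if n_b else 0.0
        if p_bg == 0.0 and k > 0:
            warnings.warn(f"no background hits for {pwm.tf}; flooring background rate")
            p_bg = 0.5 / max(n_b, 1)
        if p_bg == 0.0:
            p, fold = 1.0, 0.0
        else:
            p = float(stats.binom.sf(k - 1, n_t, p_bg))
            fold = (k / n_t) / p_bg if n_t else 0.0
        rows.append({"tf": pwm.tf, "n_target_hits": k, "bg_rate": p_bg, "fold": fold, "p": p})
    df = pd.DataFrame(rows, columns=["tf", "n_target_hits", "bg_rate", "fold", "p"])
    df["fdr"] = bh_fdr(df["p"])
    expressed = (
        df["tf"].map(lambda t: tf_expression_pct.get(t, 0.0) >= min_expression_pct)
        if tf_expression_pct is not None
        else True
    )
    df["retained"] = (df["fold"] >= min_fold) & (df["fdr"] <= max_fdr) & expressed
    return df
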