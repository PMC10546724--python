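"""Donor-level cohort statistics and cell-type proportion testing.

Demographic variables (age, post-mortem interval) are compared between the
case (LOAD) and control (Normal) groups within sex, using the printed
mean/SD/n when raw values are unavailable (pooled-variance t) or a
normality-gated choice between the pooled t and Mann-Whitney U when they are.
Cell-type and subtype proportions are compared by a bootstrapped Wilcoxon
rank-sum test over repeated subsamples of nuclei.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd
from scipy import stats

from .stats import bh_fdr


@dataclass(frozen=True)
class GroupSummary:
    """Printed summary statistics for one donor group."""

    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("sd must be nonnegative")
        if self.n < 2:
            raise ValueError("need n >= 2 per group")


def summary_t_test(g1: GroupSummary, g2: GroupSummary) -> tuple[float, int, float]:
    """Pooled-variance two-sample t-test from summary statistics.

    sp^2 = ((n1-1) sd1^2 + (n2-1) sd2^2) / (n1+n2-2);
    t = (m1-m2) / (sp * sqrt(1/n1 + 1/n2)); df = n1+n2-2; two-sided p.
    """
    df = g1.n + g2.n - 2
    sp2 = ((g1.n - 1) * g1.sd**2 + (g2.n - 1) * g2.sd**2) / df
    diff = g1.mean - g2.mean
    if sp2 == 0:
        if diff == 0:
            raise ValueError("both groups degenerate and identical")
        warnings.warn("zero pooled variance with unequal means; p set to 0")
        return float(np.sign(diff) * np.inf), df, 0.0
    t = diff / np.sqrt(sp2 * (1 / g1.n + 1 / g2.n))
    p = 2 * stats.t.sf(abs(t), df)
    return float(t), df, float(p)


@dataclass(frozen=True)
class DemographicTest:
    branch: Literal["t", "mannwhitney"]
    statistic: float
    p: float
    shapiro_p: tuple[float, float] | None
    variance_p: float | None


def demographic_compare(values1, values2, alpha: float = 0.05) -> DemographicTest:
    """Normality-gated two-group comparison of a demographic variable.

    Both groups Shapiro-Wilk normal (p > alpha) -> Bartlett variance check and
    a pooled-variance t-test; otherwise a two-sided Mann-Whitney U.  Groups of
    fewer than 3 values cannot be normality-tested and fall back to the U test.
    """
    v1 = np.asarray(values1, dtype=float)
    v2 = np.asarray(values2, dtype=float)
    if min(v1.size, v2.size) < 3:
        warnings.warn("group too small for normality testing; using Mann-Whitney U")
        u, p = stats.mannwhitneyu(v1, v2, alternative="two-sided")
        return DemographicTest("mannwhitney", float(u), float(p), None, None)
    # identical constant samples make Shapiro undefined; treat as non-normal
    try:
        sw1 = stats.shapiro(v1).pvalue
        sw2 = stats.shapiro(v2).pvalue
    except ValueError:
        sw1 = sw2 = 0.0
    if sw1 > alpha and sw2 > alpha:
        bart_p = float(stats.bartlett(v1, v2).pvalue)
        g1 = GroupSummary(float(v1.mean()), float(v1.std(ddof=1)), v1.size)
        g2 = GroupSummary(float(v2.mean()), float(v2.std(ddof=1)), v2.size)
        t, _, p = summary_t_test(g1, g2)
        return DemographicTest("t", t, p, (float(sw1), float(sw2)), bart_p)
    u, p = stats.mannwhitneyu(v1, v2, alternative="two-sided")
    return DemographicTest("mannwhitney", float(u), float(p), (float(sw1), float(sw2)), None)


def donor_proportions(nucleus_table: pd.DataFrame, unit_col: str = "unit") -> pd.DataFrame:
    """Per-donor unit proportions: nuclei of each unit / total nuclei of donor."""
    counts = (
        nucleus_table.groupby(["donor", unit_col], observed=True)
        .size()
        .unstack(fill_value=0)
    )
    props = counts.div(counts.sum(axis=1), axis=0)
    diag = nucleus_table.groupby("donor")["diagnosis"].first()
    props.insert(0, "diagnosis", diag.loc[props.index].values)
    return props


def bootstrap_wilcoxon_proportions(
    nucleus_table: pd.DataFrame,
    unit_col: str = "unit",
    frac: float = 0.2,
    iters: int = 30,
    seed: int = 0,
    combine: Literal["mean", "median", "fisher"] = "mean",
) -> pd.DataFrame:
    """Bootstrapped Wilcoxon rank-sum comparison of per-donor unit proportions.

    Each iteration draws ``frac`` of all nuclei without replacement, recomputes
    per-donor per-unit proportions, and runs a two-sided Wilcoxon rank-sum
    (Mann-Whitney U) between diagnosis groups for each unit.  The per-unit
    p-values from the ``iters`` iterations are combined (mean by default) and
    BH-adjusted across units, with significance tiers at FDR < 0.05/0.01/0.001.
    """
    required = {"donor", "diagnosis", unit_col}
    if not required <= set(nucleus_table.columns):
        raise ValueError(f"nucleus table needs columns {sorted(required)}")
    # canonical row order so the bootstrap is invariant to input row order
    table = nucleus_table.sort_values(
        ["donor", unit_col], kind="mergesort"
    ).reset_index(drop=True)
    donors = table.groupby("donor")["diagnosis"].first()
    groups = donors.groupby(donors).size()
    if len(groups) != 2 or (groups < 2).any():
        raise ValueError("need >=2 donors in each of two diagnosis groups")
    g1, g2 = sorted(donors.unique())
    units = sorted(table[unit_col].unique())
    rng = np.random.default_rng(seed)
    n = len(table)
    pmat = np.full((iters, len(units)), np.nan)
    for it in range(iters):
        idx = rng.choice(n, size=max(1, int(round(frac * n))), replace=False)
        sub = table.iloc[np.sort(idx)]
        props = donor_proportions(sub, unit_col)
        missing = donors.index.difference(props.index)
        if len(missing):
            # a donor with zero sampled nuclei contributes 0 for every unit
            pad = pd.DataFrame(0.0, index=missing, columns=props.columns)
            pad["diagnosis"] = donors.loc[missing]
            props = pd.concat([props, pad])
        for k, u in enumerate(units):
            x = props.loc[props["diagnosis"] == g1, u] if u in props else pd.Series(dtype=float)
            y = props.loc[props["diagnosis"] == g2, u] if u in props else pd.Series(dtype=float)
            if u not in props.columns:
                continue
            if np.all(np.concatenate([x, y]) == np.concatenate([x, y])[0]):
                pmat[it, k] = 1.0
                continue
            pmat[it, k] = stats.mannwhitneyu(x, y, alternative="two-sided").pvalue
    if combine == "mean":
        combined = np.nanmean(pmat, axis=0)
    elif combine == "median":
        combined = np.nanmedian(pmat, axis=0)
    elif combine == "fisher":
        combined = np.array(
            [stats.chi2.sf(-2 * np.nansum(np.log(np.clip(col, 1e-300, 1))), 2 * np.sum(~np.isnan(col)))
             for col in pmat.T]
        )
    else:
        raise ValueError(f"unknown combine rule {combine!r}")
    fdr = bh_fdr(combined)
    tiers = np.select([fdr < 0.001, fdr < 0.01, fdr < 0.05], ["***", "**", "*"], "")
    return pd.DataFrame(
        {
            "unit": units,
            "p_combined": combined,
            "fdr": fdr,
            "tier": tiers,
            "p_iterations": [pmat[:, k].tolist() for k in range(len(units))],
        }
    ).set_index("unit")
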