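"""Iterative principal-component covariate selection on donor pseudobulk.

Counts are summed to one value per donor per feature, features with zeros in
more than 20 % of donors are dropped, and the matrix is centered and scaled.
Each round runs a PCA, regresses every PC explaining more than 10 % of the
variance on every metadata variable one at a time, selects the most-associated
Bonferroni-significant variable (anchored on the top retained PC), and
residualizes all features on it; iteration stops when nothing is significant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse, stats


def donor_pseudobulk(
    counts,
    nucleus_metadata: pd.DataFrame,
    feature_ids=None,
    max_zero_fraction: float = 0.2,
) -> pd.DataFrame:
    """Sum counts per donor, filter high-zero features, center and scale.

    ``counts`` is features x nuclei (sparse or dense); ``nucleus_metadata``
    indexed like the count columns with a "donor" column.  Returns a donors x
    features frame with columns mean 0 / sd 1 (ddof=1).
    """
    if sparse.issparse(counts):
        counts = counts.toarray()
    counts = np.asarray(counts, dtype=float)
    donors = nucleus_metadata["donor"].to_numpy()
    if counts.shape[1] != len(donors):
        raise ValueError("count columns must match nucleus metadata rows")
    uniq = sorted(pd.unique(donors))
    mat = np.stack([counts[:, donors == d].sum(axis=1) for d in uniq])  # donors x features
    if feature_ids is None:
        feature_ids = [f"f{i}" for i in range(counts.shape[0])]
    df = pd.DataFrame(mat, index=uniq, columns=feature_ids)
    zero_frac = (df == 0).mean(axis=0)
    df = df.loc[:, zero_frac <= max_zero_fraction]
    sd = df.std(axis=0, ddof=1)
    keep = sd > 0
    if (~keep).any():
        warnings.warn(f"dropping {int((~keep).sum())} constant features")
    df = df.loc[:, keep]
    return (df - df.mean(axis=0)) / df.std(axis=0, ddof=1)


def _assoc_p(pc: np.ndarray, variable: pd.Series) -> float:
    """p-value of a simple regression of one PC on one metadata variable
    (numeric: slope t-test; categorical: one-way ANOVA F-test)."""
    if pd.api.types.is_numeric_dtype(variable):
        x = variable.to_numpy(dtype=float)
        if np.std(x) == 0:
            return 1.0
        res = stats.linregress(x, pc)
        return float(res.pvalue)
    groups = [pc[(variable == lvl).to_numpy()] for lvl in variable.unique()]
    groups = [g for g in groups if len(g) > 0]
    if len(groups) < 2:
        return 1.0
    return float(stats.f_oneway(*groups).pvalue)


def _residualize(matrix: pd.DataFrame, variable: pd.Series) -> pd.DataFrame:
    x = (
        pd.get_dummies(variable, drop_first=True, dtype=float)
        if not pd.api.types.is_numeric_dtype(variable)
        else variable.to_frame()
    )
    X = np.column_stack([np.ones(len(matrix)), x.to_numpy(dtype=float)])
    coef, *_ = np.linalg.lstsq(X, matrix.to_numpy(), rcond=None)
    return pd.DataFrame(matrix.to_numpy() - X @ coef, index=matrix.index, columns=matrix.columns)


@dataclass
class SelectionRound:
    round: int
    pc_variances: list[float]
    tested: pd.DataFrame  # columns: pc, variable, p, q
    selected: str | None


def iterative_pc_selection(
    matrix: pd.DataFrame,
    metadata: pd.DataFrame,
    var_threshold: float = 0.10,
    alpha: float = 0.05,
    rescale: bool = True,
) -> tuple[list[str], list[SelectionRound]]:
    """Ordered covariate list plus a per-round audit log.

    Per round: PCA on the (residual) matrix; PCs with variance fraction >
    ``var_threshold`` are each regressed on every remaining metadata variable;
    Bonferroni family size = #PCs tested x #variables.  The selected variable
    is the most-associated significant one for the top retained PC, falling
    back to the highest-variance PC that has any significant variable.  All
    features are then residualized on the selection.  The hard iteration cap
    is the number of metadata variables.
    """
    if metadata.shape[1] < 2:
        raise ValueError("need >= 2 metadata variables")
    if len(matrix) < 3:
        raise ValueError("need >= 3 donors")
    variables = [
        c for c in metadata.columns if metadata[c].nunique() > 1 or _warn_constant(c)
    ]
    remaining = list(variables)
    current = matrix.copy()
    selected: list[str] = []
    log: list[SelectionRound] = []
    for rnd in range(len(variables)):
        if not remaining:
            break
        if rescale:
            sd = current.std(axis=0, ddof=1)
            cur = (current - current.mean(axis=0)).loc[:, sd > 0] / sd[sd > 0]
        else:
            cur = current - current.mean(axis=0)
        X = cur.to_numpy()
        u, s, _ = np.linalg.svd(X, full_matrices=False)
        var_frac = s**2 / (s**2).sum()
        top = np.nonzero(var_frac > var_threshold)[0]
        if top.size == 0:
            top = np.array([0])
        pcs = u[:, top] * s[top]
        m = top.size * len(remaining)
        rows = []
        for k, pc_i in enumerate(top):
            for var in remaining:
                p = _assoc_p(pcs[:, k], metadata[var].loc[matrix.index])
                rows.append({"pc": int(pc_i) + 1, "variable": var, "p": p, "q": min(p * m, 1.0)})
        tested = pd.DataFrame(rows)
        sig = tested[tested["q"] < alpha]
        choice = None
        if not sig.empty:
            # anchor on the top retained PC; else highest-variance PC with a hit
            for pc_i in sorted(sig["pc"].unique()):
                cand = sig[sig["pc"] == pc_i]
                choice = cand.sort_values(["p", "variable"], kind="mergesort").iloc[0]["variable"]
                break
        log.append(
            SelectionRound(rnd + 1, [float(v) for v in var_frac[top]], tested, choice)
        )
        if choice is None:
            break
        selected.append(choice)
        remaining.remove(choice)
        current = _residualize(current, metadata[choice].loc[matrix.index])
    return selected, log


def _warn_constant(name: str) -> bool:
    warnings.warn(f"metadata variable {name!r} is constant; excluded")
    return False
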