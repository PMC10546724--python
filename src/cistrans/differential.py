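"""Differential expression and accessibility between disease and control.

Expression uses a two-part hurdle: a donor-random-intercept logistic model on
detection (count > 0) and a donor-random-intercept linear model on
log2(count + 1) among detected nuclei, both with diagnosis, selected
covariates, the centered/scaled cellular detection rate (CDR), and the
donor's cluster proportion; significance is a 2-df likelihood-ratio test
dropping diagnosis from both parts at once.  Accessibility uses a logistic
regression of diagnosis on nucleus covariates with and without the peak's
fragment count (1-df LRT).  Reported log2 fold changes are empirical
differences of mean log2(x + 1), positive when higher in the disease group.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .glmm import fit_joint_hurdle, fit_linear_mixed, fit_logistic_mixed
from .stats import bh_fdr


@dataclass
class HurdleFit:
    discrete_params: np.ndarray
    continuous_params: np.ndarray
    sigma_discrete: float
    sigma_continuous: float
    loglik: float
    flags: list


@dataclass
class DifferentialResult:
    feature: str
    cluster: str
    log2fc: float
    p: float
    fdr: float
    pct_group1: float
    pct_group2: float
    test: str
    log2fc_model: float = float("nan")
    flags: tuple = ()


def _design(diagnosis: np.ndarray, covariates: pd.DataFrame | None, include_group: bool) -> np.ndarray:
    cols = [np.ones(len(diagnosis))]
    if include_group:
        cols.append(diagnosis.astype(float))
    if covariates is not None and covariates.shape[1] > 0:
        arr = covariates.to_numpy(dtype=float)
        sd = arr.std(axis=0)
        keep = sd > 0
        arr = arr[:, keep]
        cols.append((arr - arr.mean(axis=0)) / arr.std(axis=0))
    return np.column_stack(cols)


def _linear_mixed_loglik(X: np.ndarray, y: np.ndarray, groups: np.ndarray) -> tuple[float, np.ndarray, float, bool]:
    """ML loglik of a random-intercept linear model; returns
    (loglik, params, intercept SD, fell_back_to_ols)."""
    if len(np.unique(groups)) < 2:
        ols = sm.OLS(y, X).fit()
        return float(ols.llf), np.asarray(ols.params), 0.0, True
    try:
        fit = fit_linear_mixed(X, y, groups)
        if not np.isfinite(fit.loglik):
            raise ValueError("non-finite loglik")
        return fit.loglik, fit.params, fit.tau, False
    except Exception:
        ols = sm.OLS(y, X).fit()
        return float(ols.llf), np.asarray(ols.params), 0.0, True


def de_hurdle(
    counts: np.ndarray,
    diagnosis: np.ndarray,
    donor_ids: np.ndarray,
    covariates: pd.DataFrame | None = None,
    feature: str = "gene",
    cluster: str = "cluster",
    min_pct: float = 0.10,
    mixed: bool = True,
    gh_nodes: int = 9,
) -> tuple[DifferentialResult | None, HurdleFit | None]:
    """Two-part hurdle test for one gene.

    ``diagnosis`` is 1 for the disease group, 0 for control.  Returns
    (None, None) when the gene is expressed in fewer than ``min_pct`` of
    nuclei in both groups, or when a group is empty after filtering.
    ``mixed=False`` drops the donor random intercepts (used to quantify the
    pseudoreplication penalty).
    """
    counts = np.asarray(counts, dtype=float)
    diagnosis = np.asarray(diagnosis).astype(int)
    detected = counts > 0
    pct1 = detected[diagnosis == 1].mean() if (diagnosis == 1).any() else 0.0
    pct0 = detected[diagnosis == 0].mean() if (diagnosis == 0).any() else 0.0
    if max(pct1, pct0) < min_pct:
        return None, None
    y_cont = np.log2(counts + 1.0)
    flags: list = []
    X_full = _design(diagnosis, covariates, include_group=True)
    X_red = _design(diagnosis, covariates, include_group=False)
    det_idx = np.nonzero(detected)[0]
    if not detected[diagnosis == 1].any() or not detected[diagnosis == 0].any():
        return None, None
    if mixed:
        # one shared donor random intercept across both parts: the 2-df LRT
        # is then a genuine likelihood ratio (summing two separately fitted
        # parts would double-count the common donor-level contrast)
        fit_full = fit_joint_hurdle(X_full, y_cont, detected, donor_ids, n_nodes=gh_nodes)
        fit_red = fit_joint_hurdle(X_red, y_cont, detected, donor_ids, n_nodes=gh_nodes)
        if not (fit_full.converged and fit_red.converged):
            flags.append("joint_nonconverged")
        ll_full = fit_full.loglik
        ll_red = fit_red.loglik
        params_d, params_c = fit_full.beta_discrete, fit_full.beta_continuous
        sigma_d, sigma_c = fit_full.loading_discrete, abs(fit_full.loading_continuous)
    else:
        ll_full_d, params_d = _logit_loglik(X_full, detected.astype(float), flags)
        ll_red_d, _ = _logit_loglik(X_red, detected.astype(float), flags)
        sigma_d = 0.0
        Xc_full, Xc_red = X_full[det_idx], X_red[det_idx]
        yc = y_cont[det_idx]
        f = sm.OLS(yc, Xc_full).fit()
        r = sm.OLS(yc, Xc_red).fit()
        params_c, sigma_c = np.asarray(f.params), 0.0
        ll_full = ll_full_d + float(f.llf)
        ll_red = ll_red_d + float(r.llf)
    lrt = 2.0 * (ll_full - ll_red)
    lrt = max(lrt, 0.0)
    p = float(sps.chi2.sf(lrt, 2))
    log2fc = float(y_cont[diagnosis == 1].mean() - y_cont[diagnosis == 0].mean())
    model_fc = float(params_c[1]) if len(params_c) > 1 else float("nan")
    result = DifferentialResult(
        feature, cluster, log2fc, p, float("nan"), pct1, pct0,
        "hurdle" if mixed else "hurdle_fixed", model_fc, tuple(flags),
    )
    fit = HurdleFit(params_d, params_c, sigma_d, sigma_c, ll_full, flags)
    return result, fit


def _logit_loglik(X: np.ndarray, y: np.ndarray, flags: list) -> tuple[float, np.ndarray]:
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
        if np.abs(fit.params).max() > 20 or not np.isfinite(fit.llf):
            raise ValueError("separation")
        return float(fit.llf), np.asarray(fit.params)
    except Exception:
        flags.append("ridge_logit")
        model = sm.Logit(y, X)
        params = model.fit_regularized(alpha=1e-3, L1_wt=0.0, disp=0).params
        return float(model.loglike(params)), np.asarray(params)


def de_cluster(
    counts: np.ndarray,
    gene_ids,
    diagnosis: np.ndarray,
    donor_ids: np.ndarray,
    covariates: pd.DataFrame | None = None,
    cluster: str = "cluster",
    min_pct: float = 0.10,
    mixed: bool = True,
) -> pd.DataFrame:
    """Hurdle DE for every gene of one cluster, BH-adjusted within cluster.

    ``counts`` is genes x nuclei; the CDR covariate (centered/scaled count of
    detected genes per nucleus) is added automatically.
    """
    cdr = (np.asarray(counts) > 0).sum(axis=0).astype(float)
    cov = covariates.copy() if covariates is not None else pd.DataFrame(index=range(counts.shape[1]))
    cov = cov.reset_index(drop=True)
    cov["cdr"] = cdr
    rows = []
    for i, gene in enumerate(gene_ids):
        res, _ = de_hurdle(
            counts[i], diagnosis, donor_ids, cov, feature=str(gene),
            cluster=cluster, min_pct=min_pct, mixed=mixed,
        )
        if res is not None:
            rows.append(res)
    if not rows:
        return pd.DataFrame(
            columns=["feature", "cluster", "log2fc", "p", "fdr", "pct_group1", "pct_group2", "test"]
        )
    df = pd.DataFrame(
        {
            "feature": [r.feature for r in rows],
            "cluster": [r.cluster for r in rows],
            "log2fc": [r.log2fc for r in rows],
            "p": [r.p for r in rows],
            "pct_group1": [r.pct_group1 for r in rows],
            "pct_group2": [r.pct_group2 for r in rows],
            "test": [r.test for r in rows],
            "log2fc_model": [r.log2fc_model for r in rows],
            "flags": [";".join(r.flags) for r in rows],
        }
    )
    df["fdr"] = bh_fdr(df["p"])
    return df


def da_binomial_lr(
    peak_counts: np.ndarray,
    diagnosis: np.ndarray,
    covariates: pd.DataFrame,
    feature: str = "peak",
    cluster: str = "cluster",
    min_pct: float = 0.025,
    log1p_counts: bool = False,
) -> DifferentialResult | None:
    """Binomial-regression LRT for one peak.

    Diagnosis is regressed on the nucleus covariates with and without the
    peak's per-nucleus fragment count (raw by default); 1-df chi-square LRT.
    Peaks detected in fewer than ``min_pct`` of nuclei are skipped.
    """
    peak_counts = np.asarray(peak_counts, dtype=float)
    diagnosis = np.asarray(diagnosis).astype(float)
    if (peak_counts > 0).mean() < min_pct:
        return None
    x = np.log1p(peak_counts) if log1p_counts else peak_counts
    X_red = _design(np.zeros_like(diagnosis), covariates, include_group=False)
    if np.std(x) == 0:
        p = 1.0
        flags: tuple = ("constant_peak",)
        lfc = 0.0
    else:
        X_full = np.column_stack([X_red, (x - x.mean()) / x.std()])
        fl: list = []
        ll_full, _ = _logit_loglik(X_full, diagnosis, fl)
        ll_red, _ = _logit_loglik(X_red, diagnosis, fl)
        lrt = max(2.0 * (ll_full - ll_red), 0.0)
        if not np.isfinite(lrt):
            return None
        p = float(sps.chi2.sf(lrt, 1))
        flags = tuple(fl)
        y = np.log2(peak_counts + 1.0)
        lfc = float(y[diagnosis == 1].mean() - y[diagnosis == 0].mean())
    return DifferentialResult(
        feature, cluster, lfc, p, float("nan"),
        float((peak_counts[diagnosis == 1] > 0).mean()),
        float((peak_counts[diagnosis == 0] > 0).mean()),
        "binomLR", float("nan"), flags,
    )


def da_cluster(
    counts: np.ndarray,
    peak_ids,
    diagnosis: np.ndarray,
    covariates: pd.DataFrame,
    cluster: str = "cluster",
    min_pct: float = 0.025,
) -> pd.DataFrame:
    """Binomial-LRT DA for every peak of one cluster, BH within cluster."""
    rows = []
    for i, pid in enumerate(peak_ids):
        res = da_binomial_lr(
            counts[i], diagnosis, covariates, feature=str(pid), cluster=cluster, min_pct=min_pct
        )
        if res is not None:
            rows.append(res)
    if not rows:
        return pd.DataFrame(
            columns=["feature", "cluster", "log2fc", "p", "fdr", "pct_group1", "pct_group2", "test"]
        )
    df = pd.DataFrame(
        {
            "feature": [r.feature for r in rows],
            "cluster": [r.cluster for r in rows],
            "log2fc": [r.log2fc for r in rows],
            "p": [r.p for r in rows],
            "pct_group1": [r.pct_group1 for r in rows],
            "pct_group2": [r.pct_group2 for r in rows],
            "test": [r.test for r in rows],
            "flags": [";".join(r.flags) for r in rows],
        }
    )
    df["fdr"] = bh_fdr(df["p"])
    return df
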