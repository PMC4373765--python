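"""Group statistics: node-wise t profiles, paired tests, ANOVA, Pearson
correlation and backward-elimination OLS.

Node-wise comparisons use the classic pooled-variance two-sample t (Welch
available by flag) with uncorrected two-sided p values — per-node
significance flags mirror the common per-node highlighting practice; a
Benjamini-Hochberg option exists but is off by default. Covariate
adjustment (age, sex, disease duration) is handled by entering covariates
into the regression rather than a separate GLM framework.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "NodeTestResult",
    "nodewise_two_sample_t",
    "two_sample_t",
    "paired_t",
    "one_way_anova",
    "pearson",
    "ols_backward",
]


@dataclass
class NodeTestResult:
    """Per-node t statistic, two-sided p and significance flag."""

    t: np.ndarray
    p: np.ndarray
    significant: np.ndarray
    valid: np.ndarray


def two_sample_t(a, b, welch: bool = False) -> dict:
    """Two-sample t test (pooled variance by default) with two-sided p."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 observations per group")
    t, p = stats.ttest_ind(a, b, equal_var=not welch)
    if not np.isfinite(t):
        return {"t": np.nan, "p": np.nan, "degenerate": True}
    return {"t": float(t), "p": float(p), "degenerate": False}


def nodewise_two_sample_t(profiles_a: np.ndarray, profiles_b: np.ndarray,
                          valid: np.ndarray | None = None,
                          alpha: float = 0.05, welch: bool = False,
                          fdr: bool = False) -> NodeTestResult:
    """t test at every node between two stacks of subject profiles.

    ``profiles_a``/``profiles_b`` are (n_subjects, n_nodes). Nodes where the
    pooled variance vanishes get NaN statistics and are never flagged.
    """
    a = np.atleast_2d(np.asarray(profiles_a, dtype=float))
    b = np.atleast_2d(np.asarray(profiles_b, dtype=float))
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise ValueError("need at least 2 subjects per group")
    if a.shape[1] != b.shape[1]:
        raise ValueError("profile stacks have different node counts")
    n_nodes = a.shape[1]
    if valid is None:
        valid = np.ones(n_nodes, dtype=bool)
    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = stats.ttest_ind(a, b, axis=0, equal_var=not welch)
    t = np.where(valid, t, np.nan)
    p = np.where(valid, p, np.nan)
    finite = np.isfinite(p)
    sig = np.zeros(n_nodes, dtype=bool)
    if fdr and finite.any():
        sig[finite] = multipletests(p[finite], alpha=alpha, method="fdr_bh")[0]
    else:
        sig[finite] = p[finite] < alpha
    return NodeTestResult(t, p, sig, np.asarray(valid, dtype=bool))


def paired_t(a, b) -> dict:
    """Paired t on the differences a - b; degenerate when all-zero variance."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or len(a) < 2:
        raise ValueError("paired samples must have equal length >= 2")
    d = a - b
    if np.ptp(d) == 0 and d.std() == 0:
        return {"t": np.nan, "p": np.nan, "df": len(d) - 1, "degenerate": True}
    t, p = stats.ttest_rel(a, b)
    return {"t": float(t), "p": float(p), "df": len(d) - 1, "degenerate": False}


def one_way_anova(*groups) -> dict:
    """Classic one-way ANOVA F over >= 2 groups of subject means."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("need >= 2 groups with >= 2 subjects each")
    if all(np.ptp(g) == 0 for g in groups) and \
            np.ptp(np.concatenate(groups)) == 0:
        return {"F": 0.0, "p": 1.0, "degenerate": True}
    f, p = stats.f_oneway(*groups)
    return {"F": float(f), "p": float(p), "degenerate": False}


def pearson(x, y) -> dict:
    """Pearson r with the t-transform p value (n - 2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need series of equal length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for constant series")
    r, p = stats.pearsonr(x, y)
    return {"r": float(r), "p": float(p), "n": int(len(x))}


def ols_backward(outcome, predictors: pd.DataFrame,
                 p_out: float = 0.05) -> dict:
    """OLS with backward elimination; reports standardized coefficients.

    Predictors (and the outcome, for standardized betas) are z-scored
    before fitting. At each step the predictor with the largest p > p_out
    is dropped and the model refit; elimination stops when every remaining
    p <= p_out. An empty final model is a legitimate outcome.
    """
    y = np.asarray(outcome, dtype=float)
    X = predictors.astype(float).copy()
    if len(y) != len(X):
        raise ValueError("outcome and predictor table lengths differ")
    if len(y) <= X.shape[1] + 1:
        raise ValueError("need n > number of predictors + 1")
    sds = X.std(ddof=1)
    if (sds == 0).any():
        raise ValueError(f"constant predictor(s): {list(sds[sds == 0].index)}")
    Xz = (X - X.mean()) / sds
    rank = np.linalg.matrix_rank(Xz.values)
    if rank < Xz.shape[1]:
        corr = Xz.corr().abs()
        np.fill_diagonal(corr.values, 0.0)
        pairs = sorted({tuple(sorted((i, j)))
                        for i in corr.index for j in corr.columns
                        if corr.loc[i, j] > 1 - 1e-10})
        raise ValueError(f"collinear predictors: {pairs or list(Xz.columns)}")
    ysd = y.std(ddof=1)
    if ysd == 0:
        raise ValueError("constant outcome")
    yz = (y - y.mean()) / ysd

    retained = list(Xz.columns)
    dropped: list[str] = []
    while retained:
        model = sm.OLS(yz, sm.add_constant(Xz[retained])).fit()
        pvals = model.pvalues.drop("const").fillna(1.0)
        if model.rsquared > 1 - 1e-12:
            # numerically perfect fit: p-values computed against a ~0
            # residual variance are meaningless for negligible coefficients
            coefs = model.params.drop("const")
            pvals[coefs.abs() < 1e-8] = 1.0
        worst = pvals.idxmax()
        if pvals[worst] <= p_out:
            coefs = model.params.drop("const")
            return {"retained": retained,
                    "coefficients": coefs.to_dict(),
                    "pvalues": pvals.to_dict(),
                    "r2": float(model.rsquared),
                    "model_p": float(model.f_pvalue),
                    "dropped": dropped}
        retained = [c for c in retained if c != worst]
        dropped.append(worst)
    return {"retained": [], "coefficients": {}, "pvalues": {},
            "r2": 0.0, "model_p": np.nan, "dropped": dropped}
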