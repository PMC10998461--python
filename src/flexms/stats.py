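"""Cohort-level statistics relating brain flexibility to clinical disability.

Group comparisons (rank-sum, Kruskal–Wallis) with Benjamini–Hochberg FDR,
Spearman correlations by phenotype, the cross-validated interaction
regression predicting a clinical score from repertoire size and MS
phenotype, and the label-permutation test on prediction residuals.

The interaction model is

    score ~ repertoire + phenotype + repertoire x phenotype

with the phenotype coded 0 for relapsing-remitting (RRMS) and 1 for
secondary-progressive (SPMS) patients and the continuous predictor z-scored
before fitting, so the reported coefficients are standardized betas.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests
from statsmodels.stats.outliers_influence import variance_inflation_factor

__all__ = [
    "TestResult",
    "RegressionResult",
    "PermutationResult",
    "wilcoxon_ranksum",
    "kruskal_wallis",
    "fdr_adjust",
    "spearman",
    "fit_interaction_model",
    "kfold_cv_predict",
    "residual_permutation_test",
    "covariate_model",
    "subgroup_correlations",
]

MS_GROUPS = ("RRMS", "SPMS")


class TestResult(NamedTuple):
    statistic: float
    p_value: float


@dataclass
class RegressionResult:
    """Fitted interaction (or covariate) model with CV diagnostics."""

    beta: dict[str, float]
    beta_p: dict[str, float]
    f_stat: float
    f_p: float
    df: tuple[int, int]
    r_squared: float
    vif: dict[str, float]
    residuals_standardized: np.ndarray
    subject_ids: list[str]
    groups: list[str]
    response: str = "edss"
    cv_predictions: np.ndarray | None = None
    cv_actual: np.ndarray | None = None
    nrmse: float | None = None
    cv_r_squared: float | None = None


@dataclass
class PermutationResult:
    observed_stat: float
    n_iterations: int
    p_value: float
    seed: int


def wilcoxon_ranksum(a: Sequence[float], b: Sequence[float]) -> TestResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Uses the exact null distribution when the combined sample size is at
    most 20 and there are no ties, and the tie-corrected normal
    approximation otherwise.  The statistic is the Mann-Whitney U of the
    first sample.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (not has_ties and pooled.size <= 20) else "asymptotic"
    res = scipy.stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return TestResult(float(res.statistic), float(res.pvalue))


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> TestResult:
    """Kruskal-Wallis H test (tie-corrected, chi-square p with k-1 df)."""
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(g.size == 0 for g in arrays):
        raise ValueError("every group must be non-empty")
    res = scipy.stats.kruskal(*arrays)
    return TestResult(float(res.statistic), float(res.pvalue))


def fdr_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order-preserving)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _spearman_exact_p(rho: float, n: int) -> float:
    """Exact two-sided p for Spearman rho with untied ranks, by enumeration."""
    perms = np.array(list(itertools.permutations(range(n))), dtype=float)
    base = np.arange(n, dtype=float)
    d2 = ((perms - base) ** 2).sum(axis=1)
    rho_null = 1.0 - 6.0 * d2 / (n * (n * n - 1.0))
    return float(np.mean(np.abs(rho_null) >= abs(rho) - 1e-12))


def spearman(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Spearman rank correlation with average ranks for ties.

    The p-value is exact (full permutation enumeration) for n <= 9 without
    ties, and the usual t-approximation otherwise.  Constant input raises,
    since the correlation is undefined.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("x and y must have equal length >= 3")
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        raise ValueError("rho undefined for constant input")
    res = scipy.stats.spearmanr(x, y)
    rho = float(res.statistic)
    no_ties = np.unique(x).size == x.size and np.unique(y).size == y.size
    if no_ties and x.size <= 9:
        return TestResult(rho, _spearman_exact_p(rho, x.size))
    return TestResult(rho, float(res.pvalue))


def _ms_subset(cohort: pd.DataFrame, response: str) -> pd.DataFrame:
    sub = cohort[cohort["group"].isin(MS_GROUPS)].copy()
    if sub[response].isna().any():
        raise ValueError(f"missing {response!r} values in MS subjects")
    return sub


def _design(rep: np.ndarray, pheno: np.ndarray, mean: float, sd: float) -> np.ndarray:
    """Interaction design matrix: const, z(rep), phenotype, z(rep)*phenotype."""
    z = (rep - mean) / sd
    return np.column_stack([np.ones_like(z), z, pheno, z * pheno])


def fit_interaction_model(cohort: pd.DataFrame, response: str = "edss") -> RegressionResult:
    """OLS of a clinical score on repertoire, phenotype, and their interaction.

    Patients only (RRMS coded 0, SPMS coded 1); repertoire size is z-scored
    before fitting.  Reports standardized betas with per-term p-values, the
    overall F with (3, n-4) degrees of freedom, R-squared, per-term VIFs
    (intercept excluded from the reported terms), and internally studentized
    residuals.
    """
    sub = _ms_subset(cohort, response)
    n = len(sub)
    if n < 8:
        raise ValueError(f"need at least 8 patients for a stable fit, got {n}")
    counts = sub["group"].value_counts()
    if any(counts.get(g, 0) < 3 for g in MS_GROUPS):
        raise ValueError("need at least 3 subjects in each phenotype")
    rep = sub["repertoire_size"].to_numpy(dtype=float)
    if rep.std(ddof=0) == 0:
        raise ValueError("repertoire size is constant: singular design")
    pheno = (sub["group"] == "SPMS").to_numpy(dtype=float)
    X = _design(rep, pheno, rep.mean(), rep.std(ddof=0))
    y = sub[response].to_numpy(dtype=float)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("singular design matrix")
    fit = sm.OLS(y, X).fit()
    terms = ["intercept", "repertoire", "phenotype", "interaction"]
    vif = {
        term: float(variance_inflation_factor(X, i))
        for i, term in enumerate(terms)
        if term != "intercept"
    }
    influence = fit.get_influence()
    return RegressionResult(
        beta=dict(zip(terms, map(float, fit.params))),
        beta_p=dict(zip(terms, map(float, fit.pvalues))),
        f_stat=float(fit.fvalue),
        f_p=float(fit.f_pvalue),
        df=(int(fit.df_model), int(fit.df_resid)),
        r_squared=float(fit.rsquared),
        vif=vif,
        residuals_standardized=np.asarray(influence.resid_studentized_internal),
        subject_ids=sub["subject_id"].tolist(),
        groups=sub["group"].tolist(),
        response=response,
    )


def kfold_cv_predict(
    cohort: pd.DataFrame,
    response: str = "edss",
    k: int = 5,
    seed: int = 0,
    stratify: bool = False,
    nrmse_norm: str = "range",
) -> RegressionResult:
    """K-fold cross-validated prediction with the interaction model.

    Subjects are shuffled by a seeded RNG into ``k`` near-equal folds
    (optionally stratified by phenotype); each fold is predicted by a model
    fit on the remaining folds, with the repertoire standardization
    parameters estimated on the training folds only.  NRMSE is the RMSE of
    the pooled out-of-fold predictions divided by the observed response
    range (or mean, with ``nrmse_norm="mean"``).
    """
    result = fit_interaction_model(cohort, response)
    sub = _ms_subset(cohort, response)
    n = len(sub)
    if not 2 <= k <= n:
        raise ValueError(f"k must be in [2, {n}], got {k}")
    if nrmse_norm not in ("range", "mean"):
        raise ValueError(f"unknown nrmse_norm {nrmse_norm!r}")
    rep = sub["repertoire_size"].to_numpy(dtype=float)
    pheno = (sub["group"] == "SPMS").to_numpy(dtype=float)
    y = sub[response].to_numpy(dtype=float)

    rng = np.random.default_rng(seed)
    if stratify:
        folds: list[list[int]] = [[] for _ in range(k)]
        for value in (0.0, 1.0):
            idx = np.flatnonzero(pheno == value)
            rng.shuffle(idx)
            for pos, i in enumerate(idx):
                folds[pos % k].append(int(i))
        fold_arrays = [np.array(f, dtype=int) for f in folds]
    else:
        order = rng.permutation(n)
        fold_arrays = [np.asarray(f, dtype=int) for f in np.array_split(order, k)]

    preds = np.full(n, np.nan)
    for test_idx in fold_arrays:
        if test_idx.size == 0:
            continue
        train = np.setdiff1d(np.arange(n), test_idx)
        mean, sd = rep[train].mean(), rep[train].std(ddof=0)
        if sd == 0:
            raise ValueError("constant repertoire in a training fold")
        X_train = _design(rep[train], pheno[train], mean, sd)
        beta = np.linalg.lstsq(X_train, y[train], rcond=None)[0]
        preds[test_idx] = _design(rep[test_idx], pheno[test_idx], mean, sd) @ beta

    rmse = float(np.sqrt(np.mean((preds - y) ** 2)))
    denom = float(np.ptp(y)) if nrmse_norm == "range" else float(np.mean(y))
    if denom == 0:
        raise ValueError("degenerate response: zero NRMSE denominator")
    ss_res = float(np.sum((y - preds) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    result.cv_predictions = preds
    result.cv_actual = y
    result.nrmse = rmse / denom
    result.cv_r_squared = 1.0 - ss_res / ss_tot if ss_tot > 0 else math.nan
    return result


def residual_permutation_test(
    residuals: Sequence[float],
    groups: Sequence,
    n_iterations: int = 10_000,
    seed: int = 0,
) -> PermutationResult:
    """Label-permutation test on group means of absolute residuals.

    The observed statistic is the difference in group means of the absolute
    standardized residuals (second label minus first, labels in sorted
    order); the null is built by permuting the group labels, and the
    two-sided p-value uses the add-one estimator
    ``(1 + #{|null| >= |observed|}) / (n_iterations + 1)``.
    """
    abs_resid = np.abs(np.asarray(residuals, dtype=float))
    labels = np.asarray(groups)
    uniq = np.unique(labels)
    if uniq.size != 2:
        raise ValueError(f"need exactly two groups, got {uniq.tolist()}")
    mask = labels == uniq[1]
    if mask.sum() < 2 or (~mask).sum() < 2:
        raise ValueError("need at least 2 subjects per group")

    observed = float(abs_resid[mask].mean() - abs_resid[~mask].mean())
    rng = np.random.default_rng(seed)
    n = abs_resid.size
    n1 = int(mask.sum())
    total = abs_resid.sum()
    # permuted label assignments, all iterations at once
    order = rng.random((n_iterations, n)).argsort(axis=1)
    perm_mask = mask[order]
    sum1 = np.where(perm_mask, abs_resid[None, :], 0.0).sum(axis=1)
    null = sum1 / n1 - (total - sum1) / (n - n1)
    n_extreme = int((np.abs(null) >= abs(observed) - 1e-15).sum())
    p = (1 + n_extreme) / (n_iterations + 1)
    return PermutationResult(
        observed_stat=observed, n_iterations=n_iterations, p_value=p, seed=seed
    )


def covariate_model(
    cohort: pd.DataFrame,
    response: str = "repertoire_size",
    covariates: Sequence[str] = ("age", "sex", "education"),
    variables: Sequence[str] = (),
) -> pd.DataFrame:
    """OLS of the response on a fixed covariate block plus one variable at a
    time, with BH-FDR across the family of variable models.

    Returns a table with one row per independent variable: its
    (unstandardized) beta, raw p, and FDR-adjusted p.  Non-numeric
    covariates (e.g. sex labels) are factor-coded.
    """
    if not variables:
        raise ValueError("need at least one independent variable")
    missing = [c for c in [response, *covariates, *variables] if c not in cohort.columns]
    if missing:
        raise ValueError(f"missing columns: {missing}")
    data = cohort.dropna(subset=[response, *covariates]).copy()
    block = []
    for cov in covariates:
        col = data[cov]
        if not pd.api.types.is_numeric_dtype(col):
            col = pd.factorize(col)[0].astype(float)
        col = np.asarray(col, dtype=float)
        if np.unique(col).size == 1:
            raise ValueError(f"covariate {cov!r} is constant")
        block.append(col)
    base = np.column_stack([np.ones(len(data)), *block]) if block else np.ones((len(data), 1))
    y = data[response].to_numpy(dtype=float)
    rows = []
    for var in variables:
        sel = ~data[var].isna().to_numpy()
        x = data[var].to_numpy(dtype=float)[sel]
        if np.unique(x).size == 1:
            raise ValueError(f"variable {var!r} is constant")
        X = np.column_stack([base[sel], x])
        fit = sm.OLS(y[sel], X).fit()
        rows.append({"variable": var, "beta": float(fit.params[-1]), "p": float(fit.pvalues[-1]), "n": int(sel.sum())})
    table = pd.DataFrame(rows)
    table["p_fdr"] = fdr_adjust(table["p"].to_numpy())
    table["significant"] = table["p_fdr"] < 0.05
    return table


def subgroup_correlations(
    cohort: pd.DataFrame, split: str = "phenotype", score: str = "edss"
) -> pd.DataFrame:
    """Spearman repertoire-vs-score correlation within cohort subgroups.

    ``split`` is ``"phenotype"`` (RRMS vs SPMS), ``"edss_cutoff:<value>"``
    (at/below vs above the cutoff), or ``"edss_median"``.  Subgroups with
    fewer than 3 subjects are reported with ``insufficient n``.
    """
    sub = cohort[cohort["group"].isin(MS_GROUPS)].dropna(subset=[score, "edss"])
    if split == "phenotype":
        parts = [(g, sub[sub["group"] == g]) for g in MS_GROUPS]
    elif split.startswith("edss_cutoff:"):
        cut = float(split.split(":", 1)[1])
        parts = [
            (f"edss<={cut:g}", sub[sub["edss"] <= cut]),
            (f"edss>{cut:g}", sub[sub["edss"] > cut]),
        ]
    elif split == "edss_median":
        med = float(sub["edss"].median())
        parts = [
            (f"edss<={med:g}", sub[sub["edss"] <= med]),
            (f"edss>{med:g}", sub[sub["edss"] > med]),
        ]
    else:
        raise ValueError(f"invalid split spec {split!r}")
    rows = []
    for name, part in parts:
        row: dict = {"subgroup": name, "n": len(part), "rho": math.nan, "p": math.nan, "note": ""}
        if len(part) < 3:
            row["note"] = "insufficient n"
        else:
            try:
                res = spearman(part["repertoire_size"], part[score])
                row["rho"], row["p"] = res.statistic, res.p_value
            except ValueError as exc:
                row["note"] = str(exc)
        rows.append(row)
    return pd.DataFrame(rows)
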