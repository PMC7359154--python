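"""Per-metabolite covariate-adjusted group comparison.

Each z-scored metabolite is regressed on a disease-group indicator with
age and sex as covariates (ordinary least squares, i.e. a Gaussian
identity-link GLM); the group coefficient's two-sided Wald p-value is
the test of differential abundance.  P-values are corrected across
metabolites by Benjamini-Hochberg (default) or Storey's q-values, with
a Bonferroni flag reported alongside.  Fold changes are computed on the
unscaled (imputed) matrix as mean(disease) / mean(control).

Because the design matrix is shared by all metabolites, the scan is a
single vectorised least-squares solve; ``fit_metabolite_glm`` is the
one-column entry point over the same code path.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data import (
    CONTROL_GROUP,
    DISEASE_GROUPS,
    FTLD_COMBINED,
    AnalysisConfig,
    CohortMetadata,
    MetaboliteMatrix,
    PathwayMap,
    ValidationError,
)
from .preprocess import PreprocessResult


@dataclass
class UnivariateResult:
    """Table-shaped differential abundance result.

    ``table`` has one row per metabolite with columns: metabolite,
    subpathway, superpathway, fold_change, effect (group coefficient on
    the z scale), p_raw, p_fdr, bonferroni_flag.
    """

    table: pd.DataFrame
    case_groups: tuple[str, ...]
    alpha: float

    @property
    def significant(self) -> pd.DataFrame:
        return self.table[self.table["p_fdr"] < self.alpha]


def _design_matrix(group: np.ndarray, age: np.ndarray, sex: np.ndarray) -> np.ndarray:
    X = np.column_stack([np.ones_like(age), group, age, sex]).astype(float)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValidationError("collinear design matrix (constant covariate?)")
    return X


def glm_group_scan(
    Y: np.ndarray, group: np.ndarray, age: np.ndarray, sex: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """OLS of each column of Y on (1, group, age, sex); Wald test on group.

    Returns (group coefficients, two-sided p-values), one per column.
    """
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if Y.ndim == 2 and Y.shape[0] != len(group):
        Y = Y.T if Y.shape[1] == len(group) else Y
    n = len(group)
    X = _design_matrix(np.asarray(group), np.asarray(age), np.asarray(sex))
    p = X.shape[1]
    if n <= p:
        raise ValidationError("not enough observations for the covariate model")
    XtX_inv = np.linalg.inv(X.T @ X)
    beta = XtX_inv @ (X.T @ Y)
    resid = Y - X @ beta
    dof = n - p
    sigma2 = np.einsum("ij,ij->j", resid, resid) / dof
    se = np.sqrt(np.maximum(sigma2, 0.0) * XtX_inv[1, 1])
    coef = beta[1]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, coef / se, np.inf * np.sign(coef))
    pvals = 2.0 * stats.t.sf(np.abs(t), dof)
    return coef, pvals


def fit_metabolite_glm(
    y: np.ndarray, group_indicator: np.ndarray, age: np.ndarray, sex_indicator: np.ndarray
) -> tuple[float, float]:
    """Group effect and p-value for a single metabolite."""
    y = np.asarray(y, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValidationError("metabolite has fewer than 2 distinct values")
    coef, pvals = glm_group_scan(y[:, None], group_indicator, age, sex_indicator)
    return float(coef[0]), float(pvals[0])


def two_sample_t_scan(Y: np.ndarray, group: np.ndarray) -> np.ndarray:
    """Plain two-sample t-test p-values per column (unadjusted screen)."""
    g = np.asarray(group).astype(bool)
    res = stats.ttest_ind(Y[g], Y[~g], axis=0)
    return np.asarray(res.pvalue)


def adjust_fdr(p_values: np.ndarray, method: str = "bh") -> np.ndarray:
    """FDR-adjusted p-values: Benjamini-Hochberg or Storey q-values."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    # step-up: running minimum from the largest p
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty_like(adj)
    out[order] = adj
    if method == "bh":
        return out
    if method == "storey":
        # Storey's pFDR with a fixed tuning parameter lambda = 0.5
        lam = 0.5
        pi0 = min(1.0, np.mean(p > lam) / (1.0 - lam))
        if pi0 <= 0:
            pi0 = 1.0 / m
        return np.minimum(out * pi0, 1.0)
    raise ValidationError(f"unknown FDR method {method!r}")


def bonferroni_flags(p_values: np.ndarray, alpha: float) -> np.ndarray:
    """Flag p-values below alpha / m (strict inequality)."""
    p = np.asarray(p_values, dtype=float)
    if p.size < 1:
        raise ValidationError("empty p-value vector")
    return p < alpha / p.size


def fold_changes(
    unscaled: MetaboliteMatrix,
    meta: CohortMetadata,
    case_groups: tuple[str, ...] = DISEASE_GROUPS,
    imputed_mask: pd.DataFrame | None = None,
) -> pd.Series:
    """Mean abundance in the case groups over the control mean, per metabolite.

    Means are taken over the imputed matrix by default; pass
    ``imputed_mask`` to restrict them to observed cells instead.
    """
    if unscaled.scaled:
        raise ValidationError("fold changes are computed on the unscaled matrix")
    vals = unscaled.values
    if imputed_mask is not None:
        vals = vals.mask(imputed_mask.loc[vals.index, vals.columns])
    case_ids = [
        pid
        for g in case_groups
        for pid in meta.ids_in_group(g)
    ]
    ctrl_ids = meta.ids_in_group(CONTROL_GROUP)
    case_mean = vals.loc[case_ids].mean(axis=0)
    ctrl_mean = vals.loc[ctrl_ids].mean(axis=0)
    if (ctrl_mean == 0).any():
        bad = list(ctrl_mean.index[ctrl_mean == 0])
        raise ValidationError(f"zero control mean, fold change undefined: {bad}")
    fc = case_mean / ctrl_mean
    fc.name = "fold_change"
    return fc


def run_univariate(
    pre: PreprocessResult,
    meta: CohortMetadata,
    config: AnalysisConfig | None = None,
    case_groups: tuple[str, ...] = DISEASE_GROUPS,
) -> UnivariateResult:
    """Full differential-abundance scan for case groups vs controls."""
    if config is None:
        config = AnalysisConfig()
    case_ids = [pid for g in case_groups for pid in meta.ids_in_group(g)]
    ctrl_ids = meta.ids_in_group(CONTROL_GROUP)
    ids = case_ids + ctrl_ids
    sub = meta.table.loc[ids]
    group = sub["group"].isin(case_groups).to_numpy(dtype=float)
    age = sub["age"].to_numpy(dtype=float)
    sex = (sub["sex"] == "M").to_numpy(dtype=float)
    Z = pre.scaled.values.loc[ids].to_numpy(dtype=float)
    coef, p_raw = glm_group_scan(Z, group, age, sex)
    p_fdr = adjust_fdr(p_raw, method=config.fdr_method)
    bonf = bonferroni_flags(p_raw, config.fdr_threshold)
    mask = None if config.fold_change_on_imputed else pre.imputed_mask
    fc = fold_changes(pre.unscaled, meta, case_groups=case_groups, imputed_mask=mask)
    ann = pre.pathway_map.table
    mets = pre.scaled.metabolite_ids
    table = pd.DataFrame(
        {
            "metabolite": mets,
            "subpathway": ann.loc[mets, "subpathway"].to_numpy(),
            "superpathway": ann.loc[mets, "superpathway"].to_numpy(),
            "fold_change": fc.loc[mets].to_numpy(),
            "effect": coef,
            "p_raw": p_raw,
            "p_fdr": p_fdr,
            "bonferroni_flag": bonf.astype(int),
        }
    ).sort_values("p_raw", kind="stable", ignore_index=True)
    return UnivariateResult(
        table=table, case_groups=tuple(case_groups), alpha=config.fdr_threshold
    )
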