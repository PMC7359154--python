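"""Two-level, pathway-structured principal component analysis.

Level one runs a "local" PCA on the z-scored metabolites of each
subpathway (correlation-matrix PCA, since columns are unit variance)
and retains components by the Kaiser criterion (eigenvalue > 1).  A
subpathway containing a single metabolite has eigenvalue exactly 1; by
default that metabolite passes through as its own component rather than
being dropped.  Retained local component scores are compared between
patients and controls by two-sample t-tests with joint FDR correction.

Level two standardises all retained local component scores and runs a
"global" PCA over them, yielding cohort-wide components that mix
subpathways.  Retention is again Kaiser by default, or a fixed top-k.

Both levels use the same deterministic sign convention: each loading
vector is flipped so its largest-magnitude entry is positive, making
repeated runs bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data import (
    CONTROL_GROUP,
    AnalysisConfig,
    CohortMetadata,
    MetaboliteMatrix,
    PathwayMap,
    ValidationError,
)
from .univariate import adjust_fdr


@dataclass
class LocalPCAModel:
    """PCA of one subpathway's z-scored metabolite block."""

    subpathway: str
    metabolite_ids: list[str]
    eigenvalues: np.ndarray  # all eigenvalues, non-increasing
    loadings: np.ndarray  # metabolites x retained components, orthonormal
    scores: pd.DataFrame  # participants x retained components
    n_retained: int
    passthrough: bool = False  # single-metabolite block kept by policy

    @property
    def component_names(self) -> list[str]:
        return list(self.scores.columns)


@dataclass
class GlobalPCAModel:
    """PCA over all retained (standardised) local component scores."""

    feature_names: list[str]  # "subpathway|PCk" labels
    eigenvalues: np.ndarray
    loadings: np.ndarray  # features x retained components
    scores: pd.DataFrame  # participants x retained components ("G1"...)
    n_retained: int

    @property
    def component_names(self) -> list[str]:
        return list(self.scores.columns)


def deterministic_sign_fix(loadings: np.ndarray) -> np.ndarray:
    """Flip each column so its largest-magnitude entry is positive.

    Ties in magnitude (within 1e-9 relative) are broken toward the
    lowest index, so the convention is stable across eigensolvers whose
    entries differ only by rounding (e.g. the equal-magnitude
    eigenvectors of a 2 x 2 correlation matrix).
    """
    out = loadings.copy()
    for k in range(out.shape[1]):
        col = np.abs(out[:, k])
        m = col.max()
        j = int(np.flatnonzero(col >= m * (1.0 - 1e-9))[0])
        if out[j, k] < 0:
            out[:, k] = -out[:, k]
    return out


_sign_fix = deterministic_sign_fix


def correlation_pca(Z: np.ndarray, ddof: int = 1) -> tuple[np.ndarray, np.ndarray]:
    """Eigendecomposition of the correlation matrix of z-scored columns.

    Returns (eigenvalues, eigenvectors) in non-increasing eigenvalue
    order with the deterministic sign convention; exact ties keep the
    original feature order (stable sort).
    """
    n = Z.shape[0]
    corr = (Z.T @ Z) / (n - ddof)
    eigval, eigvec = np.linalg.eigh(corr)
    order = np.argsort(-eigval, kind="stable")
    eigval = np.maximum(eigval[order], 0.0)
    eigvec = _sign_fix(eigvec[:, order])
    return eigval, eigvec


def local_pca(
    z_block: pd.DataFrame,
    subpathway: str,
    kaiser_threshold: float = 1.0,
    policy: str = "passthrough",
) -> LocalPCAModel:
    """Correlation-matrix PCA of one subpathway block with Kaiser retention."""
    if z_block.shape[1] < 1:
        raise ValidationError(f"empty block for subpathway {subpathway}")
    Z = z_block.to_numpy(dtype=float)
    if np.isnan(Z).any():
        raise ValidationError(f"missing values in subpathway {subpathway}")
    sds = Z.std(axis=0, ddof=1)
    if (sds == 0).any():
        bad = list(z_block.columns[sds == 0])
        raise ValidationError(f"zero-variance columns in {subpathway}: {bad}")

    if z_block.shape[1] == 1:
        # single-metabolite subpathway: eigenvalue exactly 1, strict Kaiser fails
        if policy == "drop":
            keep = 0
        elif policy == "passthrough":
            keep = 1
        else:
            raise ValidationError(f"unknown single-metabolite policy {policy!r}")
        eigval = np.array([1.0])
        loadings = np.ones((1, keep))
        scores = z_block.to_numpy() @ loadings
        return LocalPCAModel(
            subpathway=subpathway,
            metabolite_ids=list(z_block.columns),
            eigenvalues=eigval,
            loadings=loadings,
            scores=pd.DataFrame(
                scores, index=z_block.index,
                columns=[f"{subpathway}|PC1"][:keep],
            ),
            n_retained=keep,
            passthrough=keep == 1,
        )

    eigval, eigvec = correlation_pca(Z)
    keep = int(np.sum(eigval > kaiser_threshold))
    loadings = eigvec[:, :keep]
    scores = Z @ loadings
    cols = [f"{subpathway}|PC{k + 1}" for k in range(keep)]
    return LocalPCAModel(
        subpathway=subpathway,
        metabolite_ids=list(z_block.columns),
        eigenvalues=eigval,
        loadings=loadings,
        scores=pd.DataFrame(scores, index=z_block.index, columns=cols),
        n_retained=keep,
    )


def fit_local_pcas(
    scaled: MetaboliteMatrix,
    pmap: PathwayMap,
    config: AnalysisConfig | None = None,
) -> dict[str, LocalPCAModel]:
    """One local PCA per subpathway, in annotation order."""
    if config is None:
        config = AnalysisConfig()
    if not scaled.scaled:
        raise ValidationError("local PCA expects the z-scored matrix")
    models: dict[str, LocalPCAModel] = {}
    present = set(scaled.metabolite_ids)
    for sub in pmap.subpathways:
        mets = [m for m in pmap.metabolites_in(sub) if m in present]
        if not mets:
            continue
        models[sub] = local_pca(
            scaled.values[mets],
            sub,
            kaiser_threshold=config.kaiser_threshold,
            policy=config.single_metabolite_subpathway_policy,
        )
    return models


def subpathway_group_tests(
    models: dict[str, LocalPCAModel],
    meta: CohortMetadata,
    fdr_threshold: float = 0.01,
    fdr_method: str = "bh",
) -> tuple[pd.DataFrame, list[str]]:
    """Two-sample t-tests (FTLD combined vs control) on every retained
    local component score, FDR-corrected jointly.

    Returns the per-component table and the list of significant
    subpathways (a subpathway is significant if any of its components
    is).
    """
    pat = meta.patient_ids
    ctrl = meta.ids_in_group(CONTROL_GROUP)
    if len(pat) < 2 or len(ctrl) < 2:
        raise ValidationError("need at least two participants per group")
    rows = []
    for sub, model in models.items():
        for comp in model.component_names:
            s = model.scores[comp]
            t, p = stats.ttest_ind(s.loc[pat], s.loc[ctrl])
            rows.append({"subpathway": sub, "component": comp,
                         "t_statistic": float(t), "p_raw": float(p)})
    table = pd.DataFrame(rows)
    if len(table):
        table["p_fdr"] = adjust_fdr(table["p_raw"].to_numpy(), method=fdr_method)
        table["significant"] = (table["p_fdr"] < fdr_threshold).astype(int)
    significant = sorted(
        table.loc[table.get("significant", pd.Series(dtype=int)) == 1, "subpathway"]
        .unique()
        .tolist()
    ) if len(table) else []
    return table, significant


def global_pca(
    local_models: dict[str, LocalPCAModel],
    retention: str = "kaiser",
    fixed_k: int | None = None,
    kaiser_threshold: float = 1.0,
    standardize: bool = True,
) -> GlobalPCAModel:
    """PCA over all retained local component scores.

    Local scores are standardised to unit variance first (so large
    subpathways do not dominate by eigenvalue scale), then
    eigendecomposed as a correlation PCA.  Retention is Kaiser
    (eigenvalue > threshold) or a fixed top ``fixed_k``.
    """
    score_blocks = [m.scores for m in local_models.values() if m.n_retained > 0]
    if not score_blocks:
        raise ValidationError("no retained local components")
    features = pd.concat(score_blocks, axis=1)
    if features.shape[1] < 2:
        raise ValidationError("global PCA needs at least 2 input features")
    X = features.to_numpy(dtype=float)
    X = X - X.mean(axis=0)
    if standardize:
        sds = X.std(axis=0, ddof=1)
        if (sds == 0).any():
            raise ValidationError("constant local component score")
        X = X / sds
    eigval, eigvec = correlation_pca(X)
    if retention == "fixed_k":
        if fixed_k is None or fixed_k < 1:
            raise ValidationError("fixed_k retention requires a positive k")
        keep = min(fixed_k, len(eigval))
    elif retention == "kaiser":
        keep = max(1, int(np.sum(eigval > kaiser_threshold)))
    else:
        raise ValidationError(f"unknown retention {retention!r}")
    loadings = eigvec[:, :keep]
    scores = X @ loadings
    return GlobalPCAModel(
        feature_names=list(features.columns),
        eigenvalues=eigval,
        loadings=loadings,
        scores=pd.DataFrame(
            scores, index=features.index,
            columns=[f"G{k + 1}" for k in range(keep)],
        ),
        n_retained=keep,
    )


def component_loading_report(g: GlobalPCAModel, component: int | str) -> pd.DataFrame:
    """Input-feature loadings of one global component, sorted by signed
    loading, with the owning subpathway alongside."""
    if isinstance(component, str):
        if component not in g.component_names:
            raise ValidationError(f"no such component {component!r}")
        idx = g.component_names.index(component)
    else:
        idx = int(component)
        if not 0 <= idx < g.n_retained:
            raise ValidationError(f"component index {idx} out of range")
    load = g.loadings[:, idx]
    table = pd.DataFrame(
        {
            "feature": g.feature_names,
            "subpathway": [f.rsplit("|", 1)[0] for f in g.feature_names],
            "loading": load,
        }
    ).sort_values("loading", ascending=False, kind="stable", ignore_index=True)
    return table


def aggregate_loadings_by_subpathway(report: pd.DataFrame) -> pd.DataFrame:
    """Per-subpathway summary of a component loading report: the signed
    loading of largest magnitude and the total squared loading."""
    def _dominant(s: pd.Series) -> float:
        return float(s.iloc[np.argmax(np.abs(s.to_numpy()))])

    agg = report.groupby("subpathway")["loading"].agg(
        dominant_loading=_dominant, squared_loading=lambda s: float((s**2).sum())
    )
    return agg.sort_values("dominant_loading", ascending=False).reset_index()


def severity_candidate(
    g: GlobalPCAModel, reference: pd.Series | None = None
) -> tuple[str, float]:
    """The retained global component most correlated with a reference
    score (e.g. a known severity factor); returns (name, correlation)."""
    if reference is None:
        raise ValidationError("reference scores required")
    ref = reference.loc[g.scores.index].to_numpy(dtype=float)
    best, best_r = g.component_names[0], 0.0
    for name in g.component_names:
        r = float(np.corrcoef(g.scores[name].to_numpy(), ref)[0, 1])
        if abs(r) > abs(best_r):
            best, best_r = name, r
    return best, best_r
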