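"""Pairwise linear SVM classification on global PCA scores.

For each of eleven comparisons (the ten unordered pairs of the five
groups plus FTLD-combined vs control) the two classes are size-matched
by randomly subsampling the larger class, features are min-max rescaled
to [-1, 1], and a linear support vector machine (cost C = 1 by default)
is evaluated by stratified ten-fold cross-validation.  Backward
sequential feature selection greedily removes the component whose
removal best preserves CV accuracy, stopping when every candidate
removal would strictly decrease it.  Subsampling, training and
selection are repeated (10 times by default) and only components
selected in every repetition form a comparison's consensus set; the
component, if any, in the consensus of all five disease-vs-control
classifiers is the pipeline's consensus (severity) component.

The 5 x 5 accuracy matrix mirrors the conventional layout: off-diagonal
cells are pairwise accuracies, diagonal cells the accuracy of each
group against all remaining groups combined (size-matched one-vs-rest).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
import sklearn
from sklearn.svm import SVC

from .data import (
    ALL_GROUPS,
    CONTROL_GROUP,
    DISEASE_GROUPS,
    FTLD_COMBINED,
    AnalysisConfig,
    CohortMetadata,
    ValidationError,
)
from .pathway_pca import GlobalPCAModel

logger = logging.getLogger(__name__)

#: The eleven trained comparisons: all group pairs plus combined-FTLD vs control.
PAIRWISE_COMPARISONS: tuple[tuple[str, str], ...] = tuple(
    combinations(ALL_GROUPS, 2)
) + ((FTLD_COMBINED, CONTROL_GROUP),)

#: The five disease-vs-control comparisons whose consensus defines the
#: severity component.
DISEASE_VS_CONTROL: tuple[tuple[str, str], ...] = tuple(
    (g, CONTROL_GROUP) for g in DISEASE_GROUPS
) + ((FTLD_COMBINED, CONTROL_GROUP),)


@dataclass
class ClassificationResult:
    """Outcome of one repeated, size-matched pairwise classifier."""

    group_a: str
    group_b: str
    rep_accuracies: list[float]  # mean CV accuracy (%) per repetition
    rep_selected: list[frozenset[str]]  # selected component set per repetition
    consensus: frozenset[str] = field(init=False)
    mean_accuracy: float = field(init=False)

    def __post_init__(self) -> None:
        sets = self.rep_selected
        self.consensus = frozenset.intersection(*sets) if sets else frozenset()
        self.mean_accuracy = float(np.mean(self.rep_accuracies))

    @property
    def pair_label(self) -> str:
        return f"{self.group_a} vs {self.group_b}"


def rescale_features(scores: np.ndarray) -> np.ndarray:
    """Min-max rescale each column to [-1, 1]; constant columns become 0."""
    X = np.asarray(scores, dtype=float)
    if X.shape[0] < 2:
        raise ValidationError("need at least 2 participants to rescale")
    lo = X.min(axis=0)
    hi = X.max(axis=0)
    span = hi - lo
    constant = span == 0
    if constant.any():
        logger.warning("constant feature columns rescaled to zeros")
    span = np.where(constant, 1.0, span)
    out = 2.0 * (X - lo) / span - 1.0
    out[:, constant] = 0.0
    return out


def _group_ids(meta: CohortMetadata, group: str) -> list[str]:
    if group.startswith("rest:"):
        g = group.split(":", 1)[1]
        exclude = set(meta.ids_in_group(g))
        return [p for p in meta.participant_ids if p not in exclude]
    return meta.ids_in_group(group)


def size_match(
    meta: CohortMetadata,
    group_a: str,
    group_b: str,
    rng: np.random.Generator,
) -> tuple[list[str], list[str]]:
    """All of the smaller group plus an equal-size uniform subsample of
    the larger.  ``FTLD`` denotes all patients combined and ``rest:G``
    all participants outside group G."""
    ids_a = _group_ids(meta, group_a)
    ids_b = _group_ids(meta, group_b)
    if not ids_a or not ids_b:
        raise ValidationError(f"empty group in pair ({group_a}, {group_b})")
    n = min(len(ids_a), len(ids_b))

    def sample(ids: list[str]) -> list[str]:
        if len(ids) == n:
            return list(ids)
        pick = rng.choice(len(ids), size=n, replace=False)
        return [ids[i] for i in sorted(pick)]

    return sample(ids_a), sample(ids_b)


def _stratified_folds(
    y: np.ndarray, n_folds: int, rng: np.random.Generator
) -> list[np.ndarray]:
    """Shuffled stratified fold assignment; returns test-index arrays."""
    folds: list[list[int]] = [[] for _ in range(n_folds)]
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        if len(idx) < n_folds:
            raise ValidationError(
                f"class with {len(idx)} members cannot fill {n_folds} folds"
            )
        idx = idx[rng.permutation(len(idx))]
        for k, chunk in enumerate(np.array_split(idx, n_folds)):
            folds[k].extend(chunk.tolist())
    return [np.sort(np.asarray(f, dtype=int)) for f in folds]


def _cv_accuracy_folds(
    X: np.ndarray, y: np.ndarray, folds: list[np.ndarray], cost: float
) -> float:
    """Mean held-out accuracy over precomputed folds (fraction)."""
    n = len(y)
    all_idx = np.arange(n)
    accs = np.empty(len(folds))
    clf = SVC(kernel="linear", C=cost)
    # inputs are package-generated finite arrays; skip sklearn's finite checks
    with sklearn.config_context(assume_finite=True):
        for k, test in enumerate(folds):
            train = np.setdiff1d(all_idx, test, assume_unique=True)
            clf.fit(X[train], y[train])
            accs[k] = np.mean(clf.predict(X[test]) == y[test])
    return float(accs.mean())


def cv_accuracy(
    features: np.ndarray,
    labels: np.ndarray,
    n_folds: int = 10,
    svm_cost: float = 1.0,
    seed: int = 0,
) -> float:
    """Stratified k-fold CV accuracy (percent) of a linear SVM."""
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise ValidationError("both classes must be present")
    rng = np.random.default_rng(seed)
    folds = _stratified_folds(y, n_folds, rng)
    return 100.0 * _cv_accuracy_folds(X, y, folds, svm_cost)


def sequential_backward_selection(
    features: np.ndarray,
    labels: np.ndarray,
    feature_names: list[str] | None = None,
    n_folds: int = 10,
    svm_cost: float = 1.0,
    seed: int = 0,
) -> tuple[list[str], float]:
    """Greedy backward elimination against stratified CV accuracy.

    At each step the feature whose removal yields the highest CV
    accuracy is dropped; elimination continues while the best removal is
    at least as accurate as the current set (ties favour the smaller
    model) and stops when every removal would strictly decrease
    accuracy.  At least one feature is always retained.  The same fold
    partition is used for every evaluation, so selection is driven by
    feature content, not fold noise.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    if X.ndim != 2 or X.shape[1] < 1:
        raise ValidationError("need at least one feature")
    p = X.shape[1]
    if feature_names is None:
        feature_names = [f"f{j}" for j in range(p)]
    rng = np.random.default_rng(seed)
    folds = _stratified_folds(y, n_folds, rng)

    current = list(range(p))
    current_acc = _cv_accuracy_folds(X, y, folds, svm_cost)
    while len(current) > 1:
        best_j, best_acc = None, -np.inf
        for pos, j in enumerate(current):
            cand = current[:pos] + current[pos + 1:]
            acc = _cv_accuracy_folds(X[:, cand], y, folds, svm_cost)
            if acc > best_acc:
                best_j, best_acc = pos, acc
        if best_acc >= current_acc:  # ties favour removal
            del current[best_j]
            current_acc = best_acc
        else:
            break
    return [feature_names[j] for j in current], 100.0 * current_acc


def run_pair(
    scores: pd.DataFrame,
    meta: CohortMetadata,
    group_a: str,
    group_b: str,
    config: AnalysisConfig,
    seed: int,
) -> ClassificationResult:
    """Repeat {size-match, rescale, select, score} for one comparison."""
    rep_accs: list[float] = []
    rep_sets: list[frozenset[str]] = []
    names = list(scores.columns)
    for rep in range(config.n_repetitions):
        rng = np.random.default_rng(seed + rep)
        ids_a, ids_b = size_match(meta, group_a, group_b, rng)
        ids = ids_a + ids_b
        y = np.r_[np.zeros(len(ids_a)), np.ones(len(ids_b))]
        X = scores.loc[ids].to_numpy(dtype=float)
        if not config.rescale_within_folds:
            X = rescale_features(X)
        selected, acc = sequential_backward_selection(
            X, y, feature_names=names,
            n_folds=config.n_cv_folds, svm_cost=config.svm_cost,
            seed=seed + rep,
        )
        rep_accs.append(acc)
        rep_sets.append(frozenset(selected))
    return ClassificationResult(group_a, group_b, rep_accs, rep_sets)


def run_pairwise_suite(
    g: GlobalPCAModel,
    meta: CohortMetadata,
    config: AnalysisConfig | None = None,
) -> tuple[dict[tuple[str, str], ClassificationResult], pd.DataFrame]:
    """All eleven pairwise classifiers plus the one-vs-rest diagonal.

    Returns the per-comparison results (keyed by (group_a, group_b),
    including the ``rest:G`` diagonal tasks) and the 5 x 5 mean-accuracy
    matrix.
    """
    if config is None:
        config = AnalysisConfig()
    present = set(meta.groups)
    missing = set(ALL_GROUPS) - present
    if missing:
        raise ValidationError(f"groups absent from cohort: {sorted(missing)}")
    results: dict[tuple[str, str], ClassificationResult] = {}
    base = config.random_seed
    for i, (a, b) in enumerate(PAIRWISE_COMPARISONS):
        results[(a, b)] = run_pair(
            g.scores, meta, a, b, config, seed=base + 1000 * (i + 1)
        )
    for i, grp in enumerate(ALL_GROUPS):
        results[(grp, f"rest:{grp}")] = run_pair(
            g.scores, meta, grp, f"rest:{grp}", config,
            seed=base + 1000 * (len(PAIRWISE_COMPARISONS) + i + 1),
        )
    matrix = pd.DataFrame(
        np.nan, index=list(ALL_GROUPS), columns=list(ALL_GROUPS)
    )
    for (a, b), res in results.items():
        if b.startswith("rest:"):
            matrix.loc[a, a] = res.mean_accuracy
        elif a != FTLD_COMBINED:
            matrix.loc[a, b] = res.mean_accuracy
            matrix.loc[b, a] = res.mean_accuracy
    return results, matrix


def consensus_component(
    results: dict[tuple[str, str], ClassificationResult],
) -> list[str]:
    """Components in the consensus set of every disease-vs-control
    classifier; may be empty."""
    sets = []
    for pair in DISEASE_VS_CONTROL:
        if pair not in results:
            raise ValidationError(f"missing disease-vs-control result {pair}")
        sets.append(results[pair].consensus)
    return sorted(frozenset.intersection(*sets))
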