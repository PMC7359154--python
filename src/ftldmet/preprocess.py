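"""Filtering, imputation and scaling of the raw abundance matrix.

The fixed pipeline order is: missingness filter (a metabolite is
excluded when missing in strictly more than a configurable fraction of
participants, default one half), removal of exogenous metabolites
(drugs and drug pathways, by the per-metabolite flag), half-minimum
imputation of the remaining below-detection cells, and z-scoring of
every column.  Exogenous removal precedes imputation so half-minimum
values are never computed for dropped columns.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .data import AnalysisConfig, MetaboliteMatrix, PathwayMap, ValidationError

logger = logging.getLogger(__name__)


@dataclass
class PreprocessReport:
    """Bookkeeping of every exclusion and imputation decision."""

    n_input_metabolites: int
    n_excluded_missingness: int
    n_excluded_exogenous: int
    n_retained: int
    imputed_cell_count: int
    half_minimums: pd.Series
    excluded_missingness: list[str]
    excluded_exogenous: list[str]

    def validate(self) -> None:
        total = self.n_excluded_missingness + self.n_excluded_exogenous + self.n_retained
        if total != self.n_input_metabolites:
            raise ValidationError("preprocess report counts do not reconcile")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "quantity": [
                    "n_input_metabolites",
                    "n_excluded_missingness",
                    "n_excluded_exogenous",
                    "n_retained",
                    "imputed_cell_count",
                ],
                "value": [
                    self.n_input_metabolites,
                    self.n_excluded_missingness,
                    self.n_excluded_exogenous,
                    self.n_retained,
                    self.imputed_cell_count,
                ],
            }
        )


@dataclass
class PreprocessResult:
    """Analysis-ready matrices plus the accounting report.

    ``scaled`` is the z-scored matrix used by every multivariate stage;
    ``unscaled`` is the imputed matrix on the original intensity scale,
    kept for fold-change computation.
    """

    scaled: MetaboliteMatrix
    unscaled: MetaboliteMatrix
    report: PreprocessReport
    pathway_map: PathwayMap
    imputed_mask: pd.DataFrame | None = None  # True where a cell was imputed


def filter_missingness(
    m: MetaboliteMatrix, threshold_fraction: float = 0.5
) -> tuple[MetaboliteMatrix, list[str]]:
    """Drop metabolites missing in strictly more than the threshold fraction.

    A metabolite missing in exactly the threshold fraction of
    participants is retained (strict "more than" reading).
    """
    if not 0 < threshold_fraction <= 1:
        raise ValidationError("threshold_fraction must be in (0, 1]")
    if m.scaled:
        raise ValidationError("missingness filter expects an unscaled matrix")
    frac = m.values.isna().mean(axis=0)
    excluded = list(frac.index[frac > threshold_fraction])
    kept = [c for c in m.metabolite_ids if c not in set(excluded)]
    return m.subset_metabolites(kept), excluded


def remove_exogenous(
    m: MetaboliteMatrix, pmap: PathwayMap
) -> tuple[MetaboliteMatrix, list[str]]:
    """Drop drug-flagged metabolites.

    Exclusion is driven by the per-metabolite exogenous flag, not by the
    Xenobiotics superpathway wholesale: non-drug xenobiotics (dietary
    compounds such as benzoate) are retained and analysed.
    """
    unannotated = [c for c in m.metabolite_ids if c not in set(pmap.metabolite_ids)]
    if unannotated:
        raise ValidationError(f"metabolites missing pathway annotation: {unannotated}")
    exo = set(pmap.exogenous_ids())
    excluded = [c for c in m.metabolite_ids if c in exo]
    kept = [c for c in m.metabolite_ids if c not in exo]
    return m.subset_metabolites(kept), excluded


def half_minimum_values(m: MetaboliteMatrix) -> pd.Series:
    """Half of the minimum observed positive value, per metabolite."""
    vals = m.values.where(m.values > 0)
    mins = vals.min(axis=0)
    bad = list(mins.index[mins.isna()])
    if bad:
        raise ValidationError(
            f"metabolites with no observed positive value, cannot impute: {bad}"
        )
    return 0.5 * mins


def impute_half_minimum(m: MetaboliteMatrix) -> tuple[MetaboliteMatrix, pd.Series, int]:
    """Replace each missing cell with half the column's minimum positive value.

    Returns the imputed matrix, the per-metabolite half-minimums used,
    and the number of imputed cells.  Observed cells are never changed.
    """
    if m.scaled:
        raise ValidationError("imputation expects an unscaled matrix")
    halves = half_minimum_values(m)
    n_missing = int(m.values.isna().to_numpy().sum())
    filled = m.values.fillna(halves)
    return replace(m, values=filled), halves, n_missing


def scale_unit_variance(m: MetaboliteMatrix, ddof: int = 1) -> MetaboliteMatrix:
    """Z-score every column (mean 0, sd 1, sample sd by default).

    Constant columns map to all zeros with a warning.  The means and
    standard deviations are stored on the returned matrix so scaling is
    invertible via :func:`unscale`.
    """
    if m.values.isna().to_numpy().any():
        raise ValidationError("scaling requires a fully imputed matrix")
    means = m.values.mean(axis=0)
    sds = m.values.std(axis=0, ddof=ddof)
    constant = list(sds.index[sds == 0])
    if constant:
        logger.warning("constant columns scaled to zeros: %s", constant)
    safe = sds.replace(0.0, 1.0)
    z = (m.values - means) / safe
    return MetaboliteMatrix(values=z, scaled=True, column_means=means, column_sds=sds)


def unscale(m: MetaboliteMatrix) -> MetaboliteMatrix:
    """Invert :func:`scale_unit_variance` using the stored moments."""
    if not m.scaled or m.column_means is None or m.column_sds is None:
        raise ValidationError("matrix does not carry scaling moments")
    safe = m.column_sds.replace(0.0, 1.0)
    return MetaboliteMatrix(values=m.values * safe + m.column_means)


def preprocess(
    m: MetaboliteMatrix, pmap: PathwayMap, config: AnalysisConfig | None = None
) -> PreprocessResult:
    """Run the full preprocessing chain and reconcile the counts."""
    if config is None:
        config = AnalysisConfig()
    n_input = m.n_metabolites
    m1, excl_miss = filter_missingness(m, config.missingness_fraction_threshold)
    m2, excl_exo = remove_exogenous(m1, pmap)
    imputed_mask = m2.values.isna()
    imputed, halves, n_imputed = impute_half_minimum(m2)
    scaled = scale_unit_variance(imputed, ddof=config.sd_ddof)
    report = PreprocessReport(
        n_input_metabolites=n_input,
        n_excluded_missingness=len(excl_miss),
        n_excluded_exogenous=len(excl_exo),
        n_retained=m2.n_metabolites,
        imputed_cell_count=n_imputed,
        half_minimums=halves,
        excluded_missingness=excl_miss,
        excluded_exogenous=excl_exo,
    )
    report.validate()
    return PreprocessResult(
        scaled=scaled,
        unscaled=imputed,
        report=report,
        pathway_map=pmap.subset(m2.metabolite_ids),
        imputed_mask=imputed_mask,
    )
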