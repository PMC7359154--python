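"""Core domain types and table IO for the FTLD metabolomics pipeline.

The pipeline operates on three input tables:

* a participant x metabolite abundance matrix (non-negative ion
  intensities in arbitrary units, with missing cells marking values
  below the limit of detection),
* a pathway annotation mapping each metabolite to one subpathway and one
  superpathway, with a per-metabolite flag for exogenous compounds
  (drugs and drug metabolites), and
* clinical metadata per participant: diagnostic group, age, sex and --
  for patients -- survival time in days with an event indicator.

All on-disk formats are delimited text with a header row; missing cells
may be empty or ``NA``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields, replace
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: The four patient groups, in the conventional reporting order.
DISEASE_GROUPS: tuple[str, ...] = ("bvFTD", "nfvPPA", "PSP", "CBS")
CONTROL_GROUP = "Control"
ALL_GROUPS: tuple[str, ...] = DISEASE_GROUPS + (CONTROL_GROUP,)
#: Pseudo-group label meaning all four patient groups combined.
FTLD_COMBINED = "FTLD"

NA_VALUES = ("", "NA")


class ValidationError(ValueError):
    """Raised when an input table violates a structural contract."""


@dataclass
class MetaboliteMatrix:
    """Participant x metabolite abundance matrix.

    ``values`` is a DataFrame indexed by participant id with metabolite
    ids as columns; missing cells are NaN.  ``scaled`` records whether
    columns have been z-scored; a scaled matrix carries the column means
    and standard deviations used, so scaling is invertible.
    """

    values: pd.DataFrame
    scaled: bool = False
    column_means: pd.Series | None = None
    column_sds: pd.Series | None = None

    @property
    def participant_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def metabolite_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_participants(self) -> int:
        return self.values.shape[0]

    @property
    def n_metabolites(self) -> int:
        return self.values.shape[1]

    def validate(self) -> None:
        idx, cols = self.values.index, self.values.columns
        if idx.has_duplicates:
            dupes = sorted(idx[idx.duplicated()].unique())
            raise ValidationError(f"duplicate participant ids: {dupes}")
        if cols.has_duplicates:
            dupes = sorted(cols[cols.duplicated()].unique())
            raise ValidationError(f"duplicate metabolite ids: {dupes}")
        arr = self.values.to_numpy(dtype=float)
        present = ~np.isnan(arr)
        if not np.isfinite(arr[present]).all():
            raise ValidationError("non-finite abundance values present")
        if not self.scaled and (arr[present] < 0).any():
            raise ValidationError("negative abundances in unscaled matrix")
        if self.scaled:
            with np.errstate(invalid="ignore"):
                varying = np.nanstd(arr, axis=0) > 0
            mu = np.nanmean(arr[:, varying], axis=0)
            sd = np.nanstd(arr[:, varying], axis=0, ddof=1)
            if mu.size and (np.abs(mu).max() > 1e-8 or np.abs(sd - 1).max() > 1e-6):
                raise ValidationError("scaled matrix columns are not z-scores")

    def subset_metabolites(self, keep: list[str]) -> "MetaboliteMatrix":
        mm = replace(self, values=self.values[keep].copy())
        if self.column_means is not None:
            mm.column_means = self.column_means[keep]
        if self.column_sds is not None:
            mm.column_sds = self.column_sds[keep]
        return mm


@dataclass
class PathwayMap:
    """Metabolite -> (subpathway, superpathway) annotation.

    ``table`` is indexed by metabolite id with columns ``subpathway``,
    ``superpathway`` and boolean ``exogenous`` (drug / drug-pathway
    flag).  Each subpathway belongs to exactly one superpathway.
    """

    table: pd.DataFrame

    @property
    def metabolite_ids(self) -> list[str]:
        return list(self.table.index)

    @property
    def subpathways(self) -> list[str]:
        return list(pd.unique(self.table["subpathway"]))

    def metabolites_in(self, subpathway: str) -> list[str]:
        return list(self.table.index[self.table["subpathway"] == subpathway])

    def exogenous_ids(self) -> list[str]:
        return list(self.table.index[self.table["exogenous"].astype(bool)])

    def validate(self) -> None:
        if self.table.index.has_duplicates:
            dupes = sorted(self.table.index[self.table.index.duplicated()].unique())
            raise ValidationError(f"duplicate metabolite ids in pathway map: {dupes}")
        missing = {"subpathway", "superpathway", "exogenous"} - set(self.table.columns)
        if missing:
            raise ValidationError(f"pathway map missing columns: {sorted(missing)}")
        per_sub = self.table.groupby("subpathway")["superpathway"].nunique()
        bad = per_sub[per_sub > 1]
        if len(bad):
            raise ValidationError(
                f"subpathways mapped to multiple superpathways: {list(bad.index)}"
            )

    def subset(self, keep: list[str]) -> "PathwayMap":
        return PathwayMap(self.table.loc[keep].copy())


@dataclass
class CohortMetadata:
    """Per-participant clinical metadata.

    ``table`` is indexed by participant id with columns ``group`` (one
    of bvFTD/nfvPPA/PSP/CBS/Control), ``age`` (years), ``sex`` ("M" or
    "F"), ``survival_days`` (days from blood draw to death or censoring;
    NaN for controls) and ``event`` (1.0 death observed, 0.0 censored,
    NaN for controls).
    """

    table: pd.DataFrame

    @property
    def participant_ids(self) -> list[str]:
        return list(self.table.index)

    @property
    def groups(self) -> pd.Series:
        return self.table["group"]

    def ids_in_group(self, group: str) -> list[str]:
        """Participant ids for one group, or all patients for ``FTLD``."""
        if group == FTLD_COMBINED:
            mask = self.table["group"].isin(DISEASE_GROUPS)
        else:
            mask = self.table["group"] == group
        return list(self.table.index[mask])

    @property
    def patient_ids(self) -> list[str]:
        return self.ids_in_group(FTLD_COMBINED)

    def sex_indicator(self) -> pd.Series:
        """Sex as a numeric indicator, male = 1."""
        return (self.table["sex"] == "M").astype(float)

    def validate(self) -> None:
        if self.table.index.has_duplicates:
            dupes = sorted(self.table.index[self.table.index.duplicated()].unique())
            raise ValidationError(f"duplicate participant ids in metadata: {dupes}")
        bad_groups = set(self.table["group"]) - set(ALL_GROUPS)
        if bad_groups:
            raise ValidationError(f"unknown group labels: {sorted(bad_groups)}")
        bad_sex = set(self.table["sex"]) - {"M", "F"}
        if bad_sex:
            raise ValidationError(f"unknown sex codes: {sorted(bad_sex)}")
        surv = self.table["survival_days"]
        ev = self.table["event"]
        is_control = self.table["group"] == CONTROL_GROUP
        if surv[is_control].notna().any():
            raise ValidationError("controls must not carry survival times")
        if (surv.dropna() < 0).any():
            raise ValidationError("negative survival times")
        if ((ev == 1) & surv.isna()).any():
            raise ValidationError("event recorded without a survival time")


@dataclass
class AnalysisConfig:
    """Tunable analysis parameters with the pipeline defaults."""

    fdr_threshold: float = 0.01
    fdr_method: str = "bh"  # "bh" or "storey"
    missingness_fraction_threshold: float = 0.5  # strict "more than" excludes
    kaiser_threshold: float = 1.0
    n_cv_folds: int = 10
    n_repetitions: int = 10
    svm_cost: float = 1.0
    random_seed: int = 0
    km_z_cut: float = 1.0
    single_metabolite_subpathway_policy: str = "passthrough"  # or "drop"
    global_retention: str = "kaiser"  # or "fixed_k"
    global_fixed_k: int = 50
    standardize_local_scores: bool = True
    rescale_within_folds: bool = False
    sd_ddof: int = 1
    fold_change_on_imputed: bool = True

    def __post_init__(self) -> None:
        if self.fdr_threshold <= 0 or self.kaiser_threshold <= 0:
            raise ValidationError("thresholds must be positive")
        if not 0 < self.missingness_fraction_threshold <= 1:
            raise ValidationError("missingness threshold must be in (0, 1]")
        if self.n_cv_folds < 2:
            raise ValidationError("need at least 2 CV folds")
        if self.n_repetitions < 1:
            raise ValidationError("need at least 1 repetition")
        if self.fdr_method not in ("bh", "storey"):
            raise ValidationError(f"unknown fdr_method {self.fdr_method!r}")
        if self.single_metabolite_subpathway_policy not in ("passthrough", "drop"):
            raise ValidationError("single-metabolite policy must be passthrough|drop")
        if self.global_retention not in ("kaiser", "fixed_k"):
            raise ValidationError("global_retention must be kaiser|fixed_k")

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValidationError(f"unknown analysis config keys: {sorted(unknown)}")
        return cls(**d)


# ---------------------------------------------------------------------------
# IO
# ---------------------------------------------------------------------------


def _read_table(path: str | Path, index_col: int = 0) -> pd.DataFrame:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    df = pd.read_csv(
        path, sep=sep, index_col=index_col, dtype=str,
        na_values=list(NA_VALUES), keep_default_na=False,
    )
    df.index = df.index.astype(str)
    return df


def _parse_numeric(df: pd.DataFrame, path: str | Path) -> pd.DataFrame:
    out = df.apply(lambda c: pd.to_numeric(c, errors="coerce"))
    bad = out.isna() & df.notna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ValidationError(
            f"{path}: unparseable numeric cell at row {df.index[r]!r}, "
            f"column {df.columns[c]!r}: {df.iat[r, c]!r}"
        )
    return out


def read_cohort(
    abundance_path: str | Path,
    pathway_path: str | Path,
    metadata_path: str | Path,
    transposed: bool = False,
) -> tuple[MetaboliteMatrix, PathwayMap, CohortMetadata]:
    """Read and cross-validate the three input tables.

    Metabolites present in the abundance matrix but missing from the
    pathway annotation are excluded with a warning; a participant
    mismatch between matrix and metadata is a hard error.  Set
    ``transposed`` if the abundance file has metabolites as rows.
    """
    raw = _read_table(abundance_path)
    if transposed:
        raw = raw.T
    values = _parse_numeric(raw, abundance_path)

    ptab = _read_table(pathway_path)
    ptab["exogenous"] = (
        ptab["exogenous"].str.strip().str.lower().isin(("1", "true", "yes"))
    )
    pmap = PathwayMap(ptab)
    pmap.validate()

    mtab = _read_table(metadata_path)
    mtab["age"] = pd.to_numeric(mtab["age"])
    mtab["survival_days"] = pd.to_numeric(mtab["survival_days"])
    mtab["event"] = pd.to_numeric(mtab["event"])
    meta = CohortMetadata(mtab)
    meta.validate()

    matrix = MetaboliteMatrix(values)
    matrix.validate()

    unannotated = [m for m in matrix.metabolite_ids if m not in ptab.index]
    if unannotated:
        logger.warning(
            "excluding %d metabolites absent from the pathway map: %s",
            len(unannotated), unannotated,
        )
        keep = [m for m in matrix.metabolite_ids if m not in set(unannotated)]
        matrix = matrix.subset_metabolites(keep)

    only_meta = sorted(set(meta.participant_ids) - set(matrix.participant_ids))
    only_matrix = sorted(set(matrix.participant_ids) - set(meta.participant_ids))
    if only_meta or only_matrix:
        raise ValidationError(
            "participant mismatch between abundance matrix and metadata; "
            f"metadata only: {only_meta}; matrix only: {only_matrix}"
        )
    # align metadata to matrix row order
    meta = CohortMetadata(mtab.loc[matrix.participant_ids])
    pmap = pmap.subset([m for m in pmap.metabolite_ids if m in set(matrix.metabolite_ids)])
    return matrix, pmap, meta


def write_matrix(matrix: MetaboliteMatrix, path: str | Path) -> Path:
    path = Path(path)
    matrix.values.to_csv(path, index_label="participant")
    return path


def write_pathway_map(pmap: PathwayMap, path: str | Path) -> Path:
    path = Path(path)
    out = pmap.table.copy()
    out["exogenous"] = out["exogenous"].astype(int)
    out.to_csv(path, index_label="metabolite")
    return path


def write_metadata(meta: CohortMetadata, path: str | Path) -> Path:
    path = Path(path)
    meta.table.to_csv(path, index_label="participant")
    return path


def write_results(result_tables: dict[str, pd.DataFrame], output_dir: str | Path) -> list[Path]:
    """Write named result tables as CSV; round-trip preserves values.

    Floats are written with :func:`repr`-level precision so that
    ``read_result(write(...))`` reproduces them bit-for-bit.
    """
    output_dir = Path(output_dir)
    if not output_dir.exists():
        output_dir.mkdir(parents=True, exist_ok=True)
    if not output_dir.is_dir():
        raise ValidationError(f"not a writable directory: {output_dir}")
    written: list[Path] = []
    for name, table in result_tables.items():
        path = output_dir / f"{name}.csv"
        table.to_csv(path, index=False)
        written.append(path)
    return written


def read_result(path: str | Path) -> pd.DataFrame:
    """Read a result table written by :func:`write_results`."""
    return pd.read_csv(path, na_values=list(NA_VALUES), keep_default_na=False)
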