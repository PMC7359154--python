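"""Synthetic Metabolon-style cohort generator with known ground truth.

The generator emulates the statistical structure the downstream analysis
assumes: log-normal plasma metabolite abundances organised into
subpathways, fixed multiplicative group effects on a subset of
metabolites, a latent cross-pathway disease-severity factor that loads
on designated subpathways and is elevated in patients, left-censored
missingness (values below a per-metabolite detection quantile are
unobserved), and patient survival times from an exponential
proportional-hazards model whose linear predictor depends on the latent
severity and on age.  Every generated quantity is recorded in a
:class:`SyntheticTruth` so that recovery can be tested.

Defaults mirror the emulated study design: groups of 30/26/45/33
patients (bvFTD, nfvPPA, PSP, CBS) plus 32 controls, 842 endogenous
metabolites in 91 subpathways, 49 metabolites with planted fold
changes, and a severity factor spanning 12 subpathways.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .data import (
    ALL_GROUPS,
    CONTROL_GROUP,
    DISEASE_GROUPS,
    CohortMetadata,
    MetaboliteMatrix,
    PathwayMap,
    ValidationError,
    write_matrix,
    write_metadata,
    write_pathway_map,
)

#: Default group sizes (bvFTD, nfvPPA, PSP, CBS, Control).
DEFAULT_GROUP_SIZES: tuple[int, ...] = (30, 26, 45, 33, 32)

# Per-group age mean/sd (years) and male fraction, mirroring the
# demographics of the emulated cohort.
AGE_PARAMS = {
    "bvFTD": (64.5, 7.2),
    "nfvPPA": (72.0, 7.7),
    "PSP": (72.9, 8.1),
    "CBS": (70.9, 7.0),
    "Control": (68.7, 9.0),
}
MALE_FRACTION = {
    "bvFTD": 0.50,
    "nfvPPA": 0.38,
    "PSP": 0.62,
    "CBS": 0.55,
    "Control": 0.56,
}

SUPERPATHWAYS = (
    "Amino acid",
    "Carbohydrate",
    "Cofactors and vitamins",
    "Energy",
    "Lipid",
    "Nucleotide",
    "Peptide",
    "Xenobiotics",
)
# Rough relative sizes of superpathways in an untargeted plasma panel
# (lipids dominate).
SUPERPATHWAY_WEIGHTS = (0.22, 0.06, 0.07, 0.03, 0.42, 0.07, 0.05, 0.08)


@dataclass
class EffectConfig:
    """Planted effect sizes and nuisance parameters for the generator.

    ``log_fc_magnitude`` is the additive shift on the natural-log scale
    applied to affected metabolites in every patient group (fold change
    ``exp(delta)`` with random sign).  ``severity_patient_shift`` is the
    mean of the latent severity factor in patients relative to controls,
    in units of its within-group standard deviation; the factor is
    standardised to mean 0, variance 1 over the whole cohort after the
    shift.  ``factor_loading`` is the per-metabolite loading magnitude
    (on the unit-noise log scale) within the factor subpathways.
    ``log_hazard_ratio`` is the log hazard ratio per unit of
    standardised severity (default log 0.74, i.e. higher severity score
    is protective on this sign convention).
    """

    n_affected: int = 49
    log_fc_magnitude: float = 0.35
    n_factor_subpathways: int = 12
    factor_loading: float = 0.6
    severity_patient_shift: float = 2.0
    log_hazard_ratio: float = float(np.log(0.74))
    age_log_hazard: float = 0.03  # per year, centred age
    baseline_median_survival_days: float = 1460.0
    censor_rate: float = 0.3
    censored_metabolite_fraction: float = 0.3
    censor_quantile_range: tuple[float, float] = (0.05, 0.6)
    log_sd_range: tuple[float, float] = (0.2, 0.5)
    n_drug_subpathways: int = 3
    n_drug_metabolites: int = 12


@dataclass
class SyntheticTruth:
    """Ground-truth record of every planted quantity."""

    affected_metabolites: dict[str, float]  # id -> true log fold change
    latent_severity: pd.Series  # per participant, standardised
    factor_loadings: pd.Series  # per metabolite
    factor_subpathways: list[str]
    true_log_hazard_ratio: float
    censor_rate: float
    censor_quantiles: pd.Series  # per metabolite, 0 where never censored


def _partition_sizes(rng: np.random.Generator, n_items: int, n_bins: int) -> np.ndarray:
    """Skewed random partition of ``n_items`` into ``n_bins`` bins, each >= 1."""
    if n_items < n_bins:
        raise ValidationError("fewer metabolites than subpathways")
    weights = rng.gamma(1.0, 1.0, size=n_bins)
    extra = rng.multinomial(n_items - n_bins, weights / weights.sum())
    return extra + 1


def generate_cohort(
    n_per_group: tuple[int, ...] = DEFAULT_GROUP_SIZES,
    n_subpathways: int = 91,
    n_metabolites: int = 842,
    effects: EffectConfig | None = None,
    seed: int = 0,
    subpathway_sizes: list[int] | None = None,
) -> tuple[MetaboliteMatrix, PathwayMap, CohortMetadata, SyntheticTruth]:
    """Generate one synthetic cohort plus its ground truth.

    ``n_per_group`` gives sizes for (bvFTD, nfvPPA, PSP, CBS, Control).
    ``n_metabolites`` counts endogenous metabolites only; drug-flagged
    metabolites in dedicated drug subpathways are appended on top per
    ``effects``.  The same seed always yields a bit-identical cohort.
    """
    if effects is None:
        effects = EffectConfig()
    if len(n_per_group) != 5 or any(n <= 0 for n in n_per_group):
        raise ValidationError("n_per_group must be five positive sizes")
    rng = np.random.default_rng(seed)

    # --- pathway structure -------------------------------------------------
    if subpathway_sizes is None:
        sizes = _partition_sizes(rng, n_metabolites, n_subpathways)
    else:
        sizes = np.asarray(subpathway_sizes, dtype=int)
        if len(sizes) != n_subpathways or sizes.sum() != n_metabolites:
            raise ValidationError("subpathway_sizes inconsistent with counts")
    sub_names = [f"subpathway_{i + 1:03d}" for i in range(n_subpathways)]
    sub_super = rng.choice(
        len(SUPERPATHWAYS), size=n_subpathways,
        p=np.asarray(SUPERPATHWAY_WEIGHTS) / sum(SUPERPATHWAY_WEIGHTS),
    )
    met_ids: list[str] = []
    met_sub: list[str] = []
    met_super: list[str] = []
    exogenous: list[bool] = []
    k = 0
    for i, (name, size) in enumerate(zip(sub_names, sizes)):
        for _ in range(size):
            k += 1
            met_ids.append(f"met_{k:04d}")
            met_sub.append(name)
            met_super.append(SUPERPATHWAYS[sub_super[i]])
            exogenous.append(False)
    # drug subpathways: wholly exogenous, under Xenobiotics
    if effects.n_drug_subpathways > 0 and effects.n_drug_metabolites > 0:
        drug_sizes = _partition_sizes(
            rng, effects.n_drug_metabolites, effects.n_drug_subpathways
        )
        for j, size in enumerate(drug_sizes):
            name = f"drug_subpathway_{j + 1:02d}"
            for _ in range(size):
                k += 1
                met_ids.append(f"met_{k:04d}")
                met_sub.append(name)
                met_super.append("Xenobiotics")
                exogenous.append(True)
    pmap = PathwayMap(
        pd.DataFrame(
            {"subpathway": met_sub, "superpathway": met_super, "exogenous": exogenous},
            index=pd.Index(met_ids, name="metabolite"),
        )
    )

    # --- participants ------------------------------------------------------
    groups = np.repeat(ALL_GROUPS, n_per_group)
    n_total = len(groups)
    pids = [f"P{i + 1:03d}" for i in range(n_total)]
    age = np.empty(n_total)
    sex = np.empty(n_total, dtype=object)
    for g in ALL_GROUPS:
        mask = groups == g
        mu, sd = AGE_PARAMS[g]
        age[mask] = np.clip(rng.normal(mu, sd, mask.sum()), 40.0, 90.0)
        sex[mask] = np.where(rng.random(mask.sum()) < MALE_FRACTION[g], "M", "F")
    is_patient = groups != CONTROL_GROUP

    # --- latent severity ---------------------------------------------------
    raw_sev = rng.normal(0.0, 1.0, n_total)
    raw_sev[is_patient] += effects.severity_patient_shift
    severity = (raw_sev - raw_sev.mean()) / raw_sev.std()  # mean 0, var 1

    # --- metabolite-level parameters --------------------------------------
    m_total = len(met_ids)
    base_log = rng.uniform(4.0, 12.0, m_total)
    log_sd = rng.uniform(*effects.log_sd_range, m_total)

    endo = ~np.asarray(exogenous)
    endo_idx = np.flatnonzero(endo)
    if effects.n_affected > len(endo_idx):
        raise ValidationError("more affected metabolites than endogenous metabolites")
    affected_idx = rng.choice(endo_idx, size=effects.n_affected, replace=False)
    delta = np.zeros(m_total)
    delta[affected_idx] = rng.choice([-1.0, 1.0], size=effects.n_affected) * (
        effects.log_fc_magnitude
    )

    endo_subs = sub_names
    if effects.n_factor_subpathways > len(endo_subs):
        raise ValidationError("more factor subpathways than subpathways")
    factor_subs = sorted(
        rng.choice(endo_subs, size=effects.n_factor_subpathways, replace=False)
    )
    lam = np.zeros(m_total)
    in_factor = np.isin(np.asarray(met_sub), factor_subs)
    lam[in_factor] = rng.choice([-1.0, 1.0], size=in_factor.sum()) * (
        effects.factor_loading
    )

    # --- abundances --------------------------------------------------------
    noise = rng.normal(0.0, 1.0, (n_total, m_total)) * log_sd
    log_x = (
        base_log
        + np.outer(is_patient.astype(float), delta)
        + np.outer(severity, lam)
        + noise
    )
    values = np.exp(log_x)

    # --- left-censored missingness ----------------------------------------
    censor_q = np.zeros(m_total)
    if effects.censored_metabolite_fraction > 0:
        n_cens = int(round(effects.censored_metabolite_fraction * m_total))
        cens_idx = rng.choice(m_total, size=n_cens, replace=False)
        censor_q[cens_idx] = rng.uniform(*effects.censor_quantile_range, n_cens)
    for j in np.flatnonzero(censor_q > 0):
        thr = np.quantile(values[:, j], censor_q[j])
        values[values[:, j] < thr, j] = np.nan

    # --- survival (patients only) ------------------------------------------
    survival = np.full(n_total, np.nan)
    event = np.full(n_total, np.nan)
    lam0 = np.log(2.0) / effects.baseline_median_survival_days
    pat = np.flatnonzero(is_patient)
    lp = (
        effects.log_hazard_ratio * severity[pat]
        + effects.age_log_hazard * (age[pat] - age[pat].mean())
    )
    rate = lam0 * np.exp(lp)
    t_death = rng.exponential(1.0 / rate)
    if effects.censor_rate > 0:
        mu_c = rate.mean() * effects.censor_rate / (1.0 - effects.censor_rate)
        t_cens = rng.exponential(1.0 / mu_c, size=len(pat))
    else:
        t_cens = np.full(len(pat), np.inf)
    survival[pat] = np.minimum(t_death, t_cens)
    event[pat] = (t_death <= t_cens).astype(float)

    matrix = MetaboliteMatrix(
        pd.DataFrame(values, index=pd.Index(pids, name="participant"), columns=met_ids)
    )
    meta = CohortMetadata(
        pd.DataFrame(
            {
                "group": groups,
                "age": age,
                "sex": sex,
                "survival_days": survival,
                "event": event,
            },
            index=pd.Index(pids, name="participant"),
        )
    )
    truth = SyntheticTruth(
        affected_metabolites={
            met_ids[j]: float(delta[j]) for j in sorted(affected_idx)
        },
        latent_severity=pd.Series(severity, index=pids, name="latent_severity"),
        factor_loadings=pd.Series(lam, index=met_ids, name="factor_loading"),
        factor_subpathways=list(factor_subs),
        true_log_hazard_ratio=float(effects.log_hazard_ratio),
        censor_rate=float(effects.censor_rate),
        censor_quantiles=pd.Series(censor_q, index=met_ids, name="censor_quantile"),
    )
    matrix.validate()
    pmap.validate()
    meta.validate()
    return matrix, pmap, meta, truth


def null_effects(**overrides) -> EffectConfig:
    """An :class:`EffectConfig` with no planted signal of any kind."""
    base = dict(
        n_affected=0,
        log_fc_magnitude=0.0,
        n_factor_subpathways=0,
        factor_loading=0.0,
        severity_patient_shift=0.0,
        log_hazard_ratio=0.0,
    )
    base.update(overrides)
    return EffectConfig(**base)


def truth_report(truth: SyntheticTruth) -> pd.DataFrame:
    """Flat table of planted per-metabolite effects."""
    rows = [
        {
            "metabolite": m,
            "true_log_fold_change": d,
            "true_fold_change": float(np.exp(d)),
            "factor_loading": float(truth.factor_loadings.get(m, 0.0)),
        }
        for m, d in sorted(truth.affected_metabolites.items())
    ]
    return pd.DataFrame(
        rows,
        columns=["metabolite", "true_log_fold_change", "true_fold_change", "factor_loading"],
    )


def write_cohort(
    matrix: MetaboliteMatrix,
    pmap: PathwayMap,
    meta: CohortMetadata,
    truth: SyntheticTruth,
    outdir: str | Path,
) -> dict[str, Path]:
    """Write the three input CSVs plus the truth table."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "abundance": write_matrix(matrix, outdir / "abundance.csv"),
        "pathways": write_pathway_map(pmap, outdir / "pathways.csv"),
        "metadata": write_metadata(meta, outdir / "metadata.csv"),
    }
    tr = truth_report(truth)
    tr.to_csv(outdir / "truth_effects.csv", index=False)
    paths["truth_effects"] = outdir / "truth_effects.csv"
    sev = truth.latent_severity.rename_axis("participant").reset_index()
    sev.to_csv(outdir / "truth_severity.csv", index=False)
    paths["truth_severity"] = outdir / "truth_severity.csv"
    return paths
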