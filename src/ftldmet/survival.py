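"""Cox proportional-hazards and Kaplan-Meier analysis of the consensus
component.

Patients only: the standardised per-patient score on the consensus
global component enters a Cox model (Efron tie handling) together with
age, a gender indicator and FTLD-group indicators (reference bvFTD).
For illustration, patients are stratified into high (z > cut), medium
(-cut <= z <= cut, boundaries inclusive) and low (z < -cut) score
groups and compared by Kaplan-Meier curves with a log-rank test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test

from .data import DISEASE_GROUPS, CohortMetadata, ValidationError

logger = logging.getLogger(__name__)

STRATA = ("high", "medium", "low")


@dataclass
class SurvivalFit:
    """Cox model summary: one row per covariate.

    ``table`` columns: covariate, coef, hazard_ratio, ci_lower,
    ci_upper, p.
    """

    table: pd.DataFrame
    n_patients: int
    n_events: int
    n_censored: int

    def row(self, covariate: str) -> pd.Series:
        return self.table.set_index("covariate").loc[covariate]


@dataclass
class KMStrata:
    """Kaplan-Meier stratification by component z-score."""

    strata: pd.Series  # per patient: high / medium / low
    curves: dict[str, pd.DataFrame]  # stratum -> (time, at_risk, events, survival)
    logrank_statistic: float | None
    logrank_p: float | None
    z_cut: float


def standardize_scores(scores: pd.Series) -> pd.Series:
    """Z-score a component score vector across the given patients."""
    sd = scores.std(ddof=1)
    if sd == 0:
        raise ValidationError("constant component scores cannot be standardised")
    return (scores - scores.mean()) / sd


def _patient_frame(component_scores: pd.Series, meta: CohortMetadata) -> pd.DataFrame:
    pats = [p for p in meta.patient_ids if p in component_scores.index]
    if not pats:
        raise ValidationError("no patients with component scores")
    sub = meta.table.loc[pats]
    if sub["survival_days"].isna().any():
        bad = list(sub.index[sub["survival_days"].isna()])
        raise ValidationError(f"patients without survival times: {bad}")
    df = pd.DataFrame(
        {
            "score": component_scores.loc[pats].astype(float),
            "age": sub["age"].astype(float),
            "male": (sub["sex"] == "M").astype(float),
            "group": sub["group"],
            "time": sub["survival_days"].astype(float),
            "event": sub["event"].fillna(0).astype(float),
        }
    )
    return df


def fit_cox(
    component_scores: pd.Series,
    meta: CohortMetadata,
    standardize: bool = True,
) -> SurvivalFit:
    """Cox PH fit of survival on the component score with covariates.

    The score is standardised across patients before fitting, so its
    hazard ratio is per standard deviation.  Group indicators use bvFTD
    as the reference level.
    """
    df = _patient_frame(component_scores, meta)
    if df["event"].sum() < 1:
        raise ValidationError("no observed events; cannot fit Cox model")
    if standardize:
        df["score"] = standardize_scores(df["score"])
    X = df[["score", "age", "male"]].copy()
    for g in DISEASE_GROUPS[1:]:  # bvFTD is the reference
        X[f"group_{g}"] = (df["group"] == g).astype(float)
    X["time"] = df["time"]
    X["event"] = df["event"]
    cph = CoxPHFitter()
    try:
        cph.fit(X, duration_col="time", event_col="event",
                fit_options={"precision": 1e-12})
    except Exception as exc:  # convergence failure surfaces with context
        raise ValidationError(f"Cox model failed to converge: {exc}") from exc
    summ = cph.summary
    table = pd.DataFrame(
        {
            "covariate": summ.index,
            "coef": summ["coef"].to_numpy(),
            "hazard_ratio": summ["exp(coef)"].to_numpy(),
            "ci_lower": summ["exp(coef) lower 95%"].to_numpy(),
            "ci_upper": summ["exp(coef) upper 95%"].to_numpy(),
            "p": summ["p"].to_numpy(),
        }
    ).reset_index(drop=True)
    n_events = int(df["event"].sum())
    return SurvivalFit(
        table=table,
        n_patients=len(df),
        n_events=n_events,
        n_censored=len(df) - n_events,
    )


def km_stratify(
    component_scores: pd.Series,
    meta: CohortMetadata,
    z_cut: float = 1.0,
) -> KMStrata:
    """Stratify patients by component z-score and compare survival.

    high: z > z_cut; low: z < -z_cut; medium: everything in between,
    boundaries inclusive.  Empty strata are excluded from the log-rank
    test with a warning.
    """
    df = _patient_frame(component_scores, meta)
    z = df["score"]
    strata = pd.Series(
        np.where(z > z_cut, "high", np.where(z < -z_cut, "low", "medium")),
        index=df.index,
        name="stratum",
    )
    curves: dict[str, pd.DataFrame] = {}
    for name in STRATA:
        ids = strata.index[strata == name]
        if len(ids) == 0:
            logger.warning("stratum %r is empty; excluded from log-rank", name)
            continue
        kmf = KaplanMeierFitter()
        kmf.fit(df.loc[ids, "time"], df.loc[ids, "event"], label=name)
        ev = kmf.event_table
        curves[name] = pd.DataFrame(
            {
                "time": ev.index.to_numpy(dtype=float),
                "at_risk": ev["at_risk"].to_numpy(dtype=float),
                "events": ev["observed"].to_numpy(dtype=float),
                "survival": kmf.survival_function_[name]
                .loc[ev.index]
                .to_numpy(dtype=float),
            }
        )
    present = [s for s in STRATA if s in curves]
    if len(present) >= 2:
        mask = strata.isin(present)
        lr = multivariate_logrank_test(
            df.loc[mask, "time"], strata[mask], df.loc[mask, "event"]
        )
        stat, p = float(lr.test_statistic), float(lr.p_value)
    else:
        stat = p = None
    return KMStrata(
        strata=strata, curves=curves,
        logrank_statistic=stat, logrank_p=p, z_cut=z_cut,
    )


def survival_report(fit: SurvivalFit, strata: KMStrata) -> dict[str, pd.DataFrame]:
    """Flat tables for the Cox summary and each stratum's KM curve."""
    out = {"cox_summary": fit.table.copy()}
    rows = []
    for name, curve in strata.curves.items():
        c = curve.copy()
        c.insert(0, "stratum", name)
        rows.append(c)
    out["km_curves"] = (
        pd.concat(rows, ignore_index=True)
        if rows
        else pd.DataFrame(columns=["stratum", "time", "at_risk", "events", "survival"])
    )
    counts = strata.strata.value_counts()
    out["km_strata_counts"] = pd.DataFrame(
        {
            "stratum": list(STRATA),
            "n": [int(counts.get(s, 0)) for s in STRATA],
        }
    )
    return out
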