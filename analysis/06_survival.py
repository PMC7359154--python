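#!/usr/bin/env python
"""Survival on the consensus component (patients only).

Cox proportional hazards of days-to-death on the standardised consensus
component score with age, gender and FTLD-group covariates, plus
Kaplan-Meier curves for high (z > 1), medium (-1 <= z <= 1) and low
(z < -1) scoring patients with a log-rank test.
"""

from pathlib import Path

import pandas as pd

from ftldmet import read_cohort, write_results
from ftldmet.preprocess import preprocess
from ftldmet.survival import fit_cox, km_stratify, standardize_scores, survival_report

BASE = Path(__file__).resolve().parent.parent / "results" / "study"

if __name__ == "__main__":
    sim = BASE / "simulate"
    _, _, meta = read_cohort(
        sim / "abundance.csv", sim / "pathways.csv", sim / "metadata.csv"
    )
    scores = pd.read_csv(BASE / "pca" / "global_scores.csv", index_col=0)
    consensus = pd.read_csv(BASE / "classify" / "consensus.csv")["component"]
    if consensus.empty:
        print("no consensus component; nothing to model")
        raise SystemExit(0)
    comp = consensus.iloc[0]
    s = scores[comp]
    fit = fit_cox(s, meta)
    row = fit.row("score")
    print(f"Cox model on {comp} ({fit.n_patients} patients, "
          f"{fit.n_events} deaths):")
    print(f"  hazard ratio per SD = {row['hazard_ratio']:.3f} "
          f"({row['ci_lower']:.3f}-{row['ci_upper']:.3f}), p = {row['p']:.2g}")
    z = standardize_scores(s.loc[meta.patient_ids])
    strata = km_stratify(z, meta, z_cut=1.0)
    counts = strata.strata.value_counts()
    print(f"  strata: {dict(counts)}; log-rank p = {strata.logrank_p:.3g}")
    write_results(survival_report(fit, strata), BASE / "survive")
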