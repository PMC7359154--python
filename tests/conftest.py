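"""Shared fixtures: toy input files and scaled-down synthetic cohorts."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import ftldmet
from ftldmet import EffectConfig, generate_cohort


def scaled_effects(**overrides) -> EffectConfig:
    """Planted-signal configuration for the scaled-down test cohorts:
    8 equal subpathways of 5 metabolites, 4 carrying the severity
    factor, 12 metabolites with fixed fold changes."""
    base = dict(
        n_affected=12,
        n_factor_subpathways=4,
        factor_loading=0.8,
        censored_metabolite_fraction=0.2,
    )
    base.update(overrides)
    return EffectConfig(**base)


def scaled_cohort(seed: int, **effect_overrides):
    """One scaled-down cohort (166 participants, 40 metabolites)."""
    return generate_cohort(
        n_subpathways=8,
        n_metabolites=40,
        effects=scaled_effects(**effect_overrides),
        seed=seed,
        subpathway_sizes=[5] * 8,
    )


@pytest.fixture(scope="session")
def planted_cohort():
    """A fixed scaled-down cohort with planted severity and fold changes."""
    return scaled_cohort(seed=42)


@pytest.fixture(scope="session")
def planted_preprocessed(planted_cohort):
    matrix, pmap, meta, truth = planted_cohort
    pre = ftldmet.preprocess(matrix, pmap)
    return pre, meta, truth


@pytest.fixture()
def toy_files(tmp_path):
    """Three tiny consistent input CSVs; returns their paths."""
    abundance = pd.DataFrame(
        {"m1": [1.0, 2.0, 3.0], "m2": [4.0, 5.0, 6.0]},
        index=pd.Index(["P1", "P2", "P3"], name="participant"),
    )
    pathways = pd.DataFrame(
        {
            "subpathway": ["sp1", "sp1"],
            "superpathway": ["Amino acid", "Amino acid"],
            "exogenous": [0, 0],
        },
        index=pd.Index(["m1", "m2"], name="metabolite"),
    )
    metadata = pd.DataFrame(
        {
            "group": ["bvFTD", "PSP", "Control"],
            "age": [65.0, 72.0, 68.0],
            "sex": ["M", "F", "M"],
            "survival_days": [400.0, 900.0, np.nan],
            "event": [1.0, 0.0, np.nan],
        },
        index=pd.Index(["P1", "P2", "P3"], name="participant"),
    )
    paths = {
        "abundance": tmp_path / "abundance.csv",
        "pathways": tmp_path / "pathways.csv",
        "metadata": tmp_path / "metadata.csv",
    }
    abundance.to_csv(paths["abundance"])
    pathways.to_csv(paths["pathways"])
    metadata.to_csv(paths["metadata"])
    return paths
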