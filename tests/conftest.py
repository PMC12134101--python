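"""Shared fixtures: small hand-built tables and one simulated study."""

import numpy as np
import pandas as pd
import pytest

from avlipidome.containers import ConcentrationMatrix
from avlipidome.nomenclature import STAGES
from avlipidome.synthetic import (
    EffectModel,
    StudyDesign,
    build_species_panel,
    simulate_concentrations,
)


@pytest.fixture(scope="session")
def species_panel() -> list[str]:
    return build_species_panel()


def make_matrix(values: dict[str, list[float]], stages=None,
                sexes=None) -> ConcentrationMatrix:
    """Tiny concentration matrix; columns S1..Sn with simple metadata."""
    df = pd.DataFrame(values).T.astype(float)
    n = df.shape[1]
    df.columns = [f"S{i + 1}" for i in range(n)]
    stages = stages or [STAGES[i % 3] for i in range(n)]
    sexes = sexes or ["M" if i % 2 == 0 else "F" for i in range(n)]
    samples = pd.DataFrame(
        {
            "patient": [f"P{i + 1}" for i in range(n)],
            "sex": sexes,
            "morphology": ["TAV"] * n,
            "stage": stages,
            "tissue_mass_mg": [20.0] * n,
        },
        index=df.columns,
    )
    return ConcentrationMatrix(df, samples)


@pytest.fixture()
def toy_matrix() -> ConcentrationMatrix:
    # Two samples per stage; deliberately missing one SM cell.
    return make_matrix(
        {
            "CE 18:2": [300, 310, 800, 820, 700, 690],
            "CE 16:0": [30, 32, 80, 81, 70, 69],
            "PC 34:1": [100, 102, 99, 101, 98, 100],
            "LPC 18:1": [10, 11, 28, 29, 40, 41],
            "SM 18:1;O2/16:0": [50, 52, 95, np.nan, 90, 91],
            "Cer 18:1;O2/24:0": [5, 5.2, 14, 14.5, 16, 16.4],
            "Cer 18:1;O/16:0": [1, 1.1, 2.9, 3.0, 3.2, 3.3],
            "TG 52:2": [200, 205, 210, 208, 202, 207],
        },
        stages=["mildly_diseased", "mildly_diseased", "fibrotic", "fibrotic",
                "calcific", "calcific"],
    )


@pytest.fixture(scope="session")
def default_study():
    """One seeded full-size study with the default planted effects."""
    matrix, truth = simulate_concentrations(
        StudyDesign(), EffectModel(), seed=11
    )
    return matrix, truth
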