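"""In-memory containers shared across the pipeline.

Tables are pandas objects with documented schemas; the thin wrapper
classes exist to validate keys once at the boundary and to carry the
sample metadata alongside the numeric matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import SchemaError
from .formula import Formula
from .nomenclature import STAGES

__all__ = ["PeakTable", "IstdSpec", "ConcentrationMatrix", "CalibrationCurve"]

PEAK_COLUMNS = ["sample_id", "analyte", "channel", "area"]
SAMPLE_COLUMNS = ["patient", "sex", "morphology", "stage", "tissue_mass_mg"]


@dataclass
class PeakTable:
    """Long-format measured areas per (sample, analyte, adduct/fragment).

    ``data`` columns: sample_id, analyte, channel, area. The triple key
    must be unique and areas finite and non-negative.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in PEAK_COLUMNS if c not in self.data.columns]
        if missing:
            raise SchemaError(f"peak table lacks columns {missing}")
        self.data = self.data.reset_index(drop=True)
        dup = self.data.duplicated(subset=["sample_id", "analyte", "channel"])
        if dup.any():
            row = self.data[dup].iloc[0]
            raise SchemaError(
                "duplicate (sample, analyte, channel) row: "
                f"{tuple(row[['sample_id', 'analyte', 'channel']])}"
            )
        areas = self.data["area"].to_numpy(dtype=float)
        if not np.all(np.isfinite(areas)) or (areas < 0).any():
            raise SchemaError("peak areas must be finite and >= 0")

    def __len__(self) -> int:
        return len(self.data)


@dataclass(frozen=True)
class IstdSpec:
    """One internal standard: class served, spike, label, purity, formula."""

    standard_name: str
    serves_subclass: str
    spiked_amount_pmol: float
    deuterium_count: int
    isotopic_purity: float
    formula: Formula

    def __post_init__(self) -> None:
        if self.spiked_amount_pmol <= 0:
            raise ValueError("spiked amount must be > 0")
        if not (0 < self.isotopic_purity <= 1):
            raise ValueError("isotopic purity must be in (0, 1]")


@dataclass
class ConcentrationMatrix:
    """Lipids x samples, pmol per mg wet tissue, with sample metadata.

    ``values``: DataFrame indexed by normalized lipid name, one column
    per sample; NaN marks a missing (unquantified) cell. ``samples``:
    DataFrame indexed by sample id with columns patient, sex,
    morphology, stage, tissue_mass_mg.
    """

    values: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in SAMPLE_COLUMNS if c not in self.samples.columns]
        if missing:
            raise SchemaError(f"sample metadata lacks columns {missing}")
        unknown = set(self.values.columns) - set(self.samples.index)
        if unknown:
            raise SchemaError(f"samples without metadata: {sorted(unknown)[:5]}")
        self.samples = self.samples.loc[list(self.values.columns)]
        bad_stage = set(self.samples["stage"]) - set(STAGES)
        if bad_stage:
            raise SchemaError(f"unknown stage labels: {sorted(bad_stage)}")
        if (self.samples["tissue_mass_mg"] <= 0).any():
            raise SchemaError("tissue masses must be > 0")
        vals = self.values.to_numpy(dtype=float)
        if np.nanmin(vals, initial=0.0) < 0:
            raise SchemaError("concentrations must be >= 0 or missing")
        self.values = self.values.rename_axis(index="lipid", columns=None)

    # -- convenience selectors ------------------------------------------
    def sample_ids(self, **criteria) -> list[str]:
        """Sample ids matching metadata equality criteria (stage=..., sex=...)."""
        mask = pd.Series(True, index=self.samples.index)
        for col, val in criteria.items():
            mask &= self.samples[col] == val
        return list(self.samples.index[mask])

    def subset_samples(self, sample_ids) -> "ConcentrationMatrix":
        return ConcentrationMatrix(
            self.values[list(sample_ids)], self.samples.loc[list(sample_ids)]
        )

    def subset_lipids(self, lipids) -> "ConcentrationMatrix":
        return ConcentrationMatrix(self.values.loc[list(lipids)], self.samples)

    @property
    def n_missing(self) -> int:
        return int(self.values.isna().to_numpy().sum())


@dataclass
class CalibrationCurve:
    """Per-standard seven-point (or fewer) calibration fit."""

    standard_name: str
    points: pd.DataFrame = field(repr=False)  # columns: amount, area
    slope: float = float("nan")
    intercept: float = float("nan")
    r_squared: float = float("nan")
    linear_range: tuple[float, float] = (float("nan"), float("nan"))

    @property
    def n_points(self) -> int:
        return len(self.points)
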