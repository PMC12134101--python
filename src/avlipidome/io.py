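"""Readers/writers for the pipeline's plain-text interchange formats.

TSV/CSV with documented headers is the lingua franca (matching the
ecosystem of Skyline small-molecule exports and metabolomics repository
tables); YAML for configuration, JSON for the truth record and the run
manifest. All readers validate schemas eagerly and raise
:class:`~avlipidome.errors.SchemaError` with row/column context.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd

from .containers import SAMPLE_COLUMNS, ConcentrationMatrix, IstdSpec, PeakTable
from .errors import SchemaError
from .formula import Formula
from .nomenclature import STAGES, default_registry, elemental_formula, parse_shorthand

__all__ = [
    "read_peak_table",
    "write_peak_table",
    "read_metadata",
    "write_metadata",
    "read_matrix",
    "write_matrix",
    "read_istds",
    "write_istds",
    "write_manifest",
    "file_digest",
]

#: Accepted synonyms for the peak-table columns (Skyline-style exports).
_PEAK_SYNONYMS = {
    "sample_id": ("sample_id", "Replicate", "Replicate Name"),
    "analyte": ("analyte", "Molecule Name", "Molecule", "Precursor Name"),
    "channel": ("channel", "Precursor Adduct", "Transition", "Fragment Ion"),
    "area": ("area", "Area", "Total Area"),
}


def _rename_columns(df: pd.DataFrame, synonyms: dict) -> pd.DataFrame:
    mapping = {}
    for canonical, names in synonyms.items():
        hit = [c for c in df.columns if c in names]
        if not hit:
            raise SchemaError(
                f"missing column {canonical!r} (accepted: {names})"
            )
        mapping[hit[0]] = canonical
    return df.rename(columns=mapping)[list(synonyms)]


def read_peak_table(path) -> PeakTable:
    """Read a transition/peak-area export (CSV or TSV by extension)."""
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep)
    return PeakTable(_rename_columns(df, _PEAK_SYNONYMS))


def write_peak_table(peaks: PeakTable, path) -> None:
    peaks.data.to_csv(path, index=False)


def _normalize_stage(value: str) -> str:
    v = str(value).strip().lower().replace(" ", "_").replace("-", "_")
    if v not in STAGES:
        raise SchemaError(f"unknown stage label {value!r}")
    return v


def read_metadata(path) -> pd.DataFrame:
    """Sample metadata TSV -> DataFrame indexed by sample_id.

    Stage labels are normalized case-insensitively ('Calcific' ->
    'calcific'); duplicate sample ids are rejected.
    """
    df = pd.read_csv(path, sep="\t")
    if "sample_id" not in df.columns:
        raise SchemaError("metadata needs a sample_id column")
    missing = [c for c in SAMPLE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"metadata lacks columns {missing}")
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise SchemaError(f"duplicate sample_id {dup!r}")
    df["stage"] = df["stage"].map(_normalize_stage)
    return df.set_index("sample_id")


def write_metadata(samples: pd.DataFrame, path) -> None:
    samples.rename_axis("sample_id").reset_index().to_csv(
        path, sep="\t", index=False
    )


def read_matrix(values_path, metadata_path) -> ConcentrationMatrix:
    """Concentration matrix TSV (lipids x samples) + metadata TSV.

    Empty cells are the missing-value mask; lipid names are validated
    and normalized through the shorthand parser.
    """
    values = pd.read_csv(values_path, sep="\t", index_col=0)
    values.index = [str(parse_shorthand(n)) for n in values.index]
    values.index.name = "lipid"
    return ConcentrationMatrix(values, read_metadata(metadata_path))


def write_matrix(matrix: ConcentrationMatrix, values_path,
                 metadata_path=None) -> None:
    matrix.values.rename_axis("lipid").to_csv(values_path, sep="\t")
    if metadata_path is not None:
        write_metadata(matrix.samples, metadata_path)


_ISTD_COLUMNS = [
    "standard_name", "serves_subclass", "spiked_amount_pmol",
    "deuterium_count", "isotopic_purity", "formula",
]


def read_istds(path) -> dict[str, IstdSpec]:
    """Internal-standard spec TSV -> subclass -> IstdSpec.

    The formula column may be '-' to compose it from the standard's own
    shorthand name (deuterium suffix ``(dN)`` included). Exactly one
    standard per served subclass.
    """
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in _ISTD_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"ISTD table lacks columns {missing}")
    if df["serves_subclass"].duplicated().any():
        dup = df.loc[df["serves_subclass"].duplicated(), "serves_subclass"].iloc[0]
        raise SchemaError(f"more than one standard for subclass {dup!r}")
    registry = default_registry()
    out: dict[str, IstdSpec] = {}
    for _, row in df.iterrows():
        if row["formula"] in ("-", "", None) or pd.isna(row["formula"]):
            formula = elemental_formula(
                parse_shorthand(row["standard_name"], registry), registry
            )
        else:
            formula = Formula.parse(str(row["formula"]))
        out[row["serves_subclass"]] = IstdSpec(
            standard_name=row["standard_name"],
            serves_subclass=row["serves_subclass"],
            spiked_amount_pmol=float(row["spiked_amount_pmol"]),
            deuterium_count=int(row["deuterium_count"]),
            isotopic_purity=float(row["isotopic_purity"]),
            formula=formula,
        )
    return out


def write_istds(istds: dict[str, IstdSpec], path) -> None:
    pd.DataFrame(
        [
            {
                "standard_name": s.standard_name,
                "serves_subclass": s.serves_subclass,
                "spiked_amount_pmol": s.spiked_amount_pmol,
                "deuterium_count": s.deuterium_count,
                "isotopic_purity": s.isotopic_purity,
                "formula": str(s.formula),
            }
            for s in istds.values()
        ]
    ).to_csv(path, sep="\t", index=False)


def file_digest(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


def write_manifest(path, *, seed, config: dict, inputs: dict, outputs: list) -> None:
    """Run manifest: package version, seed, config digest, input hashes."""
    from . import __version__

    manifest = {
        "package": "avlipidome",
        "version": __version__,
        "seed": seed,
        "config_digest": hashlib.sha256(
            json.dumps(config, sort_keys=True, default=str).encode()
        ).hexdigest()[:16],
        "inputs": {k: file_digest(v) for k, v in inputs.items()
                   if Path(v).exists()},
        "outputs": [str(o) for o in outputs],
    }
    Path(path).write_text(json.dumps(manifest, indent=2) + "\n")
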