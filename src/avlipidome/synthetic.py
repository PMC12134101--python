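"""Ground-truthed synthetic aortic-valve lipidome studies.

The generator emulates the study conditions: ~480 quantified species
over the 28-subclass panel spanning ~6 orders of magnitude of
concentration, three sections (mildly diseased, fibrotic, calcific) per
patient, stage- and sex-specific multiplicative effects, sparse
missingness (0.16%), and a measurement model (class response factors,
monoisotopic-fraction attenuation, internal-standard spikes,
multiplicative noise, optional M+2 isotopologue leakage) whose output
the quantification module inverts.

Default effect sizes mirror the study's headline fold changes so the
estimators have known planted targets: LPC/PC ratio 2.8x/4.0x and
Cer/SM 1.5x/1.8x in fibrotic/calcific sections, SM/PC 1.6x/1.8x,
CE 2.7x/2.3x with a 4-fold fibrotic CE rise in female valves, and
elevated male triacylglyceride baseline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import ConcentrationMatrix, IstdSpec, PeakTable
from .errors import UncoveredClass
from .isotopes import m2_ratio, monoisotopic_fraction
from .nomenclature import (
    STAGES,
    ClassRegistry,
    default_registry,
    elemental_formula,
    normalize_name,
    parse_shorthand,
)

__all__ = [
    "StudyDesign",
    "EffectModel",
    "MeasurementModel",
    "build_species_panel",
    "default_istd_panel",
    "simulate_concentrations",
    "simulate_peak_areas",
    "null_study",
]


@dataclass
class StudyDesign:
    """Cohort layout: patients per (sex x morphology) cell, 3 sections each.

    The default is the tricuspid-valve arm used for the stage analyses:
    11 male + 10 female patients, i.e. n = 21 with 63 tissue sections,
    ~20 mg wet tissue per section.
    """

    n_patients: dict[tuple[str, str], int] = field(
        default_factory=lambda: {("M", "TAV"): 11, ("F", "TAV"): 10}
    )
    sections: tuple[str, ...] = STAGES
    tissue_mass_mean_mg: float = 20.0
    tissue_mass_sd_mg: float = 2.0

    def __post_init__(self) -> None:
        if any(n < 1 for n in self.n_patients.values()):
            raise ValueError("need >= 1 patient per design cell")

    @property
    def n_total_patients(self) -> int:
        return sum(self.n_patients.values())


_STAGE_MULTIPLIERS: dict[str, tuple[float, float, float]] = {
    # (mildly diseased, fibrotic, calcific); solved once from the printed
    # class-total and ratio fold changes, e.g. PC fibrotic 1.1875 makes
    # SM total 1.9x and SM/PC 1.6x simultaneously consistent.
    "CE": (1.0, 2.7, 2.3),
    "ST": (1.0, 2.6, 3.0),
    "TG": (1.0, 1.1, 1.0),
    "DG": (1.0, 1.3, 1.2),
    "MG": (1.0, 1.1, 1.0),
    "FA": (1.0, 1.2, 1.1),
    "PC": (1.0, 1.1875, 1.0),
    "PE": (1.0, 1.05, 0.9),
    "etherPE": (1.0, 1.1, 0.7),
    "PS": (1.0, 0.9, 0.45),
    "PI": (1.0, 1.0, 0.9),
    "PG": (1.0, 1.0, 0.9),
    "PA": (1.0, 1.0, 1.0),
    "CL": (1.0, 1.0, 0.5),
    "LPC": (1.0, 3.325, 4.0),
    "LPE": (1.0, 1.785, 1.62),
    "LPA": (1.0, 1.0, 1.3),
    "LPI": (1.0, 1.2, 1.3),
    "LPS": (1.0, 1.0, 0.9),
    "SM": (1.0, 1.9, 1.8),
    "Cer": (1.0, 2.85, 3.24),
    "dhCer": (1.0, 2.85, 3.24),
    "deoxyCer": (1.0, 2.85, 3.24),
    "phytoCer": (1.0, 2.85, 3.24),
    "sphingadienine-Cer": (1.0, 2.85, 3.24),
    "HexCer": (1.0, 2.0, 1.9),
    "Hex2Cer": (1.0, 2.0, 1.9),
    "GM3": (1.0, 2.0, 1.9),
}

#: Baseline class totals, pmol per mg wet tissue; headline classes use the
#: mildly diseased tricuspid totals (CE 10.80, TG 1.65, PC 0.8, SM 0.76,
#: etherPE 0.27 nmol/mg), the rest are panel-realistic fill-ins.
_BASELINE_CLASS_TOTALS: dict[str, float] = {
    "CE": 10800.0, "TG": 1650.0, "PC": 800.0, "SM": 760.0, "etherPE": 270.0,
    "ST": 3000.0, "DG": 150.0, "MG": 10.0, "FA": 200.0,
    "PE": 250.0, "PS": 60.0, "PI": 100.0, "PG": 30.0, "PA": 2.0, "CL": 40.0,
    "LPC": 60.0, "LPE": 25.0, "LPA": 1.0, "LPI": 8.0, "LPS": 4.0,
    # Cer-family totals set so the ceramide pool decomposes like the
    # tissue it emulates: sphingosine base ~74%, deoxysphingosine ~10%,
    # sphingadienine ~7% of the pool.
    "Cer": 100.0, "dhCer": 6.0, "deoxyCer": 13.0, "phytoCer": 5.0,
    "sphingadienine-Cer": 9.0, "HexCer": 40.0, "Hex2Cer": 15.0, "GM3": 20.0,
}

_SP_CLASSES = ("SM", "Cer", "dhCer", "deoxyCer", "phytoCer",
               "sphingadienine-Cer", "HexCer", "Hex2Cer", "GM3")

#: Extra multiplicative sex x stage interaction factors.
_SEX_STAGE_INTERACTIONS: dict[tuple[str, str], tuple[float, float, float]] = {
    # Female valves: 4-fold fibrotic CE rise (2.7 x 1.481); identical SP
    # factors on SM and every Cer subclass keep the planted Cer/SM ratio
    # folds exact while making sphingolipid accumulation female-dominant.
    # Male factors solved so the sex-pooled CE folds stay at 2.7x/2.3x
    # under the default 11M/10F design and CE sex baselines.
    ("CE", "F"): (1.0, 1.481, 1.174),
    ("CE", "M"): (1.0, 0.646, 0.872),
    **{(k, "F"): (1.0, 1.20, 1.30) for k in _SP_CLASSES},
    **{(k, "M"): (1.0, 0.85, 0.78) for k in _SP_CLASSES},
}

#: Baseline sex factors; male mildly diseased valves carry more TG
#: (2.2 vs 1.0 nmol/mg), concentrated in PUFA-rich species.
_SEX_BASELINE: dict[tuple[str, str], float] = {
    ("TG", "M"): 1.33,
    ("TG", "F"): 0.64,
    ("CE", "M"): 1.10,
    ("CE", "F"): 0.89,
}


@dataclass
class EffectModel:
    """Planted multiplicative effect structure of a synthetic study."""

    baseline_class_totals: dict[str, float] = field(
        default_factory=lambda: dict(_BASELINE_CLASS_TOTALS)
    )
    stage_multipliers: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(_STAGE_MULTIPLIERS)
    )
    sex_stage_interactions: dict[tuple[str, str], tuple[float, float, float]] = (
        field(default_factory=lambda: dict(_SEX_STAGE_INTERACTIONS))
    )
    sex_baseline: dict[tuple[str, str], float] = field(
        default_factory=lambda: dict(_SEX_BASELINE)
    )
    species_cv: float = 0.4        # per-cell log-normal dispersion
    patient_cv: float = 0.25       # shared across a patient's 3 sections
    missing_rate: float = 0.0016   # missing-at-random cell probability
    #: geometric rank-decay of species shares within a class; CE is steeper
    #: so its top species dominates the class the way CE 18:2 does.
    rank_decay: dict[str, float] = field(
        default_factory=lambda: {"default": 0.72, "CE": 0.45}
    )

    def null(self) -> "EffectModel":
        """Copy with every stage/sex multiplier forced to 1 (null study)."""
        return EffectModel(
            baseline_class_totals=dict(self.baseline_class_totals),
            stage_multipliers={k: (1.0, 1.0, 1.0)
                               for k in self.stage_multipliers},
            sex_stage_interactions={},
            sex_baseline={},
            species_cv=self.species_cv,
            patient_cv=self.patient_cv,
            missing_rate=self.missing_rate,
            rank_decay=dict(self.rank_decay),
        )

    def planted_ratio_folds(self) -> dict[str, tuple[float, float]]:
        """Fibrotic/calcific fold changes implied for each ratio metric.

        Exact because stage multipliers are uniform within a class and the
        sphingolipid sex interactions are shared between numerator and
        denominator classes of Cer/SM.
        """
        from .stats import RATIO_DEFINITIONS

        out = {}
        for name, (nums, dens) in RATIO_DEFINITIONS.items():
            folds = []
            for t in (1, 2):
                num = sum(
                    self.baseline_class_totals.get(k, 0.0)
                    * self.stage_multipliers[k][t]
                    for k in nums
                ) / max(
                    sum(self.baseline_class_totals.get(k, 0.0) for k in nums),
                    1e-300,
                )
                den = sum(
                    self.baseline_class_totals.get(k, 0.0)
                    * self.stage_multipliers[k][t]
                    for k in dens
                ) / max(
                    sum(self.baseline_class_totals.get(k, 0.0) for k in dens),
                    1e-300,
                )
                folds.append(num / den)
            out[name] = (folds[0], folds[1])
        return out


# --------------------------------------------------------------------------
# Species panel
# --------------------------------------------------------------------------


def _acyls(*specs: str) -> list[str]:
    return list(specs)


def build_species_panel(registry: ClassRegistry | None = None) -> list[str]:
    """The deterministic 480-name synthetic panel (normalized shorthand).

    Counts per subclass follow the study's panel structure (e.g. five
    cardiolipins, eleven phosphatidylserines, one phosphatidic acid,
    four lyso-phosphatidic acids); glycerolipids are species-level,
    sphingolipids molecular-level so they decompose into base and acyl.
    """
    registry = registry or default_registry()
    names: list[str] = []

    def grid(cls: str, carbons, dbs, n: int | None = None,
             prefix: str = "") -> None:
        combos = [f"{cls} {prefix}{c}:{d}" for c in carbons for d in dbs]
        names.extend(combos if n is None else combos[:n])

    # Within a class, panel order is abundance rank order (the baseline
    # profile decays geometrically down the list): CE 18:2 leads CE.
    names += [
        "CE 18:2", "CE 18:1", "CE 16:0", "CE 18:3", "CE 20:4", "CE 16:1",
        "CE 18:0", "CE 20:3", "CE 20:5", "CE 22:4", "CE 22:6", "CE 14:0",
    ]
    grid("TG", range(44, 63, 2), range(0, 9))            # 90
    grid("DG", range(30, 41, 2), range(0, 5), n=25)
    names += ["MG 16:0", "MG 18:0", "MG 18:1"]
    names += ["FA 14:0", "FA 16:0", "FA 16:1", "FA 18:0", "FA 18:1",
              "FA 18:2", "FA 20:4", "FA 20:5", "FA 22:5", "FA 22:6"]
    names += ["ST 27:1;O"]

    grid("PC", range(30, 41), range(0, 6), n=60)
    grid("PE", range(34, 41), range(1, 6))               # 35
    grid("PE", range(34, 41), range(2, 7), prefix="P-")  # 35 etherPE
    grid("PS", range(34, 41), range(1, 6), n=11)
    grid("PI", range(34, 39), range(1, 4))               # 15
    grid("PG", range(32, 39, 2), range(1, 3))            # 8
    names += ["PA 34:1"]
    names += ["CL 68:5", "CL 70:6", "CL 70:7", "CL 72:7", "CL 72:8"]

    grid("LPC", range(14, 23), range(0, 2), n=15)
    grid("LPE", range(16, 21), range(0, 2))              # 10
    names += ["LPA 16:0", "LPA 18:0", "LPA 18:1", "LPA 20:4"]
    names += ["LPI 16:0", "LPI 18:0", "LPI 18:1", "LPI 20:4"]
    names += ["LPS 16:0", "LPS 18:0", "LPS 18:1"]

    def sphingo(cls: str, base: str, acyls: list[str]) -> None:
        names.extend(f"{cls} {base}/{a}" for a in acyls)

    sphingo("SM", "18:1;O2", _acyls(
        "14:0", "16:0", "16:1", "18:0", "18:1", "20:0", "22:0", "22:1",
        "23:0", "24:0", "24:1", "24:2", "26:0", "26:1"))
    sphingo("SM", "18:0;O2", _acyls(
        "16:0", "18:0", "20:0", "22:0", "22:1", "23:0", "24:0", "24:1",
        "25:0", "26:0"))
    sphingo("SM", "16:1;O2", _acyls(
        "16:0", "18:0", "20:0", "22:0", "23:0", "24:0", "24:1", "26:0"))
    sphingo("SM", "18:1;O3", _acyls(
        "14:0", "16:0", "18:0", "20:0", "22:0", "24:0", "24:1", "26:0"))

    # Ceramide acyls in abundance rank order: very long chains lead
    # (24:0 > 24:1 > 16:0), as in the tissue pool being emulated.
    sphingo("Cer", "18:1;O2", _acyls(
        "24:0", "24:1", "16:0", "22:0", "23:0", "18:0", "22:1", "25:0",
        "26:0", "24:2", "20:0", "26:1", "14:0"))
    sphingo("Cer", "16:1;O2", _acyls(
        "24:0", "24:1", "16:0", "22:0", "23:0", "26:0"))
    sphingo("Cer", "17:1;O2", _acyls(
        "24:0", "24:1", "16:0", "22:0", "23:0", "26:0"))
    sphingo("Cer", "19:1;O2", _acyls("24:0", "24:1", "16:0", "22:0", "26:0"))
    sphingo("Cer", "20:1;O2", _acyls("24:0", "24:1", "16:0", "22:0", "26:0"))
    sphingo("Cer", "18:0;O2", _acyls(                      # dhCer
        "24:0", "24:1", "16:0", "22:0", "23:0", "18:0", "22:1", "25:0",
        "26:0", "24:2", "20:0", "26:1"))
    sphingo("Cer", "18:1;O", _acyls(                       # deoxyCer
        "24:0", "24:1", "16:0", "22:0", "23:0", "18:0", "25:0", "26:0"))
    sphingo("Cer", "18:0;O3", _acyls(                      # phytoCer
        "24:0", "24:1", "16:0", "22:0", "23:0", "18:0", "20:0", "25:0",
        "26:0", "26:1"))
    sphingo("Cer", "18:2;O2", _acyls(                      # sphingadienine-Cer
        "24:0", "24:1", "16:0", "22:0", "23:0", "18:0", "25:0", "26:0"))
    sphingo("HexCer", "18:1;O2", _acyls(
        "14:0", "16:0", "18:0", "20:0", "22:0", "23:0", "24:0", "24:1",
        "24:2", "25:0", "26:0", "26:1"))
    sphingo("Hex2Cer", "18:1;O2", _acyls(
        "16:0", "22:0", "24:0", "24:1", "26:0"))
    sphingo("GM3", "18:1;O2", _acyls("16:0", "24:0", "24:1"))

    return [normalize_name(parse_shorthand(n, registry)) for n in names]


# --------------------------------------------------------------------------
# Simulation
# --------------------------------------------------------------------------


def _species_baselines(
    panel: list[str], effects: EffectModel, registry: ClassRegistry
) -> pd.Series:
    """Distribute class totals over species by a geometric rank profile."""
    sub = pd.Series({n: parse_shorthand(n, registry).subclass for n in panel})
    baselines = pd.Series(0.0, index=panel)
    for subclass, members in sub.groupby(sub):
        total = effects.baseline_class_totals.get(subclass, 1.0)
        g = effects.rank_decay.get(subclass, effects.rank_decay["default"])
        n = len(members)
        weights = g ** np.arange(n)
        baselines[members.index] = total * weights / weights.sum()
    return baselines


def _lognormal_factor(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Multiplicative log-normal noise with mean exactly 1."""
    if cv == 0:
        return np.ones(size)
    sigma = np.sqrt(np.log1p(cv**2))
    return rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=size)


def simulate_concentrations(
    design: StudyDesign | None = None,
    effects: EffectModel | None = None,
    seed: int = 0,
    panel: list[str] | None = None,
    registry: ClassRegistry | None = None,
) -> tuple[ConcentrationMatrix, dict]:
    """Draw a ground-truthed concentration matrix (pmol/mg wet tissue).

    Per species and section: baseline x stage multiplier x sex factors x
    shared patient factor x log-normal residual, then missing-at-random
    masking. The returned truth record carries the pre-missingness
    matrix, all planted multipliers and the implied ratio fold changes.
    """
    design = design or StudyDesign()
    effects = effects or EffectModel()
    registry = registry or default_registry()
    panel = panel or build_species_panel(registry)
    rng = np.random.default_rng(seed)

    baselines = _species_baselines(panel, effects, registry)
    sub = pd.Series({n: parse_shorthand(n, registry).subclass for n in panel})

    meta_rows = []
    pid = 0
    for (sex, morph), n in sorted(design.n_patients.items()):
        for _ in range(n):
            pid += 1
            patient = f"P{pid:02d}"
            for stage in design.sections:
                meta_rows.append(
                    {
                        "sample_id": f"{patient}_{stage}",
                        "patient": patient,
                        "sex": sex,
                        "morphology": morph,
                        "stage": stage,
                    }
                )
    samples = pd.DataFrame(meta_rows).set_index("sample_id")
    masses = np.clip(
        rng.normal(design.tissue_mass_mean_mg, design.tissue_mass_sd_mg,
                   len(samples)),
        1.0, None,
    )
    samples["tissue_mass_mg"] = masses

    patients = samples["patient"].unique()
    patient_factor = dict(
        zip(patients, _lognormal_factor(rng, effects.patient_cv, len(patients)))
    )

    stage_idx = {s: i for i, s in enumerate(STAGES)}
    expected = np.empty((len(panel), len(samples)))
    for j, (sid, row) in enumerate(samples.iterrows()):
        t = stage_idx[row["stage"]]
        col = np.empty(len(panel))
        for i, name in enumerate(panel):
            k = sub[name]
            v = baselines[name] * effects.stage_multipliers[k][t]
            v *= effects.sex_baseline.get((k, row["sex"]), 1.0)
            v *= effects.sex_stage_interactions.get(
                (k, row["sex"]), (1.0, 1.0, 1.0)
            )[t]
            col[i] = v
        expected[:, j] = col * patient_factor[row["patient"]]

    noise = _lognormal_factor(rng, effects.species_cv, expected.shape)
    values = pd.DataFrame(
        expected * noise, index=panel, columns=samples.index
    )
    values.index.name = "lipid"
    truth_values = values.copy()

    if effects.missing_rate > 0:
        mask = rng.random(values.shape) < effects.missing_rate
        values = values.mask(mask)

    truth = {
        "seed": seed,
        "baselines": baselines,
        "expected": pd.DataFrame(expected, index=panel, columns=samples.index),
        "pre_missingness": truth_values,
        "patient_factors": patient_factor,
        "stage_multipliers": dict(effects.stage_multipliers),
        "planted_ratio_folds": effects.planted_ratio_folds(),
    }
    return ConcentrationMatrix(values, samples), truth


#: Canonical z-scale stage-trajectory shapes used for clustering checks:
#: progressive accumulation, fibrotic tipping, monotone loss, fibrotic
#: dip, and calcific-only rise.
TREND_ARCHETYPES: dict[str, tuple[float, float, float]] = {
    "up": (0.0, 1.0, 2.0),
    "peak": (0.0, 2.0, 0.2),
    "down": (2.0, 1.0, 0.0),
    "dip": (2.0, 0.0, 1.8),
    "late": (0.0, 0.1, 2.0),
}


def simulate_trend_archetypes(
    n_per: int = 40, noise_sd: float = 0.2, seed: int = 0
) -> tuple[pd.DataFrame, list[str]]:
    """Planted stage trajectories around the five archetype shapes.

    Returns a lipids x 3 stage matrix (z-scale) plus the true archetype
    label per row — ground truth for trend-clustering recovery checks.
    """
    rng = np.random.default_rng(seed)
    rows, labels = [], []
    for name, shape in TREND_ARCHETYPES.items():
        base = np.asarray(shape)
        for _ in range(n_per):
            rows.append(base + noise_sd * rng.standard_normal(3))
            labels.append(name)
    idx = [f"L{i}" for i in range(len(rows))]
    return pd.DataFrame(rows, index=idx, columns=list(STAGES)), labels


def null_study(
    design: StudyDesign | None = None,
    seed: int = 0,
    effects: EffectModel | None = None,
    **kw,
) -> ConcentrationMatrix:
    """A study with every stage/sex multiplier forced to 1 (type-I input)."""
    effects = (effects or EffectModel()).null()
    matrix, _ = simulate_concentrations(design, effects, seed, **kw)
    return matrix


# --------------------------------------------------------------------------
# Measurement model
# --------------------------------------------------------------------------

_ISTD_TEMPLATES: dict[str, tuple[str, int]] = {
    # subclass -> (representative standard name, deuterium count)
    "CE": ("CE 18:1", 7), "TG": ("TG 48:1", 7), "DG": ("DG 33:1", 7),
    "MG": ("MG 17:0", 5), "FA": ("FA 17:0", 5), "ST": ("ST 27:1;O", 7),
    "PC": ("PC 33:1", 7), "PE": ("PE 33:1", 7), "etherPE": ("PE P-35:1", 9),
    "PS": ("PS 33:1", 7), "PI": ("PI 33:1", 7), "PG": ("PG 33:1", 7),
    "PA": ("PA 34:0", 7), "CL": ("CL 72:8", 5),
    "LPC": ("LPC 18:1", 7), "LPE": ("LPE 18:1", 7), "LPA": ("LPA 17:1", 0),
    "LPI": ("LPI 17:1", 0), "LPS": ("LPS 17:1", 0),
    "SM": ("SM 18:1;O2/12:0", 9), "Cer": ("Cer 18:1;O2/17:0;O", 0),
    "dhCer": ("Cer 18:0;O2/12:0", 9), "deoxyCer": ("Cer 18:1;O/12:0", 9),
    "phytoCer": ("Cer 18:0;O3/8:0", 9),
    "sphingadienine-Cer": ("Cer 18:2;O2/12:0", 9),
    "HexCer": ("HexCer 18:1;O2/12:0", 9),
    "Hex2Cer": ("Hex2Cer 18:1;O2/12:0", 9),
    "GM3": ("GM3 18:1;O2/12:0", 9),
}


def default_istd_panel(
    effects: EffectModel | None = None,
    registry: ClassRegistry | None = None,
    purity: float = 0.98,
    mass_mg: float = 20.0,
) -> dict[str, IstdSpec]:
    """One standard per subclass with mid-range placeholder spike amounts.

    Spikes target roughly a tenth of the class's expected per-sample
    pool (baseline total x tissue mass / 10), mimicking a standard that
    sits in the middle of the endogenous dynamic range.
    """
    effects = effects or EffectModel()
    registry = registry or default_registry()
    panel: dict[str, IstdSpec] = {}
    for subclass in registry.subclasses():
        name, n_d = _ISTD_TEMPLATES[subclass]
        parsed = parse_shorthand(
            f"{name}(d{n_d})" if n_d else name, registry
        )
        spike = max(effects.baseline_class_totals.get(subclass, 1.0)
                    * mass_mg / 10.0, 0.5)
        panel[subclass] = IstdSpec(
            standard_name=normalize_name(parsed),
            serves_subclass=subclass,
            spiked_amount_pmol=round(spike, 1),
            deuterium_count=n_d,
            isotopic_purity=purity if n_d else 1.0,
            formula=elemental_formula(parsed, registry),
        )
    return panel


@dataclass
class MeasurementModel:
    """Forward LC-MS response model for simulated peak areas."""

    response_factor_cv: float = 0.3   # per-subclass, drawn once per run
    noise_cv: float = 0.0             # per-area multiplicative log-normal
    m2_leakage: bool = False          # inject ΔDB=1 M+2 isotopologue overlap
    #: relative channel split of each analyte's total area
    channel_split: dict[str, float] = field(
        default_factory=lambda: {"[M+H]+": 0.8, "[M+H-H2O]+": 0.2}
    )


def simulate_peak_areas(
    matrix: ConcentrationMatrix,
    meas: MeasurementModel | None = None,
    istds: dict[str, IstdSpec] | None = None,
    seed: int = 0,
    registry: ClassRegistry | None = None,
) -> PeakTable:
    """Invertible forward model: concentrations -> ISTD-spiked peak areas.

    Analyte area = conc x mass x class response factor x monoisotopic
    fraction x noise, split over adduct/fragment channels; standards
    scale their spiked amount the same way (response factors cancel in
    the quantification ratio). Optional M+2 leakage adds each species'
    more-unsaturated partner signal, which type II correction removes.
    """
    meas = meas or MeasurementModel()
    registry = registry or default_registry()
    istds = istds or default_istd_panel(registry=registry)
    rng = np.random.default_rng(seed)

    lipids = list(matrix.values.index)
    parsed = {n: parse_shorthand(n, registry) for n in lipids}
    missing_cov = {parsed[n].subclass for n in lipids} - set(istds)
    if missing_cov:
        raise UncoveredClass(f"no standard for {sorted(missing_cov)}")

    m0 = {n: monoisotopic_fraction(elemental_formula(parsed[n], registry))
          for n in lipids}
    subclasses = sorted({parsed[n].subclass for n in lipids})
    rf = dict(zip(
        subclasses,
        _lognormal_factor(rng, meas.response_factor_cv, len(subclasses)),
    ))

    masses = matrix.samples["tissue_mass_mg"]
    conc = matrix.values
    area = pd.DataFrame(
        {
            sid: conc[sid].to_numpy()
            * masses[sid]
            * np.array([rf[parsed[n].subclass] * m0[n] for n in lipids])
            for sid in conc.columns
        },
        index=lipids,
    )

    if meas.m2_leakage:
        r2 = {n: m2_ratio(elemental_formula(parsed[n], registry))
              for n in lipids}
        by_key: dict[tuple, dict[int, str]] = {}
        for n in lipids:
            l = parsed[n]
            key = (l.subclass, l.total_carbons, l.total_oxygens)
            by_key.setdefault(key, {})[l.total_double_bonds] = n
        leak = pd.DataFrame(0.0, index=area.index, columns=area.columns)
        for key, by_db in by_key.items():
            for db, name in by_db.items():
                partner = by_db.get(db + 1)
                if partner is not None:
                    leak.loc[name] += area.loc[partner] * r2[partner]
        area = area + leak

    rows = []
    for n in lipids:
        for sid in area.columns:
            a = area.at[n, sid]
            if not np.isfinite(a):
                continue  # missing cell: no peak observed
            for channel, frac in meas.channel_split.items():
                rows.append((sid, n, channel, a * frac))
    for subclass, spec in istds.items():
        if subclass not in subclasses:
            continue
        base = (
            spec.spiked_amount_pmol
            * rf[subclass]
            * monoisotopic_fraction(
                spec.formula, label_purity=spec.isotopic_purity
            )
        )
        for sid in area.columns:
            for channel, frac in meas.channel_split.items():
                rows.append((sid, spec.standard_name, channel, base * frac))

    df = pd.DataFrame(rows, columns=["sample_id", "analyte", "channel", "area"])
    if meas.noise_cv > 0:
        df["area"] *= _lognormal_factor(rng, meas.noise_cv, len(df))
    return PeakTable(df)
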