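"""Internal-standard single-point quantification.

The measurement chain inverted here: per sample, each analyte's
class-specific adduct/fragment areas are summed, isotopically corrected
(type I always, type II for unit-resolution panels), ratioed against
the class-matched internal standard, scaled by the spiked amount, and
normalized to wet tissue mass:

    conc [pmol/mg] = (A_analyte / A_ISTD) * (M0_ISTD / M0_analyte)
                     * spike [pmol] / mass [mg]

Calibration-linearity fitting, the per-lipid linearity/outlier screen,
and spike recovery rates live here too; both screens emit flags only —
removal is a caller decision.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .containers import CalibrationCurve, ConcentrationMatrix, IstdSpec, PeakTable
from .errors import (
    DegenerateDesign,
    MissingIstd,
    ZeroDenominator,
    ZeroIstdArea,
)
from .isotopes import m2_ratio, monoisotopic_fraction, type1_factor
from .nomenclature import (
    ClassRegistry,
    default_registry,
    elemental_formula,
    normalize_name,
    parse_shorthand,
)

logger = logging.getLogger(__name__)

__all__ = [
    "sum_channels",
    "type2_correct",
    "quantify_single_point",
    "fit_calibration",
    "linearity_screen",
    "recovery_rate",
    "LinearityFlags",
]


def sum_channels(
    peaks: PeakTable,
    channel_map: dict[str, list[str]] | None = None,
    registry: ClassRegistry | None = None,
) -> tuple[PeakTable, list[str]]:
    """Sum class-specific adduct/in-source-fragment areas per analyte.

    ``channel_map`` maps subclass -> accepted channel labels. Channels
    not in an analyte's class list are ignored with a logged warning;
    analytes whose class maps to an empty list are dropped and returned
    as flagged. With no map at all, every channel is summed.

    Returns the summed table (channel label ``"sum"``) and the list of
    flagged analyte names.
    """
    registry = registry or default_registry()
    df = peaks.data
    flagged: list[str] = []

    if channel_map is not None:
        keep = np.ones(len(df), dtype=bool)
        for analyte, grp in df.groupby("analyte", sort=False):
            subclass = parse_shorthand(analyte, registry).subclass
            allowed = channel_map.get(subclass)
            if allowed is None:
                continue  # class not restricted: sum everything
            if len(allowed) == 0:
                flagged.append(analyte)
                keep[grp.index] = False
                continue
            bad = ~grp["channel"].isin(allowed)
            if bad.any():
                logger.warning(
                    "%s: ignoring unmapped channels %s",
                    analyte,
                    sorted(grp.loc[bad, "channel"].unique()),
                )
                keep[grp.index[bad]] = False
        df = df[keep]

    summed = (
        df.groupby(["sample_id", "analyte"], sort=False, as_index=False)["area"]
        .sum()
        .assign(channel="sum")[["sample_id", "analyte", "channel", "area"]]
    )
    return PeakTable(summed), flagged


def type2_correct(
    peaks: PeakTable, registry: ClassRegistry | None = None
) -> PeakTable:
    """Subtract M+2 isotopologue overlap between ΔDB = 1 partners.

    For each species (C, d) the corrected area of its partner with one
    more double bond (same subclass, carbons and oxygens) times that
    partner's M+2/M0 ratio is subtracted, cascading from the most
    unsaturated species down; results are clipped at zero. Species
    without a partner pass through unchanged (the correction is
    idempotent on them).
    """
    registry = registry or default_registry()
    df = peaks.data.copy()

    parsed = {a: parse_shorthand(a, registry) for a in df["analyte"].unique()}
    # Deuterated standards sit several Da away from endogenous species of
    # the same composition, so the label count is part of the overlap key.
    key = df["analyte"].map(
        lambda a: (
            parsed[a].subclass,
            parsed[a].total_carbons,
            parsed[a].total_oxygens,
            parsed[a].deuterium,
        )
    )
    dbs = df["analyte"].map(lambda a: parsed[a].total_double_bonds)
    r2 = {
        a: m2_ratio(elemental_formula(l, registry)) for a, l in parsed.items()
    }

    out = df["area"].to_numpy(dtype=float).copy()
    for (_, grp) in df.groupby([df["sample_id"], key], sort=False):
        order = grp.index[np.argsort(-dbs.loc[grp.index].to_numpy())]
        by_db = {int(dbs[i]): i for i in order}
        for i in order:
            partner = by_db.get(int(dbs[i]) + 1)
            if partner is not None:
                corr = out[i] - out[partner] * r2[df.at[partner, "analyte"]]
                out[i] = max(corr, 0.0)
    df["area"] = out
    return PeakTable(df)


def quantify_single_point(
    peaks: PeakTable,
    istds: dict[str, IstdSpec],
    samples: pd.DataFrame,
    registry: ClassRegistry | None = None,
) -> ConcentrationMatrix:
    """Class-matched single-point quantification of a summed peak table.

    ``istds`` maps subclass -> :class:`IstdSpec`; the standards' own
    rows are located in the peak table by ``standard_name``. ``samples``
    carries per-sample metadata including ``tissue_mass_mg``. Raises
    :class:`MissingIstd` when an analyte's class has no standard and
    :class:`ZeroIstdArea` when a standard's area vanishes in a sample.
    """
    registry = registry or default_registry()
    df = peaks.data
    istd_names = {spec.standard_name for spec in istds.values()}

    analytes = [a for a in df["analyte"].unique() if a not in istd_names]
    parsed = {a: parse_shorthand(a, registry) for a in analytes}
    for a, l in parsed.items():
        if l.subclass not in istds:
            raise MissingIstd(f"no internal standard for {l.subclass} ({a!r})")

    m0 = {a: monoisotopic_fraction(elemental_formula(l, registry))
          for a, l in parsed.items()}
    istd_m0 = {
        sub: monoisotopic_fraction(
            spec.formula, label_purity=spec.isotopic_purity
        )
        for sub, spec in istds.items()
    }

    wide = df.pivot(index="analyte", columns="sample_id", values="area")
    sample_ids = [s for s in samples.index if s in wide.columns]
    wide = wide[sample_ids]

    rows = {}
    for a in analytes:
        l = parsed[a]
        spec = istds[l.subclass]
        if spec.standard_name not in wide.index:
            raise MissingIstd(
                f"standard {spec.standard_name!r} absent from peak table"
            )
        istd_area = wide.loc[spec.standard_name]
        if (istd_area.fillna(0) == 0).any():
            bad = istd_area.index[istd_area.fillna(0) == 0][0]
            raise ZeroIstdArea(
                f"{spec.standard_name!r} area is zero in sample {bad!r}"
            )
        factor = istd_m0[l.subclass] / m0[a]
        conc = (
            wide.loc[a] / istd_area * factor * spec.spiked_amount_pmol
            / samples.loc[sample_ids, "tissue_mass_mg"]
        )
        rows[normalize_name(l)] = conc

    values = pd.DataFrame(rows).T
    values.index.name = "lipid"
    return ConcentrationMatrix(values, samples.loc[sample_ids])


def fit_calibration(
    points: pd.DataFrame,
    standard_name: str = "",
    rel_residual_threshold: float = 0.20,
) -> CalibrationCurve:
    """OLS calibration fit (area vs amount) with a linear-range search.

    ``points`` needs columns ``amount`` and ``area`` (replicates
    allowed). The linear range is the widest contiguous span of amounts
    (at least three distinct levels) for which an OLS fit restricted to
    the span leaves every point's relative residual at or below the
    threshold; ties go to the span with more levels, then the lower one.
    Slope/intercept/R² are reported for the linear-range fit.
    """
    pts = points[["amount", "area"]].astype(float).dropna()
    if pts["amount"].nunique() < 3:
        raise DegenerateDesign("need >= 3 distinct calibration amounts")
    if pts["amount"].nunique() == 1 or np.isclose(pts["amount"].var(), 0.0):
        raise DegenerateDesign("calibration amounts have no variance")

    levels = np.sort(pts["amount"].unique())

    def _fit(sub: pd.DataFrame):
        X = sm.add_constant(sub["amount"].to_numpy())
        res = sm.OLS(sub["area"].to_numpy(), X).fit()
        pred = res.predict(X)
        denom = np.where(np.abs(pred) > 0, np.abs(pred), np.inf)
        rel = np.abs(sub["area"].to_numpy() - pred) / denom
        return res, rel

    best = None
    for i in range(len(levels)):
        for j in range(i + 2, len(levels)):
            span = levels[i : j + 1]
            sub = pts[pts["amount"].isin(span)]
            res, rel = _fit(sub)
            if np.max(rel) <= rel_residual_threshold:
                width = span[-1] - span[0]
                rank = (width, len(span), -span[0])
                if best is None or rank > best[0]:
                    best = (rank, span, res)
    if best is None:
        # No span passes: report the full fit with an empty range.
        res, _ = _fit(pts)
        return CalibrationCurve(
            standard_name, pts, res.params[1], res.params[0],
            float(res.rsquared), (float("nan"), float("nan")),
        )
    _, span, res = best
    return CalibrationCurve(
        standard_name,
        pts,
        slope=float(res.params[1]),
        intercept=float(res.params[0]),
        r_squared=float(res.rsquared),
        linear_range=(float(span[0]), float(span[-1])),
    )


@dataclass
class LinearityFlags:
    """Outcome of the per-lipid concentration-vs-area screen."""

    nonlinear_lipids: list[str]
    outlier_samples: pd.DataFrame  # columns: lipid, sample_id, studentized
    skipped_lipids: list[str]


def linearity_screen(
    matrix: ConcentrationMatrix,
    peaks: PeakTable,
    r2_threshold: float = 0.8,
    residual_threshold: float = 3.0,
    min_samples: int = 5,
) -> LinearityFlags:
    """Flag nonlinear lipids and outlier samples, without removing either.

    Per lipid, calculated concentration is regressed on summed area
    across samples; lipids with R² below ``r2_threshold`` are flagged as
    nonlinear and samples whose externally studentized residual exceeds
    ``residual_threshold`` in magnitude are flagged as outliers. Lipids
    observed in fewer than ``min_samples`` samples are skipped with a
    warning.
    """
    areas = peaks.data.pivot(index="analyte", columns="sample_id", values="area")
    areas.index = [
        normalize_name(parse_shorthand(a)) for a in areas.index
    ]

    nonlinear: list[str] = []
    outliers: list[dict] = []
    skipped: list[str] = []
    for lipid, conc in matrix.values.iterrows():
        if lipid not in areas.index:
            skipped.append(lipid)
            continue
        joined = pd.concat(
            [conc.rename("conc"), areas.loc[lipid].rename("area")], axis=1
        ).dropna()
        if len(joined) < min_samples:
            logger.warning("linearity screen: %s has < %d samples, skipped",
                           lipid, min_samples)
            skipped.append(lipid)
            continue
        X = sm.add_constant(joined["area"].to_numpy())
        res = sm.OLS(joined["conc"].to_numpy(), X).fit()
        if res.rsquared < r2_threshold:
            nonlinear.append(lipid)
        with np.errstate(divide="ignore", invalid="ignore"):
            student = res.get_influence().resid_studentized_external
        for sid, t in zip(joined.index, student):
            # leverage ~1 yields an infinite external residual: an extreme outlier
            if np.isinf(t) or (np.isfinite(t) and abs(t) > residual_threshold):
                outliers.append(
                    {"lipid": lipid, "sample_id": sid, "studentized": float(t)}
                )
    return LinearityFlags(
        nonlinear_lipids=nonlinear,
        outlier_samples=pd.DataFrame(
            outliers, columns=["lipid", "sample_id", "studentized"]
        ),
        skipped_lipids=skipped,
    )


def recovery_rate(before, after) -> float:
    """Spike recovery: 100 x mean(spiked before) / mean(spiked after)."""
    before = np.asarray(list(before), dtype=float)
    after = np.asarray(list(after), dtype=float)
    if before.size == 0 or after.size == 0:
        raise ZeroDenominator("recovery groups must be non-empty")
    denom = after.mean()
    if denom == 0:
        raise ZeroDenominator("post-extraction mean area is zero")
    return 100.0 * before.mean() / denom
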