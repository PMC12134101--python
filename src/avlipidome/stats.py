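"""Class totals, lipoprotein-proxy ratios and differential statistics.

Conventions follow the study design: three disease stages per patient
(mildly diseased -> fibrotic -> calcific), fold changes are ratios of
group arithmetic means relative to the mildly diseased stage, Welch's
unequal-variance t test is the default two-group test, one-way
(unpaired) ANOVA the default across-stage test, and volcano
significance requires both FC > 1.5 (either direction) and p < 0.05.
No multiple-testing correction is applied by default (raw p < 0.05);
Benjamini-Hochberg is available via ``adjust="bh"``.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .containers import ConcentrationMatrix
from .errors import InsufficientData, UndefinedRatio
from .nomenclature import (
    ClassRegistry,
    STAGES,
    classify,
    default_registry,
    parse_shorthand,
)

logger = logging.getLogger(__name__)

__all__ = [
    "RATIO_DEFINITIONS",
    "lipid_subclasses",
    "class_totals",
    "ratio_metric",
    "stage_fold_changes",
    "welch_t",
    "one_way_anova",
    "volcano_prep",
    "heatmap_prep",
    "distribution_plot_data",
]

#: Lipoprotein-proxy ratio metrics: name -> (numerator, denominator classes).
#: LPC/PC and Cer/SM are activity surrogates for LpPLA2 and sphingomyelinase.
CER_FAMILY = ("Cer", "dhCer", "deoxyCer", "phytoCer", "sphingadienine-Cer")
RATIO_DEFINITIONS: dict[str, tuple[tuple[str, ...], tuple[str, ...]]] = {
    "LPC_PC": (("LPC",), ("PC",)),
    "LPE_PE": (("LPE",), ("PE",)),
    "Cer_SM": (CER_FAMILY, ("SM",)),
    "SM_PC": (("SM",), ("PC",)),
    "CE_TG": (("CE",), ("TG",)),
}


def lipid_subclasses(
    matrix: ConcentrationMatrix, registry: ClassRegistry | None = None
) -> pd.Series:
    """Subclass of every lipid row, parsed from its normalized name."""
    registry = registry or default_registry()
    return pd.Series(
        {name: parse_shorthand(name, registry).subclass
         for name in matrix.values.index},
        name="subclass",
    )


def class_totals(
    matrix: ConcentrationMatrix,
    level: str = "subclass",
    registry: ClassRegistry | None = None,
) -> pd.DataFrame:
    """Per-sample totals per subclass or category (missing treated as absent).

    Returns a groups x samples DataFrame; category totals sum to the
    matrix grand total because the category partition is total.
    """
    registry = registry or default_registry()
    sub = lipid_subclasses(matrix, registry)
    if level == "subclass":
        groups = sub
    elif level == "category":
        groups = sub.map(lambda s: classify(s, registry))
    else:
        raise ValueError(f"level must be 'subclass' or 'category', got {level!r}")
    return matrix.values.groupby(groups.reindex(matrix.values.index)).sum(
        min_count=0
    )


def _stage_means(per_sample: pd.Series, samples: pd.DataFrame) -> pd.Series:
    stage = samples.loc[per_sample.index, "stage"]
    return per_sample.groupby(stage).mean().reindex(list(STAGES))


def ratio_metric(
    matrix: ConcentrationMatrix,
    name: str,
    registry: ClassRegistry | None = None,
) -> pd.DataFrame:
    """Per-sample class-total ratio with stage means and fold changes.

    Returns a tidy frame with one row per sample (columns: sample_id,
    stage, value) and attributes ``stage_means`` and ``fold_changes``
    (vs mildly diseased). Samples with a zero denominator total are
    excluded with a warning; if none remain, :class:`UndefinedRatio`.
    """
    registry = registry or default_registry()
    num_classes, den_classes = RATIO_DEFINITIONS[name]
    totals = class_totals(matrix, "subclass", registry)
    num = totals.reindex(list(num_classes)).fillna(0).sum(axis=0)
    den = totals.reindex(list(den_classes)).fillna(0).sum(axis=0)

    bad = den == 0
    if bad.any():
        logger.warning("%s: excluding %d samples with zero denominator",
                       name, int(bad.sum()))
    num, den = num[~bad], den[~bad]
    if len(num) == 0:
        raise UndefinedRatio(f"{name}: denominator zero in every sample")

    value = num / den
    out = pd.DataFrame(
        {
            "sample_id": value.index,
            "stage": matrix.samples.loc[value.index, "stage"].to_numpy(),
            "value": value.to_numpy(),
        }
    )
    means = _stage_means(value, matrix.samples)
    out.attrs["stage_means"] = means
    out.attrs["fold_changes"] = means / means["mildly_diseased"]
    return out


def stage_fold_changes(
    matrix: ConcentrationMatrix,
    grouping: str = "subclass",
    stratify_by: str | None = None,
    registry: ClassRegistry | None = None,
) -> pd.DataFrame:
    """Fold change of group means vs the mildly diseased stage.

    ``grouping`` is ``"subclass"``, ``"category"``, ``"lipid"`` (per
    species) or ``"total"`` (grand total). Optionally stratified by a
    metadata column (``"sex"``, ``"morphology"``). Fold changes are
    ratios of stage arithmetic means, hence invariant to any global
    multiplicative calibration.
    """
    registry = registry or default_registry()
    if grouping == "lipid":
        table = matrix.values
    elif grouping == "total":
        table = matrix.values.sum(min_count=0).to_frame("total").T
    else:
        table = class_totals(matrix, grouping, registry)

    strata = (
        [(None, list(matrix.samples.index))]
        if stratify_by is None
        else [
            (lvl, matrix.sample_ids(**{stratify_by: lvl}))
            for lvl in sorted(matrix.samples[stratify_by].unique())
        ]
    )
    records = []
    for label, sids in strata:
        stage = matrix.samples.loc[sids, "stage"]
        means = table[sids].T.groupby(stage).mean().T
        base = means["mildly_diseased"]
        for grp in table.index:
            if base[grp] == 0 or not np.isfinite(base[grp]):
                continue
            rec = {"group": grp}
            if label is not None:
                rec[stratify_by] = label
            for st in STAGES:
                rec[f"fc_{st}"] = means.at[grp, st] / base[grp]
            records.append(rec)
    return pd.DataFrame(records)


def welch_t(group_a, group_b) -> tuple[float, float]:
    """Welch's unequal-variance t statistic and two-sided p."""
    a = np.asarray(list(group_a), dtype=float)
    b = np.asarray(list(group_b), dtype=float)
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    if len(a) < 2 or len(b) < 2:
        raise InsufficientData("Welch t needs >= 2 values per group")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        # Degenerate but well-defined: identical constants are a null result.
        if a.mean() == b.mean():
            return 0.0, 1.0
        raise InsufficientData("both groups constant with different means")
    t, p = sps.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)


def one_way_anova(*groups) -> tuple[float, float]:
    """Classical unpaired one-way ANOVA F and p across stage groups."""
    arrays = [np.asarray(list(g), dtype=float) for g in groups]
    arrays = [g[np.isfinite(g)] for g in arrays]
    if len(arrays) < 2 or any(len(g) < 2 for g in arrays):
        raise InsufficientData("ANOVA needs >= 2 groups with >= 2 values each")
    f, p = sps.f_oneway(*arrays)
    return float(f), float(p)


def _comparison_groups(
    matrix: ConcentrationMatrix, comparison: dict[str, object]
) -> tuple[list[str], list[str]]:
    """Resolve a comparison spec into two sample-id groups.

    ``comparison`` holds a ``between`` column and its two levels ``a``
    and ``b``, plus optional equality filters (e.g. restrict to one
    stage): ``{"between": "sex", "a": "F", "b": "M", "stage": "calcific"}``.
    """
    comparison = dict(comparison)
    col = comparison.pop("between")
    a_level, b_level = comparison.pop("a"), comparison.pop("b")
    base = matrix.sample_ids(**comparison)
    meta = matrix.samples.loc[base]
    return (
        list(meta.index[meta[col] == a_level]),
        list(meta.index[meta[col] == b_level]),
    )


def volcano_prep(
    matrix: ConcentrationMatrix,
    comparison: dict[str, object],
    fc_threshold: float = 1.5,
    p_threshold: float = 0.05,
    max_missing_fraction: float = 0.5,
    adjust: str | None = None,
) -> pd.DataFrame:
    """Per-lipid differential table for a two-group comparison.

    Columns: lipid, mean_a, mean_b, fold_change (mean_a / mean_b),
    log2_fc, p_value, neg_log10_p, significant. Lipids missing in more
    than half of either group are excluded. Significance requires
    |log2 FC| > log2(threshold) AND p below threshold; ``adjust="bh"``
    switches the p gate to Benjamini-Hochberg-adjusted values.
    """
    ids_a, ids_b = _comparison_groups(matrix, comparison)
    if len(ids_a) < 2 or len(ids_b) < 2:
        raise InsufficientData("volcano comparison needs >= 2 samples per group")
    sub_a, sub_b = matrix.values[ids_a], matrix.values[ids_b]

    keep = (sub_a.isna().mean(axis=1) <= max_missing_fraction) & (
        sub_b.isna().mean(axis=1) <= max_missing_fraction
    )
    rows = []
    for lipid in matrix.values.index[keep]:
        a = sub_a.loc[lipid].dropna().to_numpy()
        b = sub_b.loc[lipid].dropna().to_numpy()
        if len(a) < 2 or len(b) < 2 or b.mean() == 0:
            continue
        try:
            _, p = welch_t(a, b)
        except InsufficientData:
            continue
        fc = a.mean() / b.mean()
        rows.append(
            {"lipid": lipid, "mean_a": a.mean(), "mean_b": b.mean(),
             "fold_change": fc, "log2_fc": np.log2(fc), "p_value": p}
        )
    out = pd.DataFrame(
        rows, columns=["lipid", "mean_a", "mean_b", "fold_change",
                       "log2_fc", "p_value"]
    )
    if len(out) == 0:
        out["neg_log10_p"] = out["significant"] = []
        return out
    p_gate = out["p_value"]
    if adjust == "bh":
        p_gate = pd.Series(
            multipletests(out["p_value"], method="fdr_bh")[1], index=out.index
        )
        out["p_adjusted"] = p_gate
    out["neg_log10_p"] = -np.log10(out["p_value"])
    out["significant"] = (
        (np.abs(out["log2_fc"]) > np.log2(fc_threshold)) & (p_gate < p_threshold)
    )
    return out


def heatmap_prep(
    matrix: ConcentrationMatrix,
    lipids=None,
    log_guard_factor: float = 1e-3,
) -> pd.DataFrame:
    """Log-transform, mean-center and unit-scale each lipid row.

    Missing values are imputed first by the trend-analysis rule (1/5 of
    the lipid's observed minimum). Zeros are kept finite by adding the
    matrix's smallest positive value times ``log_guard_factor`` before
    the natural log. Zero-variance rows are dropped with a warning.
    """
    from .trends import impute_min_fifth  # local import to avoid a cycle

    sub = matrix if lipids is None else matrix.subset_lipids(lipids)
    if len(sub.values) == 0:
        raise ValueError("heatmap subset is empty")
    filled = impute_min_fifth(sub).values
    positive = filled.to_numpy()[filled.to_numpy() > 0]
    guard = (positive.min() if positive.size else 1.0) * log_guard_factor
    logged = np.log(filled + guard)
    sd = logged.std(axis=1, ddof=0)
    flat = sd == 0
    if flat.any():
        logger.warning("heatmap: dropping %d zero-variance rows", int(flat.sum()))
    logged, sd = logged[~flat], sd[~flat]
    return logged.sub(logged.mean(axis=1), axis=0).div(sd, axis=0)


def distribution_plot_data(
    matrix: ConcentrationMatrix,
    sample_ids=None,
    registry: ClassRegistry | None = None,
) -> pd.DataFrame:
    """Per-subclass descending species means plus the subclass sum.

    Mean concentrations are taken over ``sample_ids`` (default: all
    samples). Returns a tidy frame (subclass, lipid, mean_conc, rank,
    log10_conc) with per-subclass totals carried in
    ``attrs["class_sums"]`` — the plot-ready form of the class
    distribution figure.
    """
    registry = registry or default_registry()
    sids = list(sample_ids) if sample_ids is not None else list(matrix.values.columns)
    means = matrix.values[sids].mean(axis=1)
    sub = lipid_subclasses(matrix, registry)

    rows = []
    for subclass, grp in means.groupby(sub.reindex(means.index)):
        ordered = grp.sort_values(ascending=False)
        for rank, (lipid, v) in enumerate(ordered.items(), start=1):
            rows.append(
                {"subclass": subclass, "lipid": lipid, "mean_conc": v,
                 "rank": rank,
                 "log10_conc": np.log10(v) if v > 0 else np.nan}
            )
    out = pd.DataFrame(rows)
    out.attrs["class_sums"] = means.groupby(sub.reindex(means.index)).sum()
    return out
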