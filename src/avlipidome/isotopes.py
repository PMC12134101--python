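"""Isotopologue arithmetic for type I/II corrections.

Type I correction rescales an analyte/standard area ratio by the share
of each molecule's signal that resides in its monoisotopic (M0) peak.
Type II correction removes the M+2 isotopologue of a species with one
more double bond that overlaps a less-unsaturated species' M0 peak in
unit-resolution (SRM) acquisition.

Natural abundances are a fixed, configurable table; deuterium label
positions contribute their isotopic purity instead of a natural
abundance.
"""

from __future__ import annotations

import numpy as np

from .formula import Formula

__all__ = [
    "ISOTOPE_ABUNDANCES",
    "monoisotopic_fraction",
    "isotopologue_distribution",
    "m2_ratio",
    "type1_factor",
]

#: Per element: abundances of isotopes at nominal mass offsets 0, +1, +2 ...
#: relative to the lightest isotope.
ISOTOPE_ABUNDANCES: dict[str, tuple[float, ...]] = {
    "C": (0.9893, 0.0107),
    "H": (0.999885, 0.000115),
    "N": (0.99636, 0.00364),
    "O": (0.99757, 0.00038, 0.00205),
    "P": (1.0,),
    "S": (0.9499, 0.0075, 0.0425, 0.0, 0.0001),
}

DEFAULT_LABEL_PURITY = 0.98


def monoisotopic_fraction(
    f: Formula,
    abundances: dict[str, tuple[float, ...]] | None = None,
    label_purity: float = DEFAULT_LABEL_PURITY,
) -> float:
    """Fraction of the isotopologue distribution in the M0 peak.

    The product over elements of (lightest-isotope abundance)^count;
    deuterium positions contribute ``label_purity`` per position. Equals
    the M0 term of the full convolution by construction.
    """
    ab = abundances or ISOTOPE_ABUNDANCES
    out = 1.0
    for el, n in f.items():
        if el == "D":
            out *= label_purity**n
        else:
            out *= ab[el][0] ** n
    return out


def isotopologue_distribution(
    f: Formula,
    max_shift: int = 4,
    abundances: dict[str, tuple[float, ...]] | None = None,
    label_purity: float = DEFAULT_LABEL_PURITY,
) -> np.ndarray:
    """Aggregated isotopologue pattern at nominal mass shifts 0..max_shift.

    Computed by repeated polynomial convolution of per-element isotope
    vectors (coefficient k of the polynomial = probability of a +k Da
    shift). Truncation at ``max_shift`` is exact for the returned terms.
    """
    ab = abundances or ISOTOPE_ABUNDANCES
    dist = np.zeros(max_shift + 1)
    dist[0] = 1.0
    for el, n in f.items():
        if el == "D":
            vec = np.array([label_purity, 1.0 - label_purity])
        else:
            vec = np.asarray(ab[el], dtype=float)
        for _ in range(n):
            dist = np.convolve(dist, vec)[: max_shift + 1]
    return dist


def m2_ratio(f: Formula, **kw) -> float:
    """M+2 / M0 isotopologue ratio (the type II interference factor)."""
    dist = isotopologue_distribution(f, max_shift=2, **kw)
    return float(dist[2] / dist[0])


def type1_factor(
    analyte: Formula,
    istd: Formula,
    abundances: dict[str, tuple[float, ...]] | None = None,
    label_purity: float = DEFAULT_LABEL_PURITY,
) -> float:
    """Multiplier for the analyte/ISTD area ratio under type I correction.

    Equals monoisotopic_fraction(istd) / monoisotopic_fraction(analyte);
    reduces to the familiar carbon-only formula when all other elements
    match. The factor exceeds 1 when the analyte is larger (its M0 peak
    under-represents it relative to the standard).
    """
    return monoisotopic_fraction(
        istd, abundances, label_purity
    ) / monoisotopic_fraction(analyte, abundances, label_purity)
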