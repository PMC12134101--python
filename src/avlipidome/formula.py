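"""Elemental formulas over {C, H, N, O, P, S, D}.

A :class:`Formula` is an immutable element->count mapping with addition,
subtraction and scalar multiplication, plus monoisotopic mass. Deuterium
is tracked as its own symbol ``D`` so that label purity can be applied
per position during isotopic correction.
"""

from __future__ import annotations

import re
from collections.abc import Mapping

ELEMENTS = ("C", "H", "N", "O", "P", "S", "D")

#: Monoisotopic masses of the lightest (for D: the labeled) isotope, in Da.
MONOISOTOPIC_MASS = {
    "C": 12.0,
    "H": 1.00782503207,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "P": 30.97376163,
    "S": 31.97207100,
    "D": 2.01410177812,
}

_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


class Formula(Mapping):
    """Immutable elemental formula; counts must stay non-negative."""

    __slots__ = ("_counts",)

    def __init__(self, counts: Mapping[str, int] | None = None, **kw: int):
        merged: dict[str, int] = {}
        for src in (counts or {}), kw:
            for el, n in src.items():
                if el not in ELEMENTS:
                    raise ValueError(f"unsupported element {el!r}")
                merged[el] = merged.get(el, 0) + int(n)
        if any(n < 0 for n in merged.values()):
            raise ValueError(f"negative element count in {merged}")
        self._counts = {el: n for el, n in merged.items() if n}

    @classmethod
    def parse(cls, text: str) -> "Formula":
        """Parse a Hill-style string like ``C42H82NO8P``; '-' is empty."""
        if text in ("", "-"):
            return cls()
        counts: dict[str, int] = {}
        pos = 0
        for m in _TOKEN.finditer(text):
            if m.start() != pos:
                raise ValueError(f"cannot parse formula {text!r}")
            el, num = m.group(1), m.group(2)
            counts[el] = counts.get(el, 0) + (int(num) if num else 1)
            pos = m.end()
        if pos != len(text):
            raise ValueError(f"cannot parse formula {text!r}")
        return cls(counts)

    # -- mapping protocol ------------------------------------------------
    def __getitem__(self, el: str) -> int:
        return self._counts.get(el, 0)

    def __iter__(self):
        return iter(self._counts)

    def __len__(self):
        return len(self._counts)

    # -- arithmetic ------------------------------------------------------
    def __add__(self, other: "Formula") -> "Formula":
        counts = dict(self._counts)
        for el, n in other.items():
            counts[el] = counts.get(el, 0) + n
        return Formula(counts)

    def __sub__(self, other: "Formula") -> "Formula":
        counts = dict(self._counts)
        for el, n in other.items():
            counts[el] = counts.get(el, 0) - n
        return Formula(counts)

    def __mul__(self, k: int) -> "Formula":
        return Formula({el: n * k for el, n in self._counts.items()})

    __rmul__ = __mul__

    def __eq__(self, other) -> bool:
        return isinstance(other, Formula) and self._counts == other._counts

    def __hash__(self):
        return hash(tuple(sorted(self._counts.items())))

    def with_deuterium(self, n_d: int) -> "Formula":
        """Move ``n_d`` hydrogens into deuterium positions."""
        if n_d == 0:
            return self
        if self["H"] < n_d:
            raise ValueError(f"cannot deuterate {n_d} positions of {self}")
        return self - Formula(H=n_d) + Formula(D=n_d)

    @property
    def monoisotopic_mass(self) -> float:
        return sum(MONOISOTOPIC_MASS[el] * n for el, n in self._counts.items())

    def __str__(self) -> str:
        # Hill order: C, H, then alphabetical.
        order = [el for el in ("C", "H", "D", "N", "O", "P", "S") if self[el]]
        return "".join(
            f"{el}{self[el]}" if self[el] > 1 else el for el in order
        ) or "-"

    def __repr__(self) -> str:
        return f"Formula({str(self)!r})"


WATER = Formula(H=2, O=1)
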