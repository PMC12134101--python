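"""Sphingolipid decomposition and flow (Sankey) tables.

Every molecular-level sphingolipid resolves into a sphingoid base
(first chain, e.g. sphingosine 18:1;O2), an amide-linked N-acyl (second
chain) and its subclass. Pool concentrations aggregate into
base -> subclass and subclass -> acyl links whose sums are conserved, the
plot-ready form of a Sankey flow diagram.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .containers import ConcentrationMatrix
from .errors import EmptyPool, UnresolvedChains
from .nomenclature import (
    ClassRegistry,
    LipidName,
    default_registry,
    parse_shorthand,
)

logger = logging.getLogger(__name__)

__all__ = ["decompose_sphingolipid", "flow_table", "vlcfa_flag", "SphingoFlow"]

#: Inclusive N-acyl carbon range counted as very long chain fatty acids.
VLCFA_RANGE = (22, 26)


def decompose_sphingolipid(
    l: LipidName | str, registry: ClassRegistry | None = None
) -> tuple[str, str, str]:
    """Split a molecular-level sphingolipid into (base, subclass, acyl).

    The base keeps shorthand form (``18:1;O2``); the acyl is prefixed
    ``FA`` (``FA 24:0``). Species-level names cannot be decomposed and
    raise :class:`UnresolvedChains`.
    """
    registry = registry or default_registry()
    if isinstance(l, str):
        l = parse_shorthand(l, registry)
    if registry.category(l.subclass) != "SP":
        raise UnresolvedChains(f"{l.raw_name!r} is not a sphingolipid")
    if l.level != "molecular" or len(l.chains) != 2:
        raise UnresolvedChains(
            f"{l.raw_name!r}: species-level sphingolipid, chains unresolved"
        )
    base, acyl = l.chains
    return str(base), l.subclass, f"FA {acyl}"


def vlcfa_flag(l: LipidName | str, registry: ClassRegistry | None = None) -> bool:
    """True iff the N-acyl carries a very long chain (C22-C26, inclusive)."""
    registry = registry or default_registry()
    if isinstance(l, str):
        l = parse_shorthand(l, registry)
    lo, hi = VLCFA_RANGE
    _, _, acyl = decompose_sphingolipid(l, registry)
    carbons = int(acyl.split()[1].split(":")[0])
    return lo <= carbons <= hi


@dataclass
class SphingoFlow:
    """Sankey links over a sphingolipid pool.

    ``links`` columns: source, target, value (summed mean concentration,
    pmol/mg), percent (of the pool total). Base -> subclass and
    subclass -> acyl link sums both equal ``pool_total`` by construction.
    """

    links: pd.DataFrame
    pool_total: float
    skipped_species: list[str] = field(default_factory=list)

    def side_sum(self, side: str) -> float:
        """Total over the base->subclass ('left') or subclass->acyl ('right') links."""
        mask = self.links["kind"] == ("base_subclass" if side == "left"
                                      else "subclass_acyl")
        return float(self.links.loc[mask, "value"].sum())


def flow_table(
    matrix: ConcentrationMatrix,
    subclasses=None,
    sample_ids=None,
    registry: ClassRegistry | None = None,
) -> SphingoFlow:
    """Aggregate mean concentrations into sphingolipid Sankey links.

    ``subclasses`` restricts the pool (default: every SP subclass);
    ``sample_ids`` selects the averaging group (default: all samples).
    Species-level SP that cannot be decomposed are counted in
    ``skipped_species`` and logged, never silently dropped.
    """
    registry = registry or default_registry()
    sids = list(sample_ids) if sample_ids is not None else list(matrix.values.columns)
    means = matrix.values[sids].mean(axis=1)

    wanted = set(subclasses) if subclasses is not None else set(
        registry.subclasses("SP")
    )
    links: dict[tuple[str, str, str], float] = {}
    skipped: list[str] = []
    total = 0.0
    for name, conc in means.items():
        l = parse_shorthand(name, registry)
        if l.subclass not in wanted or registry.category(l.subclass) != "SP":
            continue
        if not pd.notna(conc):
            continue
        try:
            base, subclass, acyl = decompose_sphingolipid(l, registry)
        except UnresolvedChains:
            skipped.append(name)
            continue
        links[("base_subclass", base, subclass)] = (
            links.get(("base_subclass", base, subclass), 0.0) + conc
        )
        links[("subclass_acyl", subclass, acyl)] = (
            links.get(("subclass_acyl", subclass, acyl), 0.0) + conc
        )
        total += conc
    if total == 0 or not links:
        raise EmptyPool("no decomposable sphingolipid species in the pool")
    if skipped:
        logger.warning(
            "flow table: %d species-level SP skipped: %s",
            len(skipped), skipped[:5],
        )

    df = pd.DataFrame(
        [
            {"kind": kind, "source": src, "target": tgt, "value": v,
             "percent": 100.0 * v / total}
            for (kind, src, tgt), v in sorted(links.items())
        ]
    )
    return SphingoFlow(links=df, pool_total=total, skipped_species=skipped)
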