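"""Lipid shorthand nomenclature: parsing, normalization, classification.

Shorthand names follow the ``CLASS C:DB;On`` convention used across
quantitative lipidomics, e.g. ``CE 18:2``, ``SM 32:0;O3``,
``Cer 18:1;O2/24:0``, ``PE P-38:4``. A name is *species level* when only
the summed composition is given and *molecular level* when individual
chains are resolved by ``/``.

The 28-subclass panel of the aortic-valve study is shipped as an
editable TSV registry (``data/class_registry.tsv``) mapping each
subclass to its category (NL, GPL, lysoGPL, SP, ST), head-group formula
contribution, chain-slot count and linkage rule. Ceramide-family
subclasses (Cer, dhCer, deoxyCer, phytoCer, sphingadienine-Cer) are
resolved from the sphingoid-base composition rather than from distinct
class tokens: ``Cer 18:1;O/16:0`` is a 1-deoxyceramide because its base
carries a single oxygen.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field, replace
from functools import lru_cache
from importlib import resources

from .errors import MalformedComposition, UnknownClass, UnsupportedClassForFormula
from .formula import WATER, Formula

__all__ = [
    "Chain",
    "LipidName",
    "ClassInfo",
    "ClassRegistry",
    "default_registry",
    "parse_shorthand",
    "normalize_name",
    "as_species",
    "classify",
    "elemental_formula",
]

CATEGORIES = ("NL", "GPL", "lysoGPL", "SP", "ST")
STAGES = ("mildly_diseased", "fibrotic", "calcific")


@dataclass(frozen=True)
class Chain:
    """One acyl/alkyl chain or sphingoid base: carbons, double bonds, oxygens."""

    carbons: int
    double_bonds: int
    oxygens: int = 0

    def __str__(self) -> str:
        s = f"{self.carbons}:{self.double_bonds}"
        if self.oxygens == 1:
            s += ";O"
        elif self.oxygens > 1:
            s += f";O{self.oxygens}"
        return s


@dataclass(frozen=True)
class LipidName:
    """Parsed shorthand species; the universal key of every table."""

    raw_name: str
    class_token: str          # display token, e.g. "Cer" even for dhCer species
    subclass: str             # registry key, e.g. "dhCer"
    level: str                # "species" | "molecular"
    chains: tuple[Chain, ...] # empty at species level
    total_carbons: int
    total_double_bonds: int
    total_oxygens: int
    ether_type: str = "none"  # "none" | "O" | "P"
    deuterium: int = 0        # label positions, for internal standards

    def __str__(self) -> str:
        return normalize_name(self)


@dataclass(frozen=True)
class ClassInfo:
    subclass: str
    category: str
    headgroup_formula: Formula
    n_chain_slots: int
    linkage: str  # "ester" | "free" | "sphingo" | "lookup"


@dataclass
class ClassRegistry:
    """The editable study panel: exactly one row per quantified subclass."""

    classes: dict[str, ClassInfo] = field(default_factory=dict)

    def __contains__(self, subclass: str) -> bool:
        return subclass in self.classes

    def __getitem__(self, subclass: str) -> ClassInfo:
        try:
            return self.classes[subclass]
        except KeyError:
            raise UnknownClass(f"subclass {subclass!r} not in registry") from None

    def category(self, subclass: str) -> str:
        return self[subclass].category

    def subclasses(self, category: str | None = None) -> list[str]:
        if category is None:
            return list(self.classes)
        return [k for k, v in self.classes.items() if v.category == category]

    @classmethod
    def from_tsv(cls, path_or_buf) -> "ClassRegistry":
        if hasattr(path_or_buf, "read"):
            rows = list(csv.DictReader(path_or_buf, delimiter="\t"))
        else:
            with open(path_or_buf, newline="") as fh:
                rows = list(csv.DictReader(fh, delimiter="\t"))
        reg = cls()
        for r in rows:
            if r["category"] not in CATEGORIES:
                raise ValueError(f"unknown category {r['category']!r}")
            reg.classes[r["subclass"]] = ClassInfo(
                subclass=r["subclass"],
                category=r["category"],
                headgroup_formula=Formula.parse(r["headgroup_formula"]),
                n_chain_slots=int(r["n_chain_slots"]),
                linkage=r["linkage"],
            )
        return reg


@lru_cache(maxsize=1)
def default_registry() -> ClassRegistry:
    """The packaged 28-subclass aortic-valve panel."""
    ref = resources.files("avlipidome.data").joinpath("class_registry.tsv")
    with ref.open("r") as fh:
        return ClassRegistry.from_tsv(fh)


# --------------------------------------------------------------------------
# Parsing
# --------------------------------------------------------------------------

# Class tokens accepted in names. Family tokens (Cer, SM, HexCer, ...) may
# resolve to a different registry subclass once the sphingoid base is known.
_SP_FAMILY = {"Cer", "SM", "HexCer", "Hex2Cer", "GM3"}
_CER_LIKE = {"Cer", "dhCer", "deoxyCer", "phytoCer", "sphingadienine-Cer"}

_CHUNK = re.compile(r"^(?:([OP])-)?(\d+):(\d+)(?:;O(\d*))?$")
_DEUTERIUM = re.compile(r"\s*\(d(\d+)\)\s*$")


def _parse_chunk(text: str, where: str) -> tuple[str | None, Chain]:
    m = _CHUNK.match(text)
    if not m:
        raise MalformedComposition(f"cannot parse chain {text!r} in {where!r}")
    ether, c, d, ox = m.groups()
    oxygens = 0 if ox is None else (1 if ox == "" else int(ox))
    return ether, Chain(int(c), int(d), oxygens)


def _sphingo_subclass(token: str, base: Chain) -> str:
    """Resolve the ceramide-family subclass from the sphingoid base.

    Keyed on the base's oxygenation/unsaturation pattern, not its carbon
    count, so chain-length variants (16:1;O2, 20:1;O2, ...) map like the
    canonical C18 bases. Glycosylated classes and SM keep their
    head-group subclass regardless of base.
    """
    if token != "Cer":
        return token
    if base.oxygens == 1:
        return "deoxyCer"
    if base.oxygens >= 3:
        return "phytoCer"
    if base.double_bonds == 0:
        return "dhCer"
    if base.double_bonds >= 2:
        return "sphingadienine-Cer"
    return "Cer"


def parse_shorthand(name: str, registry: ClassRegistry | None = None) -> LipidName:
    """Parse a shorthand name into a fully populated :class:`LipidName`.

    Raises :class:`UnknownClass` for class tokens outside the registry and
    :class:`MalformedComposition` for unparsable compositions. ``;O`` with
    no digit means one oxygen.
    """
    registry = registry or default_registry()
    raw = name
    name = name.strip()
    if not name:
        raise MalformedComposition("empty lipid name")

    deuterium = 0
    m = _DEUTERIUM.search(name)
    if m:
        deuterium = int(m.group(1))
        name = name[: m.start()]

    parts = name.split(None, 1)
    if len(parts) != 2:
        raise MalformedComposition(f"no composition in {name!r}")
    token, comp = parts

    forced_ether = False
    if token == "etherPE":  # alias used in the study's figures
        token, forced_ether = "PE", True
    known_tokens = set(registry.classes) | _SP_FAMILY
    if token not in known_tokens:
        raise UnknownClass(f"unknown lipid class token {token!r} in {name!r}")

    ether_type = "none"
    chains: list[Chain] = []
    for i, chunk in enumerate(comp.split("/")):
        ether, chain = _parse_chunk(chunk.strip(), name)
        if ether is not None:
            if i != 0:
                raise MalformedComposition(
                    f"ether prefix on non-first chain in {name!r}"
                )
            ether_type = ether
        chains.append(chain)
    if forced_ether and ether_type == "none":
        ether_type = "P"  # plasmalogen is the study's dominant ether form

    level = "molecular" if len(chains) > 1 else "species"
    total_c = sum(c.carbons for c in chains)
    total_d = sum(c.double_bonds for c in chains)
    total_o = sum(c.oxygens for c in chains)

    subclass = token
    if token in _SP_FAMILY and level == "molecular":
        subclass = _sphingo_subclass(token, chains[0])
    if token == "PE" and ether_type != "none":
        subclass = "etherPE"
    if subclass not in registry:
        raise UnknownClass(f"subclass {subclass!r} not in registry ({name!r})")

    info = registry[subclass]
    if level == "molecular" and info.linkage != "lookup":
        if len(chains) != info.n_chain_slots:
            raise MalformedComposition(
                f"{name!r}: {len(chains)} chains for {subclass} "
                f"(expects {info.n_chain_slots})"
            )

    return LipidName(
        raw_name=raw,
        class_token=token,
        subclass=subclass,
        level=level,
        chains=tuple(chains) if level == "molecular" else (),
        total_carbons=total_c,
        total_double_bonds=total_d,
        total_oxygens=total_o,
        ether_type=ether_type,
        deuterium=deuterium,
    )


def normalize_name(l: LipidName) -> str:
    """Canonical text form; ``parse(normalize(parse(x))) == parse(x)``."""
    prefix = "" if l.ether_type == "none" else f"{l.ether_type}-"
    if l.level == "molecular":
        comp = "/".join(
            (prefix if i == 0 else "") + str(c) for i, c in enumerate(l.chains)
        )
    else:
        comp = prefix + str(
            Chain(l.total_carbons, l.total_double_bonds, l.total_oxygens)
        )
    name = f"{l.class_token} {comp}"
    if l.deuterium:
        name += f"(d{l.deuterium})"
    return name


def as_species(l: LipidName) -> LipidName:
    """Collapse a molecular-level name to its species-level sum composition."""
    if l.level == "species":
        return l
    collapsed = replace(
        l,
        level="species",
        chains=(),
        raw_name=l.raw_name,
    )
    return replace(collapsed, raw_name=normalize_name(collapsed))


def classify(l: LipidName | str, registry: ClassRegistry | None = None) -> str:
    """Category of a species: NL, GPL, lysoGPL, SP or ST."""
    registry = registry or default_registry()
    subclass = l if isinstance(l, str) else l.subclass
    return registry.category(subclass)


# --------------------------------------------------------------------------
# Elemental composition
# --------------------------------------------------------------------------


def _chain_sum_formula(carbons: int, double_bonds: int, oxygens: int,
                       n_chains: int) -> Formula:
    """Free fatty acids totalling C:DB with extra ;O oxygens, n_chains acids."""
    return Formula(
        C=carbons,
        H=2 * carbons - 2 * double_bonds,
        O=2 * n_chains + oxygens,
    )


def elemental_formula(
    l: LipidName, registry: ClassRegistry | None = None
) -> Formula:
    """Compose the elemental formula of a parsed species.

    Built as head-group contribution plus chain contributions minus one
    water per ester/amide linkage; ether bonds replace an ester (O- loses
    one O and gains two H relative to the diacyl form, P- additionally
    carries the vinyl-ether double bond, i.e. two H fewer than O-).
    Deuterium label positions are substituted for hydrogens at the end.
    Species-level names suffice: the formula depends only on the summed
    composition and the registry's chain-slot count.
    """
    registry = registry or default_registry()
    info = registry[l.subclass]
    c, d, o = l.total_carbons, l.total_double_bonds, l.total_oxygens

    if info.linkage == "lookup":
        f = info.headgroup_formula
    elif info.linkage == "free":
        f = _chain_sum_formula(c, d, o, n_chains=1)
    elif info.linkage == "ester":
        # A 0:0 chain is an empty sn-position, not an esterified acid.
        if l.level == "molecular":
            n = sum(1 for ch in l.chains if ch.carbons > 0)
        else:
            n = info.n_chain_slots
        f = info.headgroup_formula + _chain_sum_formula(c, d, o, n) - n * WATER
        if l.ether_type == "O":
            f = f - Formula(O=1) + Formula(H=2)
        elif l.ether_type == "P":
            f = f - Formula(O=1)
    elif info.linkage == "sphingo":
        # Ceramide core from totals: C_c H_{2c+1-2d} N O_{o+1}; the N-acyl
        # carbonyl oxygen is implicit in the shorthand, the amide water
        # loss is already folded in. Head-group additions (phosphocholine,
        # hexoses, GM3 glycan) come from the registry.
        f = Formula(C=c, H=2 * c + 1 - 2 * d, N=1, O=o + 1)
        f = f + info.headgroup_formula
    else:  # pragma: no cover - registry is validated on load
        raise UnsupportedClassForFormula(
            f"no composition rule for linkage {info.linkage!r}"
        )

    return f.with_deuterium(l.deuterium)
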