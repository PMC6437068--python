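"""Shorthand lipid nomenclature: parsing, canonical formatting, and masses.

The supported grammar covers the eight classes profiled in spheroid-EMT
breast-cancer lipidomics (LPC, PC, PC O-, PE, PE O-, TG, SM, Cer) at two
resolutions:

* species-sum, e.g. ``PC(34:1)`` or ``SM(d34:1)`` — total acyl carbons and
  double bonds only;
* molecular-acyl, e.g. ``TG(17:0/17:0/17:0)`` or ``Cer(d18:1/17:0)`` —
  individual chains, optionally with an omega label (``22:6n3``).

Elemental compositions are assembled from a packaged class-template table
(backbone formula + per-chain increments), so each added CH2 increases the
monoisotopic mass by exactly one methylene increment and each double bond
removes H2.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass
from importlib import resources
from typing import Mapping, Optional

import pandas as pd

from .elements import (
    ELECTRON_MASS,
    MONOISOTOPIC_MASS,
    PROTON_MASS,
    format_formula,
    formula_mass,
    parse_formula,
)

__all__ = [
    "Acyl",
    "LipidSpecies",
    "ElementalComposition",
    "ClassTemplate",
    "ParseError",
    "UnknownLipidClass",
    "UnsupportedClass",
    "UnknownAdduct",
    "parse_lipid_name",
    "format_lipid_name",
    "saturation_class",
    "elemental_composition",
    "mz_for_adduct",
    "species_mz",
    "load_class_templates",
    "default_adducts",
    "ADDUCTS",
]


class ParseError(ValueError):
    """Malformed shorthand lipid name."""


class UnknownLipidClass(ParseError):
    """Class token not present in the template table."""


class UnsupportedClass(KeyError):
    """Lipid class without a registered backbone template."""


class UnknownAdduct(KeyError):
    """Adduct name missing from the adduct table."""


# linkage vocabulary: ester (O-acyl), ether (O-alkyl), amide (sphingolipid
# N-acyl), sphingoid (the long-chain base itself)
LINKAGES = ("ester", "ether", "amide", "sphingoid")


@dataclass(frozen=True, order=True)
class Acyl:
    """One chain: carbon count, C=C double bonds, optional omega label."""

    carbons: int
    double_bonds: int
    n_position: Optional[int] = None
    linkage: str = "ester"

    def __post_init__(self) -> None:
        if self.carbons < 2:
            raise ParseError(f"acyl needs >=2 carbons, got {self.carbons}")
        if not 0 <= self.double_bonds <= self.carbons // 2:
            raise ParseError(
                f"{self.carbons}:{self.double_bonds} has impossible double-bond count"
            )
        if self.n_position is not None and not 0 < self.n_position <= self.carbons:
            raise ParseError(f"omega label n{self.n_position} out of range")
        if self.linkage not in LINKAGES:
            raise ParseError(f"unknown linkage {self.linkage!r}")

    @property
    def name(self) -> str:
        """Field-style fatty-acid name, e.g. ``16:1`` or ``22:6n3``."""
        omega = f"n{self.n_position}" if self.n_position else ""
        return f"{self.carbons}:{self.double_bonds}{omega}"


@dataclass(frozen=True)
class LipidSpecies:
    """A parsed shorthand lipid identity."""

    lipid_class: str
    backbone: str
    sum_carbons: int
    sum_double_bonds: int
    resolution: str  # "species-sum" | "molecular-acyl"
    acyls: tuple[Acyl, ...] = ()
    sphingoid_hydroxyls: Optional[int] = None

    def __post_init__(self) -> None:
        if self.resolution not in ("species-sum", "molecular-acyl"):
            raise ValueError(f"bad resolution {self.resolution!r}")
        if self.acyls:
            if sum(a.carbons for a in self.acyls) != self.sum_carbons:
                raise ParseError("acyl carbons do not sum to sum_carbons")
            if sum(a.double_bonds for a in self.acyls) != self.sum_double_bonds:
                raise ParseError("acyl double bonds do not sum to sum_double_bonds")

    @property
    def name(self) -> str:
        return format_lipid_name(self)

    @property
    def chain_acyls(self) -> tuple[Acyl, ...]:
        """Ester/amide-linked fatty-acyl chains (excludes ether alkyls and
        the sphingoid base), i.e. the chains released as fatty acids on
        saponification."""
        return tuple(a for a in self.acyls if a.linkage in ("ester", "amide"))


@dataclass(frozen=True)
class ElementalComposition:
    """Element counts plus the monoisotopic mass they imply."""

    counts: Mapping[str, int]
    monoisotopic_mass: float

    @property
    def formula(self) -> str:
        return format_formula(self.counts)


@dataclass(frozen=True)
class ClassTemplate:
    lipid_class: str
    backbone: str
    core_formula: str
    n_positions: int
    n_ether: int
    sphingoid: bool
    adducts: tuple[str, ...]


def load_class_templates(path=None) -> dict[str, ClassTemplate]:
    """Read the packaged (or a user-supplied) class-template TSV."""
    if path is None:
        source = resources.files("spherolipid.data") / "class_templates.tsv"
        with resources.as_file(source) as p:
            table = pd.read_csv(p, sep="\t", comment="#")
    else:
        table = pd.read_csv(path, sep="\t", comment="#")
    templates = {}
    for row in table.itertuples(index=False):
        templates[row.lipid_class] = ClassTemplate(
            lipid_class=row.lipid_class,
            backbone=row.backbone,
            core_formula=row.core_formula,
            n_positions=int(row.n_positions),
            n_ether=int(row.n_ether),
            sphingoid=bool(int(row.sphingoid)),
            adducts=tuple(str(row.adducts).split(";")),
        )
    return templates


_TEMPLATES: dict[str, ClassTemplate] | None = None


def class_templates() -> dict[str, ClassTemplate]:
    global _TEMPLATES
    if _TEMPLATES is None:
        _TEMPLATES = load_class_templates()
    return _TEMPLATES


# ---------------------------------------------------------------------------
# parsing / formatting
# ---------------------------------------------------------------------------

_SEGMENT = re.compile(r"^(?P<d>d)?(?P<c>\d+):(?P<db>\d+)(?:n(?P<n>\d+))?$")


def _parse_segment(text: str, linkage: str) -> tuple[Acyl, bool]:
    m = _SEGMENT.match(text)
    if m is None:
        raise ParseError(f"malformed chain token {text!r}")
    acyl = Acyl(
        carbons=int(m.group("c")),
        double_bonds=int(m.group("db")),
        n_position=int(m.group("n")) if m.group("n") else None,
        linkage=linkage,
    )
    return acyl, m.group("d") is not None


def _split_head_body(name: str) -> tuple[str, str, bool]:
    """Return (class token, chain body, ether flag), tolerating the common
    placements of the ``O-`` ether marker and of whitespace."""
    s = name.strip()
    if not s:
        raise ParseError("empty lipid name")
    if "(" in s:
        head, _, rest = s.partition("(")
        if ")" not in rest:
            raise ParseError(f"unbalanced parentheses in {name!r}")
        body = rest[: rest.index(")")].strip()
        head = head.strip()
    else:
        m = re.match(r"^([A-Za-z]+(?:[\s-]?O-)?)\s*(\S.*)$", s)
        if m is None:
            raise ParseError(f"cannot split class and chains in {name!r}")
        head, body = m.group(1).strip(), m.group(2).strip()
    ether = False
    # "PC O-", "PC-O", "PCO-" prefix variants
    for suffix in (" O-", "-O-", "-O", "O-"):
        if head.endswith(suffix) and len(head) > len(suffix):
            head = head[: -len(suffix)].strip()
            ether = True
            break
    if body.startswith("O-"):
        ether = True
        body = body[2:].strip()
    return head, body, ether


def parse_lipid_name(name: str) -> LipidSpecies:
    """Parse a shorthand lipid name into a :class:`LipidSpecies`.

    Accepts whitespace and ether-marker placement variants
    (``PC O-(34:1)``, ``PC(O-34:1)``); sphingolipid names without the
    ``d`` prefix (``Cer(18:1/17:0)``) are canonicalized to the
    di-hydroxy-base form.
    """
    head, body, ether = _split_head_body(name)
    templates = class_templates()
    cls = head
    if ether:
        cls = f"{head} O-"
    if cls not in templates:
        raise UnknownLipidClass(f"unknown lipid class token {head!r} in {name!r}")
    tpl = templates[cls]
    if not body:
        raise ParseError(f"no chain information in {name!r}")

    segments = [seg for seg in re.split(r"[/_]", body) if seg]
    if not segments:
        raise ParseError(f"no chain information in {name!r}")

    if len(segments) == 1 and tpl.n_positions > 1:
        acyl, has_d = _parse_segment(segments[0], "ester")
        if tpl.sphingoid and not has_d:
            # tolerate "SM(34:1)"; canonical form carries the d prefix
            pass
        if has_d and not tpl.sphingoid:
            raise ParseError(f"d-prefix on non-sphingolipid class in {name!r}")
        return LipidSpecies(
            lipid_class=cls,
            backbone=tpl.backbone,
            sum_carbons=acyl.carbons,
            sum_double_bonds=acyl.double_bonds,
            resolution="species-sum",
            acyls=(),
            sphingoid_hydroxyls=2 if tpl.sphingoid else None,
        )

    if len(segments) != tpl.n_positions:
        raise ParseError(
            f"{cls} expects {tpl.n_positions} chains, got {len(segments)} in {name!r}"
        )

    acyls: list[Acyl] = []
    for i, seg in enumerate(segments):
        if tpl.sphingoid and i == 0:
            linkage = "sphingoid"
        elif tpl.sphingoid:
            linkage = "amide"
        elif ether and i == 0:
            linkage = "ether"
        else:
            linkage = "ester"
        acyl, has_d = _parse_segment(seg, linkage)
        if has_d and linkage != "sphingoid":
            raise ParseError(f"misplaced d-prefix in {name!r}")
        acyls.append(acyl)

    return LipidSpecies(
        lipid_class=cls,
        backbone=tpl.backbone,
        sum_carbons=sum(a.carbons for a in acyls),
        sum_double_bonds=sum(a.double_bonds for a in acyls),
        resolution="molecular-acyl",
        acyls=tuple(acyls),
        sphingoid_hydroxyls=2 if tpl.sphingoid else None,
    )


def format_lipid_name(species: LipidSpecies) -> str:
    """Canonical shorthand string; ``parse_lipid_name`` round-trips it."""
    tpl = class_templates().get(species.lipid_class)
    if tpl is None:
        raise UnsupportedClass(species.lipid_class)
    base_cls = species.lipid_class[:-3] if species.lipid_class.endswith(" O-") else species.lipid_class
    ether_prefix = "O-" if tpl.n_ether else ""
    if species.resolution == "species-sum" or not species.acyls:
        d = "d" if tpl.sphingoid else ""
        return f"{base_cls}({ether_prefix}{d}{species.sum_carbons}:{species.sum_double_bonds})"
    parts = []
    for acyl in species.acyls:
        d = "d" if acyl.linkage == "sphingoid" else ""
        parts.append(f"{d}{acyl.name}")
    return f"{base_cls}({ether_prefix}{'/'.join(parts)})"


# ---------------------------------------------------------------------------
# saturation classes
# ---------------------------------------------------------------------------

def saturation_class(acyl: Acyl | int, *, pufa_min: int = 3) -> str:
    """Bucket a chain by double-bond count.

    Default thresholds: 0 -> SFA, 1 -> MUFA, 2 -> DUFA, >= ``pufa_min``
    (3) -> PUFA.  The di-unsaturated bucket is kept separate because the
    polyunsaturated marker used in the figures is explicitly >=3 C=C
    bonds.
    """
    db = acyl.double_bonds if isinstance(acyl, Acyl) else int(acyl)
    if db < 0:
        raise ValueError("negative double-bond count")
    if db == 0:
        return "SFA"
    if db == 1:
        return "MUFA"
    if db >= pufa_min:
        return "PUFA"
    return "DUFA"


# ---------------------------------------------------------------------------
# elemental composition and adduct m/z
# ---------------------------------------------------------------------------

def elemental_composition(species: LipidSpecies) -> ElementalComposition:
    """Neutral elemental composition from the class template.

    The composition depends only on the class and the C:DB totals: every
    ester chain contributes CnH(2n-2-2d)O, every ether alkyl CnH(2n-2d),
    and sphingolipid classes fold base + N-acyl into a single
    CnH(2n-2d) hydrocarbon term against a residual core.
    """
    tpl = class_templates().get(species.lipid_class)
    if tpl is None:
        raise UnsupportedClass(species.lipid_class)
    counts = Counter(parse_formula(tpl.core_formula))
    t, d = species.sum_carbons, species.sum_double_bonds
    counts["C"] += t
    if tpl.sphingoid:
        counts["H"] += 2 * t - 2 * d
    else:
        n_ester = tpl.n_positions - tpl.n_ether
        counts["H"] += 2 * t - 2 * d - 2 * n_ester
        counts["O"] += n_ester
    if any(v < 0 for v in counts.values()):
        raise ParseError(f"impossible composition for {species.name}")
    return ElementalComposition(counts=dict(counts), monoisotopic_mass=formula_mass(counts))


def _adduct_table() -> dict[str, float]:
    h = MONOISOTOPIC_MASS["H"]
    n = MONOISOTOPIC_MASS["N"]
    na = MONOISOTOPIC_MASS["Na"]
    c = MONOISOTOPIC_MASS["C"]
    o = MONOISOTOPIC_MASS["O"]
    return {
        "[M+H]+": PROTON_MASS,
        "[M+NH4]+": n + 4 * h - ELECTRON_MASS,
        "[M+Na]+": na - ELECTRON_MASS,
        "[M-H]-": -PROTON_MASS,
        "[M+HCOO]-": c + h + 2 * o + ELECTRON_MASS,
    }


ADDUCTS: dict[str, float] = _adduct_table()

POSITIVE_ADDUCTS = {a for a in ADDUCTS if a.endswith("+")}
NEGATIVE_ADDUCTS = {a for a in ADDUCTS if a.endswith("-")}


def adduct_polarity(adduct: str) -> str:
    if adduct in POSITIVE_ADDUCTS:
        return "+"
    if adduct in NEGATIVE_ADDUCTS:
        return "-"
    raise UnknownAdduct(adduct)


def mz_for_adduct(mass: float, adduct: str, table: Mapping[str, float] | None = None) -> float:
    """m/z of a singly charged adduct ion of a neutral of given mass."""
    if mass <= 0:
        raise ValueError("mass must be positive")
    tab = ADDUCTS if table is None else table
    try:
        return mass + tab[adduct]
    except KeyError:
        raise UnknownAdduct(adduct) from None


def species_mz(species: LipidSpecies, adduct: str) -> float:
    """Theoretical adduct m/z of a species (composition + adduct shift)."""
    return mz_for_adduct(elemental_composition(species).monoisotopic_mass, adduct)


def default_adducts(lipid_class: str, polarity: str | None = None) -> tuple[str, ...]:
    """Default adducts for a class, optionally filtered by polarity."""
    tpl = class_templates().get(lipid_class)
    if tpl is None:
        raise UnsupportedClass(lipid_class)
    adducts = tpl.adducts
    if polarity is not None:
        adducts = tuple(a for a in adducts if adduct_polarity(a) == polarity)
    return adducts
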