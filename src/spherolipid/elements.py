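"""Monoisotopic atomic masses and chemical-formula arithmetic.

Masses are CODATA/AME monoisotopic values in Da. Formulas are plain
element-count strings such as ``C40H80NO8P``; an optional trailing ``+``
or ``-`` marks a singly charged ion, in which case the electron mass is
subtracted or added when computing the ion m/z.
"""

from __future__ import annotations

import re
from collections import Counter
from typing import Mapping

MONOISOTOPIC_MASS: dict[str, float] = {
    "H": 1.0078250319,
    "C": 12.0,
    "N": 14.0030740052,
    "O": 15.9949146221,
    "P": 30.97376151,
    "Na": 22.98976928,
    "S": 31.97207069,
}

ELECTRON_MASS = 0.00054857990946
PROTON_MASS = MONOISOTOPIC_MASS["H"] - ELECTRON_MASS

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


class FormulaError(ValueError):
    """Raised for an unparsable chemical formula string."""


def parse_formula(formula: str) -> Counter:
    """Parse ``C5H15NO4P`` style formulas into element counts.

    A trailing ``+``/``-`` charge marker, if present, must be stripped by
    the caller; this function accepts element symbols only.
    """
    if not formula:
        raise FormulaError("empty formula")
    counts: Counter = Counter()
    pos = 0
    for match in _FORMULA_TOKEN.finditer(formula):
        if match.start() != pos:
            raise FormulaError(f"unparsable formula {formula!r} at {pos}")
        if not match.group(0):
            break
        symbol, digits = match.groups()
        if symbol not in MONOISOTOPIC_MASS:
            raise FormulaError(f"unknown element {symbol!r} in {formula!r}")
        counts[symbol] += int(digits) if digits else 1
        pos = match.end()
    if pos != len(formula):
        raise FormulaError(f"unparsable formula {formula!r} at {pos}")
    return counts


def formula_mass(counts: Mapping[str, int]) -> float:
    """Monoisotopic mass (Da) of a neutral formula given as element counts."""
    return float(sum(MONOISOTOPIC_MASS[el] * n for el, n in counts.items()))


def mass_of(formula: str) -> float:
    """Monoisotopic mass of a neutral formula string."""
    return formula_mass(parse_formula(formula))


def ion_mz(formula: str) -> float:
    """m/z of a singly charged ion written as formula plus ``+``/``-``.

    ``C5H15NO4P+`` is the phosphocholine cation; the electron mass is
    subtracted for cations and added for anions.
    """
    if formula.endswith("+"):
        return mass_of(formula[:-1]) - ELECTRON_MASS
    if formula.endswith("-"):
        return mass_of(formula[:-1]) + ELECTRON_MASS
    raise FormulaError(f"ion formula {formula!r} must end in '+' or '-'")


def format_formula(counts: Mapping[str, int]) -> str:
    """Hill-order formula string (C, H, then alphabetical)."""
    ordered = []
    for el in ("C", "H"):
        if counts.get(el):
            ordered.append((el, counts[el]))
    for el in sorted(k for k in counts if k not in ("C", "H") and counts[k]):
        ordered.append((el, counts[el]))
    return "".join(f"{el}{n if n != 1 else ''}" for el, n in ordered)
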