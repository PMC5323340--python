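"""Element constants, mass defects and homologue-unit mass algebra.

A homologue series spaces its LC-HRMS signals by a repeating chemical
unit (CH2, C2H4O, ...).  Feasible series peaks are constrained by how
the *mass defect* -- the deviation of an exact mass from its nearest
integer -- can change per Thomson of mass difference.  For any element
set, those changes are bounded by the extreme per-mass defect ratios of
the lightest isotopes of the elements involved: the most negative ratio
(79Br among C/H/N/O/S/Cl/Br) gives ``gamma_min``, the most positive
(1H) gives ``gamma_max``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Mapping

__all__ = [
    "ElementRecord",
    "GammaBounds",
    "element_table",
    "mass_defect",
    "gamma_bounds",
    "unit_mass",
    "parse_formula",
]


@dataclass(frozen=True)
class ElementRecord:
    """Lightest-isotope mass and defect of a chemical element."""

    symbol: str
    lightest_isotope_mass: float  # u
    mass_defect: float  # u, in [-0.5, 0.5)

    def __post_init__(self) -> None:
        if self.lightest_isotope_mass <= 0:
            raise ValueError("isotope mass must be positive")
        if not -0.5 <= self.mass_defect < 0.5:
            raise ValueError("mass defect outside [-0.5, 0.5)")


@dataclass(frozen=True)
class GammaBounds:
    """Extreme slopes of mass-defect change per unit of m/z difference."""

    gamma_min: float
    gamma_max: float

    def __post_init__(self) -> None:
        if self.gamma_min > self.gamma_max:
            raise ValueError("gamma_min must not exceed gamma_max")


def mass_defect(mass: float) -> float:
    """Signed deviation of an exact mass (u or Th) from its nearest integer.

    Ties at exactly x.5 round away from zero, so the result lies in
    [-0.5, 0.5).
    """
    if mass <= 0:
        raise ValueError(f"mass must be positive, got {mass}")
    # round-half-away-from-zero for positive mass == floor(m + 0.5)
    import math

    return mass - math.floor(mass + 0.5)


def _load_table() -> dict[str, ElementRecord]:
    table: dict[str, ElementRecord] = {}
    text = (
        resources.files("homolseries").joinpath("data/elements.tsv").read_text()
    )
    for line in text.splitlines()[1:]:
        if not line.strip():
            continue
        symbol, mass_s = line.split("\t")
        mass = float(mass_s)
        table[symbol] = ElementRecord(symbol, mass, mass_defect(mass))
    return table


_TABLE: dict[str, ElementRecord] | None = None


def element_table() -> dict[str, ElementRecord]:
    """The bundled table of lightest-isotope exact masses."""
    global _TABLE
    if _TABLE is None:
        _TABLE = _load_table()
    return _TABLE


def _lookup(symbol: str) -> ElementRecord:
    try:
        return element_table()[symbol]
    except KeyError:
        known = ", ".join(sorted(element_table()))
        raise KeyError(
            f"unknown element symbol {symbol!r}; known: {known}"
        ) from None


def gamma_bounds(elements: Iterable[str]) -> GammaBounds:
    """Defect-per-mass slope bounds over an element set.

    For each element the ratio mass_defect / lightest_isotope_mass is
    formed; gamma_min and gamma_max are the minimum and maximum of those
    ratios.  Over {C,H,N,O,S,Cl,Br} this yields about (-0.0010, 0.0078),
    set by 79Br and 1H respectively.
    """
    symbols = list(elements)
    if not symbols:
        raise ValueError("element set must be non-empty")
    ratios = [
        _lookup(s).mass_defect / _lookup(s).lightest_isotope_mass
        for s in symbols
    ]
    return GammaBounds(min(ratios), max(ratios))


_FORMULA_RE = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(formula: str) -> dict[str, int]:
    """Parse a Hill-style formula string like ``C2H4O`` into counts."""
    counts: dict[str, int] = {}
    pos = 0
    for m in _FORMULA_RE.finditer(formula):
        if not m.group(0):
            continue
        if m.start() != pos:
            raise ValueError(f"cannot parse formula {formula!r}")
        pos = m.end()
        counts[m.group(1)] = counts.get(m.group(1), 0) + int(m.group(2) or 1)
    if pos != len(formula) or not counts:
        raise ValueError(f"cannot parse formula {formula!r}")
    return counts


def unit_mass(formula: Mapping[str, int] | str, charge: int = 1) -> float:
    """Exact Δm/z (Th) of a repeating chemical unit at charge ``charge``.

    Monoisotopic (lightest-isotope) masses are summed over the formula
    and divided by the charge, e.g. CH2 -> 14.016 Th at z=1 and
    7.008 Th at z=2.
    """
    if isinstance(formula, str):
        formula = parse_formula(formula)
    if charge < 1:
        raise ValueError(f"charge must be >= 1, got {charge}")
    if not formula or all(c < 1 for c in formula.values()):
        raise ValueError("formula must contain at least one atom")
    total = 0.0
    for symbol, count in formula.items():
        if count < 0:
            raise ValueError(f"negative count for {symbol}")
        total += count * _lookup(symbol).lightest_isotope_mass
    return total / charge
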