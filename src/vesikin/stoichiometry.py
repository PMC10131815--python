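"""Mass-to-copy-number conversions and per-unit stoichiometry.

Everything here is mole arithmetic: copies = mass / MW * N_A, copies per
particle/cell/EV = total copies / entity count, translation yield = protein
copies per mRNA copy.  Copy counts are kept as reals (they are estimates
from bulk mass); rounding to integers happens only at display.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple

__all__ = [
    "AVOGADRO",
    "ENTITIES",
    "CopyCount",
    "PerUnitCopies",
    "mass_to_copies",
    "copies_to_mass",
    "per_unit_copies",
    "translation_yield",
    "fold_ratio",
    "normalize_per_weight",
    "round_sig",
]

#: Avogadro constant, exact 2019 SI value, per mol.
AVOGADRO = 6.02214076e23

#: Closed set of entity labels a copy count may refer to.
ENTITIES = frozenset({"mRNA", "protein", "particle", "cell", "EV"})


@dataclass(frozen=True)
class CopyCount:
    """A molecule count attached to an entity label."""

    copies: float
    entity: str = "mRNA"

    def __post_init__(self) -> None:
        if self.entity not in ENTITIES:
            raise ValueError(f"unknown entity {self.entity!r}; expected one of {sorted(ENTITIES)}")
        if self.copies < 0:
            raise ValueError(f"copies must be non-negative, got {self.copies}")


class PerUnitCopies(NamedTuple):
    """Copies per unit, both at full precision and rounded for display."""

    value: float
    nearest: int


def _copies_of(x: CopyCount | float) -> float:
    return x.copies if isinstance(x, CopyCount) else float(x)


def mass_to_copies(mass_g: float, mw_g_per_mol: float, entity: str = "mRNA") -> CopyCount:
    """Convert a mass in grams to a molecule count: mass / MW * N_A."""
    if mw_g_per_mol <= 0:
        raise ValueError(f"molecular weight must be positive, got {mw_g_per_mol}")
    if mass_g < 0:
        raise ValueError(f"mass must be non-negative, got {mass_g}")
    return CopyCount(copies=mass_g / mw_g_per_mol * AVOGADRO, entity=entity)


def copies_to_mass(copies: CopyCount | float, mw_g_per_mol: float) -> float:
    """Exact inverse of :func:`mass_to_copies`; returns grams."""
    if mw_g_per_mol <= 0:
        raise ValueError(f"molecular weight must be positive, got {mw_g_per_mol}")
    return _copies_of(copies) / AVOGADRO * mw_g_per_mol


def per_unit_copies(total: CopyCount | float, units: float) -> PerUnitCopies:
    """Total copies divided by an entity count (particles, cells or EVs)."""
    if units <= 0:
        raise ValueError(f"unit count must be positive, got {units}")
    value = _copies_of(total) / units
    return PerUnitCopies(value=value, nearest=round(value))


def translation_yield(protein: CopyCount | float, mrna: CopyCount | float) -> float:
    """Protein copies produced per mRNA copy delivered (dimensionless)."""
    if isinstance(protein, CopyCount) and protein.entity != "protein":
        raise ValueError(f"numerator entity must be 'protein', got {protein.entity!r}")
    if isinstance(mrna, CopyCount) and mrna.entity != "mRNA":
        raise ValueError(f"denominator entity must be 'mRNA', got {mrna.entity!r}")
    m = _copies_of(mrna)
    if m <= 0:
        raise ValueError("mRNA copy count must be positive")
    return _copies_of(protein) / m


def fold_ratio(a: float, b: float) -> float:
    """Fold difference a / b between two per-unit copy numbers."""
    if b <= 0:
        raise ValueError(f"denominator must be positive, got {b}")
    return a / b


def normalize_per_weight(amount: float, weight_g: float) -> float:
    """Normalize a concentration (e.g. pg/mL) to tissue weight in grams."""
    if weight_g <= 0:
        raise ValueError(f"weight must be positive, got {weight_g}")
    return amount / weight_g


def round_sig(x: float, digits: int = 2) -> float:
    """Round to a number of significant figures (display helper)."""
    if x == 0:
        return 0.0
    return round(x, digits - 1 - int(math.floor(math.log10(abs(x)))))
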