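"""Species registry, elemental bookkeeping and unit conversions.

All chemistry in the package is expressed over a small fixed basis of aqueous
species.  Element counts are used for reaction balancing; pinned molar masses
(g/mol) are used for mg/l <-> mol/l conversions.  Sulfide is carried as total
dissolved S(-II) on an H2S basis, biomass as the conventional cell formula
C5H7O2N.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

ELEMENTS = ("C", "H", "O", "N", "S")

_FORMULA_RE = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(formula: str) -> dict[str, int]:
    """Parse a simple molecular formula like ``C5H7O2N`` into element counts."""
    counts: dict[str, int] = {}
    pos = 0
    for m in _FORMULA_RE.finditer(formula):
        if not m.group(0):
            continue
        if m.start() != pos:
            raise ValueError(f"cannot parse formula {formula!r}")
        pos = m.end()
        el, n = m.group(1), int(m.group(2) or 1)
        if el not in ELEMENTS:
            raise ValueError(f"unknown element {el!r} in formula {formula!r}")
        counts[el] = counts.get(el, 0) + n
    if pos != len(formula):
        raise ValueError(f"cannot parse formula {formula!r}")
    return counts


@dataclass(frozen=True)
class Species:
    name: str
    formula: str
    charge: int
    molar_mass: float  # g/mol, pinned table value
    elements: dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        object.__setattr__(self, "elements", parse_formula(self.formula))


#: Canonical species basis.  Molar masses are the conventional tabulated
#: values used to convert the experimental mg/l scales.
SPECIES: dict[str, Species] = {
    s.name: s
    for s in [
        Species("lactate", "C3H5O3", -1, 89.07),
        Species("sulfate", "SO4", -2, 96.06),
        Species("sulfide", "H2S", 0, 34.08),
        Species("sulfur", "S", 0, 32.06),
        Species("nitrate", "NO3", -1, 62.00),
        Species("nitrite", "NO2", -1, 46.01),
        Species("ammonium", "NH4", +1, 18.04),
        Species("dinitrogen", "N2", 0, 28.01),
        Species("biomass", "C5H7O2N", 0, 113.1),
        Species("co2", "CO2", 0, 44.01),
        Species("water", "H2O", 0, 18.02),
        Species("proton", "H", +1, 1.008),
    ]
}

#: Species whose concentrations are integrated in time.  Water, protons and
#: CO2 are treated as buffered/non-limiting (no pH or carbonate speciation).
DYNAMIC_SPECIES = (
    "lactate",
    "sulfate",
    "sulfide",
    "sulfur",
    "nitrate",
    "nitrite",
    "ammonium",
    "dinitrogen",
)


class UnknownSpeciesError(KeyError):
    """Raised when a species has no registered elemental composition."""


def species(name: str) -> Species:
    try:
        return SPECIES[name]
    except KeyError:
        raise UnknownSpeciesError(name) from None


def mg_per_l_to_mol_per_l(value: float, name: str) -> float:
    return value / 1000.0 / species(name).molar_mass


def mol_per_l_to_mg_per_l(value: float, name: str) -> float:
    return value * 1000.0 * species(name).molar_mass


def to_mol_per_l(value: float, unit: str, name: str | None = None) -> float:
    """Convert ``value`` in ``unit`` ('mg/l', 'mM' or 'mol/l') to mol/l."""
    if unit == "mol/l":
        return value
    if unit == "mM":
        return value * 1e-3
    if unit == "mg/l":
        if name is None:
            raise ValueError("mg/l conversion needs a species name")
        return mg_per_l_to_mol_per_l(value, name)
    raise ValueError(f"unknown unit {unit!r}")


def from_mol_per_l(value: float, unit: str, name: str | None = None) -> float:
    if unit == "mol/l":
        return value
    if unit == "mM":
        return value * 1e3
    if unit == "mg/l":
        if name is None:
            raise ValueError("mg/l conversion needs a species name")
        return mol_per_l_to_mg_per_l(value, name)
    raise ValueError(f"unknown unit {unit!r}")
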