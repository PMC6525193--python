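"""Bioenergetic construction of microbial community reactions.

Each community's overall growth reaction is assembled from three
electron-equivalent half-reactions — an electron donor, an electron acceptor
and a cell-synthesis half-reaction — with the donor's electrons split between
energy generation (fraction ``fe``, routed to the acceptor) and cell synthesis
(fraction ``fs = 1 - fe``, routed to biomass C5H7O2N with ammonium as the
nitrogen source).  Writing every half-reaction per one electron equivalent
makes the overall stoichiometry a simple weighted sum, and guarantees element
and charge balance by construction.

The inventory below covers the sulfur and nitrogen cycle arms needed for
souring and nitrate treatment: lactate oxidation (12 e-eq/mol), sulfate
reduction to sulfide (8), nitrate to nitrite (2), nitrite to ammonium (6,
DNRA) or to N2 (3, denitrification), and the three sulfide/sulfur oxidation
arms (8, 2 and 6 e-eq/mol).

Communities pair into *groups* A-F, each a (nitrate-step, nitrite-step) pair
sharing one electron donor; admissible community *scenarios* combine groups
within one nitrate-reduction pathway family (DNRA: A-D; denitrification:
E-F), with the constraint that sulfur oxidation (group D) requires the
sulfide-to-sulfur pair (group C) that produces its substrate.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from fractions import Fraction

from .chem import ELEMENTS, species

BALANCE_TOL = 1e-8


class BalanceError(ValueError):
    """A reaction's element/charge bookkeeping does not close."""


# ---------------------------------------------------------------------------
# Half-reactions
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class HalfReaction:
    """A redox (or synthesis) half-reaction written per 1 electron equivalent.

    ``stoich`` is stored in the *reduction* direction (the half-reaction
    accepting one electron): products positive, reactants negative.  The
    electron itself is implicit, so a balanced half-reaction has zero element
    residuals and a net charge of -1.  Donor half-reactions are reversed when
    combined into an overall reaction.
    """

    id: str
    role: str  # "donor" | "acceptor" | "synthesis"
    stoich: dict[str, Fraction]
    e_eq_per_mole: int  # electron equivalents per mole of the reference species
    reference_species: str

    def __post_init__(self):
        if self.role not in ("donor", "acceptor", "synthesis"):
            raise ValueError(f"bad role {self.role!r}")
        if self.e_eq_per_mole <= 0:
            raise ValueError("e_eq_per_mole must be > 0")
        res = half_reaction_residuals(self)
        bad = {k: float(v) for k, v in res.items() if abs(v) > BALANCE_TOL}
        if bad:
            raise BalanceError(f"half-reaction {self.id}: residuals {bad}")


def half_reaction_residuals(hr: HalfReaction) -> dict[str, float]:
    """Element residuals plus charge residual (charge must net to -1)."""
    res = {el: 0.0 for el in ELEMENTS}
    charge = 0.0
    for name, coeff in hr.stoich.items():
        sp = species(name)
        for el, n in sp.elements.items():
            res[el] += float(coeff) * n
        charge += float(coeff) * sp.charge
    res["charge"] = charge + 1.0  # one electron consumed on the reactant side
    return res


def _fr(n, d=1) -> Fraction:
    return Fraction(n, d)


#: Half-reaction inventory in standard electron-equivalent form.
HALF_REACTIONS: dict[str, HalfReaction] = {
    hr.id: hr
    for hr in [
        # --- donors (stored as reductions; reversed on use) ---
        HalfReaction(
            "lactate_oxidation",
            "donor",
            {
                "co2": _fr(-1, 4),
                "proton": _fr(-11, 12),
                "lactate": _fr(1, 12),
                "water": _fr(1, 4),
            },
            12,
            "lactate",
        ),
        HalfReaction(
            "sulfide_to_sulfate",
            "donor",
            {
                "sulfate": _fr(-1, 8),
                "proton": _fr(-5, 4),
                "sulfide": _fr(1, 8),
                "water": _fr(1, 2),
            },
            8,
            "sulfide",
        ),
        HalfReaction(
            "sulfide_to_sulfur",
            "donor",
            {"sulfur": _fr(-1, 2), "proton": _fr(-1), "sulfide": _fr(1, 2)},
            2,
            "sulfide",
        ),
        HalfReaction(
            "sulfur_to_sulfate",
            "donor",
            {
                "sulfate": _fr(-1, 6),
                "proton": _fr(-4, 3),
                "sulfur": _fr(1, 6),
                "water": _fr(2, 3),
            },
            6,
            "sulfur",
        ),
        # --- acceptors ---
        HalfReaction(
            "sulfate_reduction",
            "acceptor",
            {
                "sulfate": _fr(-1, 8),
                "proton": _fr(-5, 4),
                "sulfide": _fr(1, 8),
                "water": _fr(1, 2),
            },
            8,
            "sulfate",
        ),
        HalfReaction(
            "nitrate_to_nitrite",
            "acceptor",
            {
                "nitrate": _fr(-1, 2),
                "proton": _fr(-1),
                "nitrite": _fr(1, 2),
                "water": _fr(1, 2),
            },
            2,
            "nitrate",
        ),
        HalfReaction(
            "nitrite_to_ammonium",
            "acceptor",
            {
                "nitrite": _fr(-1, 6),
                "proton": _fr(-4, 3),
                "ammonium": _fr(1, 6),
                "water": _fr(1, 3),
            },
            6,
            "nitrite",
        ),
        HalfReaction(
            "nitrite_to_n2",
            "acceptor",
            {
                "nitrite": _fr(-1, 3),
                "proton": _fr(-4, 3),
                "dinitrogen": _fr(1, 6),
                "water": _fr(2, 3),
            },
            3,
            "nitrite",
        ),
        # --- cell synthesis (CO2 carbon, ammonium nitrogen) ---
        HalfReaction(
            "cell_synthesis",
            "synthesis",
            {
                "co2": _fr(-1, 4),
                "ammonium": _fr(-1, 20),
                "proton": _fr(-19, 20),
                "biomass": _fr(1, 20),
                "water": _fr(2, 5),
            },
            20,
            "biomass",
        ),
    ]
}


# ---------------------------------------------------------------------------
# Overall community reactions
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CommunityReaction:
    """A balanced overall growth reaction, normalized to 1 mol biomass.

    ``stoich`` maps species to signed coefficients (products positive) per
    mole of biomass synthesized; for the no-synthesis limit ``fe = 1`` the
    normalization is per mole of donor instead and the biomass coefficient
    is zero.  ``inhibitor`` names the species whose product inhibition enters
    this community's rate law (nitrite for SRB), if any.
    """

    name: str
    donor_species: str
    acceptor_species: str
    fe: float
    stoich: dict[str, float]
    donor_id: str = ""
    acceptor_id: str = ""
    inhibitor: str | None = None

    @property
    def fs(self) -> float:
        return 1.0 - self.fe


def combine_half_reactions(
    donor: HalfReaction,
    acceptor: HalfReaction,
    synthesis: HalfReaction,
    fe: float,
    name: str = "",
    inhibitor: str | None = None,
) -> CommunityReaction:
    """Combine donor/acceptor/synthesis half-reactions with energy fraction fe.

    Per electron equivalent released by the (reversed) donor, a fraction
    ``fe`` is passed to the acceptor and ``fs = 1 - fe`` to synthesis.  The
    result is renormalized to 1 mol biomass (or 1 mol donor when ``fe = 1``).
    """
    if donor.role != "donor":
        raise ValueError(f"{donor.id} is not a donor half-reaction")
    if acceptor.role != "acceptor":
        raise ValueError(f"{acceptor.id} is not an acceptor half-reaction")
    if synthesis.role != "synthesis":
        raise ValueError(f"{synthesis.id} is not a synthesis half-reaction")
    if not 0.0 < fe <= 1.0:
        raise ValueError(f"fe must be in (0, 1], got {fe}")
    fs = 1.0 - fe

    net: dict[str, float] = {}

    def add(stoich, weight):
        for sp, c in stoich.items():
            net[sp] = net.get(sp, 0.0) + weight * float(c)

    add(acceptor.stoich, fe)
    add(synthesis.stoich, fs)
    add(donor.stoich, -1.0)  # reverse the donor reduction

    if fs > 0.0:
        scale = 1.0 / net["biomass"]  # = e_eq(synthesis) / fs
    else:
        scale = -1.0 / net[donor.reference_species]  # per mole donor
    stoich = {
        sp: c * scale for sp, c in net.items() if abs(c * scale) > 1e-12
    }

    rxn = CommunityReaction(
        name=name or f"{donor.id}+{acceptor.id}(fe={fe:g})",
        donor_species=donor.reference_species,
        acceptor_species=acceptor.reference_species,
        fe=fe,
        stoich=stoich,
        donor_id=donor.id,
        acceptor_id=acceptor.id,
        inhibitor=inhibitor,
    )
    residuals = check_balance(rxn)
    bad = {k: v for k, v in residuals.items() if abs(v) > BALANCE_TOL}
    if bad:  # pragma: no cover - construction guarantees balance
        raise BalanceError(f"{rxn.name}: residuals {bad}")
    return rxn


def check_balance(rxn: CommunityReaction) -> dict[str, float]:
    """Per-element residuals plus charge residual of an overall reaction."""
    res = {el: 0.0 for el in ELEMENTS}
    charge = 0.0
    for name, coeff in rxn.stoich.items():
        sp = species(name)
        for el, n in sp.elements.items():
            res[el] += coeff * n
        charge += coeff * sp.charge
    res["charge"] = charge
    return res


def stoich_yield(rxn: CommunityReaction, species_a: str, species_b: str) -> float:
    """|coefficient(a) / coefficient(b)| — the mol/mol yield of a per b."""
    try:
        ca = rxn.stoich[species_a]
        cb = rxn.stoich[species_b]
    except KeyError as e:
        raise KeyError(f"species {e.args[0]!r} not in reaction {rxn.name}") from None
    return abs(ca / cb)


# ---------------------------------------------------------------------------
# Community inventory, groups and scenarios
# ---------------------------------------------------------------------------

#: Energy electron fractions pinned so the overall stoichiometry reproduces
#: the canonical yields of the SRB and NRSOB reactions (e.g. 12*0.8499/8 =
#: 1.2748 mol sulfate per mol lactate for SRB).
DEFAULT_FE = {
    "SRB": 0.8499,
    "NRSOB1": 0.8623,
    "NRSOB2": 0.8656,
}
FALLBACK_FE = 0.86

#: (donor id, acceptor id) per community.  One SRB plus ten nitrate/nitrite
#: reducer communities; the nitrate steps of groups A/E and B/F are shared.
COMMUNITY_SPECS: dict[str, tuple[str, str]] = {
    "SRB": ("lactate_oxidation", "sulfate_reduction"),
    "NRB1": ("lactate_oxidation", "nitrate_to_nitrite"),
    "NRB2": ("lactate_oxidation", "nitrite_to_ammonium"),
    "NRB3": ("lactate_oxidation", "nitrite_to_n2"),
    "NRSOB1": ("sulfide_to_sulfate", "nitrate_to_nitrite"),
    "NRSOB2": ("sulfide_to_sulfate", "nitrite_to_ammonium"),
    "NRSOB3": ("sulfide_to_sulfate", "nitrite_to_n2"),
    "NRSOB4": ("sulfide_to_sulfur", "nitrate_to_nitrite"),
    "NRSOB5": ("sulfide_to_sulfur", "nitrite_to_ammonium"),
    "NRSOB6": ("sulfur_to_sulfate", "nitrate_to_nitrite"),
    "NRSOB7": ("sulfur_to_sulfate", "nitrite_to_ammonium"),
}


def build_communities(
    fe_overrides: dict[str, float] | None = None,
) -> dict[str, CommunityReaction]:
    """Build the full community reaction inventory (SRB + 10 N reducers)."""
    fe_map = dict(DEFAULT_FE)
    if fe_overrides:
        fe_map.update(fe_overrides)
    out = {}
    for name, (donor_id, acceptor_id) in COMMUNITY_SPECS.items():
        out[name] = combine_half_reactions(
            HALF_REACTIONS[donor_id],
            HALF_REACTIONS[acceptor_id],
            HALF_REACTIONS["cell_synthesis"],
            fe=fe_map.get(name, FALLBACK_FE),
            name=name,
            inhibitor="nitrite" if name == "SRB" else None,
        )
    return out


@dataclass(frozen=True)
class Group:
    """A (nitrate step, nitrite step) community pair sharing one donor."""

    label: str
    nitrate_step: str
    nitrite_step: str
    trophic_mode: str  # heterotrophic | autotrophic
    pathway: str  # DNRA | denitrification
    sulfur_role: str  # none | sulfide->sulfate | sulfide->S0 | S0->sulfate


GROUPS: dict[str, Group] = {
    "A": Group("A", "NRB1", "NRB2", "heterotrophic", "DNRA", "none"),
    "B": Group("B", "NRSOB1", "NRSOB2", "autotrophic", "DNRA", "sulfide->sulfate"),
    "C": Group("C", "NRSOB4", "NRSOB5", "autotrophic", "DNRA", "sulfide->S0"),
    "D": Group("D", "NRSOB6", "NRSOB7", "autotrophic", "DNRA", "S0->sulfate"),
    "E": Group("E", "NRB1", "NRB3", "heterotrophic", "denitrification", "none"),
    "F": Group("F", "NRSOB1", "NRSOB3", "autotrophic", "denitrification", "sulfide->sulfate"),
}

DNRA_GROUPS = ("A", "B", "C", "D")
DENITRIFICATION_GROUPS = ("E", "F")


@dataclass(frozen=True)
class Scenario:
    """An admissible set of groups; SRB is always part of the network."""

    groups: tuple[str, ...]
    includes_srb: bool = True
    admissible: bool = True
    fit_result: object | None = field(default=None, compare=False)

    @property
    def label(self) -> str:
        return "+".join(self.groups)

    def communities(self) -> list[str]:
        """Ordered, de-duplicated community names (SRB first)."""
        names = ["SRB"]
        for g in self.groups:
            grp = GROUPS[g]
            for step in (grp.nitrate_step, grp.nitrite_step):
                if step not in names:
                    names.append(step)
        return names


def is_admissible(labels: tuple[str, ...]) -> bool:
    """Same pathway family, non-empty, and D only in the presence of C."""
    if not labels:
        return False
    fams = {GROUPS[g].pathway for g in labels}
    if len(fams) != 1:
        return False
    if "D" in labels and "C" not in labels:
        return False
    return True


def enumerate_scenarios(families: tuple[str, ...] = ("DNRA", "denitrification")) -> list[Scenario]:
    """All admissible scenarios in canonical (lexicographic) order.

    DNRA: non-empty subsets of {A,B,C,D} with D implying C (11 scenarios);
    denitrification: non-empty subsets of {E,F} (3 scenarios).
    """
    out: list[Scenario] = []
    pools = {"DNRA": DNRA_GROUPS, "denitrification": DENITRIFICATION_GROUPS}
    for fam in ("DNRA", "denitrification"):
        if fam not in families:
            continue
        pool = pools[fam]
        subsets = []
        for r in range(1, len(pool) + 1):
            subsets.extend(itertools.combinations(pool, r))
        subsets.sort()
        for labels in subsets:
            if is_admissible(labels):
                out.append(Scenario(groups=labels))
    return out


def with_fit_result(scenario: Scenario, fit_result) -> Scenario:
    return replace(scenario, fit_result=fit_result)
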