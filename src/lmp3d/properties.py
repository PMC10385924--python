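"""Atomic property table used for element inference and descriptor weighting.

Values are fixed constants so that descriptor output is reproducible:
Bondi van der Waals radii, vdW volume = (4/3)*pi*r^3, Pauling
electronegativity, static dipole polarizabilities, NIST first ionization
potentials, and electron affinities.  United-atom (UA) carbon pseudo-atoms
(CH, CH2, CH3, CH4) inherit carbon's radius/volume/electronic properties but
keep their own mass, which is how coarse-grained force fields such as
TraPPE-UA report them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .errors import UnknownMass


@dataclass(frozen=True)
class ElementProperties:
    """Per-element constants: masses g/mol, radii A, volumes A^3,
    polarizability A^3, ionization potential and electron affinity eV."""

    mass: float
    vdw_radius: float
    vdw_volume: float
    electronegativity: float
    polarizability: float
    ionization_potential: float
    electron_affinity: float
    covalent_radius: float


def _vol(r: float) -> float:
    return 4.0 / 3.0 * math.pi * r**3


#            mass      rvdw   en     pol    ip      ea      rcov
_RAW = {
    "H":  (1.008,   1.20, 2.20, 0.667, 13.598, 0.754, 0.31),
    "C":  (12.011,  1.70, 2.55, 1.760, 11.260, 1.262, 0.76),
    "N":  (14.007,  1.55, 3.04, 1.100, 14.534, -0.070, 0.71),
    "O":  (15.999,  1.52, 3.44, 0.802, 13.618, 1.461, 0.66),
    "F":  (18.998,  1.47, 3.98, 0.557, 17.423, 3.401, 0.57),
    "P":  (30.974,  1.80, 2.19, 3.630, 10.487, 0.746, 1.07),
    "S":  (32.060,  1.80, 2.58, 2.900, 10.360, 2.077, 1.05),
    "Cl": (35.450,  1.75, 3.16, 2.180, 12.968, 3.613, 1.02),
    "Br": (79.904,  1.85, 3.19, 3.050, 11.814, 3.364, 1.20),
    "I":  (126.904, 1.98, 2.66, 5.350, 10.451, 3.059, 1.39),
}

# UA carbon pseudo-atoms: carbon properties, their own mass.
_UA_MASSES = {"CH": 13.019, "CH2": 14.027, "CH3": 15.035, "CH4": 16.043}

PROPERTY_TABLE: dict[str, ElementProperties] = {}
for _key, (_m, _r, _en, _pol, _ip, _ea, _rc) in _RAW.items():
    PROPERTY_TABLE[_key] = ElementProperties(
        mass=_m,
        vdw_radius=_r,
        vdw_volume=_vol(_r),
        electronegativity=_en,
        polarizability=_pol,
        ionization_potential=_ip,
        electron_affinity=_ea,
        covalent_radius=_rc,
    )
for _key, _m in _UA_MASSES.items():
    _c = PROPERTY_TABLE["C"]
    PROPERTY_TABLE[_key] = ElementProperties(
        mass=_m,
        vdw_radius=_c.vdw_radius,
        vdw_volume=_c.vdw_volume,
        electronegativity=_c.electronegativity,
        polarizability=_c.polarizability,
        ionization_potential=_c.ionization_potential,
        electron_affinity=_c.electron_affinity,
        covalent_radius=_c.covalent_radius,
    )

#: Mass-match tolerance in g/mol for element inference.
MASS_TOLERANCE = 0.5

#: Scaled-property names, in the canonical order used by descriptor modules.
PROPERTY_NAMES = (
    "mass",
    "vdw_volume",
    "electronegativity",
    "polarizability",
    "ionization_potential",
    "electron_affinity",
)


def infer_element(mass: float) -> str:
    """Map an atomic mass (g/mol) to an element key or a UA pseudo-element.

    The nearest table entry (element or UA carbon) within 0.5 g/mol wins;
    UA masses such as CH2 (14.027) lie within tolerance of real elements
    (N, 14.007), so nearest-match rather than first-match keeps the mapping
    unambiguous.  Raises :class:`UnknownMass` when nothing is close enough.
    """
    if mass <= 0:
        raise UnknownMass(mass)
    best_key, best_diff = None, MASS_TOLERANCE
    for key, props in PROPERTY_TABLE.items():
        diff = abs(mass - props.mass)
        if diff <= best_diff:
            best_key, best_diff = key, diff
    if best_key is None:
        raise UnknownMass(mass)
    return best_key


def carbon_scaled(property_name: str, element: str) -> float:
    """Property of `element` divided by carbon's value (descriptor convention)."""
    value = getattr(PROPERTY_TABLE[element], property_name)
    return value / getattr(PROPERTY_TABLE["C"], property_name)


def property_table_csv() -> str:
    """CSV rendering of the full table for inspection alongside outputs."""
    header = (
        "element,mass,vdw_radius,vdw_volume,electronegativity,"
        "polarizability,ionization_potential,electron_affinity,covalent_radius"
    )
    rows = [header]
    for key, p in PROPERTY_TABLE.items():
        rows.append(
            f"{key},{p.mass},{p.vdw_radius},{p.vdw_volume:.6f},"
            f"{p.electronegativity},{p.polarizability},"
            f"{p.ionization_potential},{p.electron_affinity},{p.covalent_radius}"
        )
    return "\n".join(rows) + "\n"
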