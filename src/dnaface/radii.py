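"""Group-radius assignment for accessible-surface calculations.

The default set uses united-atom ("group") radii of the Chothia style:
heavy atoms carry a class radius that subsumes their bonded hydrogens, so
hydrogens themselves contribute no surface.  Carbons are split into
tetrahedral (CH/CH2/CH3 groups) and trigonal (aromatic / carbonyl / sp2)
classes; N, O, S and P each carry a single class radius.  The set name is
recorded so downstream reports can echo their parameter provenance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from . import chem
from .core import Structure

#: class radii (Angstrom) for the default group-radius set
_CHOTHIA_CLASS_RADII = {
    "C_tetrahedral": 1.87,
    "C_trigonal": 1.76,
    "N": 1.65,
    "O": 1.40,
    "S": 1.85,
    "P": 1.80,
    "H": 1.00,
}

_ELEMENT_FALLBACK = {
    "C": 1.87, "N": 1.65, "O": 1.40, "S": 1.85, "P": 1.80, "H": 1.00,
    "F": 1.47, "CL": 1.77, "BR": 1.85, "I": 1.98,
}


@dataclass
class RadiusSet:
    """Maps (residue name, atom name) -> group radius with element fallback."""

    set_name: str = "chothia_group"
    class_radii: dict[str, float] = field(
        default_factory=lambda: dict(_CHOTHIA_CLASS_RADII))
    element_fallback: dict[str, float] = field(
        default_factory=lambda: dict(_ELEMENT_FALLBACK))

    def lookup(self, res_name: str, atom_name: str, element: str) -> float:
        element = element.upper()
        if element == "H":
            return self.class_radii["H"]
        if element == "C":
            key = ("C_trigonal" if chem.is_trigonal_carbon(res_name, atom_name)
                   else "C_tetrahedral")
            return self.class_radii[key]
        if element in self.class_radii:
            return self.class_radii[element]
        if element in self.element_fallback:
            warnings.warn(
                f"atom {atom_name} of {res_name}: element-fallback radius "
                f"used for element {element}", stacklevel=2)
            return self.element_fallback[element]
        raise KeyError(
            f"no radius for element {element!r} (atom {atom_name} of {res_name})")


DEFAULT_RADII = RadiusSet()


def assign_radii(structure: Structure,
                 radius_set: RadiusSet = DEFAULT_RADII) -> Structure:
    """Attach a group radius to every atom, in place; returns the structure.

    Idempotent; unknown residues fall back to element radii.  Raises
    ``KeyError`` for an element absent from both tables.
    """
    for _, res, atom in structure.iter_atoms():
        atom.radius = radius_set.lookup(res.name, atom.name, atom.element)
    return structure
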