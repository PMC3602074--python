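"""Idealized polar-hydrogen placement on donor heavy atoms.

Hydrogens are placed with template geometry: N-H 1.01 A, O-H 0.96 A;
ring/backbone N-H along the in-plane bisector of the two heavy neighbours,
sp2 amino groups (Arg NH1/NH2, Asn/Gln amides, base N4/N6/N2) in the plane
of the parent's substituents at 120 deg, hydroxyls and the Lys ammonium
staggered anti to the grandparent atom.  Existing hydrogens are counted and
preserved, which makes the operation idempotent.
"""

from __future__ import annotations

import warnings

import numpy as np

from . import chem
from .core import Atom, Residue, Structure

NH_LENGTH = 1.01
OH_LENGTH = 0.96

#: hydrogen names per (residue, donor heavy atom)
HYDROGEN_NAMES: dict[tuple[str, str], list[str]] = {
    ("*", "N"): ["H"],
    ("ARG", "NE"): ["HE"],
    ("ARG", "NH1"): ["HH11", "HH12"],
    ("ARG", "NH2"): ["HH21", "HH22"],
    ("LYS", "NZ"): ["HZ1", "HZ2", "HZ3"],
    ("SER", "OG"): ["HG"],
    ("THR", "OG1"): ["HG1"],
    ("TYR", "OH"): ["HH"],
    ("ASN", "ND2"): ["HD21", "HD22"],
    ("GLN", "NE2"): ["HE21", "HE22"],
    ("HIS", "ND1"): ["HD1"],
    ("HIS", "NE2"): ["HE2"],
    ("TRP", "NE1"): ["HE1"],
    ("DA", "N6"): ["H61", "H62"],
    ("DC", "N4"): ["H41", "H42"],
    ("DG", "N1"): ["H1"],
    ("DG", "N2"): ["H21", "H22"],
    ("DT", "N3"): ["H3"],
}

_BOND_MAX = 1.75          # heavy-atom covalent bond cutoff, Angstrom
_H_BOND_MAX = 1.25        # H attached to parent within this distance

_TET = np.deg2rad(109.5)


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n < 1e-9:
        raise ValueError("degenerate geometry")
    return v / n


def _any_perpendicular(u: np.ndarray) -> np.ndarray:
    ref = np.array([1.0, 0.0, 0.0])
    if abs(u @ ref) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    return _unit(np.cross(u, ref))


def _heavy_neighbours(atom: Atom, heavy: list[Atom]) -> list[Atom]:
    out = []
    for other in heavy:
        if other is atom:
            continue
        if np.linalg.norm(other.coords - atom.coords) < _BOND_MAX:
            out.append(other)
    return out


def _ideal_positions(d: np.ndarray, neighbours: list[np.ndarray],
                     grand: np.ndarray | None, k: int,
                     length: float) -> list[np.ndarray]:
    """All k ideal hydrogen sites for a donor at ``d``."""
    if len(neighbours) >= 2:
        # ring / backbone nitrogen: in-plane bisector
        bis = -(_unit(neighbours[0] - d) + _unit(neighbours[1] - d))
        return [d + length * _unit(bis)]
    e1 = _unit(neighbours[0] - d)
    if grand is not None:
        p = (grand - neighbours[0])
        p = p - (p @ e1) * e1
        v = -_unit(p) if np.linalg.norm(p) > 1e-6 else _any_perpendicular(e1)
    else:
        v = _any_perpendicular(e1)
    w = np.cross(e1, v)
    if k == 2:
        # sp2 amino group in the (e1, v) plane at +-120 deg from the parent
        c, s = -0.5, np.sqrt(3.0) / 2.0
        return [d + length * (c * e1 + s * v), d + length * (c * e1 - s * v)]
    # sp3: one (hydroxyl, anti) or three (ammonium, staggered) positions
    c, s = np.cos(np.pi - _TET), np.sin(np.pi - _TET)
    sites = []
    for phi in (0.0, 2 * np.pi / 3, 4 * np.pi / 3)[:k]:
        sites.append(d + length * (-c * e1 + s * (np.cos(phi) * v
                                                  + np.sin(phi) * w)))
    return sites


def add_polar_hydrogens(structure: Structure) -> Structure:
    """Place idealized hydrogens on every donor heavy atom, in place.

    Pre-existing hydrogens are kept; donors whose geometric context is
    incomplete (missing bonded neighbour) are skipped with a warning.
    """
    max_serial = max((a.serial for _, _, a in structure.iter_atoms()),
                     default=0)
    for chain in structure.chains:
        prev_res: Residue | None = None
        for res in chain.residues:
            heavy = [a for a in res.atoms if not a.is_hydrogen]
            # peptide bond: previous C is a neighbour of this backbone N
            extra: list[Atom] = []
            if (res.kind == "protein" and prev_res is not None
                    and prev_res.has_atom("C")):
                extra.append(prev_res.atom("C"))
            hydrogens = [a for a in res.atoms if a.is_hydrogen]
            for donor in heavy:
                k = chem.donor_hydrogen_count(res.name, donor.name)
                if k == 0:
                    continue
                attached = [h for h in hydrogens
                            if np.linalg.norm(h.coords - donor.coords)
                            < _H_BOND_MAX]
                if len(attached) >= k:
                    continue
                neigh = _heavy_neighbours(donor, heavy + extra)
                if not neigh:
                    warnings.warn(
                        f"{res.label}:{donor.name}: no bonded heavy "
                        "neighbour, hydrogen placement skipped", stacklevel=2)
                    continue
                grand = None
                gneigh = _heavy_neighbours(neigh[0], heavy + extra)
                for g in gneigh:
                    if g is not donor:
                        grand = g.coords
                        break
                length = OH_LENGTH if donor.element == "O" else NH_LENGTH
                try:
                    sites = _ideal_positions(
                        donor.coords, [n.coords for n in neigh], grand, k,
                        length)
                except ValueError:
                    warnings.warn(
                        f"{res.label}:{donor.name}: degenerate geometry, "
                        "hydrogen placement skipped", stacklevel=2)
                    continue
                names = list(HYDROGEN_NAMES.get(
                    (res.name, donor.name),
                    HYDROGEN_NAMES.get(("*", donor.name), [])))
                if not names:
                    continue
                used = {h.name for h in hydrogens}
                # keep the ideal sites farthest from already-present hydrogens
                if attached:
                    sites.sort(key=lambda s: -min(
                        np.linalg.norm(s - h.coords) for h in attached))
                n_new = k - len(attached)
                free_names = [n for n in names if n not in used]
                for site, name in zip(sites[:n_new], free_names):
                    max_serial += 1
                    h = Atom(serial=max_serial, name=name, element="H",
                             coords=site, radius=1.0, is_hydrogen=True)
                    res.atoms.append(h)
                    hydrogens.append(h)
            prev_res = res
    return structure
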