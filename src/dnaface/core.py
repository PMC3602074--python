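"""Molecular data model: Atom / Residue / Chain / Structure.

A deliberately small hierarchy tailored to interface analysis: coordinates
in Angstrom, group radii attached directly to atoms, and a ``kind`` label
(protein / nucleic / other) on every residue so that the two sides of a
protein-DNA complex can be partitioned without external bookkeeping.
Atoms are referenced in reports as ``CHAIN:RESNAMESEQ:ATOMNAME``
(e.g. ``A:ARG337:CZ``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterator

import numpy as np

from . import chem


@dataclass
class Atom:
    serial: int
    name: str
    element: str
    coords: np.ndarray          # shape (3,), Angstrom
    radius: float = 0.0         # group radius, Angstrom; 0.0 = unassigned
    is_hydrogen: bool = False
    alt_loc: str = ""
    occupancy: float = 1.0

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,):
            raise ValueError(f"atom {self.name}: coords must be a 3-vector")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.name}: non-finite coordinates")

    def copy(self) -> "Atom":
        return replace(self, coords=self.coords.copy())


@dataclass
class Residue:
    name: str
    seq_id: int
    atoms: list[Atom] = field(default_factory=list)

    @property
    def kind(self) -> str:
        return chem.residue_kind(self.name)

    def atom(self, name: str) -> Atom:
        for a in self.atoms:
            if a.name == name:
                return a
        raise KeyError(f"{self.name}{self.seq_id} has no atom {name!r}")

    def has_atom(self, name: str) -> bool:
        return any(a.name == name for a in self.atoms)

    @property
    def label(self) -> str:
        return f"{self.name}{self.seq_id}"


@dataclass
class Chain:
    chain_id: str
    residues: list[Residue] = field(default_factory=list)

    def __iter__(self) -> Iterator[Residue]:
        return iter(self.residues)


@dataclass
class Structure:
    chains: list[Chain] = field(default_factory=list)
    title: str = ""

    def __iter__(self) -> Iterator[Chain]:
        return iter(self.chains)

    # -- traversal helpers -------------------------------------------------

    def iter_atoms(self) -> Iterator[tuple[Chain, Residue, Atom]]:
        for chain in self.chains:
            for res in chain.residues:
                for atom in res.atoms:
                    yield chain, res, atom

    def atom_count(self) -> int:
        return sum(1 for _ in self.iter_atoms())

    def chain(self, chain_id: str) -> Chain:
        for c in self.chains:
            if c.chain_id == chain_id:
                return c
        raise KeyError(f"no chain {chain_id!r}")

    def coords(self, include_hydrogens: bool = True) -> np.ndarray:
        pts = [a.coords for _, _, a in self.iter_atoms()
               if include_hydrogens or not a.is_hydrogen]
        return np.array(pts, dtype=float).reshape(-1, 3)

    def copy(self) -> "Structure":
        return Structure(
            chains=[Chain(c.chain_id,
                          [Residue(r.name, r.seq_id, [a.copy() for a in r.atoms])
                           for r in c.residues])
                    for c in self.chains],
            title=self.title,
        )

    def transformed(self, rotation: np.ndarray, translation: np.ndarray,
                    center: np.ndarray | None = None) -> "Structure":
        """Rigid transform: ``x -> R (x - c) + c + t`` (c defaults to 0)."""
        rotation = np.asarray(rotation, dtype=float)
        translation = np.asarray(translation, dtype=float)
        c = np.zeros(3) if center is None else np.asarray(center, dtype=float)
        out = self.copy()
        for _, _, atom in out.iter_atoms():
            atom.coords = rotation @ (atom.coords - c) + c + translation
        return out


def atom_ref(chain: Chain, res: Residue, atom: Atom) -> str:
    """Report notation for one atom, e.g. ``A:ARG337:CZ``."""
    return f"{chain.chain_id}:{res.label}:{atom.name}"


def guess_element(atom: Atom, res_name: str = "") -> str:
    return chem.element_from_name(atom.name, res_name)


def min_cross_distance(a: Structure, b: Structure,
                       heavy_only: bool = True) -> float:
    """Closest heavy-atom approach between two structures, Angstrom."""
    xa = a.coords(include_hydrogens=not heavy_only)
    xb = b.coords(include_hydrogens=not heavy_only)
    if len(xa) == 0 or len(xb) == 0:
        return math.inf
    from scipy.spatial import cKDTree

    return float(cKDTree(xa).query(xb, k=1)[0].min())
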