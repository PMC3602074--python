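"""Intermolecular contact detection and interaction-table parsing.

A hydrophobic contact is a cross-side carbon-carbon pair closer than the
cutoff (default 4.5 A, strict inequality).  A hydrogen bond is a
donor-H...acceptor triple whose H...acceptor distance and D-H...A angle
meet the configured criteria; the donor side (protein vs nucleic) is the
chain kind of the donor heavy atom.  The default geometric criteria are
permissive (H...A <= 2.6 A, angle >= 80 deg) so that every literature-style
contact list with distances up to ~2.5 A and angles down to ~86 deg is
admitted; both are configuration, not constants.

The module also parses TSV transcriptions of published interaction tables
(hydrophobic-contact lists keyed by residue with comma-separated atom
names, and H-bond lists in ``CHAIN:RES:ATOM`` notation with distance and
angle columns).
"""

from __future__ import annotations

import math
import re
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from . import chem
from .core import Structure, atom_ref
from .interface import InterfacePartition


@dataclass
class ContactCriteria:
    hydrophobic_cutoff: float = 4.5     # A, strict less-than
    hbond_h_acceptor_max: float = 2.6   # A
    hbond_dha_min_angle: float = 80.0   # degrees

    def __post_init__(self) -> None:
        if self.hydrophobic_cutoff <= 0 or self.hbond_h_acceptor_max <= 0:
            raise ValueError("distance criteria must be positive")
        if not 0 < self.hbond_dha_min_angle <= 180:
            raise ValueError("angle criterion must lie in (0, 180]")


@dataclass
class HydrophobicContact:
    protein_atom: str      # "A:ARG337:CZ" notation
    nucleic_atom: str
    distance: float

    @property
    def protein_residue(self) -> str:
        return self.protein_atom.split(":")[1]

    @property
    def nucleic_residue(self) -> str:
        return self.nucleic_atom.split(":")[1]


@dataclass
class HBond:
    donor: str             # donor heavy atom ref
    hydrogen: str
    acceptor: str
    h_acceptor_distance: float
    dha_angle: float
    donor_side: str        # "protein" | "nucleic"


def _side_atoms(structure: Structure, chain_ids: set[str]):
    out = []
    for chain, res, atom in structure.iter_atoms():
        if chain.chain_id in chain_ids:
            out.append((chain, res, atom))
    return out


def _check_partition(structure: Structure, partition: InterfacePartition):
    present = {c.chain_id for c in structure.chains}
    missing = (set(partition.side_a) | set(partition.side_b)) - present
    if missing:
        raise KeyError(f"partition references missing chain(s): {sorted(missing)}")


def find_hydrophobic_contacts(
        structure: Structure, partition: InterfacePartition,
        criteria: ContactCriteria | None = None) -> list[HydrophobicContact]:
    """All cross-side C-C pairs at distance < cutoff (strict).

    Sorted by protein residue (chain, seq) then nucleic residue then atom
    names; intra-side pairs are never reported.
    """
    criteria = criteria or ContactCriteria()
    _check_partition(structure, partition)
    carbons_a = [(c, r, a) for c, r, a in
                 _side_atoms(structure, set(partition.side_a))
                 if a.element == "C"]
    carbons_b = [(c, r, a) for c, r, a in
                 _side_atoms(structure, set(partition.side_b))
                 if a.element == "C"]
    if not carbons_a or not carbons_b:
        return []
    xa = np.array([a.coords for _, _, a in carbons_a])
    xb = np.array([a.coords for _, _, a in carbons_b])
    tree = cKDTree(xb)
    contacts = []
    for i, (ca, ra, aa) in enumerate(carbons_a):
        for j in tree.query_ball_point(xa[i], criteria.hydrophobic_cutoff):
            d = float(np.linalg.norm(xa[i] - xb[j]))
            if d < criteria.hydrophobic_cutoff:
                cb, rb, ab = carbons_b[j]
                contacts.append(HydrophobicContact(
                    protein_atom=atom_ref(ca, ra, aa),
                    nucleic_atom=atom_ref(cb, rb, ab),
                    distance=round(d, 2)))
    contacts.sort(key=lambda c: (c.protein_atom.split(":")[0],
                                 _res_sort_key(c.protein_residue),
                                 _res_sort_key(c.nucleic_residue),
                                 c.protein_atom, c.nucleic_atom))
    return contacts


def _res_sort_key(label: str) -> tuple[int, str]:
    m = re.match(r"([A-Z]+)(-?\d+)", label)
    return (int(m.group(2)), m.group(1)) if m else (0, label)


def _hydrogen_parent(res, hydrogen):
    """Donor heavy atom a hydrogen rides on (nearest N/O within 1.25 A)."""
    best, best_d = None, 1.25
    for a in res.atoms:
        if a.is_hydrogen or a.element not in ("N", "O"):
            continue
        d = float(np.linalg.norm(a.coords - hydrogen.coords))
        if d < best_d:
            best, best_d = a, d
    return best


def find_hbonds(structure: Structure, partition: InterfacePartition,
                criteria: ContactCriteria | None = None) -> list[HBond]:
    """All cross-side donor-H...acceptor triples meeting the criteria.

    Requires explicit polar hydrogens (see ``add_polar_hydrogens``);
    geometry is reported to 2 decimals (distance) and 1 decimal (angle).
    """
    criteria = criteria or ContactCriteria()
    _check_partition(structure, partition)

    def donors(chain_ids):
        out = []
        for chain, res, atom in _side_atoms(structure, chain_ids):
            if not atom.is_hydrogen:
                continue
            parent = _hydrogen_parent(res, atom)
            if parent is None:
                continue
            if chem.donor_hydrogen_count(res.name, parent.name) > 0:
                out.append((chain, res, parent, atom))
        return out

    def acceptors(chain_ids):
        return [(c, r, a) for c, r, a in _side_atoms(structure, chain_ids)
                if not a.is_hydrogen and chem.is_acceptor(r.name, a.name)]

    sides = (set(partition.side_a), set(partition.side_b))
    bonds: list[HBond] = []
    any_h = False
    for don_side, acc_side in (sides, sides[::-1]):
        ds = donors(don_side)
        any_h = any_h or bool(ds)
        acc = acceptors(acc_side)
        if not ds or not acc:
            continue
        xacc = np.array([a.coords for _, _, a in acc])
        tree = cKDTree(xacc)
        for chain, res, parent, h in ds:
            for j in tree.query_ball_point(h.coords,
                                           criteria.hbond_h_acceptor_max):
                ca, ra, aa = acc[j]
                d = float(np.linalg.norm(h.coords - aa.coords))
                if d > criteria.hbond_h_acceptor_max:
                    continue
                v1 = parent.coords - h.coords
                v2 = aa.coords - h.coords
                cosang = float(v1 @ v2 /
                               (np.linalg.norm(v1) * np.linalg.norm(v2)))
                angle = math.degrees(math.acos(max(-1.0, min(1.0, cosang))))
                if angle < criteria.hbond_dha_min_angle:
                    continue
                bonds.append(HBond(
                    donor=atom_ref(chain, res, parent),
                    hydrogen=atom_ref(chain, res, h),
                    acceptor=atom_ref(ca, ra, aa),
                    h_acceptor_distance=round(d, 2),
                    dha_angle=round(angle, 1),
                    donor_side=res.kind if res.kind in ("protein", "nucleic")
                    else "protein"))
    if not any_h:
        warnings.warn("no donor hydrogens found on either side; did you run "
                      "add_polar_hydrogens?", stacklevel=2)
    bonds.sort(key=lambda b: (b.donor, b.acceptor))
    return bonds


def classify_donor_side(hbond: HBond) -> str:
    """Side (protein / nucleic) of the donor heavy atom's residue."""
    res_label = hbond.donor.split(":")[1]
    name = re.match(r"([A-Za-z]+)", res_label).group(1)
    kind = chem.residue_kind(_normalize_nuc(name))
    return kind if kind in ("protein", "nucleic") else "protein"


# --------------------------------------------------------------------------
# Interaction-table fixtures
# --------------------------------------------------------------------------

def _normalize_atom(name: str) -> str:
    """Normalize primed-atom spellings: ``O5*``/``O5′`` -> ``O5'``."""
    return name.strip().replace("*", "'").replace("′", "'")


def _normalize_nuc(name: str) -> str:
    name = name.strip().upper()
    if name in {"A", "C", "G", "T"}:
        return "D" + name
    return name


def _split_ref(ref: str) -> tuple[str, str, int, str]:
    """``A:LYS367:HZ1`` -> (chain, resname, seq, atom)."""
    parts = ref.strip().split(":")
    if len(parts) != 3:
        raise ValueError(f"malformed atom reference {ref!r}")
    chain, res_label, atom = parts
    m = re.match(r"([A-Za-z]+)(-?\d+)$", res_label.strip())
    if not m:
        raise ValueError(f"malformed residue label in {ref!r}")
    return (chain.strip(), _normalize_nuc(m.group(1)), int(m.group(2)),
            _normalize_atom(atom))


def parse_interaction_table(path, kind: str) -> pd.DataFrame:
    """Parse a TSV transcription of a published interaction table.

    ``kind="hydrophobic"``: columns amino_acid, protein_atoms, nucleotide,
    nucleotide_atoms; comma-separated atom cells are preserved as lists
    (no pair expansion).  ``kind="hbond"``: columns donor, acceptor,
    distance, angle; atom references are split into chain/residue/atom
    parts and primed-atom spellings normalized.
    """
    df = pd.read_csv(path, sep="\t", comment="#", skipinitialspace=True)
    df.columns = [c.strip().lower() for c in df.columns]
    if kind == "hydrophobic":
        required = {"amino_acid", "protein_atoms", "nucleotide",
                    "nucleotide_atoms"}
        if not required <= set(df.columns):
            raise ValueError(f"{path}: expected columns {sorted(required)}")
        for col in ("protein_atoms", "nucleotide_atoms"):
            df[col] = df[col].map(
                lambda s: [_normalize_atom(x) for x in str(s).split(",") if x.strip()])
        df["amino_acid"] = df["amino_acid"].str.strip().str.upper()
        df["nucleotide"] = df["nucleotide"].map(
            lambda s: _normalize_nuc(re.match(r"([A-Za-z]+)", str(s).strip()).group(1))
            + re.search(r"(-?\d+)", str(s)).group(1))
        return df
    if kind == "hbond":
        required = {"donor", "acceptor", "distance", "angle"}
        if not required <= set(df.columns):
            raise ValueError(f"{path}: expected columns {sorted(required)}")
        for i, row in df.iterrows():
            try:
                for col in ("donor", "acceptor"):
                    ch, rn, sq, at = _split_ref(str(row[col]))
                    df.at[i, col] = f"{ch}:{rn}{sq}:{at}"
                df.at[i, "distance"] = float(row["distance"])
                df.at[i, "angle"] = float(row["angle"])
            except (ValueError, AttributeError) as exc:
                raise ValueError(f"{path}: malformed row {i + 2}: {exc}") from exc
        df["donor_side"] = [
            classify_donor_side(HBond(d, "", a, 0, 0, ""))
            for d, a in zip(df["donor"], df["acceptor"])]
        return df
    raise ValueError(f"unknown table kind {kind!r}")


def distinct_protein_residues(df: pd.DataFrame, kind: str) -> set[str]:
    """Distinct protein residues participating in a parsed table.

    For H-bond tables both donor- and acceptor-side protein atoms count as
    participation.
    """
    if kind == "hydrophobic":
        return set(df["amino_acid"])
    out = set()
    for col in ("donor", "acceptor"):
        for ref in df[col]:
            _ch, res_atom = ref.split(":", 1)
            res_label = res_atom.split(":")[0]
            name = re.match(r"([A-Z]+)", res_label).group(1)
            if chem.residue_kind(name) == "protein":
                out.add(res_label)
    return out
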