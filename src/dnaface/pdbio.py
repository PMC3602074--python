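"""PDB reading and writing.

Parsing is delegated to :mod:`gemmi`; the result is converted into the
package's own :class:`~dnaface.core.Structure` hierarchy.  Alternate
locations are resolved to the highest-occupancy conformer (ties broken by
first occurrence) and waters are dropped by default, since the solvent is
modelled implicitly by the SASA probe.  Writing emits fixed-column ATOM
records with three-decimal coordinates and a TER record after each chain.
"""

from __future__ import annotations

import os

import gemmi

from . import chem
from .core import Atom, Chain, Residue, Structure


def read_pdb(path: str | os.PathLike, model_index: int = 0,
             keep_waters: bool = False) -> Structure:
    """Read one model of a PDB file into a :class:`Structure`.

    Parameters
    ----------
    path:
        PDB file containing ATOM/HETATM records.
    model_index:
        0-based model to extract (NMR-style multi-model files).
    keep_waters:
        Retain HOH/WAT residues (excluded by default).
    """
    try:
        doc = gemmi.read_pdb(str(path))
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"cannot parse PDB file {path}: {exc}") from exc
    if model_index >= len(doc):
        raise ValueError(
            f"model_index {model_index} out of range: file has {len(doc)} model(s)")
    model = doc[model_index]

    structure = Structure(title=doc.name or "")
    for gchain in model:
        chain = Chain(chain_id=(gchain.name or "A")[:1] or "A")
        for gres in gchain:
            name = gres.name.strip()
            if not keep_waters and name in chem.WATER_NAMES:
                continue
            res = Residue(name=name, seq_id=gres.seqid.num)
            best: dict[str, Atom] = {}
            for gatom in gres:
                el = gatom.element.name if gatom.element else ""
                if not el or el == "X":
                    el = chem.element_from_name(gatom.name, name)
                atom = Atom(
                    serial=gatom.serial,
                    name=gatom.name.strip(),
                    element=el.upper(),
                    coords=[gatom.pos.x, gatom.pos.y, gatom.pos.z],
                    is_hydrogen=(el.upper() == "H"),
                    alt_loc=gatom.altloc if gatom.altloc != "\x00" else "",
                    occupancy=gatom.occ,
                )
                prev = best.get(atom.name)
                if prev is None or atom.occupancy > prev.occupancy:
                    best[atom.name] = atom
            res.atoms = list(best.values())
            for a in res.atoms:
                a.alt_loc = ""
            if res.atoms:
                chain.residues.append(res)
        if chain.residues:
            structure.chains.append(chain)
    if not structure.chains:
        raise ValueError(f"no atoms found in {path} (model {model_index})")
    return structure


def _format_atom_name(name: str, element: str) -> str:
    # PDB column rule: single-letter elements start in column 14 unless the
    # name is 4 characters long.
    if len(name) >= 4:
        return name[:4]
    if len(element) == 1:
        return f" {name:<3s}"
    return f"{name:<4s}"


def write_pdb(structure: Structure, path: str | os.PathLike) -> str:
    """Write a structure as fixed-column PDB; returns the path written."""
    if not structure.chains or structure.atom_count() == 0:
        raise ValueError("refusing to write an empty structure")
    lines: list[str] = []
    if structure.title:
        lines.append(f"TITLE     {structure.title[:70]}")
    serial = 0
    for chain in structure.chains:
        last_res = None
        for res in chain.residues:
            for atom in res.atoms:
                serial += 1
                x, y, z = atom.coords
                for v in (x, y, z):
                    if abs(v) >= 10000:
                        raise ValueError(
                            f"coordinate {v:.1f} overflows the PDB field "
                            f"(atom {atom.name} of {res.label})")
                lines.append(
                    "ATOM  {serial:5d} {name} {res:>3s} {ch}{seq:4d}    "
                    "{x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{b:6.2f}          "
                    "{el:>2s}".format(
                        serial=serial % 100000,
                        name=_format_atom_name(atom.name, atom.element),
                        res=res.name[:3],
                        ch=chain.chain_id[:1],
                        seq=res.seq_id,
                        x=x, y=y, z=z,
                        occ=atom.occupancy, b=0.0,
                        el=atom.element[:2],
                    ))
            last_res = res
        if last_res is not None:
            serial += 1
            lines.append(
                "TER   {serial:5d}      {res:>3s} {ch}{seq:4d}".format(
                    serial=serial % 100000, res=last_res.name[:3],
                    ch=chain.chain_id[:1], seq=last_res.seq_id))
    lines.append("END")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
    return str(path)
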