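"""Residue and atom chemistry dictionaries.

Classification tables used across the package: residue kinds, Watson-Crick
complements, hydrogen-bond donor/acceptor atom names and the trigonal-carbon
table that drives group-radius assignment.  Residue and atom naming follows
the PDB convention (primed sugar atoms written with an ASCII apostrophe,
e.g. ``C3'``).
"""

from __future__ import annotations

AMINO_ACIDS = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}

DEOXYNUCLEOTIDES = {"DA", "DC", "DG", "DT"}

#: 1-letter -> 3-letter amino-acid codes
AA_1TO3 = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}

#: Watson-Crick complement on the 1-letter DNA alphabet
DNA_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

WATER_NAMES = {"HOH", "WAT", "DOD"}


def residue_kind(name: str) -> str:
    """Classify a residue name as ``protein``, ``nucleic`` or ``other``."""
    name = name.strip().upper()
    if name in AMINO_ACIDS:
        return "protein"
    if name in DEOXYNUCLEOTIDES or name in {"A", "C", "G", "T", "U", "DU"}:
        return "nucleic"
    return "other"


# --------------------------------------------------------------------------
# Hydrogen-bond chemistry.
#
# Donor entries map a heavy-atom name to the number of hydrogens it carries
# in the protonation state modelled here (neutral His tautomer ND1-H; Lys
# and Arg charged).  Acceptors are lone-pair bearing N/O sites.
# --------------------------------------------------------------------------

#: protein donors: residue -> {heavy atom name: n_hydrogens}
PROTEIN_DONORS: dict[str, dict[str, int]] = {
    "*backbone*": {"N": 1},          # amide N-H (absent on proline)
    "ARG": {"NE": 1, "NH1": 2, "NH2": 2},
    "LYS": {"NZ": 3},
    "SER": {"OG": 1},
    "THR": {"OG1": 1},
    "TYR": {"OH": 1},
    "ASN": {"ND2": 2},
    "GLN": {"NE2": 2},
    "HIS": {"ND1": 1, "NE2": 1},
    "TRP": {"NE1": 1},
}

#: protein acceptors: residue -> atom names (backbone O handled separately).
#: Arg NE is included for the neutral tautomer, which appears as an
#: acceptor in published protein-DNA contact lists.
PROTEIN_ACCEPTORS: dict[str, set[str]] = {
    "*backbone*": {"O", "OXT"},
    "ARG": {"NE"},
    "ASP": {"OD1", "OD2"},
    "GLU": {"OE1", "OE2"},
    "ASN": {"OD1"},
    "GLN": {"OE1"},
    "SER": {"OG"},
    "THR": {"OG1"},
    "TYR": {"OH"},
    "HIS": {"ND1", "NE2"},
}

#: DNA donors (base exocyclic amino / imino groups)
DNA_DONORS: dict[str, dict[str, int]] = {
    "DA": {"N6": 2},
    "DC": {"N4": 2},
    "DG": {"N1": 1, "N2": 2},
    "DT": {"N3": 1},
}

#: DNA acceptors: phosphate / sugar oxygens common to all, plus base sites
_DNA_BACKBONE_ACCEPTORS = {"OP1", "OP2", "O3'", "O5'", "O4'"}
DNA_ACCEPTORS: dict[str, set[str]] = {
    "DA": _DNA_BACKBONE_ACCEPTORS | {"N1", "N3", "N7"},
    "DC": _DNA_BACKBONE_ACCEPTORS | {"O2", "N3"},
    "DG": _DNA_BACKBONE_ACCEPTORS | {"O6", "N3", "N7"},
    "DT": _DNA_BACKBONE_ACCEPTORS | {"O2", "O4"},
}


def donor_hydrogen_count(res_name: str, atom_name: str) -> int:
    """Number of hydrogens carried by a donor heavy atom, 0 if not a donor."""
    res_name = res_name.strip().upper()
    if res_name in AMINO_ACIDS:
        if atom_name == "N" and res_name != "PRO":
            return 1
        return PROTEIN_DONORS.get(res_name, {}).get(atom_name, 0)
    if res_name in DEOXYNUCLEOTIDES:
        return DNA_DONORS.get(res_name, {}).get(atom_name, 0)
    return 0


def is_acceptor(res_name: str, atom_name: str) -> bool:
    res_name = res_name.strip().upper()
    if res_name in AMINO_ACIDS:
        if atom_name in PROTEIN_ACCEPTORS["*backbone*"]:
            return True
        return atom_name in PROTEIN_ACCEPTORS.get(res_name, set())
    if res_name in DEOXYNUCLEOTIDES:
        return atom_name in DNA_ACCEPTORS.get(res_name, set())
    return False


# --------------------------------------------------------------------------
# Trigonal (sp2 / aromatic) carbons, used by the group-radius table.  Any
# carbon not listed here is treated as tetrahedral.  The backbone carbonyl
# carbon "C" is trigonal in every amino acid.
# --------------------------------------------------------------------------

TRIGONAL_CARBONS: dict[str, set[str]] = {
    "ARG": {"CZ"},
    "ASP": {"CG"},
    "ASN": {"CG"},
    "GLU": {"CD"},
    "GLN": {"CD"},
    "HIS": {"CG", "CD2", "CE1"},
    "PHE": {"CG", "CD1", "CD2", "CE1", "CE2", "CZ"},
    "TYR": {"CG", "CD1", "CD2", "CE1", "CE2", "CZ"},
    "TRP": {"CG", "CD1", "CD2", "CE2", "CE3", "CZ2", "CZ3", "CH2"},
    # base ring and exocyclic sp2 carbons
    "DA": {"C2", "C4", "C5", "C6", "C8"},
    "DG": {"C2", "C4", "C5", "C6", "C8"},
    "DC": {"C2", "C4", "C5", "C6"},
    "DT": {"C2", "C4", "C5", "C6"},
}


def is_trigonal_carbon(res_name: str, atom_name: str) -> bool:
    res_name = res_name.strip().upper()
    if res_name in AMINO_ACIDS and atom_name == "C":
        return True
    return atom_name in TRIGONAL_CARBONS.get(res_name, set())


def element_from_name(atom_name: str, res_name: str = "") -> str:
    """Infer the chemical element from a PDB atom name.

    Handles the standard-residue vocabulary: two-letter elements occur in
    standard amino acids / deoxynucleotides only for none of the atoms
    (P, S are single letters), so the first alphabetic character decides,
    except names beginning with a digit (e.g. ``1H5'``) which are hydrogens.
    """
    name = atom_name.strip()
    if not name:
        raise ValueError("empty atom name")
    if name[0].isdigit():
        return name[1].upper()
    return name[0].upper()
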