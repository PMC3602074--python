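"""Structure model: PDB round-trips, radius assignment, polar hydrogens."""

import warnings

import numpy as np
import pytest

from dnaface import chem
from dnaface.core import Atom, Chain, Residue, Structure
from dnaface.hydrogens import add_polar_hydrogens
from dnaface.pdbio import read_pdb, write_pdb
from dnaface.radii import DEFAULT_RADII, assign_radii
from dnaface.synth import build_helix_peptide


def one_atom_structure():
    return Structure(chains=[Chain("A", [Residue("ALA", 1, [
        Atom(1, "CA", "C", [1.0, 2.0, 3.0])])])])


def test_write_then_read_single_atom(tmp_path):
    path = tmp_path / "one.pdb"
    write_pdb(one_atom_structure(), path)
    text = path.read_text().splitlines()
    assert text[0].startswith("ATOM")
    assert text[1].startswith("TER")
    assert text[2] == "END"
    back = read_pdb(path)
    assert len(back.chains) == 1
    res = back.chains[0].residues[0]
    assert (res.name, res.seq_id) == ("ALA", 1)
    np.testing.assert_allclose(res.atoms[0].coords, [1.0, 2.0, 3.0])


def test_round_trip_preserves_counts_names_coords(tmp_path):
    pep = build_helix_peptide("SYVRKN")
    path = tmp_path / "pep.pdb"
    write_pdb(pep, path)
    back = read_pdb(path)
    assert back.atom_count() == pep.atom_count()
    for (c1, r1, a1), (c2, r2, a2) in zip(pep.iter_atoms(),
                                          back.iter_atoms()):
        assert a1.name == a2.name
        assert r1.name == r2.name
        np.testing.assert_allclose(a1.coords, a2.coords, atol=5.1e-4)


def test_kind_partition_protein_vs_nucleic(tmp_path):
    from dnaface.dna import build_ssdna

    pep = build_helix_peptide("AY")
    dna = build_ssdna("ACG")
    merged = Structure(chains=pep.chains + dna.chains)
    kinds = {r.kind for c in merged.chains for r in c.residues}
    assert kinds == {"protein", "nucleic"}


def test_residue_name_right_justified(tmp_path):
    from dnaface.dna import build_ssdna

    path = tmp_path / "dna.pdb"
    write_pdb(build_ssdna("G"), path)
    line = path.read_text().splitlines()[1]
    assert line[17:20] == " DG"


def test_coordinate_overflow_rejected(tmp_path):
    s = one_atom_structure()
    s.chains[0].residues[0].atoms[0].coords = np.array([1e5, 0.0, 0.0])
    with pytest.raises(ValueError, match="overflow"):
        write_pdb(s, tmp_path / "bad.pdb")


def test_empty_structure_rejected(tmp_path):
    with pytest.raises(ValueError):
        write_pdb(Structure(chains=[]), tmp_path / "empty.pdb")
    (tmp_path / "none.pdb").write_text("END\n")
    with pytest.raises(ValueError):
        read_pdb(tmp_path / "none.pdb")


def test_altloc_resolved_to_highest_occupancy(tmp_path):
    lines = [
        "ATOM      1  CA AALA A   1       0.000   0.000   0.000  0.40  0.00           C",
        "ATOM      2  CA BALA A   1       1.000   0.000   0.000  0.60  0.00           C",
        "END",
    ]
    path = tmp_path / "alt.pdb"
    path.write_text("\n".join(lines) + "\n")
    s = read_pdb(path)
    res = s.chains[0].residues[0]
    assert len(res.atoms) == 1
    np.testing.assert_allclose(res.atoms[0].coords, [1.0, 0.0, 0.0])


def test_waters_dropped_by_default(tmp_path):
    lines = [
        "ATOM      1  CA  ALA A   1       0.000   0.000   0.000  1.00  0.00           C",
        "HETATM    2  O   HOH A   2       5.000   0.000   0.000  1.00  0.00           O",
        "END",
    ]
    path = tmp_path / "wat.pdb"
    path.write_text("\n".join(lines) + "\n")
    assert read_pdb(path).atom_count() == 1
    assert read_pdb(path, keep_waters=True).atom_count() == 2


# -- radii ------------------------------------------------------------------

AA_ATOMS = {
    "ALA": ["N", "CA", "C", "O", "CB"],
    "ARG": ["N", "CA", "C", "O", "CB", "CG", "CD", "NE", "CZ", "NH1", "NH2"],
    "ASN": ["N", "CA", "C", "O", "CB", "CG", "OD1", "ND2"],
    "ASP": ["N", "CA", "C", "O", "CB", "CG", "OD1", "OD2"],
    "CYS": ["N", "CA", "C", "O", "CB", "SG"],
    "GLN": ["N", "CA", "C", "O", "CB", "CG", "CD", "OE1", "NE2"],
    "GLU": ["N", "CA", "C", "O", "CB", "CG", "CD", "OE1", "OE2"],
    "GLY": ["N", "CA", "C", "O"],
    "HIS": ["N", "CA", "C", "O", "CB", "CG", "ND1", "CD2", "CE1", "NE2"],
    "ILE": ["N", "CA", "C", "O", "CB", "CG1", "CG2", "CD1"],
    "LEU": ["N", "CA", "C", "O", "CB", "CG", "CD1", "CD2"],
    "LYS": ["N", "CA", "C", "O", "CB", "CG", "CD", "CE", "NZ"],
    "MET": ["N", "CA", "C", "O", "CB", "CG", "SD", "CE"],
    "PHE": ["N", "CA", "C", "O", "CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ"],
    "PRO": ["N", "CA", "C", "O", "CB", "CG", "CD"],
    "SER": ["N", "CA", "C", "O", "CB", "OG"],
    "THR": ["N", "CA", "C", "O", "CB", "OG1", "CG2"],
    "TRP": ["N", "CA", "C", "O", "CB", "CG", "CD1", "CD2", "NE1", "CE2",
            "CE3", "CZ2", "CZ3", "CH2"],
    "TYR": ["N", "CA", "C", "O", "CB", "CG", "CD1", "CD2", "CE1", "CE2",
            "CZ", "OH"],
    "VAL": ["N", "CA", "C", "O", "CB", "CG1", "CG2"],
}
NUC_ATOMS = {
    "DA": ["P", "OP1", "OP2", "O5'", "C5'", "C4'", "O4'", "C3'", "O3'",
           "C2'", "C1'", "N9", "C8", "N7", "C5", "C6", "N6", "N1", "C2",
           "N3", "C4"],
    "DC": ["P", "OP1", "OP2", "O5'", "C5'", "C4'", "O4'", "C3'", "O3'",
           "C2'", "C1'", "N1", "C2", "O2", "N3", "C4", "N4", "C5", "C6"],
    "DG": ["P", "OP1", "OP2", "O5'", "C5'", "C4'", "O4'", "C3'", "O3'",
           "C2'", "C1'", "N9", "C8", "N7", "C5", "C6", "O6", "N1", "C2",
           "N2", "N3", "C4"],
    "DT": ["P", "OP1", "OP2", "O5'", "C5'", "C4'", "O4'", "C3'", "O3'",
           "C2'", "C1'", "N1", "C2", "O2", "N3", "C4", "O4", "C5", "C7",
           "C6"],
}


@pytest.mark.parametrize("res_name,atoms",
                         sorted(AA_ATOMS.items()) + sorted(NUC_ATOMS.items()))
def test_radius_table_total_over_standard_residues(res_name, atoms):
    """Every heavy atom of every standard residue resolves without fallback
    warnings, with a positive radius."""
    with warnings.catch_warnings():
        warnings.simplefilter("error")
        for name in atoms:
            r = DEFAULT_RADII.lookup(res_name, name,
                                     chem.element_from_name(name))
            assert r > 0


def test_specific_group_radii():
    assert DEFAULT_RADII.lookup("ALA", "CB", "C") == pytest.approx(1.87)
    assert DEFAULT_RADII.lookup("TYR", "CZ", "C") == pytest.approx(1.76)
    assert DEFAULT_RADII.lookup("DG", "P", "P") == pytest.approx(1.80)


def test_assign_radii_idempotent_and_fallback():
    s = one_atom_structure()
    s.chains[0].residues[0].atoms.append(Atom(2, "XX", "C", [3.0, 0, 0]))
    s.chains[0].residues[0].name = "XYZ"  # unknown residue -> element path
    assign_radii(s)
    first = [a.radius for _, _, a in s.iter_atoms()]
    assign_radii(s)
    assert [a.radius for _, _, a in s.iter_atoms()] == first
    assert all(r > 0 for r in first)


def test_unknown_element_raises():
    s = Structure(chains=[Chain("A", [Residue("XYZ", 1, [
        Atom(1, "QQ", "Q", [0.0, 0.0, 0.0])])])])
    with pytest.raises(KeyError):
        assign_radii(s)


# -- polar hydrogens --------------------------------------------------------

def test_hydrogens_on_parent_within_bond_range():
    pep = build_helix_peptide("SYVRKNAQW")
    found_any = False
    for _, res, a in pep.iter_atoms():
        if not a.is_hydrogen:
            continue
        found_any = True
        d = min(np.linalg.norm(a.coords - b.coords)
                for b in res.atoms
                if not b.is_hydrogen and b.element in ("N", "O"))
        assert 0.90 <= d <= 1.05
    assert found_any


def test_ser_hydroxyl_and_asn_amide_counts():
    pep = build_helix_peptide("SN")
    ser, asn = pep.chains[0].residues
    assert sum(a.name == "HG" for a in ser.atoms) == 1
    hg = ser.atom("HG")
    og = ser.atom("OG")
    assert np.linalg.norm(hg.coords - og.coords) == pytest.approx(0.96,
                                                                  abs=1e-6)
    assert {a.name for a in asn.atoms if a.is_hydrogen} >= {"HD21", "HD22"}


def test_existing_hydrogen_not_duplicated():
    pep = build_helix_peptide("K")
    lys = pep.chains[0].residues[0]
    hz = [a for a in lys.atoms if a.name.startswith("HZ")]
    assert len(hz) == 3
    add_polar_hydrogens(pep)
    hz_after = [a for a in lys.atoms if a.name.startswith("HZ")]
    assert len(hz_after) == 3


def test_dc_amino_hydrogens_in_base_plane():
    from dnaface.dna import build_ssdna

    dna = build_ssdna("C")
    res = dna.chains[0].residues[0]
    h41, h42 = res.atom("H41"), res.atom("H42")
    n4, c4 = res.atom("N4"), res.atom("C4")
    for h in (h41, h42):
        assert 0.90 <= np.linalg.norm(h.coords - n4.coords) <= 1.05
    # coplanarity with the base: H-N4-C4 span the amide plane
    ring = [res.atom(n).coords for n in ("N1", "C2", "N3", "C4", "C5", "C6")]
    ring = np.array(ring)
    centroid = ring.mean(0)
    normal = np.linalg.svd(ring - centroid)[2][2]
    for h in (h41, h42):
        assert abs((h.coords - centroid) @ normal) < 0.25
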