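"""Contact/H-bond detection and the published interaction-table fixtures."""

import numpy as np
import pytest

from dnaface import chem
from dnaface.contacts import (ContactCriteria, HBond, classify_donor_side,
                              distinct_protein_residues, find_hbonds,
                              find_hydrophobic_contacts,
                              parse_interaction_table)
from dnaface.core import Atom, Chain, Residue, Structure
from dnaface.interface import InterfacePartition

PARTITION = InterfacePartition(("A",), ("S",))


def pair_structure(atoms_a, atoms_b, res_a="ALA", res_b="DA"):
    """Two one-residue chains from (name, element, xyz) triples."""
    def mk(cid, rname, atoms):
        res = Residue(rname, 1)
        for i, (name, el, xyz) in enumerate(atoms):
            res.atoms.append(Atom(i + 1, name, el, np.asarray(xyz, float),
                                  radius=1.7, is_hydrogen=(el == "H")))
        return Chain(cid, [res])

    return Structure(chains=[mk("A", res_a, atoms_a), mk("S", res_b, atoms_b)])


@pytest.mark.parametrize("distance,expected", [(4.4, 1), (4.5, 0), (4.6, 0)])
def test_cutoff_is_strict_less_than(distance, expected):
    s = pair_structure([("CB", "C", [0, 0, 0])],
                       [("C2", "C", [distance, 0, 0])])
    assert len(find_hydrophobic_contacts(s, PARTITION)) == expected


def test_only_carbon_pairs_count():
    s = pair_structure([("CB", "C", [0, 0, 0])],
                       [("N3", "N", [3.0, 0, 0])])
    assert find_hydrophobic_contacts(s, PARTITION) == []


def test_intra_side_pairs_never_reported():
    s = pair_structure([("CB", "C", [0, 0, 0]), ("CG", "C", [1.5, 0, 0])],
                       [("C2", "C", [50, 0, 0])])
    assert find_hydrophobic_contacts(s, PARTITION) == []


def test_contact_records_use_report_notation():
    s = pair_structure([("CB", "C", [0, 0, 0])],
                       [("C2", "C", [4.0, 0, 0])])
    (c,) = find_hydrophobic_contacts(s, PARTITION)
    assert c.protein_atom == "A:ALA1:CB"
    assert c.nucleic_atom == "S:DA1:C2"
    assert c.distance == pytest.approx(4.0)


def ideal_hbond_structure(h_acc=2.0, bend=180.0):
    """Ser OG-HG ... O2(DT), collinear by default."""
    ang = np.radians(180.0 - bend)
    acc = [0.96 + h_acc * np.cos(ang), h_acc * np.sin(ang), 0.0]
    return pair_structure(
        [("OG", "O", [0, 0, 0]), ("HG", "H", [0.96, 0, 0])],
        [("O2", "O", acc)], res_a="SER", res_b="DT")


def test_collinear_hbond_detected():
    s = ideal_hbond_structure()
    (hb,) = find_hbonds(s, PARTITION)
    assert hb.donor == "A:SER1:OG"
    assert hb.acceptor == "S:DT1:O2"
    assert hb.h_acceptor_distance == pytest.approx(2.0, abs=0.01)
    assert hb.dha_angle == pytest.approx(180.0, abs=0.1)
    assert hb.donor_side == "protein"


def test_long_hbond_not_detected():
    assert find_hbonds(ideal_hbond_structure(h_acc=3.5), PARTITION) == []


def test_bent_hbond_rejected_by_angle():
    assert find_hbonds(ideal_hbond_structure(bend=60.0), PARTITION) == []
    assert len(find_hbonds(ideal_hbond_structure(bend=100.0),
                           PARTITION)) == 1


def test_no_hydrogens_warns_and_returns_empty():
    s = pair_structure([("OG", "O", [0, 0, 0])], [("O2", "O", [2.5, 0, 0])],
                       res_a="SER", res_b="DT")
    with pytest.warns(UserWarning, match="hydrogens"):
        assert find_hbonds(s, PARTITION) == []


def test_table2_row_geometry_reproduced():
    """A Lys ammonium donating to thymine O4 at the printed 1.67 A and
    129.8 deg is detected with matching rounded geometry."""
    d, ang = 1.67, 129.8
    theta = np.radians(180.0 - ang)
    acc = [1.01 + d * np.cos(theta), d * np.sin(theta), 0.0]
    s = pair_structure(
        [("NZ", "N", [0, 0, 0]), ("HZ1", "H", [1.01, 0, 0])],
        [("O4", "O", acc)], res_a="LYS", res_b="DT")
    (hb,) = find_hbonds(s, PARTITION)
    assert hb.h_acceptor_distance == pytest.approx(1.67, abs=0.005)
    assert hb.dha_angle == pytest.approx(129.8, abs=0.05)


def test_swapping_sides_mirrors_contacts(toy_complex):
    structure, _ = toy_complex
    fwd = find_hydrophobic_contacts(structure, PARTITION)
    rev = find_hydrophobic_contacts(structure, PARTITION.swapped())
    assert {(c.protein_atom, c.nucleic_atom, c.distance) for c in fwd} == \
        {(c.nucleic_atom, c.protein_atom, c.distance) for c in rev}


@pytest.mark.parametrize("fixture_name", ["toy_complex", "toy_complex_hb"])
def test_enumeration_equals_brute_force_manifest(fixture_name, request):
    structure, manifest = request.getfixturevalue(fixture_name)
    assert manifest.hydrophobic          # non-vacuous
    found = find_hydrophobic_contacts(structure, PARTITION)
    assert {(c.protein_atom, c.nucleic_atom, c.distance) for c in found} == \
        set(map(tuple, manifest.hydrophobic))
    bonds = find_hbonds(structure, PARTITION)
    assert {(b.donor, b.hydrogen, b.acceptor, b.h_acceptor_distance,
             b.dha_angle) for b in bonds} == set(map(tuple, manifest.hbonds))


def test_hbond_manifest_is_non_vacuous(toy_complex_hb):
    _structure, manifest = toy_complex_hb
    assert len(manifest.hbonds) >= 1


# -- donor-side classification ---------------------------------------------

def test_donor_side_from_table_notation():
    assert classify_donor_side(
        HBond("A:TYR224:OH", "A:TYR224:HH", "S:DG9:OP1", 2.18, 121.3,
              "")) == "protein"
    assert classify_donor_side(
        HBond("S:DC3:N4", "S:DC3:H42", "A:GLN335:OE1", 2.11, 130.1,
              "")) == "nucleic"


# -- packaged tables --------------------------------------------------------

def test_human_hbond_table_has_7_records_5_protein_donors(tables):
    df = parse_interaction_table(tables["human_hbond"], "hbond")
    assert len(df) == 7
    counts = df["donor_side"].value_counts().to_dict()
    assert counts == {"protein": 5, "nucleic": 2}


def test_mouse_hydrophobic_table_13_distinct_residues(tables):
    df = parse_interaction_table(tables["mouse_hydrophobic"], "hydrophobic")
    assert len(distinct_protein_residues(df, "hydrophobic")) == 13


def test_mouse_hbond_table_6_distinct_residues(tables):
    df = parse_interaction_table(tables["mouse_hbond"], "hbond")
    assert len(distinct_protein_residues(df, "hbond")) == 6


def test_star_spellings_normalized(tables):
    df = parse_interaction_table(tables["mouse_hbond"], "hbond")
    acceptors = set(df["acceptor"])
    assert "S:DC13:O5'" in acceptors
    assert "S:DC17:O3'" in acceptors          # bare "C17" normalized too
    assert not any("*" in a for a in acceptors)


def test_multi_atom_cells_preserved_unexpanded(tables):
    df = parse_interaction_table(tables["human_hydrophobic"], "hydrophobic")
    row = df[(df["amino_acid"] == "ARG337") & (df["nucleotide"] == "DG6")]
    assert row["protein_atoms"].iloc[0] == ["CB", "CZ"]
    assert row["nucleotide_atoms"].iloc[0] == ["C2", "C4", "C5", "C6"]


def test_table_atom_names_resolve_in_dictionaries(tables):
    """Every donor and acceptor atom in the H-bond fixtures is covered by
    the embedded donor/acceptor chemistry."""
    from dnaface.hydrogens import HYDROGEN_NAMES

    for key in ("human_hbond", "mouse_hbond"):
        df = parse_interaction_table(tables[key], "hbond")
        for ref in df["donor"]:
            _ch, res_atom = ref.split(":", 1)
            res_label, h_name = res_atom.split(":")
            res_name = "".join(c for c in res_label if c.isalpha())
            named = (HYDROGEN_NAMES.get((res_name, "")) or [])
            all_h = [h for (rn, _d), hs in HYDROGEN_NAMES.items()
                     if rn in (res_name, "*") for h in hs]
            assert h_name in all_h, ref
        for ref in df["acceptor"]:
            _ch, res_atom = ref.split(":", 1)
            res_label, a_name = res_atom.split(":")
            res_name = "".join(c for c in res_label if c.isalpha())
            assert chem.is_acceptor(res_name, a_name), ref


def test_malformed_table_row_is_an_error(tmp_path):
    bad = tmp_path / "bad.tsv"
    bad.write_text("donor\tacceptor\tdistance\tangle\n"
                   "A:LYS367:HZ1\tS:DT5:O4\t1.67\t129.8\n"
                   "not-a-ref\tS:DT5:O4\txx\t1.0\n")
    with pytest.raises(ValueError, match="row 3"):
        parse_interaction_table(bad, "hbond")


def test_criteria_admit_all_printed_rows(tables):
    """Default geometric criteria accept every published H-bond row
    (distances 1.67-2.48 A, minimum angle 86.1 deg)."""
    crit = ContactCriteria()
    for key in ("human_hbond", "mouse_hbond"):
        df = parse_interaction_table(tables[key], "hbond")
        assert (df["distance"] <= crit.hbond_h_acceptor_max).all()
        assert (df["angle"] >= crit.hbond_dha_min_angle).all()
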