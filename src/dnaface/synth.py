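"""Synthetic test structures with known ground truth.

Three generators:

* :func:`make_toy_complex` — an ideal alpha-helical peptide (phi -57,
  psi -47, full side chains from chemical-component ideal geometry)
  positioned against a built B-form ssDNA strand at a controlled
  closest-approach distance.  A ground-truth manifest of every cross-side
  C-C contact and donor-H...acceptor triple is computed by brute-force
  double loops at generation time, independently of the detection code
  it is used to test.

* :func:`make_pocket_fixture` — a pseudo-atom sphere cluster with a
  hemispherical surface pocket plus the complementary ball, with the
  embedding pose recorded; a shape-complementarity docking fixture.

* :func:`packaged_tables` — paths of the TSV transcriptions of the
  published human/mouse interaction tables, integrity-checked.

All generators are deterministic given their seed.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
from scipy.spatial.transform import Rotation

from . import chem
from .core import Atom, Chain, Residue, Structure
from .dna import build_ssdna
from .hydrogens import add_polar_hydrogens
from .radii import assign_radii

# ideal backbone geometry (lengths A, angles deg)
_N_CA, _CA_C, _C_N, _C_O = 1.458, 1.525, 1.329, 1.231
_ANG_N_CA_C, _ANG_CA_C_N, _ANG_C_N_CA, _ANG_CA_C_O = 111.2, 116.2, 121.7, 120.8
_PHI, _PSI, _OMEGA = -57.0, -47.0, 180.0

#: default toy peptide: donor/acceptor-rich residue types of the kind seen
#: at protein-DNA interfaces (Tyr, Val, Arg, Lys, Asn, Ser, Gln)
DEFAULT_PEPTIDE = "SYVRKNAQVRKY"


def _place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
                bond: float, angle: float, torsion: float) -> np.ndarray:
    """NeRF placement: the returned point D is bonded to ``c`` with bond
    angle b-c-D and dihedral a-b-c-D (degrees)."""
    ang, tor = math.radians(angle), math.radians(torsion)
    bc = c - b
    bc = bc / np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n = n / np.linalg.norm(n)
    m = np.cross(n, bc)
    return c + bond * (-bc * math.cos(ang)
                       + m * math.sin(ang) * math.cos(tor)
                       + n * math.sin(ang) * math.sin(tor))


def _kabsch(P: np.ndarray, Q: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares rotation R and translation t with R @ P_i + t ~ Q_i."""
    pc, qc = P.mean(0), Q.mean(0)
    H = (P - pc).T @ (Q - qc)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    return R, qc - R @ pc


def _ccd_residue(name: str):
    import biotite.structure.info as info

    return info.residue(name)


def build_helix_peptide(sequence: str, chain_id: str = "A") -> Structure:
    """Ideal alpha-helical peptide from a 1-letter sequence.

    Backbone by internal-coordinate chaining at phi -57 / psi -47 deg;
    side-chain heavy atoms grafted from chemical-component ideal geometry
    by superposition on the local N/CA/C frame; polar hydrogens added with
    template geometry.
    """
    if not sequence:
        raise ValueError("empty peptide sequence")
    seq3 = []
    for pos, aa in enumerate(sequence.upper()):
        if aa not in chem.AA_1TO3:
            raise ValueError(f"invalid amino acid {aa!r} at position {pos + 1}")
        seq3.append(chem.AA_1TO3[aa])

    n_res = len(seq3)
    bb = np.zeros((n_res, 3, 3))        # N, CA, C per residue
    bb[0, 0] = [0.0, 0.0, 0.0]
    bb[0, 1] = [_N_CA, 0.0, 0.0]
    ang = math.radians(_ANG_N_CA_C)
    bb[0, 2] = bb[0, 1] + _CA_C * np.array([-math.cos(ang), math.sin(ang), 0.0])
    for i in range(1, n_res):
        n_prev, ca_prev, c_prev = bb[i - 1]
        bb[i, 0] = _place_atom(n_prev, ca_prev, c_prev, _C_N, _ANG_CA_C_N, _PSI)
        bb[i, 1] = _place_atom(ca_prev, c_prev, bb[i, 0], _N_CA, _ANG_C_N_CA,
                               _OMEGA)
        bb[i, 2] = _place_atom(c_prev, bb[i, 0], bb[i, 1], _CA_C, _ANG_N_CA_C,
                               _PHI)

    chain = Chain(chain_id=chain_id)
    serial = 0
    for i, res_name in enumerate(seq3):
        res = Residue(name=res_name, seq_id=i + 1)
        n_xyz, ca_xyz, c_xyz = bb[i]
        o_xyz = _place_atom(n_xyz, ca_xyz, c_xyz, _C_O, _ANG_CA_C_O,
                            _PSI + 180.0)
        for name, el, xyz in (("N", "N", n_xyz), ("CA", "C", ca_xyz),
                              ("C", "C", c_xyz), ("O", "O", o_xyz)):
            serial += 1
            res.atoms.append(Atom(serial=serial, name=name, element=el,
                                  coords=xyz))
        # graft the side chain via the local backbone frame
        ccd = _ccd_residue(res_name)
        ccd_idx = {n: k for k, n in enumerate(ccd.atom_name)}
        ref = np.array([ccd.coord[ccd_idx["N"]], ccd.coord[ccd_idx["CA"]],
                        ccd.coord[ccd_idx["C"]]], dtype=float)
        R, t = _kabsch(ref, np.array([n_xyz, ca_xyz, c_xyz]))
        for k, name in enumerate(ccd.atom_name):
            el = ccd.element[k].upper()
            if name in ("N", "CA", "C", "O", "OXT") or el == "H":
                continue
            serial += 1
            res.atoms.append(Atom(
                serial=serial, name=str(name), element=str(el),
                coords=R @ np.asarray(ccd.coord[k], dtype=float) + t))
        chain.residues.append(res)
    structure = Structure(chains=[chain], title=f"ideal helix {sequence}")
    add_polar_hydrogens(structure)
    return structure


# --------------------------------------------------------------------------
# toy protein-ssDNA complex
# --------------------------------------------------------------------------

@dataclass
class ToyComplexSpec:
    peptide: str = DEFAULT_PEPTIDE
    odn: str = "TCCATGACGTT"
    approach_distance: float = 3.5      # closest heavy-atom cross distance, A
    orientation: tuple[float, float, float] | None = None  # ZYZ Euler, deg
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.peptide or not self.odn:
            raise ValueError("sequences must be non-empty")
        if self.approach_distance < 2.0:
            raise ValueError("approach_distance < 2.0 A would clash")


@dataclass
class ContactManifest:
    """Brute-force ground truth for a generated complex."""
    hydrophobic: list[tuple[str, str, float]]       # (protein ref, dna ref, d)
    hbonds: list[tuple[str, str, str, float, float]]  # donor, H, acc, d, angle
    criteria: dict = field(default_factory=dict)


def _principal_axis(xyz: np.ndarray) -> np.ndarray:
    c = xyz - xyz.mean(0)
    return np.linalg.svd(c, full_matrices=False)[2][0]


def _brute_force_manifest(complex_structure: Structure,
                          protein_chain: str, dna_chain: str,
                          cutoff: float = 4.5, hmax: float = 2.6,
                          amin: float = 80.0) -> ContactManifest:
    """All-pairs double-loop contact census (no spatial index)."""
    prot, dna = [], []
    for chain, res, atom in complex_structure.iter_atoms():
        (prot if chain.chain_id == protein_chain else dna).append(
            (chain, res, atom))
    hydro = []
    for ca, ra, aa in prot:
        if aa.element != "C":
            continue
        for cb, rb, ab in dna:
            if ab.element != "C":
                continue
            d = float(np.linalg.norm(aa.coords - ab.coords))
            if d < cutoff:
                hydro.append((f"{ca.chain_id}:{ra.label}:{aa.name}",
                              f"{cb.chain_id}:{rb.label}:{ab.name}",
                              round(d, 2)))
    hbonds = []
    for don_list, acc_list in ((prot, dna), (dna, prot)):
        for ch, rh, h in don_list:
            if not h.is_hydrogen:
                continue
            parent = None
            for _, rp, p in don_list:
                if rp is rh and not p.is_hydrogen and p.element in ("N", "O"):
                    if np.linalg.norm(p.coords - h.coords) < 1.25:
                        parent = p
                        break
            if parent is None:
                continue
            if chem.donor_hydrogen_count(rh.name, parent.name) == 0:
                continue
            for ca, ra, a in acc_list:
                if a.is_hydrogen or not chem.is_acceptor(ra.name, a.name):
                    continue
                d = float(np.linalg.norm(h.coords - a.coords))
                if d > hmax:
                    continue
                v1 = parent.coords - h.coords
                v2 = a.coords - h.coords
                cosang = float(v1 @ v2
                               / (np.linalg.norm(v1) * np.linalg.norm(v2)))
                angle = math.degrees(math.acos(max(-1.0, min(1.0, cosang))))
                if angle < amin:
                    continue
                hbonds.append((f"{ch.chain_id}:{rh.label}:{parent.name}",
                               f"{ch.chain_id}:{rh.label}:{h.name}",
                               f"{ca.chain_id}:{ra.label}:{a.name}",
                               round(d, 2), round(angle, 1)))
    return ContactManifest(
        hydrophobic=sorted(hydro), hbonds=sorted(hbonds),
        criteria={"hydrophobic_cutoff": cutoff, "hbond_h_acceptor_max": hmax,
                  "hbond_dha_min_angle": amin})


def make_toy_complex(spec: ToyComplexSpec) -> tuple[Structure, ContactManifest]:
    """Peptide helix posed against a built ssDNA at a set closest approach.

    The peptide is rotated (explicit ZYZ orientation, or one drawn from the
    seed), its helix axis is kept parallel to the DNA axis, and it is slid
    in along +x until the closest heavy-atom cross distance equals
    ``approach_distance`` (bisection to 1e-6 A).  Returns the complex
    (protein chain A, DNA chain S) and its brute-force contact manifest.
    """
    dna = build_ssdna(spec.odn, chain_id="S")
    pep = build_helix_peptide(spec.peptide, chain_id="A")

    pep_xyz = pep.coords(include_hydrogens=False)
    axis = _principal_axis(pep_xyz)
    # align the helix axis with z (the DNA axis), then apply orientation
    rot_align = Rotation.align_vectors([[0.0, 0.0, 1.0]], [axis])[0]
    if spec.orientation is not None:
        extra = Rotation.from_euler("ZYZ", spec.orientation, degrees=True)
    else:
        rng = np.random.default_rng(spec.seed)
        extra = Rotation.from_euler(
            "z", float(rng.uniform(0.0, 360.0)), degrees=True)
    R = (extra * rot_align).as_matrix()
    pep = pep.transformed(R, np.zeros(3), center=pep_xyz.mean(0))

    dna_xyz = dna.coords(include_hydrogens=False)
    dna_center = dna_xyz.mean(0)
    pep_center = pep.coords(include_hydrogens=False).mean(0)
    # start far out on +x, level with the DNA center
    start = dna_center + np.array([60.0, 0.0, 0.0])
    pep = pep.transformed(np.eye(3), start - pep_center)

    def min_dist(shift: float) -> float:
        moved = pep.coords(include_hydrogens=False) - np.array([shift, 0, 0])
        d = np.linalg.norm(moved[:, None, :] - dna_xyz[None, :, :], axis=-1)
        return float(d.min())

    lo, hi = 0.0, 62.0
    if min_dist(hi) > spec.approach_distance:
        raise ValueError("cannot reach requested approach distance")
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if min_dist(mid) > spec.approach_distance:
            lo = mid
        else:
            hi = mid
    pep = pep.transformed(np.eye(3), np.array([-0.5 * (lo + hi), 0.0, 0.0]))

    complex_structure = Structure(chains=pep.chains + dna.chains,
                                  title="toy helix-ssDNA complex")
    assign_radii(complex_structure)
    manifest = _brute_force_manifest(complex_structure, "A", "S")
    return complex_structure, manifest


# --------------------------------------------------------------------------
# docking pocket fixture
# --------------------------------------------------------------------------

def _pseudo_structure(points: np.ndarray, chain_id: str,
                      res_name: str = "UNK") -> Structure:
    chain = Chain(chain_id=chain_id)
    serial = 0
    for start in range(0, len(points), 50):
        res = Residue(name=res_name, seq_id=start // 50 + 1)
        for k, p in enumerate(points[start:start + 50]):
            serial += 1
            res.atoms.append(Atom(serial=serial, name=f"C{k + 1}",
                                  element="C", coords=p, radius=1.7))
        chain.residues.append(res)
    return Structure(chains=[chain])


def make_pocket_fixture(ball_radius: float = 4.0, seed: int = 0,
                        receptor_radius: float = 9.0,
                        lattice: float = 1.0,
                        wall_gap: float = 1.8):
    """Sphere cluster with a spherical surface pocket + complementary ball.

    Returns ``(receptor, ligand, true_translation)``: docking the ligand
    (centroid at the origin) with identity rotation and the returned
    translation embeds the ball half-buried in the pocket.  The pocket is
    carved around a seed-dependent surface direction; ``wall_gap`` is the
    minimum pseudo-atom center separation between the embedded ligand and
    the pocket wall (the contact shell), verified at generation time.
    """
    if ball_radius < 2.0:
        raise ValueError("ball_radius must be >= 2 A")
    rng = np.random.default_rng(seed)
    u = rng.normal(size=3)
    u /= np.linalg.norm(u)
    pocket_center = u * (receptor_radius - 0.5 * ball_radius)

    n = int(math.ceil(receptor_radius / lattice))
    axis = np.arange(-n, n + 1) * lattice
    gx, gy, gz = np.meshgrid(axis, axis, axis, indexing="ij")
    pts = np.stack([gx.ravel(), gy.ravel(), gz.ravel()], axis=1)
    inside = np.linalg.norm(pts, axis=1) <= receptor_radius
    carve = (np.linalg.norm(pts - pocket_center, axis=1)
             <= ball_radius + wall_gap)
    receptor = _pseudo_structure(pts[inside & ~carve], "R")

    lig_n = int(math.ceil(ball_radius / lattice))
    axis = np.arange(-lig_n, lig_n + 1) * lattice
    gx, gy, gz = np.meshgrid(axis, axis, axis, indexing="ij")
    lpts = np.stack([gx.ravel(), gy.ravel(), gz.ravel()], axis=1)
    lpts = lpts[np.linalg.norm(lpts, axis=1) <= ball_radius]
    lpts = lpts - lpts.mean(0)
    ligand = _pseudo_structure(lpts, "L")

    # generation-time clearance check: wall gap holds at the true pose
    rec_pts = pts[inside & ~carve]
    embedded = lpts + pocket_center
    dmin = np.min(np.linalg.norm(
        rec_pts[:, None, :] - embedded[None, :, :], axis=-1))
    if dmin < wall_gap - 1e-9:
        raise AssertionError("pocket fixture wall clearance violated")
    return receptor, ligand, pocket_center.copy()


# --------------------------------------------------------------------------
# packaged tables
# --------------------------------------------------------------------------

TABLE_FILES = {
    "human_hydrophobic": "human_hydrophobic.tsv",
    "human_hbond": "human_hbond.tsv",
    "mouse_hydrophobic": "mouse_hydrophobic.tsv",
    "mouse_hbond": "mouse_hbond.tsv",
}

#: sha256 of the shipped fixtures; verified on access
TABLE_SHA256 = {
    "human_hydrophobic":
        "7d8db13881c78e4cd5e159949f0b05e9302c9b50e1d1f2c63168d9709cebceea",
    "human_hbond":
        "b1b43fcfb28411ca912198d0af03157bc94bb129b77ec98fe38a5ca2bf3717f7",
    "mouse_hydrophobic":
        "d5ed1cf181c0c65273d8f8f446c4705594d5c157a83a6aa5bb3131d405598c3e",
    "mouse_hbond":
        "ad823ae88ceb1bd5a2eeda46ad0e8c5e397c4df4d140fad8794a9c37c8349631",
}


def packaged_tables(verify: bool = True) -> dict[str, str]:
    """Paths of the four packaged interaction-table fixtures."""
    out = {}
    for key, fname in TABLE_FILES.items():
        ref = resources.files("dnaface").joinpath(f"data/tables/{fname}")
        if not ref.is_file():
            raise FileNotFoundError(
                f"packaged table {fname} missing; broken installation")
        if verify and TABLE_SHA256.get(key):
            digest = hashlib.sha256(ref.read_bytes()).hexdigest()
            if digest != TABLE_SHA256[key]:
                raise RuntimeError(
                    f"packaged table {fname} corrupted (checksum mismatch)")
        out[key] = str(ref)
    return out
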