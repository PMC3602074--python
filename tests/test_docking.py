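"""Docking: FFT-vs-naive oracle, pose transforms, rasterization rules."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from dnaface.dna import build_ssdna
from dnaface.docking import (DockParams, DockPose, apply_pose, charge_sites,
                             correlate_direct, correlate_fft, dock_fft,
                             rasterize, rotation_grid)
from dnaface.radii import assign_radii
from dnaface.synth import build_helix_peptide, make_pocket_fixture

from conftest import pseudo_cluster


def small_params(**kw):
    defaults = dict(grid_spacing=1.0, translation_extent=6.0, n_keep=5)
    defaults.update(kw)
    return DockParams(**defaults)


@pytest.mark.parametrize("shape", [(8, 8, 8), (6, 7, 8), (16, 16, 16)])
def test_fft_correlation_equals_naive(shape):
    rng = np.random.default_rng(sum(shape))
    a = rng.normal(size=shape)
    b = rng.normal(size=shape)
    fast = correlate_fft(a, b)
    slow = correlate_direct(a, b)
    assert np.max(np.abs(fast - slow)) / np.max(np.abs(slow)) < 1e-6


def test_single_atom_rasterization_geometry():
    s = pseudo_cluster([[0.0, 0.0, 0.0]])
    grid = rasterize(s, small_params(grid_spacing=0.6), "ligand")
    occ = grid.shape_grid > 0
    idx = np.argwhere(occ)
    centers = grid.origin + idx * grid.spacing
    d = np.linalg.norm(centers, axis=1)
    assert np.all(d <= 1.7 + 1e-9)
    # exterior cells well beyond the radius are empty
    assert occ.sum() < occ.size


def test_receptor_interior_cells_penalized():
    rng = np.random.default_rng(2)
    s = pseudo_cluster((rng.uniform(0, 6, (60, 3))).tolist())
    grid = rasterize(s, small_params(grid_spacing=0.8), "receptor")
    vals = set(np.unique(grid.shape_grid))
    assert vals <= {0.0, 1.0, -15.0}
    assert -15.0 in vals and 1.0 in vals


def test_lysine_charge_site_on_nz():
    pep = assign_radii(build_helix_peptide("AKA"))
    sites = charge_sites(pep)
    assert len(sites) == 1
    pos, q = sites[0]
    assert q == +1.0
    nz = pep.chains[0].residues[1].atom("NZ")
    np.testing.assert_allclose(pos, nz.coords)


def test_built_20mer_has_19_phosphate_charges():
    odn = assign_radii(build_ssdna("TCCATGACGTTCCTGACGTT"))
    sites = charge_sites(odn)
    assert len(sites) == 19
    assert all(q == -1.0 for _, q in sites)


def test_apply_pose_identity_and_translation():
    lig = pseudo_cluster([[0, 0, 0], [2, 0, 0], [0, 3, 0]])
    identity = DockPose((0, 0, 0), np.zeros(3), 0, 0)
    same = apply_pose(lig, identity)
    np.testing.assert_allclose(same.coords(), lig.coords(), atol=1e-12)
    shifted = apply_pose(lig, DockPose((0, 0, 0), np.array([1.0, 0, 0]),
                                       0, 0))
    np.testing.assert_allclose(shifted.coords()[:, 0],
                               lig.coords()[:, 0] + 1.0, atol=1e-12)


def test_apply_pose_preserves_internal_distances():
    rng = np.random.default_rng(4)
    lig = pseudo_cluster(rng.uniform(0, 5, (12, 3)).tolist())
    pose = DockPose((30.0, 45.0, 60.0), np.array([3.0, -2.0, 1.0]), 0, 0)
    moved = apply_pose(lig, pose)
    d0 = np.linalg.norm(lig.coords()[:, None] - lig.coords()[None], axis=-1)
    d1 = np.linalg.norm(moved.coords()[:, None] - moved.coords()[None],
                        axis=-1)
    np.testing.assert_allclose(d1, d0, rtol=1e-9)


def test_pose_composition_matches_composed_transform():
    rng = np.random.default_rng(5)
    lig = pseudo_cluster(rng.uniform(0, 5, (8, 3)).tolist())
    p1 = DockPose((20.0, 10.0, 0.0), np.array([1.0, 2.0, 3.0]), 0, 0)
    p2 = DockPose((0.0, 30.0, 40.0), np.array([-2.0, 0.5, 1.0]), 0, 0)
    step = apply_pose(apply_pose(lig, p1), p2)

    # composed rigid transform, accounting for the centroid convention
    c = lig.coords().mean(0)
    R1, t1 = p1.rotation_matrix(), p1.translation
    c1 = c + t1
    R2, t2 = p2.rotation_matrix(), p2.translation
    composed = lig.copy()
    for _, _, atom in composed.iter_atoms():
        x = R1 @ (atom.coords - c) + c + t1
        atom.coords = R2 @ (x - c1) + c1 + t2
    np.testing.assert_allclose(step.coords(), composed.coords(), atol=1e-6)


def test_rotation_grid_covers_so3_without_pole_duplicates():
    rots = rotation_grid(90.0)
    assert (0.0, 0.0, 0.0) in rots
    polar = [r for r in rots if r[1] in (0.0, 180.0)]
    assert all(r[2] == 0.0 for r in polar)
    assert len(set(rots)) == len(rots)


def test_identity_translation_scan_recovers_pocket_embedding():
    receptor, ligand, true_t = make_pocket_fixture(ball_radius=4.0, seed=3)
    params = DockParams(grid_spacing=0.6, translation_extent=12.0,
                        rotation_step=15.0, n_keep=3)
    poses = dock_fft(receptor, ligand, params, rotations=[(0.0, 0.0, 0.0)])
    best = poses[0]
    assert np.linalg.norm(best.translation - true_t) <= 0.6 + 1e-9


def test_interior_pose_scores_below_surface_pose():
    receptor, ligand, true_t = make_pocket_fixture(ball_radius=4.0, seed=3)
    params = DockParams(grid_spacing=0.8, translation_extent=12.0, n_keep=50)
    poses = dock_fft(receptor, ligand, params, rotations=[(0.0, 0.0, 0.0)],
                     per_rotation_keep=50)
    best = poses[0]
    # hand-score the fully-buried pose at the receptor centre
    rec_grid = rasterize(receptor, params, "receptor")
    lig_centered = apply_pose(ligand, DockPose((0, 0, 0),
                                               np.zeros(3), 0, 0))
    lig_grid = rasterize(lig_centered, params, "ligand",
                         grid_shape=rec_grid.shape_grid.shape,
                         origin=rec_grid.origin)
    buried_score = float(np.sum(rec_grid.shape_grid *
                                (lig_grid.shape_grid > 0)))
    assert best.total_score > buried_score
    assert buried_score < 0


def test_joint_rotation_leaves_top_score_nearly_invariant():
    """Rotating receptor and ligand together changes the top score only
    by grid-discretization noise (a thicker contact shell damps the
    lattice jaggedness)."""
    receptor, ligand, _ = make_pocket_fixture(ball_radius=4.0, seed=3)
    params = DockParams(grid_spacing=0.5, surface_thickness=2.5,
                        translation_extent=10.0, n_keep=1)
    base = dock_fft(receptor, ligand, params,
                    rotations=[(0.0, 0.0, 0.0)])[0]
    for euler in ((40.0, 25.0, 10.0), (15.0, 30.0, 0.0), (70.0, 45.0, 20.0)):
        R = Rotation.from_euler("ZYZ", euler, degrees=True)
        rec_rot = receptor.transformed(R.as_matrix(), np.zeros(3))
        lig_rot = ligand.transformed(R.as_matrix(), np.zeros(3))
        rot = dock_fft(rec_rot, lig_rot, params,
                       rotations=[(0.0, 0.0, 0.0)])[0]
        assert rot.total_score == pytest.approx(base.total_score, rel=0.05)


def test_empty_structures_rejected():
    from dnaface.core import Structure

    lig = pseudo_cluster([[0, 0, 0]])
    with pytest.raises(ValueError):
        dock_fft(Structure(chains=[]), lig, small_params())
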