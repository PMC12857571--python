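"""Invariance, round-trip and oracle checks for the geometric features."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from conftest import random_rigid_motion
from surffold.geometry import (
    DegenerateFrameError,
    LocalFrame,
    assemble_node_features,
    backbone_edge_features,
    build_local_frame,
    compose_euler,
    euler_angles,
    frame_of_residue,
    relative_rotation,
    rotation_angle_omega,
    sidechain_torsions,
    spherical_coords,
    SideChainTorsions,
)
from surffold.structure import SyntheticSpec, dihedral, make_synthetic_structure


def dihedral_oracle(p0, p1, p2, p3):
    """Independent dihedral: angle between plane normals, signed by the
    orientation of their cross product along the central bond."""
    b2 = p2 - p1
    n1 = np.cross(p1 - p0, b2)
    n2 = np.cross(b2, p3 - p2)
    cosang = np.dot(n1, n2) / (np.linalg.norm(n1) * np.linalg.norm(n2))
    ang = np.arccos(np.clip(cosang, -1, 1))
    if np.dot(np.cross(n1, n2), b2) < 0:
        ang = -ang
    return ang


def transform_frame(frame, R, t):
    return LocalFrame(origin=R @ frame.origin + t, basis=frame.basis @ R.T)


# -------------------------------------------------------------------- frames
def test_frame_orthonormal_right_handed(rng):
    for _ in range(20):
        n, ca, c = rng.normal(scale=3.0, size=(3, 3))
        f = build_local_frame(n, ca, c)
        np.testing.assert_allclose(f.basis @ f.basis.T, np.eye(3), atol=1e-10)
        assert np.linalg.det(f.basis) > 0.99


def test_frame_equivariance(rng):
    n, ca, c = rng.normal(scale=3.0, size=(3, 3))
    f = build_local_frame(n, ca, c)
    for _ in range(20):
        R, t = random_rigid_motion(rng)
        ft = build_local_frame(R @ n + t, R @ ca + t, R @ c + t)
        np.testing.assert_allclose(ft.origin, R @ f.origin + t, atol=1e-10)
        np.testing.assert_allclose(ft.basis, f.basis @ R.T, atol=1e-10)


def test_frame_degenerate_raises():
    with pytest.raises(DegenerateFrameError):
        build_local_frame([-1, 0, 0], [0, 0, 0], [1, 0, 0])
    with pytest.raises(DegenerateFrameError):
        build_local_frame([0, 0, 0], [0, 0, 0], [1, 0, 0])


def test_frame_deterministic(rng):
    n, ca, c = rng.normal(size=(3, 3))
    f1, f2 = build_local_frame(n, ca, c), build_local_frame(n, ca, c)
    np.testing.assert_array_equal(f1.basis, f2.basis)


# ----------------------------------------------------------------- spherical
def test_spherical_on_axis_point(rng):
    n, ca, c = rng.normal(size=(3, 3))
    f = build_local_frame(n, ca, c)
    d, theta, phi = spherical_coords(f, f.origin + 5.0 * f.basis[2])
    assert d == pytest.approx(5.0)
    assert theta == pytest.approx(0.0, abs=1e-7)
    assert phi == 0.0


def test_spherical_distance_is_euclidean(rng):
    n, ca, c = rng.normal(size=(3, 3))
    f = build_local_frame(n, ca, c)
    p = rng.normal(scale=8.0, size=3)
    d, _, _ = spherical_coords(f, p)
    assert d == pytest.approx(np.linalg.norm(p - f.origin))


def test_spherical_coincident_point_flagged_zero(rng):
    n, ca, c = rng.normal(size=(3, 3))
    f = build_local_frame(n, ca, c)
    assert spherical_coords(f, f.origin) == (0.0, 0.0, 0.0)


def test_spherical_rigid_invariance(rng):
    n, ca, c = rng.normal(size=(3, 3))
    f = build_local_frame(n, ca, c)
    p = rng.normal(scale=8.0, size=3)
    ref = spherical_coords(f, p)
    for _ in range(20):
        R, t = random_rigid_motion(rng)
        got = spherical_coords(transform_frame(f, R, t), R @ p + t)
        np.testing.assert_allclose(got, ref, atol=1e-8)


# --------------------------------------------------------------------- omega
def _random_frame_pair(rng, separation=6.0):
    n, ca, c = rng.normal(size=(3, 3))
    f = build_local_frame(n, ca, c)
    e = rng.normal(size=3)
    e /= np.linalg.norm(e)
    fj = LocalFrame(origin=f.origin + separation * e, basis=f.basis.copy())
    return f, fj, e


def test_omega_zero_for_pure_translation(rng):
    f, fj, _ = _random_frame_pair(rng)
    assert rotation_angle_omega(f, fj) == pytest.approx(0.0, abs=1e-10)


@pytest.mark.parametrize("alpha", [-2.5, -0.7, 0.4, 1.9])
def test_omega_equals_rotation_about_edge(rng, alpha):
    f, fj, e = _random_frame_pair(rng)
    R = Rotation.from_rotvec(alpha * e).as_matrix()
    fj_rot = LocalFrame(origin=fj.origin, basis=(R @ fj.basis.T).T)
    assert rotation_angle_omega(f, fj_rot) == pytest.approx(alpha, abs=1e-8)


def test_omega_rigid_invariance(rng):
    f, fj, e = _random_frame_pair(rng)
    R0 = Rotation.from_rotvec(0.9 * e).as_matrix()
    fj = LocalFrame(origin=fj.origin, basis=(R0 @ fj.basis.T).T)
    ref = rotation_angle_omega(f, fj)
    for _ in range(20):
        R, t = random_rigid_motion(rng)
        got = rotation_angle_omega(transform_frame(f, R, t), transform_frame(fj, R, t))
        assert got == pytest.approx(ref, abs=1e-8)


# --------------------------------------------------------------------- euler
def test_euler_identity_rotation(rng):
    n, ca, c = rng.normal(size=(3, 3))
    f = build_local_frame(n, ca, c)
    fj = LocalFrame(origin=f.origin + np.array([5.0, 0, 0]), basis=f.basis.copy())
    np.testing.assert_allclose(euler_angles(f, fj), (0, 0, 0), atol=1e-8)


def test_euler_round_trip_reproduces_relative_rotation(rng):
    for _ in range(50):
        n1, ca1, c1, n2, ca2, c2 = rng.normal(size=(6, 3))
        try:
            fi = build_local_frame(n1, ca1, c1)
            fj = build_local_frame(n2, ca2, c2)
        except DegenerateFrameError:
            continue
        t1, t2, t3 = euler_angles(fi, fj)
        assert -np.pi < t1 <= np.pi and 0 <= t2 <= np.pi and -np.pi < t3 <= np.pi
        err = np.linalg.norm(compose_euler(t1, t2, t3) - relative_rotation(fi, fj))
        assert err < 1e-8


def test_euler_gimbal_lock_sets_tau3_zero(rng):
    n, ca, c = rng.normal(size=(3, 3))
    f = build_local_frame(n, ca, c)
    # rotate about the frame's z axis only: relative rotation has tau2 = 0
    R = Rotation.from_rotvec(1.1 * f.basis[2]).as_matrix()
    fj = LocalFrame(origin=f.origin, basis=f.basis @ R.T)
    t1, t2, t3 = euler_angles(f, fj)
    assert t2 == pytest.approx(0.0, abs=1e-8)
    assert t3 == 0.0
    np.testing.assert_allclose(compose_euler(t1, t2, t3),
                               relative_rotation(f, fj), atol=1e-8)


def test_euler_rigid_invariance(rng):
    n1, ca1, c1, n2, ca2, c2 = rng.normal(size=(6, 3))
    fi, fj = build_local_frame(n1, ca1, c1), build_local_frame(n2, ca2, c2)
    ref = euler_angles(fi, fj)
    for _ in range(20):
        R, t = random_rigid_motion(rng)
        got = euler_angles(transform_frame(fi, R, t), transform_frame(fj, R, t))
        np.testing.assert_allclose(got, ref, atol=1e-8)


# ------------------------------------------------------------------ torsions
def test_dihedral_matches_independent_oracle(rng):
    for _ in range(1000):
        pts = rng.normal(scale=3.0, size=(4, 3))
        got = dihedral(*pts)
        want = dihedral_oracle(*pts)
        assert abs(got - want) < 1e-9 or abs(abs(got) - np.pi) < 1e-9


def test_dihedral_planar_cis_trans():
    cis = [np.array([1.0, 1, 0]), np.array([0.0, 0, 0]),
           np.array([2.0, 0, 0]), np.array([1.0, 1, 0]) + [2, 0, 0]]
    assert dihedral(*cis) == pytest.approx(0.0, abs=1e-12)
    trans = [np.array([1.0, 1, 0]), np.array([0.0, 0, 0]),
             np.array([2.0, 0, 0]), np.array([1.0, -1, 0]) + [2, 0, 0]]
    assert abs(dihedral(*trans)) == pytest.approx(np.pi)


def test_glycine_has_no_torsions():
    s = make_synthetic_structure(SyntheticSpec(n_residues=3, seed=0, sequence="AGA"))
    torsions = sidechain_torsions(s.residues[1])
    assert not torsions.present.any()
    np.testing.assert_array_equal(torsions.chi, 0.0)


def test_missing_sidechain_atom_masks_torsion():
    s = make_synthetic_structure(SyntheticSpec(n_residues=1, seed=0, sequence="K"))
    res = s.residues[0]
    del res.atoms["NZ"]
    torsions = sidechain_torsions(res)
    np.testing.assert_array_equal(torsions.present, [True, True, True, False])
    assert torsions.chi[3] == 0.0


# ------------------------------------------------------------- node features
def test_node_features_all_absent():
    t = SideChainTorsions(chi=np.zeros(4), present=np.zeros(4, dtype=bool))
    np.testing.assert_array_equal(assemble_node_features(t), np.zeros(12))


def test_node_features_chi_slot_encoding():
    t = SideChainTorsions(chi=np.array([np.pi / 2, 0, 0, 0]),
                          present=np.array([True, False, False, False]))
    v = assemble_node_features(t)
    assert v[0] == pytest.approx(1.0)   # sin chi1
    assert v[4] == pytest.approx(0.0, abs=1e-12)  # cos chi1
    assert v[8] == 1.0                  # mask chi1
    np.testing.assert_array_equal(v[[1, 2, 3, 5, 6, 7, 9, 10, 11]], 0.0)


def test_node_feature_length_constant(helix50):
    lengths = {len(assemble_node_features(sidechain_torsions(r))) for r in helix50.residues}
    assert lengths == {12}


# ------------------------------------------------------- full invariance set
def _structure_features(structure):
    frames = [frame_of_residue(r) for r in structure.residues]
    rows = []
    for i in range(len(frames) - 1):
        rows.append(backbone_edge_features(frames[i], frames[i + 1]).as_array())
    node = [assemble_node_features(sidechain_torsions(r)) for r in structure.residues]
    return np.concatenate([np.concatenate(rows), np.concatenate(node)])


def _transformed(structure, R, t):
    import copy

    s2 = copy.deepcopy(structure)
    for r in s2.residues:
        for k in r.atoms:
            r.atoms[k] = R @ r.atoms[k] + t
    return s2


def test_all_features_invariant_under_rigid_motions(rng, helix30):
    ref = _structure_features(helix30)
    for _ in range(20):
        R, t = random_rigid_motion(rng)
        got = _structure_features(_transformed(helix30, R, t))
        assert np.abs(got - ref).max() < 1e-6


def test_mirror_flips_chirality_sensitive_angles(helix30):
    M = np.diag([1.0, 1.0, -1.0])
    mirrored = _transformed(helix30, M, np.zeros(3))
    f0, f1 = frame_of_residue(helix30.residues[0]), frame_of_residue(helix30.residues[1])
    m0, m1 = frame_of_residue(mirrored.residues[0]), frame_of_residue(mirrored.residues[1])
    w = rotation_angle_omega(f0, f1)
    w_m = rotation_angle_omega(m0, m1)
    assert w_m == pytest.approx(-w, abs=1e-8)  # twist flips under reflection
    # and the full feature set is NOT reflection-invariant
    assert np.abs(_structure_features(mirrored) - _structure_features(helix30)).max() > 0.1
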