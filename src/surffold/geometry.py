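"""Backbone and side-chain geometric features.

Each residue carries a right-handed local frame built from its N, CA and C
atoms.  Edge features between residues i and j are the spherical coordinates
(d, theta, phi) of Ca_j in frame i, the twist omega of frame j about the
connecting line, and the three Z-Y-Z Euler angles of the relative rotation
between the two frames.  Node features are the four side-chain torsions
chi1..chi4 (sin/cos encoded, with a presence mask).  All of these are scalars
or angles measured between frames, hence invariant under any global rotation
and translation of the structure — and, being chirality-sensitive, they flip
sign under reflection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .structure import Residue, chi_atom_quadruples, dihedral

__all__ = [
    "LocalFrame",
    "BackboneEdgeFeatures",
    "SideChainTorsions",
    "build_local_frame",
    "spherical_coords",
    "rotation_angle_omega",
    "euler_angles",
    "sidechain_torsions",
    "assemble_node_features",
    "backbone_edge_features",
    "NODE_FEATURE_DIM",
]

NODE_FEATURE_DIM = 12  # 4 chi * (sin, cos) + 4 presence bits


class DegenerateFrameError(ValueError):
    """N, CA, C are collinear or coincident: no frame is defined."""


@dataclass
class LocalFrame:
    origin: np.ndarray  # Ca position, A
    basis: np.ndarray   # rows are the x, y, z unit axes (right-handed)


@dataclass
class BackboneEdgeFeatures:
    d: float
    theta: float
    phi: float
    omega: float
    tau1: float
    tau2: float
    tau3: float

    def as_array(self) -> np.ndarray:
        return np.array([self.d, self.theta, self.phi, self.omega,
                         self.tau1, self.tau2, self.tau3])


@dataclass
class SideChainTorsions:
    chi: np.ndarray      # 4 angles, radians; 0 where absent
    present: np.ndarray  # 4 booleans


def build_local_frame(n_pos: np.ndarray, ca_pos: np.ndarray, c_pos: np.ndarray) -> LocalFrame:
    """Residue frame at the Ca: Gram-Schmidt on (N->Ca, Ca->C).

    x is the unit N->Ca direction, z the normal of the N-Ca-C plane, y = z x x.
    Equivariant: a rigid motion of the three atoms rotates the basis and
    translates the origin identically.
    """
    n_pos = np.asarray(n_pos, dtype=np.float64)
    ca_pos = np.asarray(ca_pos, dtype=np.float64)
    c_pos = np.asarray(c_pos, dtype=np.float64)
    u = ca_pos - n_pos
    v = c_pos - ca_pos
    nu = np.linalg.norm(u)
    if nu < 1e-8:
        raise DegenerateFrameError("N and CA coincide")
    x = u / nu
    z = np.cross(x, v)
    nz = np.linalg.norm(z)
    if nz < 1e-8:
        raise DegenerateFrameError("N, CA, C are collinear")
    z = z / nz
    y = np.cross(z, x)
    return LocalFrame(origin=ca_pos, basis=np.stack([x, y, z]))


def frame_of_residue(res: Residue) -> LocalFrame:
    return build_local_frame(res.atoms["N"], res.atoms["CA"], res.atoms["C"])


def spherical_coords(frame_i: LocalFrame, pos_j: np.ndarray) -> tuple[float, float, float]:
    """Distance, polar angle from the frame z axis, azimuth in the xy plane.

    On-axis points (azimuth undefined) and coincident points return 0 for the
    undefined angles.
    """
    rel = frame_i.basis @ (np.asarray(pos_j, dtype=np.float64) - frame_i.origin)
    d = float(np.linalg.norm(rel))
    if d < 1e-12:
        return 0.0, 0.0, 0.0
    theta = float(np.arccos(np.clip(rel[2] / d, -1.0, 1.0)))
    if abs(rel[0]) < 1e-12 and abs(rel[1]) < 1e-12:
        phi = 0.0
    else:
        phi = float(np.arctan2(rel[1], rel[0]))
    return d, theta, phi


def rotation_angle_omega(frame_i: LocalFrame, frame_j: LocalFrame) -> float:
    """Twist of frame j's x axis relative to frame i's about the edge line.

    Computed as the dihedral of (origin_i + x_i, origin_i, origin_j,
    origin_j + x_j): zero for a pure translation, alpha when frame j is
    additionally rotated by alpha about the connecting axis.
    """
    e = frame_j.origin - frame_i.origin
    ne = np.linalg.norm(e)
    if ne < 1e-12:
        return 0.0
    return dihedral(frame_i.origin + frame_i.basis[0], frame_i.origin,
                    frame_j.origin, frame_j.origin + frame_j.basis[0])


def relative_rotation(frame_i: LocalFrame, frame_j: LocalFrame) -> np.ndarray:
    """Rotation matrix of frame j expressed in frame i (basis_i^-1 . basis_j)."""
    return frame_i.basis @ frame_j.basis.T


def euler_angles(frame_i: LocalFrame, frame_j: LocalFrame) -> tuple[float, float, float]:
    """Intrinsic Z-Y-Z Euler angles of the relative rotation.

    tau1, tau3 in (-pi, pi], tau2 in [0, pi]; at gimbal lock (tau2 = 0 or pi)
    the decomposition is degenerate and tau3 is fixed to 0.
    """
    rel = relative_rotation(frame_i, frame_j)
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # scipy warns at gimbal lock; tau3=0 there
        t1, t2, t3 = Rotation.from_matrix(rel).as_euler("ZYZ")
    return float(t1), float(t2), float(t3)


def compose_euler(tau1: float, tau2: float, tau3: float) -> np.ndarray:
    """Inverse of :func:`euler_angles`: rebuild the relative rotation matrix."""
    return Rotation.from_euler("ZYZ", [tau1, tau2, tau3]).as_matrix()


def sidechain_torsions(res: Residue) -> SideChainTorsions:
    """chi1..chi4 from the standard atom quadruples for the residue type.

    Angles whose defining atoms are missing, or that the residue type does not
    define, are reported as 0 with ``present`` false.  Output carries only
    angles and the mask — no atom identities.
    """
    chi = np.zeros(4)
    present = np.zeros(4, dtype=bool)
    for k, quad in enumerate(chi_atom_quadruples(res.name)):
        if all(a in res.atoms for a in quad):
            chi[k] = dihedral(*(res.atoms[a] for a in quad))
            present[k] = True
    return SideChainTorsions(chi=chi, present=present)


def backbone_edge_features(frame_i: LocalFrame, frame_j: LocalFrame) -> BackboneEdgeFeatures:
    d, theta, phi = spherical_coords(frame_i, frame_j.origin)
    omega = rotation_angle_omega(frame_i, frame_j)
    t1, t2, t3 = euler_angles(frame_i, frame_j)
    return BackboneEdgeFeatures(d=d, theta=theta, phi=phi, omega=omega,
                                tau1=t1, tau2=t2, tau3=t3)


def assemble_node_features(torsions: SideChainTorsions) -> np.ndarray:
    """Fixed-length node feature vector: (sin, cos) per chi plus the mask.

    Absent torsions contribute (0, 0) — not the (0, 1) of a true zero angle —
    so the network can distinguish "no chi" from "chi = 0".
    """
    mask = torsions.present.astype(np.float64)
    sin = np.sin(torsions.chi) * mask
    cos = np.cos(torsions.chi) * mask
    out = np.concatenate([sin, cos, mask])
    if not np.all(np.isfinite(out)):
        raise ValueError("non-finite node features")
    return out
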