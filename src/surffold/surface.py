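"""Smooth-distance-function protein surfaces as point clouds with normals.

The protein surface is the level set ``SDF(x) = level`` of a soft-min
distance to the atom cloud:

    sigma(x) = sum_k w_k(x) sigma_k / sum_k w_k(x),   w_k(x) = exp(-|x - a_k| / sigma_k)
    SDF(x)   = -sigma(x) * log sum_k w_k(x)

where ``sigma_k`` is the van der Waals radius of atom ``k``.  For a single
atom this collapses exactly to the Euclidean distance.  Points are seeded at
atom positions plus Gaussian noise, projected onto the isosurface by gradient
descent on |SDF - level|, down-sampled on a voxel grid for uniform coverage,
and oriented by the normalized SDF gradient.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .structure import ProteinStructure

__all__ = [
    "AtomCloud",
    "SurfaceConfig",
    "SurfacePointCloud",
    "VDW_RADII",
    "ELEMENT_VOCAB",
    "atom_cloud_from_structure",
    "smooth_distance",
    "sdf_gradient",
    "sample_surface",
    "downsample",
    "write_ply",
    "read_ply",
]

# Van der Waals radii (A); elements outside the table fall back to 1.80 A.
VDW_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "H": 1.10}
DEFAULT_RADIUS = 1.80
ELEMENT_VOCAB = ["C", "N", "O", "S", "H", "other"]


@dataclass
class AtomCloud:
    """Atom positions (K x 3, A), radii sigma_k (K,) and element type codes."""

    positions: np.ndarray
    radii: np.ndarray
    type_index: np.ndarray

    def __post_init__(self):
        self.positions = np.atleast_2d(np.asarray(self.positions, dtype=np.float64))
        self.radii = np.atleast_1d(np.asarray(self.radii, dtype=np.float64))
        self.type_index = np.atleast_1d(np.asarray(self.type_index, dtype=np.intp))
        if self.positions.shape[0] == 0:
            raise ValueError("AtomCloud requires at least one atom")
        if np.any(self.radii <= 0):
            raise ValueError("atom radii must be positive")

    @property
    def n_atoms(self) -> int:
        return self.positions.shape[0]


def atom_cloud_from_structure(structure: ProteinStructure) -> AtomCloud:
    positions, radii, types = [], [], []
    for atom in structure.iter_atoms():
        positions.append(atom.position)
        radii.append(VDW_RADII.get(atom.element, DEFAULT_RADIUS))
        el = atom.element if atom.element in ELEMENT_VOCAB else "other"
        types.append(ELEMENT_VOCAB.index(el))
    return AtomCloud(np.array(positions), np.array(radii), np.array(types))


@dataclass
class SurfaceConfig:
    """Isosurface sampling parameters (all lengths in A)."""

    level: float = 1.05
    init_points_per_atom: int = 20
    init_noise_scale: float = 3.0
    projection_steps: int = 40
    projection_tol: float = 1e-2
    target_spacing: float = 1.2
    seed: int = 0

    def __post_init__(self):
        for name in ("level", "init_points_per_atom", "init_noise_scale",
                     "projection_steps", "projection_tol", "target_spacing"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.projection_tol >= self.level:
            raise ValueError("projection_tol must be smaller than the isosurface level")


@dataclass
class SurfacePointCloud:
    """Sampled isosurface points with outward unit normals."""

    points: np.ndarray
    normals: np.ndarray
    source_protein: str = ""
    n_discarded: int = 0

    def __post_init__(self):
        self.points = np.atleast_2d(np.asarray(self.points, dtype=np.float64))
        self.normals = np.atleast_2d(np.asarray(self.normals, dtype=np.float64))

    @property
    def n_points(self) -> int:
        return self.points.shape[0]


def _log_weights(x: np.ndarray, atoms: AtomCloud) -> tuple[np.ndarray, np.ndarray]:
    """Pairwise distances and log w_k = -d_k / sigma_k for queries x (Q x 3)."""
    diff = x[:, None, :] - atoms.positions[None, :, :]  # Q x K x 3
    d = np.linalg.norm(diff, axis=-1)
    return d, -d / atoms.radii[None, :]


def smooth_distance(x: np.ndarray, atoms: AtomCloud) -> np.ndarray:
    """SDF values at query points, evaluated via a shifted log-sum-exp."""
    x = np.atleast_2d(np.asarray(x, dtype=np.float64))
    _, lw = _log_weights(x, atoms)
    m = lw.max(axis=1, keepdims=True)
    e = np.exp(lw - m)
    s = e.sum(axis=1)
    log_sum = m[:, 0] + np.log(s)
    sigma_x = (e * atoms.radii[None, :]).sum(axis=1) / s
    return -sigma_x * log_sum


def sdf_gradient(x: np.ndarray, atoms: AtomCloud) -> np.ndarray:
    """Analytic gradient of the SDF with respect to the query point.

    With w_k = exp(-d_k/sigma_k), S = sum w_k, sigma(x) = sum w_k sigma_k / S:

        grad SDF = -(grad sigma) log S - sigma(x) (grad S) / S
        grad w_k = -w_k u_k / sigma_k,   u_k = (x - a_k)/d_k
    """
    x = np.atleast_2d(np.asarray(x, dtype=np.float64))
    diff = x[:, None, :] - atoms.positions[None, :, :]
    d = np.linalg.norm(diff, axis=-1)
    u = diff / np.maximum(d, 1e-12)[:, :, None]
    lw = -d / atoms.radii[None, :]
    m = lw.max(axis=1, keepdims=True)
    w = np.exp(lw - m)  # rescaled weights; ratios are what matter below
    S = w.sum(axis=1)
    log_sum = m[:, 0] + np.log(S)
    sigma_x = (w * atoms.radii[None, :]).sum(axis=1) / S

    inv_r = 1.0 / atoms.radii[None, :]
    grad_w = -(w * inv_r)[:, :, None] * u              # Q x K x 3 (rescaled)
    grad_S = grad_w.sum(axis=1)                        # Q x 3
    grad_sigma = ((grad_w * atoms.radii[None, :, None]).sum(axis=1)
                  - sigma_x[:, None] * grad_S) / S[:, None]
    return -grad_sigma * log_sum[:, None] - sigma_x[:, None] * grad_S / S[:, None]


def downsample(points: np.ndarray, target_spacing: float) -> np.ndarray:
    """Deterministic subsampling to pairwise separation >= target_spacing.

    A voxel-grid pass keeps the lowest-index point per occupied voxel, then a
    greedy sweep in index order drops any survivor closer than
    ``target_spacing`` to an already-kept point (voxel neighbors across a
    boundary can otherwise be arbitrarily close).  Returns sorted indices
    into ``points``; retained count is bounded above by the occupied-voxel
    count.
    """
    points = np.atleast_2d(points)
    if points.shape[0] == 0:
        return np.array([], dtype=np.intp)
    cells = np.floor(points / target_spacing).astype(np.int64)
    _, first = np.unique(cells, axis=0, return_index=True)
    first = np.sort(first)
    grid: dict[tuple[int, int, int], list[int]] = {}
    kept: list[int] = []
    for i in first:
        p = points[i]
        cell = tuple(cells[i])
        near = False
        for dx in (-1, 0, 1):
            for dy in (-1, 0, 1):
                for dz in (-1, 0, 1):
                    for j in grid.get((cell[0] + dx, cell[1] + dy, cell[2] + dz), ()):
                        if np.linalg.norm(points[j] - p) < target_spacing:
                            near = True
                            break
                    if near:
                        break
                if near:
                    break
            if near:
                break
        if near:
            continue
        kept.append(int(i))
        grid.setdefault(cell, []).append(int(i))
    return np.array(kept, dtype=np.intp)


def sample_surface(atoms: AtomCloud, config: SurfaceConfig,
                   source_protein: str = "",
                   init_points: np.ndarray | None = None) -> SurfacePointCloud:
    """Sample the isosurface ``SDF = level`` as an oriented point cloud.

    Deterministic given ``config.seed``.  Non-converged points (|SDF - level|
    still above tolerance after the step budget) are discarded and counted in
    ``n_discarded``.  ``init_points`` overrides the Gaussian initialization
    (e.g. to carry initial noise along with a rigid motion of the atoms).
    """
    if init_points is not None:
        x = np.array(init_points, dtype=np.float64)
        n_init = x.shape[0]
    else:
        rng = np.random.default_rng(config.seed)
        n_init = atoms.n_atoms * config.init_points_per_atom
        x = np.repeat(atoms.positions, config.init_points_per_atom, axis=0)
        x = x + rng.normal(scale=config.init_noise_scale, size=(n_init, 3))

    step = config.level / 4.0
    active = np.ones(n_init, dtype=bool)
    for _ in range(config.projection_steps):
        idx = np.flatnonzero(active)
        if idx.size == 0:
            break
        f = smooth_distance(x[idx], atoms) - config.level
        done = np.abs(f) <= config.projection_tol
        active[idx[done]] = False
        idx = idx[~done]
        f = f[~done]
        if idx.size == 0:
            break
        g = sdf_gradient(x[idx], atoms)
        gn = np.maximum(np.linalg.norm(g, axis=1, keepdims=True), 1e-12)
        # Move along the descent direction of |SDF - level|, capped at the
        # fixed step so points do not overshoot the level set.
        delta = np.clip(np.abs(f), None, step)
        x[idx] = x[idx] - np.sign(f)[:, None] * delta[:, None] * g / gn

    f = smooth_distance(x, atoms) - config.level
    converged = np.abs(f) <= config.projection_tol
    n_discarded = int((~converged).sum())
    x = x[converged]
    if x.shape[0] == 0:
        raise RuntimeError(
            f"surface sampling produced no converged points "
            f"({n_discarded} discarded; level={config.level}, "
            f"tol={config.projection_tol}, steps={config.projection_steps})"
        )

    keep = downsample(x, config.target_spacing)
    x = x[keep]
    g = sdf_gradient(x, atoms)
    normals = g / np.linalg.norm(g, axis=1, keepdims=True)
    return SurfacePointCloud(points=x, normals=normals,
                             source_protein=source_protein, n_discarded=n_discarded)


# ------------------------------------------------------------------ PLY I/O
def write_ply(cloud: SurfacePointCloud, path: str | Path) -> None:
    """ASCII PLY with per-vertex position and normal."""
    with open(path, "w") as fh:
        fh.write("ply\nformat ascii 1.0\n")
        fh.write(f"element vertex {cloud.n_points}\n")
        for prop in ("x", "y", "z", "nx", "ny", "nz"):
            fh.write(f"property float {prop}\n")
        fh.write("end_header\n")
        for p, n in zip(cloud.points, cloud.normals):
            fh.write(f"{p[0]:.6f} {p[1]:.6f} {p[2]:.6f} {n[0]:.6f} {n[1]:.6f} {n[2]:.6f}\n")


def read_ply(path: str | Path) -> SurfacePointCloud:
    with open(path) as fh:
        line = fh.readline()
        if line.strip() != "ply":
            raise ValueError(f"{path}: not a PLY file")
        n_vertex = 0
        while True:
            line = fh.readline().strip()
            if line.startswith("element vertex"):
                n_vertex = int(line.split()[-1])
            if line == "end_header":
                break
        data = np.loadtxt(fh, max_rows=n_vertex).reshape(n_vertex, 6)
    return SurfacePointCloud(points=data[:, :3], normals=data[:, 3:])
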