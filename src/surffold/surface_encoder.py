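"""Per-point surface features and quasi-geodesic convolution layers.

Three ingredients make up the surface branch:

* learned chemical features from each point's 16 nearest atoms (one-hot
  element type + inverse distance, per-neighbor MLP, symmetric pooling);
* multi-scale mean and Gaussian curvature from local quadric fits;
* quasi-geodesic convolutions, whose neighborhoods are Gaussian windows over
  the quasi-geodesic distance d_ij = |x_i - x_j| (2 - <n_i, n_j>) — normals
  pointing apart inflate the distance, so points on opposite sheets that are
  close through space are suppressed.

All inputs to the learned layers are types, distances and angles between
normals, so the per-point embeddings are invariant under global rotations
and translations of the protein by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from . import nn
from .surface import AtomCloud, SurfacePointCloud, ELEMENT_VOCAB

__all__ = [
    "chemical_neighborhoods",
    "curvatures",
    "quasi_geodesic_weights",
    "geodesic_kernels",
    "ChemicalFeatureNet",
    "QuasiGeodesicConv",
    "SurfaceEncoder",
    "SurfaceEncoderConfig",
    "SurfaceFeatures",
    "precompute_surface_features",
]

N_CHEM_NEIGHBORS = 16
CHEM_INPUT_DIM = len(ELEMENT_VOCAB) + 1  # one-hot type + inverse distance
WEIGHT_FLOOR = 1e-4  # quasi-geodesic weights below this are dropped


def chemical_neighborhoods(points: np.ndarray, atoms: AtomCloud) -> np.ndarray:
    """Input array (P, 16, T+1): one-hot atom type and inverse distance.

    If the protein has fewer than 16 atoms the nearest atom is repeated to
    pad the neighborhood.
    """
    points = np.atleast_2d(points)
    k = min(N_CHEM_NEIGHBORS, atoms.n_atoms)
    tree = cKDTree(atoms.positions)
    dist, idx = tree.query(points, k=k)
    dist = np.atleast_2d(dist).reshape(len(points), k)
    idx = np.atleast_2d(idx).reshape(len(points), k)
    if k < N_CHEM_NEIGHBORS:
        pad = N_CHEM_NEIGHBORS - k
        dist = np.concatenate([dist, np.repeat(dist[:, :1], pad, axis=1)], axis=1)
        idx = np.concatenate([idx, np.repeat(idx[:, :1], pad, axis=1)], axis=1)
    out = np.zeros((len(points), N_CHEM_NEIGHBORS, CHEM_INPUT_DIM))
    one_hot = np.eye(len(ELEMENT_VOCAB))[atoms.type_index[idx]]
    out[:, :, : len(ELEMENT_VOCAB)] = one_hot
    out[:, :, -1] = 1.0 / np.maximum(dist, 1e-6)
    return out


def _tangent_basis(normal: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Any orthonormal pair spanning the plane orthogonal to ``normal``."""
    a = np.zeros(3)
    a[np.argmin(np.abs(normal))] = 1.0
    t1 = np.cross(normal, a)
    t1 /= np.linalg.norm(t1)
    t2 = np.cross(normal, t1)
    return t1, t2


def curvatures(points: np.ndarray, normals: np.ndarray,
               scales: tuple[float, ...]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Mean and Gaussian curvature per point and scale via weighted quadric fits.

    At each scale s, neighbors within radius s are expressed in the point's
    tangent frame and a Monge patch ``h(u, v)`` (full quadric, Gaussian
    weights of width s/2) is fitted; H and K follow from the first and second
    fundamental forms.  Height is measured against the outward normal so a
    convex region (normals diverging) has H > 0.  Points with fewer than 6
    neighbors at a scale get (0, 0) and a False validity flag.

    Returns (H, K, valid), each of shape (P, n_scales).
    """
    points = np.atleast_2d(points)
    normals = np.atleast_2d(normals)
    P = len(points)
    S = len(scales)
    H = np.zeros((P, S))
    K = np.zeros((P, S))
    valid = np.zeros((P, S), dtype=bool)
    tree = cKDTree(points)
    for si, s in enumerate(scales):
        neighbor_lists = tree.query_ball_point(points, r=s)
        for i in range(P):
            nb = [j for j in neighbor_lists[i] if j != i]
            if len(nb) < 6:
                continue
            n = normals[i]
            t1, t2 = _tangent_basis(n)
            delta = points[nb] - points[i]
            u = delta @ t1
            v = delta @ t2
            h = -(delta @ n)  # height against the outward normal: convex => h > 0
            d2 = (delta**2).sum(axis=1)
            w = np.exp(-d2 / (2.0 * (s / 2.0) ** 2))
            A = np.stack([np.ones_like(u), u, v, 0.5 * u**2, u * v, 0.5 * v**2], axis=1)
            Aw = A * w[:, None]
            coef, *_ = np.linalg.lstsq(Aw.T @ A, Aw.T @ h, rcond=None)
            _, p1, p2, fa, fb, fc = coef
            denom = np.sqrt(1.0 + p1**2 + p2**2)
            E, F, G = 1.0 + p1**2, p1 * p2, 1.0 + p2**2
            Lf, Mf, Nf = fa / denom, fb / denom, fc / denom
            det1 = E * G - F**2
            H[i, si] = (E * Nf - 2.0 * F * Mf + G * Lf) / (2.0 * det1)
            K[i, si] = (Lf * Nf - Mf**2) / det1
            valid[i, si] = True
    return H, K, valid


def quasi_geodesic_weights(points: np.ndarray, normals: np.ndarray,
                           window: float) -> np.ndarray:
    """Dense symmetric Gaussian weights over the quasi-geodesic distance.

    w_ij = exp(-d_ij^2 / (2 window^2)) with
    d_ij = |x_i - x_j| (2 - <n_i, n_j>); entries below 1e-4 are dropped.
    """
    points = np.atleast_2d(points)
    normals = np.atleast_2d(normals)
    euc = np.linalg.norm(points[:, None, :] - points[None, :, :], axis=-1)
    cos = normals @ normals.T
    d = euc * (2.0 - cos)
    w = np.exp(-(d**2) / (2.0 * window**2))
    w[w < WEIGHT_FLOOR] = 0.0
    return w


def geodesic_kernels(points: np.ndarray, normals: np.ndarray,
                     window: float) -> np.ndarray:
    """Fixed geometric aggregation kernels (4, P, P), row-normalized.

    Each kernel is the quasi-geodesic Gaussian weight modulated by one
    rigid-invariant pairwise scalar: 1, the Euclidean distance over the
    window, the offset component along the receiving normal over the window,
    and the normal alignment <n_i, n_j>.  These carry the neighbor-offset
    information (radial / normal / tangential split) into the convolution
    without reference to any global frame.
    """
    points = np.atleast_2d(points)
    normals = np.atleast_2d(normals)
    w = quasi_geodesic_weights(points, normals, window)
    delta = points[None, :, :] - points[:, None, :]  # delta[i, j] = x_j - x_i
    euc = np.linalg.norm(delta, axis=-1)
    along_normal = np.einsum("ijk,ik->ij", delta, normals)
    cos = normals @ normals.T
    denom = np.maximum(w.sum(axis=1, keepdims=True), 1e-12)
    basis = np.stack([np.ones_like(w), euc / window, along_normal / window, cos])
    return (w[None] * basis) / denom[None]


@dataclass
class SurfaceEncoderConfig:
    d_surf: int = 128
    n_layers: int = 3
    chem_hidden: int = 32
    chem_out: int = 32
    scales: tuple[float, ...] = (1.0, 2.0, 3.0, 5.0, 10.0)
    window: float = 6.0


@dataclass
class SurfaceFeatures:
    """Static (non-learned) per-cloud arrays the encoder consumes."""

    points: np.ndarray
    normals: np.ndarray
    chem_input: np.ndarray   # (P, 16, T+1)
    curvature: np.ndarray    # (P, 2 * n_scales): H then K per scale
    kernels: np.ndarray      # (4, P, P)

    @property
    def n_points(self) -> int:
        return self.points.shape[0]


def precompute_surface_features(cloud: SurfacePointCloud, atoms: AtomCloud,
                                config: SurfaceEncoderConfig) -> SurfaceFeatures:
    chem = chemical_neighborhoods(cloud.points, atoms)
    H, K, valid = curvatures(cloud.points, cloud.normals, config.scales)
    curv = np.concatenate([H * valid, K * valid], axis=1)
    kernels = geodesic_kernels(cloud.points, cloud.normals, config.window)
    return SurfaceFeatures(points=cloud.points, normals=cloud.normals,
                           chem_input=chem, curvature=curv, kernels=kernels)


class ChemicalFeatureNet(nn.Module):
    """Per-neighbor MLP, mean pooling over the 16 neighbors, second MLP.

    Mean pooling makes the output invariant to neighbor order.
    """

    def __init__(self, hidden: int, out: int, rng: np.random.Generator):
        self.mlp1 = nn.MLP([CHEM_INPUT_DIM, hidden, hidden], rng)
        self.mlp2 = nn.MLP([hidden, hidden, out], rng)

    def __call__(self, chem_input: np.ndarray) -> nn.Tensor:
        P = chem_input.shape[0]
        x = nn.Tensor(chem_input.reshape(P * N_CHEM_NEIGHBORS, CHEM_INPUT_DIM))
        h = self.mlp1(x).reshape(P, N_CHEM_NEIGHBORS, -1).mean(axis=1)
        return self.mlp2(h)


class QuasiGeodesicConv(nn.Module):
    """One quasi-geodesic convolution layer.

    Neighbor features pass through a message transform, are aggregated under
    the four fixed geometric kernels (Gaussian-weighted, sum-normalized) and
    concatenated with the point's own features before the output transform.
    """

    def __init__(self, dim: int, rng: np.random.Generator):
        self.msg = nn.Linear(dim, dim, rng)
        self.out = nn.Linear(5 * dim, dim, rng)

    def __call__(self, feats: nn.Tensor, kernels: np.ndarray) -> nn.Tensor:
        m = self.msg(feats)
        parts = [feats] + [nn.Tensor(kernels[b]) @ m for b in range(kernels.shape[0])]
        return self.out(nn.gelu(nn.concat(parts, axis=-1)))


class SurfaceEncoder(nn.Module):
    """Chemical + curvature features through stacked quasi-geodesic convolutions."""

    def __init__(self, config: SurfaceEncoderConfig, rng: np.random.Generator):
        self.config = config
        self.chem = ChemicalFeatureNet(config.chem_hidden, config.chem_out, rng)
        in_dim = config.chem_out + 2 * len(config.scales)
        self.input_proj = nn.Linear(in_dim, config.d_surf, rng)
        self.convs = nn.ModuleList(
            [QuasiGeodesicConv(config.d_surf, rng) for _ in range(config.n_layers)]
        )
        self.norms = nn.ModuleList(
            [nn.LayerNorm(config.d_surf) for _ in range(config.n_layers)]
        )

    def __call__(self, feats: SurfaceFeatures) -> nn.Tensor:
        chem = self.chem(feats.chem_input)
        x = self.input_proj(nn.concat([chem, nn.Tensor(feats.curvature)], axis=-1))
        for conv, norm in zip(self.convs, self.norms):
            x = norm(x + conv(x, feats.kernels))
        return x
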