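"""Residue graph construction and EdgeGraphConv message passing.

Residues are nodes at their Ca positions; a directed edge j -> i exists
whenever |Ca_i - Ca_j| is below the cutoff (10 A by default).  Edge features
are the invariant backbone geometry of the pair (spherical coordinates, edge
twist, Euler angles); node features are the side-chain torsion encodings.
EdgeGraphConv is GraphConv with the neighbor features gated by a learned
projection of the edge features through a Hadamard product:

    x_i' = W1 x_i + W2 sum_{j in N(i)} g(e_ji) * x_j
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from . import nn
from .geometry import (
    NODE_FEATURE_DIM,
    assemble_node_features,
    backbone_edge_features,
    frame_of_residue,
    sidechain_torsions,
)
from .structure import ProteinStructure

__all__ = [
    "ProteinGraph",
    "build_graph",
    "encode_edge_features",
    "EdgeGraphConv",
    "StructureEncoder",
    "StructureEncoderConfig",
    "N_RBF",
    "EDGE_FEATURE_DIM",
]

N_RBF = 16
EDGE_FEATURE_DIM = N_RBF + 12  # distance RBFs + sin/cos of 6 angles


@dataclass
class ProteinGraph:
    node_features: np.ndarray   # (L, NODE_FEATURE_DIM)
    edge_index: np.ndarray      # (2, E), rows (src j, dst i)
    edge_features: np.ndarray   # (E, 7) raw (d, theta, phi, omega, tau1..3)
    edge_encoded: np.ndarray    # (E, EDGE_FEATURE_DIM)
    ca_coords: np.ndarray       # (L, 3)
    cutoff: float = 10.0

    @property
    def n_nodes(self) -> int:
        return self.node_features.shape[0]

    @property
    def n_edges(self) -> int:
        return self.edge_index.shape[1]


def rbf_encode(d: np.ndarray, cutoff: float, n_rbf: int = N_RBF) -> np.ndarray:
    """Gaussian radial basis encoding of distances on [0, cutoff]."""
    centers = np.linspace(0.0, cutoff, n_rbf)
    width = cutoff / n_rbf
    return np.exp(-((np.asarray(d)[..., None] - centers) ** 2) / (2.0 * width**2))


def encode_edge_features(raw: np.ndarray, cutoff: float) -> np.ndarray:
    """RBF-encode the distance and sin/cos-encode the six angles."""
    raw = np.atleast_2d(raw)
    angles = raw[:, 1:]
    return np.concatenate(
        [rbf_encode(raw[:, 0], cutoff), np.sin(angles), np.cos(angles)], axis=1
    )


def build_graph(structure: ProteinStructure, cutoff: float = 10.0) -> ProteinGraph:
    """Ca radius graph with invariant node and edge features.

    Edges are symmetric and directed (both j->i and i->j are present); no
    self-loops.
    """
    if structure.n_residues == 0 or any("CA" not in r.atoms for r in structure.residues):
        raise ValueError("every residue needs a CA atom to build the graph")
    ca = structure.ca_coords()
    frames = [frame_of_residue(r) for r in structure.residues]
    node_feats = np.stack(
        [assemble_node_features(sidechain_torsions(r)) for r in structure.residues]
    )

    tree = cKDTree(ca)
    pairs = tree.query_pairs(r=cutoff, output_type="ndarray")  # i < j, d < cutoff
    # strict inequality: query_pairs includes d == r; drop boundary pairs
    if len(pairs):
        d = np.linalg.norm(ca[pairs[:, 0]] - ca[pairs[:, 1]], axis=1)
        pairs = pairs[d < cutoff]
    src, dst = [], []
    for i, j in pairs:
        src.extend((j, i))
        dst.extend((i, j))
    edge_index = np.array([src, dst], dtype=np.intp).reshape(2, -1)
    order = np.lexsort((edge_index[0], edge_index[1]))  # deterministic ordering
    edge_index = edge_index[:, order]

    raw = np.zeros((edge_index.shape[1], 7))
    for e in range(edge_index.shape[1]):
        j, i = edge_index[0, e], edge_index[1, e]
        raw[e] = backbone_edge_features(frames[i], frames[j]).as_array()
    return ProteinGraph(
        node_features=node_feats,
        edge_index=edge_index,
        edge_features=raw,
        edge_encoded=encode_edge_features(raw, cutoff) if len(raw) else raw.reshape(0, EDGE_FEATURE_DIM),
        ca_coords=ca,
        cutoff=cutoff,
    )


class EdgeGraphConv(nn.Module):
    """GraphConv with edge-feature gating via a Hadamard product."""

    def __init__(self, dim: int, edge_dim: int, rng: np.random.Generator):
        self.lin_self = nn.Linear(dim, dim, rng)
        self.lin_neigh = nn.Linear(dim, dim, rng, bias=False)
        self.gate = nn.Linear(edge_dim, dim, rng)

    def __call__(self, x: nn.Tensor, edge_encoded: np.ndarray,
                 edge_index: np.ndarray, n_nodes: int) -> nn.Tensor:
        if edge_index.shape[1] == 0:
            return self.lin_self(x)
        src, dst = edge_index
        if src.max() >= n_nodes or dst.max() >= n_nodes:
            raise IndexError("edge index out of range")
        gates = self.gate(nn.Tensor(edge_encoded))
        messages = gates * nn.take_rows(x, src)
        agg = nn.index_add_rows(messages, dst, n_nodes)
        return self.lin_self(x) + self.lin_neigh(agg)


@dataclass
class StructureEncoderConfig:
    d_struct: int = 128
    n_layers: int = 3
    cutoff: float = 10.0


class StructureEncoder(nn.Module):
    """Node embedding followed by stacked EdgeGraphConv layers with residuals."""

    def __init__(self, config: StructureEncoderConfig, rng: np.random.Generator):
        self.config = config
        self.embed = nn.Linear(NODE_FEATURE_DIM, config.d_struct, rng)
        self.convs = nn.ModuleList(
            [EdgeGraphConv(config.d_struct, EDGE_FEATURE_DIM, rng)
             for _ in range(config.n_layers)]
        )
        self.norms = nn.ModuleList(
            [nn.LayerNorm(config.d_struct) for _ in range(config.n_layers)]
        )

    def __call__(self, graph: ProteinGraph,
                 node_features: np.ndarray | None = None) -> nn.Tensor:
        feats = graph.node_features if node_features is None else node_features
        x = self.embed(nn.Tensor(feats))
        for conv, norm in zip(self.convs, self.norms):
            x = norm(x + nn.gelu(conv(x, graph.edge_encoded, graph.edge_index, graph.n_nodes)))
        return x
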