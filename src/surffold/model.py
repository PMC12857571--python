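"""Full inverse-folding model: featurization, ablation variants, decoding.

The model composes the structure encoder (Ca graph + EdgeGraphConv), the
surface encoder (chemical + curvature features through quasi-geodesic
convolutions), the 8-nearest-neighbor alignment + cross-attention fusion,
and a position-wise one-shot decoder that maps each residue's fused vector
independently to logits over the 20 amino acids.

Ablation variants are expressed as configuration flags:

========  ============  ===========  ==================  ====================
variant   use_sidechain  use_surface  use_knn_alignment   use_cross_attention
========  ============  ===========  ==================  ====================
model1    yes           no           --                  --
model2    no            no           --                  --
model3    no            yes          yes                 yes
model4    yes           yes          yes                 no
model5    yes           yes          no (global pool)    yes
full      yes           yes          yes                 yes
========  ============  ===========  ==================  ====================
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import nn
from .fusion import AlignmentFusion, FusionConfig, build_surf2struc_index, pool_aligned
from .structure import AA_INDEX, ProteinStructure
from .structure_encoder import ProteinGraph, StructureEncoder, StructureEncoderConfig, build_graph
from .surface import SurfaceConfig, atom_cloud_from_structure, sample_surface
from .surface_encoder import (
    SurfaceEncoder,
    SurfaceEncoderConfig,
    SurfaceFeatures,
    precompute_surface_features,
)

__all__ = [
    "ModelConfig",
    "ProteinFeatures",
    "featurize_structure",
    "SurfFoldModel",
    "build_model",
    "variant_config",
    "N_CLASSES",
]

N_CLASSES = 20


@dataclass
class ModelConfig:
    """Architecture and ablation flags for the full model."""

    use_sidechain: bool = True
    use_surface: bool = True
    use_knn_alignment: bool = True
    use_cross_attention: bool = True
    d_struct: int = 128
    d_surf: int = 128
    d_fuse: int = 128
    n_struct_layers: int = 3
    n_surf_layers: int = 3
    n_heads: int = 4
    dropout: float = 0.1
    cutoff: float = 10.0
    surface: SurfaceConfig = field(default_factory=SurfaceConfig)
    surf_encoder_scales: tuple[float, ...] = (1.0, 2.0, 3.0, 5.0, 10.0)
    surf_window: float = 6.0
    seed: int = 0

    def __post_init__(self):
        if not self.use_surface and (self.use_knn_alignment or self.use_cross_attention):
            raise ValueError(
                "knn alignment / cross attention require the surface branch"
            )


VARIANTS = {
    "model1": dict(use_surface=False, use_knn_alignment=False, use_cross_attention=False),
    "model2": dict(use_sidechain=False, use_surface=False,
                   use_knn_alignment=False, use_cross_attention=False),
    "model3": dict(use_sidechain=False),
    "model4": dict(use_cross_attention=False),
    "model5": dict(use_knn_alignment=False),
    "full": dict(),
}


def variant_config(name: str, base: ModelConfig | None = None) -> ModelConfig:
    """Ablation-grid configuration by name (model1..model5, full)."""
    if name not in VARIANTS:
        raise ValueError(f"unknown variant {name!r}; choose from {sorted(VARIANTS)}")
    base = base or ModelConfig()
    return replace(base, **VARIANTS[name])


@dataclass
class ProteinFeatures:
    """Precomputed per-protein arrays: everything the model consumes.

    Static geometry (graph, surface cloud features, alignment index) is
    computed once per protein; only the learned layers run per training step.
    """

    identifier: str
    graph: ProteinGraph
    labels: np.ndarray              # (L,) int codes, -1 for X/unknown
    mask: np.ndarray                # (L,) bool: scored positions
    surface: SurfaceFeatures | None = None
    surf2struc: np.ndarray | None = None  # (L, 8)

    @property
    def n_residues(self) -> int:
        return self.graph.n_nodes


def featurize_structure(structure: ProteinStructure, config: ModelConfig) -> ProteinFeatures:
    """Compute all static features for one protein under a model config."""
    graph = build_graph(structure, cutoff=config.cutoff)
    labels = np.array([AA_INDEX.get(r.name, -1) for r in structure.residues], dtype=np.intp)
    mask = labels >= 0
    surface = None
    surf2struc = None
    if config.use_surface:
        atoms = atom_cloud_from_structure(structure)
        cloud = sample_surface(atoms, config.surface, source_protein=structure.identifier)
        enc_cfg = SurfaceEncoderConfig(
            d_surf=config.d_surf, n_layers=config.n_surf_layers,
            scales=config.surf_encoder_scales, window=config.surf_window,
        )
        surface = precompute_surface_features(cloud, atoms, enc_cfg)
        surf2struc = build_surf2struc_index(graph.ca_coords, cloud.points)
    return ProteinFeatures(identifier=structure.identifier, graph=graph,
                           labels=labels, mask=mask,
                           surface=surface, surf2struc=surf2struc)


class OneShotDecoder(nn.Module):
    """Position-wise MLP from fused vectors to amino-acid logits.

    No coupling between positions: predictions are conditionally independent
    given the fused representation.
    """

    def __init__(self, d_in: int, rng: np.random.Generator, hidden: int | None = None):
        hidden = hidden or 2 * d_in
        self.mlp = nn.MLP([d_in, hidden, N_CLASSES], rng)

    def __call__(self, fused: nn.Tensor) -> nn.Tensor:
        return self.mlp(fused)


class SurfFoldModel(nn.Module):
    """The assembled structure + surface inverse-folding network."""

    def __init__(self, config: ModelConfig, rng: np.random.Generator | None = None):
        self.config = config
        rng = rng if rng is not None else np.random.default_rng(config.seed)
        self.structure_encoder = StructureEncoder(
            StructureEncoderConfig(d_struct=config.d_struct,
                                   n_layers=config.n_struct_layers,
                                   cutoff=config.cutoff), rng)
        if config.use_surface:
            self.surface_encoder = SurfaceEncoder(
                SurfaceEncoderConfig(d_surf=config.d_surf,
                                     n_layers=config.n_surf_layers,
                                     scales=config.surf_encoder_scales,
                                     window=config.surf_window), rng)
            self.fusion = AlignmentFusion(
                FusionConfig(d_struct=config.d_struct, d_surf=config.d_surf,
                             d_fuse=config.d_fuse, n_heads=config.n_heads,
                             dropout=config.dropout,
                             use_cross_attention=config.use_cross_attention), rng)
            d_dec = config.d_fuse
        else:
            self.struct_proj = nn.Linear(config.d_struct, config.d_fuse, rng)
            d_dec = config.d_fuse
        self.decoder = OneShotDecoder(d_dec, rng)

    def fused_representation(self, feats: ProteinFeatures, training: bool = False,
                             rng: np.random.Generator | None = None) -> nn.Tensor:
        node_features = feats.graph.node_features
        if not self.config.use_sidechain:
            node_features = np.zeros_like(node_features)
        a = self.structure_encoder(feats.graph, node_features=node_features)
        if not self.config.use_surface:
            return self.struct_proj(a)
        if feats.surface is None:
            raise ValueError(f"{feats.identifier}: no surface features precomputed")
        emb = self.surface_encoder(feats.surface)
        if self.config.use_knn_alignment:
            b = pool_aligned(emb, feats.surf2struc)
        else:
            # global mean pool broadcast to every residue
            b = emb.mean(axis=0, keepdims=True) * np.ones((feats.n_residues, 1))
        return self.fusion(a, b, training=training, rng=rng)

    def __call__(self, feats: ProteinFeatures, training: bool = False,
                 rng: np.random.Generator | None = None) -> nn.Tensor:
        return self.decoder(self.fused_representation(feats, training=training, rng=rng))

    def predict_sequence(self, feats: ProteinFeatures) -> str:
        from .structure import AMINO_ACIDS

        logits = self(feats, training=False)
        codes = logits.data.argmax(axis=1)
        return "".join(AMINO_ACIDS[c] for c in codes)


def build_model(config: ModelConfig) -> SurfFoldModel:
    """Construct a model from a configuration (validates flag combinations)."""
    return SurfFoldModel(config)
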