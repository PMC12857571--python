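"""Surface-to-structure alignment and bidirectional cross-attention fusion.

The surface cloud has far more points than the protein has residues.  Each
residue is aligned to its 8 nearest surface points (by Euclidean distance to
the Ca), whose embeddings are average-pooled to residue resolution.  The two
streams are projected into a shared width,

    a' = W_a a + b_a,    b' = W_b b + b_b,

refined by bidirectional multi-head cross-attention,

    AttnA = MHA(a', b', b'),    AttnB = MHA(b', a', a'),

and fused through residual + LayerNorm paths and a final MLP:

    a1 = LayerNorm(a' + Dropout(AttnA)),  b1 = LayerNorm(b' + Dropout(AttnB)),
    f_fused = MLP_fusion([a1; b1]).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn

__all__ = [
    "N_ALIGN",
    "build_surf2struc_index",
    "pool_aligned",
    "AlignmentFusion",
    "FusionConfig",
]

N_ALIGN = 8


def build_surf2struc_index(ca_coords: np.ndarray, surface_points: np.ndarray) -> np.ndarray:
    """Index (L, 8) of each residue's 8 nearest surface points.

    Exact nearest-neighbor search; ties broken by lower point index (stable
    sort).  With fewer than 8 surface points available, the sorted neighbors
    are cycled (sampling with replacement), so a single point repeats 8x.
    """
    ca_coords = np.atleast_2d(ca_coords)
    surface_points = np.atleast_2d(surface_points)
    if surface_points.shape[0] == 0:
        raise ValueError("empty surface point cloud")
    d = np.linalg.norm(ca_coords[:, None, :] - surface_points[None, :, :], axis=-1)
    order = np.argsort(d, axis=1, kind="stable")
    P = surface_points.shape[0]
    if P >= N_ALIGN:
        return order[:, :N_ALIGN].astype(np.intp)
    reps = int(np.ceil(N_ALIGN / P))
    return np.tile(order, (1, reps))[:, :N_ALIGN].astype(np.intp)


def pool_aligned(surface_embedding: nn.Tensor, index: np.ndarray) -> nn.Tensor:
    """Average-pool the 8 indexed embedding rows per residue -> (L, D_surf)."""
    return nn.take_rows(surface_embedding, index).mean(axis=1)


@dataclass
class FusionConfig:
    d_struct: int = 128
    d_surf: int = 128
    d_fuse: int = 128
    n_heads: int = 4
    dropout: float = 0.1
    use_cross_attention: bool = True


class AlignmentFusion(nn.Module):
    """Project, cross-attend and fuse the structure and surface streams.

    With cross-attention disabled (ablation), the projected streams pass
    through their LayerNorms and are concatenated directly into the fusion
    MLP.
    """

    def __init__(self, config: FusionConfig, rng: np.random.Generator):
        self.config = config
        self.proj_a = nn.Linear(config.d_struct, config.d_fuse, rng)
        self.proj_b = nn.Linear(config.d_surf, config.d_fuse, rng)
        if config.use_cross_attention:
            self.mha_a = nn.MultiHeadAttention(config.d_fuse, config.n_heads, rng)
            self.mha_b = nn.MultiHeadAttention(config.d_fuse, config.n_heads, rng)
        self.ln_a = nn.LayerNorm(config.d_fuse)
        self.ln_b = nn.LayerNorm(config.d_fuse)
        self.fusion = nn.MLP([2 * config.d_fuse, 2 * config.d_fuse, config.d_fuse], rng)

    def project(self, a: nn.Tensor, b: nn.Tensor) -> tuple[nn.Tensor, nn.Tensor]:
        if a.shape[0] != b.shape[0]:
            raise ValueError(f"row mismatch: {a.shape[0]} vs {b.shape[0]}")
        return self.proj_a(a), self.proj_b(b)

    def cross_attend(self, a_p: nn.Tensor, b_p: nn.Tensor) -> tuple[nn.Tensor, nn.Tensor]:
        return self.mha_a(a_p, b_p, b_p), self.mha_b(b_p, a_p, a_p)

    def fuse(self, a_p: nn.Tensor, b_p: nn.Tensor, attn_a: nn.Tensor | None,
             attn_b: nn.Tensor | None, training: bool = False,
             rng: np.random.Generator | None = None) -> nn.Tensor:
        p = self.config.dropout
        if training and p > 0 and rng is None:
            raise ValueError("training-mode dropout needs an RNG")
        if attn_a is not None:
            a1 = self.ln_a(a_p + nn.dropout(attn_a, p, rng, training))
        else:
            a1 = self.ln_a(a_p)
        if attn_b is not None:
            b1 = self.ln_b(b_p + nn.dropout(attn_b, p, rng, training))
        else:
            b1 = self.ln_b(b_p)
        return self.fusion(nn.concat([a1, b1], axis=-1))

    def __call__(self, a: nn.Tensor, b: nn.Tensor, training: bool = False,
                 rng: np.random.Generator | None = None) -> nn.Tensor:
        a_p, b_p = self.project(a, b)
        if self.config.use_cross_attention:
            attn_a, attn_b = self.cross_attend(a_p, b_p)
        else:
            attn_a = attn_b = None
        return self.fuse(a_p, b_p, attn_a, attn_b, training=training, rng=rng)
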