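# Methods

This note records the model as implemented, the choices made where the
design was genuinely open, and what the synthetic-data experiments do and do
not establish.

## Geometric features and conventions

Residue frames are built at the Cα by Gram–Schmidt on (N→Cα, Cα→C): x is the
unit N→Cα direction, z the unit normal of the N–Cα–C plane, y = z × x. The
frame is right-handed and equivariant: a rigid motion of the atoms rotates
the basis and translates the origin identically. Any fixed, consistent
convention works here; a different choice re-parameterizes the features by a
fixed rotation without changing their information content.

Per directed residue pair (j→i) the features are the spherical coordinates
(d, θ, φ) of Cα_j in frame i (θ polar from the frame z axis, φ azimuth,
both conventionally 0 when undefined, i.e. on-axis or coincident points);
the edge twist ω, computed as the dihedral x_i-axis / edge / x_j-axis so
that a pure translation gives ω = 0 and a rotation by α about the connecting
line gives ω = α; and the intrinsic Z–Y–Z Euler angles (τ₁, τ₂, τ₃) of
basis_i⁻¹·basis_j with τ₁, τ₃ ∈ (−π, π], τ₂ ∈ [0, π]. At gimbal lock
(τ₂ ∈ {0, π}) the decomposition is degenerate and τ₃ is fixed to 0; the
round-trip test (recomposing the rotation from the angles) covers this
branch. Dihedrals follow the standard sign convention, cross-checked
against biotite's backbone dihedrals: the synthetic α-helix reports
φ/ψ = −57°/−47°.

Side-chain torsions χ₁–χ₄ use the standard atom quadruples per residue type
(χ₁: N–CA–CB–γ, χ₂: CA–CB–γ–δ, …). Torsions the residue type does not
define, or whose atoms are missing, are encoded as (0, 0) with a zero mask
bit rather than imputed, so "no χ" is distinguishable from "χ = 0". All
angles enter the networks as (sin, cos) pairs to remove the 2π
discontinuity. These features are invariant under global rotation and
translation but **not** under reflection — ω flips sign exactly under a
mirror, and the Euler angles change — which is the desired behavior for a
chiral molecule.

## Synthetic structures

The generator builds polypeptides by natural-extension-reference-frame
placement with ideal covalent geometry (N–Cα 1.46 Å, Cα–C 1.52 Å, C–N
1.33 Å, trans peptide bonds, standard backbone bond angles) at helix
(φ/ψ = −57°/−47°), strand (−120°/+120°) or mixed torsions; consecutive
Cα–Cα distances come out at 3.80 Å. Side chains are placed out to the
χ-defining atoms with bond length 1.52 Å and angle 111°, at prescribed or
seeded-random torsions; branched residues carry the primary branch that
defines χ (e.g. CG1 for Val). Residue types are drawn uniformly from the 20
canonical amino acids unless a sequence is given. Multiple chains are laid
out 30 Å apart. The generator is a pure function of its spec: identical
specs give bit-identical coordinates.

What this emulates: correct local geometry, known ground-truth torsions and
labels, realistic Cα graph connectivity and a closed molecular surface.
What it does not: real rotamer statistics, full side-chain atom sets beyond
the χ chain, packing interactions, hydrogens, chain breaks, experimental
noise, or sequence–structure correlations learned from nature. Passing
tests on these fixtures therefore demonstrate correctness of the geometry,
the invariances and the optimization machinery — not biological recovery
rates on real proteins, which would require training on a real corpus such
as CATH.

## Surface generation

Atom radii are element-keyed van der Waals values (C 1.70, N 1.55, O 1.52,
S 1.80, H 1.10, others 1.80 Å). The surface is the level set SDF = 1.05 Å
of the soft-min distance function; the level, point budget and convergence
parameters are all exposed in `SurfaceConfig`. Evaluation uses a shifted
log-sum-exp, and the gradient is analytic (verified against central
differences at h = 10⁻⁴ Å to better than 10⁻⁴ relative).

Sampling seeds `init_points_per_atom` points per atom with Gaussian noise
(scale 3 Å, larger than any atom radius so most points start outside),
then iterates x ← x − sign(SDF−level)·min(|SDF−level|, level/4)·∇SDF/‖∇SDF‖
for at most 40 steps; points still more than 10⁻² Å from the level set are
discarded and counted. Interior cavity surfaces are not specially handled.
Downsampling keeps one point per occupied voxel of pitch `target_spacing`
and then greedily drops survivors closer than the spacing to an
already-kept point (voxel neighbors across a boundary can otherwise be
arbitrarily close); the result is deterministic, pairwise separated by at
least the spacing, and bounded above by the occupied-voxel count. Normals
are the normalized analytic gradient, pointing outward (toward increasing
distance). Surfaces are deterministic per (structure, config, seed) and are
computed once per protein at featurization time, not per training step.

## Surface encoder

Chemical features: for each surface point the 16 nearest atoms (with-
replacement padding below 16) contribute one-hot element type and inverse
distance; a per-neighbor MLP, mean pooling and a second MLP produce a
32-dim descriptor. Pooling makes the output invariant to neighbor order,
and the inputs involve only types and distances, hence rigid invariance.

Curvature: at each scale s ∈ {1, 2, 3, 5, 10} Å a Monge patch h(u, v)
(full quadric, Gaussian weights of width s/2) is fitted over neighbors
within radius s in the point's tangent frame, and H, K follow from the
first and second fundamental forms. Height is measured against the outward
normal so convex regions have H > 0; a sphere of radius R sampled at 2000
points recovers H = 1/R within 10% and K = 1/R² within 25% at scale 2 Å.
Points with fewer than 6 neighbors at a scale get zeros and a validity
flag. A quadric fit was chosen over covariance-eigenvalue shape estimates
because it yields a signed H and a true K.

Quasi-geodesic convolution: neighbor weights are
w_ij = exp(−d_ij²/2w²) with d_ij = ‖x_i−x_j‖(2 − ⟨n̂_i, n̂_j⟩) and window
w = 6 Å; weights below 10⁻⁴ are dropped. Neighbor offsets enter through
four fixed rigid-invariant kernels — the weight itself, the weight times
the Euclidean distance over the window, times the offset component along
the receiving normal over the window, and times the normal alignment —
each row-normalized by the total weight. A layer transforms point features,
aggregates them under the four kernels, concatenates with the point's own
features and applies an output transform; layers are stacked (3 by default,
width 128) with residual connections and LayerNorm. Because the kernels
carry all pairwise geometry as invariant scalars (the radial/normal/
tangential decomposition of the offset is recoverable from them), the
tangent gauge never appears and invariance is exact by construction, which
the invariance suite confirms end to end at 10⁻³.

## Structure encoder, alignment, fusion, decoder

The Cα radius graph uses a 10 Å cutoff (symmetric directed edges, no
self-loops, deterministic ordering); edge distances are RBF-encoded over 16
Gaussian centers on [0, cutoff] and angles as sin/cos. EdgeGraphConv gates
neighbor features by a learned linear projection of the edge encoding via a
Hadamard product; with the gate forced to 1 the layer reduces exactly to
GraphConv, which the test suite asserts. Three layers, width 128, residual
+ LayerNorm; isolated nodes keep their self term.

The Surf2Struc index stores, per residue, the 8 surface points nearest its
Cα — exact nearest neighbors with ties broken by lower point index, padded
by cycling when fewer than 8 points exist. At package scales (L ≤ a few
hundred, P ≤ a few thousand) the exact distance matrix plus a stable
argsort is the simplest implementation of that contract; a spatial tree
gives the same result asymptotically faster and could be swapped in for
larger inputs. Pooled surface vectors and structure vectors are projected
to a shared width (128), refined by one block of 4-head bidirectional
cross-attention with dropout 0.1 on the residual paths, and fused by a
2-layer GELU MLP. The decoder is a position-wise MLP to 20 logits; X and
dropped residues are masked from loss and metrics. Perplexity is always
computed without label smoothing so that the uniform predictor scores
exactly 20.

Ablation variants (backbone-only, ± side chains, ± surface, ± cross-
attention, global-mean instead of 8-NN pooling) are flag combinations of
the same model class; disabling the surface branch routes the projected
structure representation directly to the decoder, and disabling
cross-attention concatenates the LayerNormed projections.

## Training and numerics

All learnable components run on an in-package reverse-mode autodiff over
float64 numpy arrays; every primitive's gradient is tested against central
finite differences. Optimization is full-batch Adam (lr 10⁻³–2×10⁻³,
optional cosine schedule and gradient clipping), seeded end to end;
checkpoints store parameters, optimizer moments and the RNG state, and a
resumed run reproduces the uninterrupted continuation to 10⁻⁵. Training
aborts on non-finite loss.

The memorization experiment uses five 30-residue synthetic proteins with a
3 Å surface spacing (≈130 points per cloud) — sizes chosen so the whole
suite runs in well under a minute on one CPU while still exercising every
module; the full model reaches 95% training recovery in under 20 epochs.
The backbone-only ablation trains on the same fixtures but has strictly
less input information; on converged memorization runs its final loss is
never below the full model's.

## Known limitations

- No mmCIF input, hydrogen handling, or structure repair; residues missing
  any of N/CA/C are dropped with a warning.
- Cavity (interior) surfaces are not distinguished from the outer shell.
- The quasi-geodesic weight matrix is dense (O(P²) memory); fine for
  desk-scale clouds, not for very large proteins at fine spacing.
- Synthetic-data results certify machinery, not biological performance;
  no pretrained weights are shipped.
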