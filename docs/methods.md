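# Methods

## Representation

A single-chain protein is stored in the fixed "atom37" layout: per residue,
37 slots indexed by canonical PDB v3 heavy-atom name (`N, CA, C, CB, O`,
then side-chain atoms, with the optional C-terminal `OXT` last) plus a
presence mask.  Hydrogens are never represented.  Non-standard residues,
waters, hetero records and alternate locations other than `'A'`/blank are
dropped at parse time; a residue missing any of N/CA/C is rejected, because
those three atoms define the residue's local frame.  `OXT` is a valid
(optional) slot for every residue type — with it the per-residue valid-atom
sets jointly cover all 37 slots.

Residue frames follow the backbone construction: origin at Cα,
y = unit(N − Cα), u = unit(C − Cα), z = unit(u × y), x = y × z.  Frames are
rejected as degenerate when |u × y| < 1e-6 — real backbones never approach
this.  Frames and all graph features are computed once from the input
model's coordinates; features are not recomputed inside the network.

## Graph

Nodes are all present heavy atoms (or only N/CA/C/O in the backbone-only
variant).  Each node receives directed edges from its min(k, n−1) nearest
atoms, k = 128 by default.  Distances are quantized to 1e-6 Å before a
stable sort so that exact geometric ties — common in ideal periodic
helices — resolve identically under rigid motion, and ties break toward the
lower source index.  The graph is not symmetrized; messages flow source →
destination.

Edge scalars (49 per edge): 36 Gaussian RBF distance bins
(σ_d = 0.57 Å, centers 0…35·σ_d; values at far centers underflow to 0 in
float64, which is harmless), one covalent-bond flag (0.4 Å lower cutoff,
element covalent radii + 0.56 Å tolerance, all config-overridable), the
3-vector displacement in the source residue's frame, and the 9 entries of
the destination frame's axes expressed in the source frame.  The
relative-position/orientation features use the *source* atom's residue
frame.  All 49 are rigid-motion invariant; this is property-tested.

## Network

Type-0 state: per-node invariant scalars, embedded 57 → 32.  Type-1 state:
per-node equivariant 3-vectors, 16 channels.  Raw coordinates cannot seed
the type-1 state directly without breaking translation invariance, so the
initial vector state is each node's displacement to the centroid of its
edge sources, linearly expanded over channels — a documented design choice.

Each of the two blocks performs multi-head attention (4 heads) over each
node's incoming edges.  Queries are linear projections of node scalars.
The edge kernel is a one-hidden-layer ReLU map of [embedded edge features ∥
source scalars]; keys, scalar value messages, and vector gates are linear
in that kernel.  Vector messages are a channel-mixed copy of the source's
vector state plus the inter-node unit displacement scaled by the learned
gate — the only degree-1 operations used, so equivariance is exact rather
than approximate.  Attention logits are scaled by 1/√(head width) and
softmaxed per destination node (numerically stabilized with a detached
segment max); vector messages are aggregated with the head-averaged
attention weights.  Both aggregates enter through residual connections.
Each block ends with an equivariant normalization layer: layer norm with
learned gain/bias on scalars, and per-node RMS rescaling of vector channels
(ε-guarded, direction-preserving, zero vectors map to zero).

The output head projects the 16 vector channels to one 3-vector per atom
and is zero-initialized, so an untrained model predicts zero shifts and
refinement degrades gracefully to the identity.  The two blocks do not
share parameters.  All parameter initialization is seeded.  Computation is
in float64 throughout (the NumPy tape has no float32 mode; on CPU BLAS
there is no speed advantage to float32, and equivariance then holds to
~1e-8 rather than ~1e-4).

Automatic differentiation is a small in-package reverse-mode tape over
NumPy arrays (broadcasted arithmetic, ND×2D matmul, gather/segment-sum via
cached sparse scatter operators, exp/sqrt/relu/tanh, reductions, concat).
Gradients are verified against central finite differences in the test
suite.  A consequence of the architecture is that the last block's
scalar-path output parameters receive no gradient (the head reads only the
vector state); they are simply carried.

## Training

The regression target for an (initial, native) pair is the per-atom shift
after the native is rigid-body superposed (Kabsch, proper rotation) onto
the initial model over all shared heavy atoms — all atoms, not Cα only,
for consistency with the all-atom loss.  Superposition makes the target
invariant to independent rigid motions of either input (property-tested to
1e-6 Å).  The loss is the MSE over all shift components (Å²).

Optimizer: Adam, β₁ = 0.9, β₂ = 0.999, weight decay 0.001 (added to the
gradient), batch size 1.  The learning rate is not part of the protocol
constants; the default is 1e-3, chosen on the single-pair overfitting task
during development.  Epoch budget 50 with early stopping after 5 epochs
without validation improvement; the best-validation checkpoint is restored.
Structures longer than `crop_len` (default 1500 residues) are cropped to a
seeded random contiguous window, re-drawn per epoch.  Cross-validation
trains one model per fold (validation = the held-out fold; the same MSE is
the early-stopping metric) and `select_models` keeps the checkpoints with
the lowest validation loss, ties broken by fold index.  Desk-scale runs in
the tests and the acceptance script use 2-fold/small-epoch settings; the
protocol values remain the config defaults.

The public surface is the sklearn-style estimator `SE3Refiner`
(`fit`/`predict`/`transform`, `get_params`/`set_params`); `train_fold`,
`cross_validate` and `select_models` are thin functional wrappers over it.

## Metrics

* **Kabsch superposition**: closed-form SVD solution with the determinant
  correction enforcing a proper rotation; mirror images therefore retain a
  positive RMSD.
* **GDT-TS / GDT-HA**: mean over cutoffs ({1,2,4,8} / {0.5,1,2,4} Å) of the
  maximal fraction of Cα atoms superposable within the cutoff.  For n ≤ 10
  residues the search is exact by enumeration of all residue subsets of
  size ≥ 3.  Above that, a deterministic heuristic: contiguous seed
  fragments of several lengths are iteratively re-superposed on their
  within-cutoff subset to a fixed point, and from each fixed point the m
  best-fitting residues (every m) are retried as superposition subsets.  A
  contiguous-fragment search alone provably cannot always reach the
  optimum (counterexamples exist where the optimal subset is
  non-contiguous), which is why the small-n branch is exact.
* **lDDT**: all-atom, superposition-free; reference pairs are native atom
  pairs in different residues closer than 15 Å; a pair is preserved under a
  tolerance if the model distance differs by less than it; per-residue
  scores average the four tolerances {0.5,1,2,4} Å over the residue's
  pairs, and the global score averages residues.  No stereochemistry
  penalty is applied.
* **best_of_five**: argmax of GDT-HA over an ensemble's refined models,
  ties to the lower index.

## Synthetic data

`make_native` builds all-atom structures from ideal internal coordinates
(N–CA 1.458 Å, CA–C 1.525 Å, C–N 1.329 Å, C=O 1.231 Å; standard backbone
angles; trans peptide).  Geometries: ideal α-helix (φ/ψ = −57/−47),
extended β-strand (−139/135), or per-residue coil sampled across
Ramachandran basins with 10° jitter.  Cβ is placed with the L-amino-acid
improper (C-N-CA-CB = −122.6°, matching published ideal alanine
coordinates), and side chains come from one idealized internal-coordinate
rotamer per residue type, including closed aromatic/proline rings.  The
construction records its own covalent topology, which the distance-based
bond detection reproduces exactly on extended chains — the construction
oracle used in tests.

`perturb` derives an initial model by (1) Gaussian φ/ψ torsion noise
applied as rigid rotations of all downstream atoms, (2) isotropic Cartesian
jitter of standard deviation σ per coordinate (pre-superposition all-atom
RMSD σ√3), and (3) optionally a rigid displacement of a contiguous residue
block.  Defaults emulate the study conditions used throughout the tests:
σ = 0.5 Å jitter, no torsion noise, no block shift; datasets draw lengths
uniformly from 12–24 residues and geometries uniformly from
helix/strand/coil.

What the generator does *not* emulate: rotamer diversity, sequence-local
error correlation of real predictors, clash-free packing (idealized
rotamers in compact folds can clash sterically — visible as rare spurious
bond flags on coil fixtures), and multi-domain architecture.  Passing the
efficacy test therefore shows that the pipeline can learn to invert the
modelled noise process at desk scale, not that it reaches benchmark-grade
refinement of real predicted structures; that would require the original
training corpus and GPU-scale optimization, plus a final bonded-geometry
relaxation step, all outside this package's scope.

## Problem sizes and numerical choices

The test suite and acceptance script run entirely on synthetic structures
of 8–24 residues (≈60–190 atoms; at these sizes the k = 128 neighbour cap
makes the atom graph complete), a 40/10 train/test split for the efficacy
experiment, 12 training epochs with a 32/8 train/validation split, and 500
optimizer steps for the single-pair capacity check.  These sizes are the
package's chosen desk-scale defaults; all are config parameters.
Tolerances: frame orthonormality 1e-9, feature invariance 1e-7,
end-to-end equivariance asserted at 1e-4 (measured ~1e-12 in float64),
shift-target invariance 1e-6 Å.  Epsilons: 1e-8 in normalization layers and
softmax stabilization; 0-vector inputs stay 0.

## Known limitations

* Training is single-threaded NumPy.  Large proteins are supported by the
  KDTree KNN path for featurization, but training them at scale is outside
  this implementation's intended use.
* The KDTree branch (n > 2048 atoms) does not quantize distances, so exact
  ties could in principle order differently than the dense branch.
* The GDT heuristic above n = 10 is a lower-bound search; it can
  undershoot the true optimum on adversarial instances.
* lDDT excludes residues with no qualifying reference pairs from the
  global average.
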