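# Methods

## The design problem

Fixed-backbone protein sequence design asks: given only the backbone
coordinates of a target structure — the N, Cα and C atoms of each
residue, in Å — which amino-acid sequence will fold into it?  The
approach implemented here rests on a locality assumption: a sequence
whose every residue is compatible with its immediate structural
surroundings will tend to be compatible with the structure globally.
The package therefore (1) summarizes each residue position's
surroundings in a compact, rigid-motion-invariant representation,
(2) trains a classifier to predict a residue-type distribution from
that representation, and (3) designs sequences by iterated local
argmax reassignment.

## Local environments and their representation

For position *i*, the environment is the set of residues *j* whose Cα
lies within a cutoff *T* of Cα_i (default **T = 12 Å**, boundary
inclusive).  Each residue carries an orthonormal right-handed frame at
its Cα: x along Cα→C, y the Gram–Schmidt orthogonalization of Cα→N
against x, z = x × y.  A neighbor is described by three feature groups,
46 numbers in all:

* **21** — one-hot amino-acid type (20 canonical types in alphabetical
  three-letter order ALA…VAL, plus an unknown/non-standard channel at
  index 20).  During design the type comes from the *current working
  sequence*, so environments update as the sequence mutates.
* **12** — the relative rigid transform of the neighbor's frame
  expressed in the target's frame: the 3×3 rotation flattened row-major,
  then the neighbor's Cα position in the target's coordinates (Å, raw,
  no normalization).
* **13** — one-hot of the signed sequence offset *j − i* clipped to
  [−6, +6].  Exactly which 13 features encode sequence position
  is a package convention: the clipped signed-offset one-hot is the
  minimal 13-dimensional encoding.  Bin 0 (offset 0) is unreachable —
  a residue is never its own neighbor — and retained for symmetry.

Because rotations and translations are expressed relative to the
target's own frame, the whole representation is invariant under global
rigid motions of the structure and, because z = x × y fixes chirality,
sensitive to mirror reflection.  Neighbors are ordered by increasing Cα
distance with index tie-breaks; distances are quantized to 1e-6 Å
before comparison because idealized backbones contain exactly
equidistant neighbor pairs whose ordering would otherwise flip under
the ~1e-13 Å arithmetic noise of a rigid motion.  Ordering affects only
reproducibility of logs — the classifier is permutation-invariant.

## The classifier

A K×46 environment matrix is mapped to a 20-way distribution by:

1. a dense input projection 46 → d (default d = 256 = 16 heads × 16
   dims per head);
2. three transformer layers, each a masked multi-head self-attention
   sub-layer and a position-wise fully connected sub-layer (single
   linear + ReLU), each wrapped in a residual connection with
   post-layer normalization;
3. masked mean pooling over the K neighbor embeddings;
4. a dense head d → 20 with softmax.

No positional encoding is added; sequence information enters only
through the offset features, so the predictor is exactly
permutation-invariant over neighbors.  Variable-K batches are padded
and masked; masked keys receive a −1e9 attention score whose softmax
weight underflows to exactly zero, so padding provably never changes a
prediction.  The head covers only the 20 canonical types even though
inputs encode 21 — unknown types can be observed but never proposed.

The network is implemented directly in numpy (float32 parameters),
with hand-derived backpropagation verified against central finite
differences (relative error ~6e-8 in float64).  Training minimizes
mean cross-entropy (natural log) with Adam, β₁ = 0.9, β₂ = 0.999,
learning rate 1e-3, batch size 1000; shuffling is seeded and batches
are bucketed by K to minimize padding.  Epoch count is a required user
setting.  No dropout is applied by default.  Checkpoints embed the
config, alphabet and a format version; save/load round-trips reproduce
predictions bitwise.

Confidence of a prediction is its negative Shannon entropy Σ p ln p:
0 for a point mass, −ln 20 ≈ −2.996 for the uniform distribution.

## The design loop

The objective is the pseudo-likelihood P(S|B) ≈ Π_i P(s_i | env_i),
maximized coordinate-wise: starting from a uniform random (or supplied)
sequence, each step selects a position uniformly at random (with
replacement), evaluates the classifier on its current environment, and
assigns the argmax type (ties broken toward the lowest alphabet index).
Mutating position *i* changes the environments of all residues whose
neighborhood contains *i*; their conditional probabilities are
refreshed before the next step, and the per-step trace records the
full pseudo-log-likelihood (natural log, summed over positions with at
least one neighbor).  The traced value is maintained from cached
per-position terms that are bit-identical to fresh evaluations, so it
matches a from-scratch recomputation at any checkpoint.

Convergence is declared when no letter has changed for
`convergence_window` consecutive steps (default: one sequence length
n), with a hard budget of `max_iters` steps (default 20·n).  One
caveat documented as a reliability parameter: with uniform position
selection, a window of n steps can close while some position was never
visited (probability ≈ (1−1/n)ⁿ ≈ 0.37 per outstanding position), so
the fixed-point validation runs in this package use a window of 10·n,
for which that probability is ~4e-5.  Positions with no neighbor
inside the cutoff have no defined environment: they keep their initial
letter and are excluded from selection.  The pseudo-log-likelihood is
not guaranteed to rise monotonically — a local argmax can lower
neighboring terms — and only its finiteness and final-vs-initial
improvement on noiseless synthetic problems are asserted.

## Synthetic data: what it emulates and what it does not

Real training data is extracted from any directory of PDB/mmCIF files
(one labeled sample per residue with a canonical native type and ≥ 1
neighbor; train/test splits are by source structure, and an exclusion
list accepts the names an external sequence-similarity filter flags).
Because desk-scale testing cannot assume a structure corpus, two
generators stand in:

**Ideal toy backbones.**  α-helix (Cα radius 2.3 Å, rise 1.5 Å/residue,
100°/residue turn) and extended zig-zag (~3.8 Å Cα spacing)
parametrizations with N–Cα 1.46 Å, Cα–C 1.52 Å, N–Cα–C 111°; frames are
always well defined and validation finds no geometry faults.  These
reproduce realistic neighbor counts and distances but none of the
irregularity of real folds (loops, packing defects, long-range
contacts between secondary-structure elements).

**Toy-rule environments.**  Labeled datasets in which the residue type
is a *known* function of the environment, so estimator quality can be
measured against a closed form.  Two rules ship:

* `reference` (default): label = (K + b + t) mod 20, where K is the
  neighbor count, b the nearest-neighbor distance bucket (edges at 6
  and 9 Å), and t the nearest neighbor's type index.
* `geometric`: label = (K + b) mod 20.  Its labels depend only on
  geometry, so a structure has a well-defined rule labeling that is an
  exact fixed point of the design loop.  (The type-dependent rule is
  self-referential on a structure: any backbone contains
  mutual-nearest residue pairs, which impose a mod-20 cycle constraint
  that generic backbones do not satisfy, so no fixed point exists in
  general.)

With probability ε a label is redrawn uniformly over all 20 types,
giving a Bayes-optimal top-1 accuracy of exactly 1 − 19ε/20 (0.81 at
ε = 0.2).  Environment generation and label noise use independent
seeded streams, so datasets with equal seeds and different ε contain
identical environments.

The randomized-geometry generator for the reference rule is designed
as a controlled experiment: only the quantities the rule reads vary —
K ∈ {1, 2, 3}, the distances (all neighbors drawn inside one shared
bucket, ≥ 0.5 Å from its edges), and a single shared neighbor type —
while every nuisance factor is held fixed (identity rotations, one
canonical translation direction per distance rank, offsets equal to
rank).  The reason is identifiability at the dataset sizes the
recovery experiment uses: free nuisance variation (random rotations
are nine continuous numbers per neighbor) acts as a per-sample
fingerprint that a high-capacity classifier memorizes in preference to
the rule, so the measured accuracy would reflect overfitting dynamics
rather than estimator correctness.  Consequently, passing parameter
recovery demonstrates that featurization, masking, pooling, training
and inference are wired correctly — it does not demonstrate
robustness to the full variability of real structures, which no toy
generator provides.  The `geometric`-rule datasets, by contrast, take
their geometry from actual toy backbones with fully general rotations
and random working sequences.

## Numerical and design choices

* Natural logarithm everywhere (cross-entropy, confidence,
  pseudo-likelihood); only orderings and optimization depend on the
  base.
* float64 geometry; float32 network.  Permutation invariance holds to
  ~1e-6 (float32 summation-order effects), far inside the 1e-5
  assertion bands.
* Collinearity guard for frames at 1e-6 rad; real backbones never
  approach it.
* Argmax ties (measure-zero in practice) resolve to the lowest
  canonical alphabet index, making every pipeline stage deterministic
  given its seeds.
* Chain selection on file read defaults to the first chain with at
  least one complete backbone; residues missing any of N/Cα/C are
  dropped and reported, not imputed, because their frame is undefined.
  Multi-chain complexes are designed one protomer at a time; no
  cross-chain environment mode exists.
* Experiment scale: the trained-model validations use a reduced width
  (3 layers, 4 heads × 8 dims) and problem sizes of 5000 training
  environments / 2000 held-out (reference rule) and 60 toy structures
  (geometric rule), which train in a couple of minutes on a single
  CPU; the 256-wide default architecture is exercised by the
  structural checks and is the default for real use.

## Known limitations

* The classifier is CPU-bound numpy; training on corpus-scale data
  (millions of residues) is out of reach without a GPU framework —
  the architecture, not the implementation, is the contribution this
  package reproduces at desk scale.
* No sidechain, solvent-accessibility or secondary-structure features;
  the representation deliberately uses backbone geometry and neighbor
  types only.  A hook accepts externally computed per-residue
  accessibility values for confidence-correlation analysis.
* Design treats a single chain; inter-chain contacts are invisible.
* The convergence test is heuristic (no-change window); it certifies a
  coordinate-wise fixed point only with the caveat discussed above.
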