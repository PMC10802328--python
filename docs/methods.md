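# Methods

## Overview

`catrace` converts a cryo-EM density map plus chain sequences into a
connected, sequence-registered Cα backbone in two stages: per-voxel
classification by a 3D transformer, and sequence-to-structure alignment by
a hidden Markov model decoded with a unique-state Viterbi algorithm. This
note records the model definitions, the parameter choices and their
rationale, the numerical conventions, and what the synthetic-data tests do
and do not demonstrate.

## Voxel classifier

### Architecture

The classifier maps a 32×32×32 single-channel density sub-grid to
per-voxel class logits. The encoder is a ViT-Base-style transformer: the
input is split into non-overlapping 16³ patches (N = 8 patches), each
flattened and linearly embedded into K = 768 dimensions (with bias), a
learnable N×K positional encoding is added, and 12 pre-norm blocks follow
(LayerNorm → 12-head self-attention with QKV and output-projection biases
→ residual; LayerNorm → MLP 768→3072→768 with GELU → residual), closed by
a final LayerNorm.

Features from blocks 3, 6, 9, 12 and the raw input feed a U-Net-style
decoder with base feature width 16, doubling per level (16/32/64/128).
Decoder convolutions are bias-free and each is followed by non-affine
instance normalization and LeakyReLU (slope 0.01); the 2× upsampling steps
are kernel-2 stride-2 transposed convolutions. The schedule:

* **stem** (raw input, full resolution): residual block, two 3³
  convolutions 1→16→16 with a 1×1×1 shortcut;
* **skip chains**: z3 → three deconvolutions 768→32→32→32 (to 16³);
  z6 → two deconvolutions 768→64→64 (to 8³); z9 → one deconvolution
  768→128 (to 4³);
* **up path**: z12 is deconvolved 768→128 and fused with the z9 chain by
  a residual block (256→128); the remaining stages deconvolve
  128→64→32→16, concatenate their skip, and fuse with a single 3³
  convolution followed by 1, 0, and 1 extra refinement convolutions
  respectively (recorded as `decoder_refine=(1, 0, 1)` in `ModelConfig`
  so alternative schedules remain testable);
* **head**: 1×1×1 convolution with bias, 16 → C channels.

Two heads are used: C = 4 for backbone-atom typing (channel order Cα, C,
N, no-atom) and C = 21 for amino-acid typing (the 20 standard residues in
alphabetical one-letter order, then none/unknown). The instantiated
networks have 92,281,604 and 92,281,893 trainable parameters; the
difference, 289 = 17 × (16 + 1), is exactly the head delta, since
everything else is shared. The per-stage refinement-conv counts and the
residual stem are the schedule consistent with these totals under the
conventions above; the totals are verified exactly by the test suite by
instantiating and counting.

The implementation is pure NumPy: parameter arrays are created from an
explicit seeded generator in a fixed construction order, so parameter
counts are seed-invariant and forward passes are bit-reproducible.
Dropout (rate 0.1, applied after the patch embedding) is an architectural
marker that acts as the identity — the package performs inference and
desk-scale exercises only. Whether dropout belongs in the attention, the
MLP, or both is left open; since no training happens here, the choice has
no observable effect.

### Loss and class weights

Voxel labels are dominated by the no-atom/no-residue class, so class *c*
receives weight `w_c = 1 − n_c / Σ_k n_k` from the label counts; the C
weights always sum to C − 1. The training loss is

    L = −(1/N) Σ_n w_{y_n} · log softmax(x_n)_{y_n},

normalized by the sample count N. Note that several library
implementations of weighted cross-entropy instead divide by the sum of
the applied weights Σ_n w_{y_n}; the two conventions differ by a
batch-dependent factor. This package implements the N-normalized form and
tests it against an independent elementwise evaluation.

Training at corpus scale (thousands of maps, distributed optimization) is
out of scope; the optimizer settings a training loop would use (NADAM,
learning rate 1e-4, batch 720, 0.1 LR decay after five stagnant epochs)
are recorded in `TrainConfig` for provenance.

## Candidate extraction and clustering

Voxels with p(Cα) strictly greater than 0.4 become candidates (boundary
voxels at exactly 0.4 are excluded). The candidate's amino-acid vector is
taken from the 21-class grid at the same voxel, the none/unknown channel
dropped, and the remaining 20 entries renormalized (a voxel with all mass
on the unknown class yields a uniform vector). Thresholding happens
before clustering — cheaper, and the representative averages then run
over confidently predicted voxels only.

Clustering is single-linkage: candidates are vertices, pairs within 2 Å
are edges, clusters are connected components. This reads "within a 2 Å
radius" as pairwise proximity grouping and is deterministic and
parameter-free beyond the radius; note that single-linkage chains can
extend a cluster beyond 2 Å end-to-end. The representative is the member
closest to the member centroid (ties: lexicographically lowest
coordinate); it keeps its own lattice coordinate — re-centering onto the
centroid would leave the voxel lattice — but carries the cluster-averaged
detection and amino-acid probabilities. Output clusters are sorted by
representative coordinate, making the partition independent of input
order.

## The HMM

Each clustered site is a hidden state. With K states:

* **Transitions** γ (K×K): the distance between states i and j is scored
  by a Gaussian density with mean μ = 3.8047 Å and standard deviation
  σ = 0.036 Å — the empirical spacing of consecutive Cα atoms — widened
  by the scale factor Λ = 10 (effective width Λσ = 0.36 Å) so that the
  model tolerates lattice discretization and coordinate error. Rows are
  normalized over j ≠ i; the diagonal is zero ("any state to any other
  state" is read as excluding self-transitions, since a site cannot host
  two consecutive residues). Row normalization is performed in log space
  (log-sum-exp): with σΛ = 0.36 Å, a site 40 Å from everything else has
  densities ~e^−6000, which underflow to zero in linear space and would
  leave its row undefined.
* **Emissions** δ (K×20): the normalized geometric mean
  √(a_iv · b_v) / Σ_u √(a_iu · b_u) of the predicted amino-acid
  probability *a* and a background composition *b*. The background
  defaults to the Swiss-Prot release-statistics composition (renormalized)
  and is configurable; it regularizes over-confident predictions while a
  zero prediction still annihilates the emission. A state with an all-zero
  amino-acid vector is rejected at build time.
* **Initial distribution** Π: proportional to each active state's emission
  of the chain's first residue, normalized over the active set; if that
  symbol has zero emission everywhere (or is a non-standard residue), Π
  falls back to uniform over the active states. Π spans all currently
  active states rather than a high-emission subset.

Non-standard residues (X, U, ...) in a sequence emit uniformly (1/20)
from every state: they are uninformative for registration but still
consume a state.

## Unique-state Viterbi

A hidden state may appear at most once in a decoded path, because one Cα
site hosts one residue. Exact simple-path optimization is combinatorial,
so the decoder uses a history heuristic: each DP cell (t, j) stores the
score, backpointer, and visited-state set of its best partial path, and a
transition (t−1, i) → (t, j) is forbidden when j is already in cell
(t−1, i)'s visited set. Cost is O(T·K²) time and O(K²) memory for the
visited bitmap. The heuristic is not guaranteed optimal among simple
paths, but whenever the *unconstrained* Viterbi optimum is itself simple
the two coincide — verified exhaustively against brute-force enumeration
of all K^T state sequences on hundreds of random instances (K ≤ 7,
T ≤ 5), and the decoded path is asserted simple on every decode.

Numerical conventions: all decoding in log space with −∞ sentinels for
zero probabilities; DP ties broken toward the lowest predecessor state
index (reruns are bit-identical); a decode that reaches a step where
every extension is forbidden raises rather than returning a partial path.

Chains of a complex are aligned sequentially — by input (FASTA) order by
default, longest-first as an option — and the states consumed by a chain
are removed before the next one; the transition matrix is renormalized
over the remaining active set (assumption: the removed-state HMM
redistributes each row's mass over surviving targets). Alignment requires
at least as many active states as residues; a shortfall raises an error
naming the chain. The decoder materializes the active-set transition
matrix, which bounds practical problem sizes to a few thousand states —
the intended desk scale.

## Evaluation metrics

Predicted and reference Cα sets are paired one-to-one by greedy
distance-ascending matching under a 3 Å cutoff (all cross pairs sorted by
distance, ties by index; a pair is accepted iff both atoms are unused).
Greedy matching is deterministic and order-independent, but can return
fewer pairs than the optimal assignment on adversarial geometries; a test
documents a 3×3 instance where greedy finds one pair fewer than the
brute-force optimum. From the matching: recall = |pairs|/n_true,
precision = |pairs|/n_pred, F1 their harmonic mean, Cα match score =
|pairs|/n_pred, sequence match score = identical-identity fraction among
pairs (0 when there are none), and Cα quality score = match × n_pred /
n_true, clamped to [0, 1] (an over-built model could nominally exceed 1).
Under this pairing match × n_pred = |pairs|, so the quality score equals
recall — asserted as an internal identity. All metrics are invariant to
rigid translations applied to both structures.

## Synthetic data

`generate_backbone` produces seeded self-avoiding random walks with
exactly 3.8047 Å steps, pseudo-bond angles uniform in 80°–150° (a
protein-plausible band; no dihedral realism is needed for tracing tests),
uniform random dihedrals, and a 3.0 Å self-avoidance radius enforced
within and across chains. `simulate_predictions` emulates the classifier's
error modes: sites dropped with probability `p_drop`, Gaussian coordinate
jitter, amino-acid vectors drawn from Dirichlet(1 + c·e_true) with
concentration c (`None` = exact one-hot), Poisson(fp_rate·n) false
positives uniform in the 5 Å-inflated bounding box with uniform
amino-acid vectors. True sites draw detection probabilities from
Beta(20, 2) (mean ≈ 0.91); false positives from Uniform(0.41, 0.8) so
they pass the 0.4 threshold and genuinely stress the alignment.
`simulate_density` places unit-peak isotropic Gaussians at the Cα
positions on a padded lattice; its integral is n·(2πσ²)^{3/2} per voxel
volume, checked analytically. Under this unit-peak convention a wider
blur raises the raw peak (overlapping tails add) while spreading mass
into the background — the tests check the mass integral and the
diffuseness, not a peak decrease.

What passing these tests shows: the tracing stack is exact on clean
input (zero-noise closure recovers coordinates with RMSD 0 and 100%
identity) and robust to moderate emission noise, drops, and false
positives. What it does not show: performance on real maps, where density
is continuous, anisotropic, and resolution-dependent, classifier errors
are spatially correlated, and candidate counts can fall below residue
counts in poorly resolved regions. Noisy-recovery statistics are
computed over replicates satisfying the alignment precondition
(states ≥ residues); random draws where drops exceed false positives are
infeasible by construction and are skipped deterministically.

## Map and model I/O

Maps are read via gemmi with axes reordered to X,Y,Z-ascending; voxel
(i, j, k) sits at `origin + (i, j, k) · voxel_size` with 0-based indices
(Å externally, lattice indices internally). The origin comes from the
ORIGIN header words when set, else from NC/NR/NS-START. Densities are
min-max normalized to [0, 1] by default (constant maps → zeros); z-score
normalization is available. Maps are not resampled by default. Inference
tiles are 32³ with stride 32 (non-overlapping, matching the training
sub-grid convention); smaller strides give overlapping tiles whose
predictions are averaged, and stitching discards padding. Models are
written as Cα-only PDB (three-decimal coordinates); models beyond the
PDB fixed-width limits (≥ 100,000 atoms or > 26 chains) switch to mmCIF
with a warning.

## Known limitations

* The unique-state decoder is a heuristic; pathological instances exist
  where the best simple path is missed (exactness is claimed only where
  the brute-force oracle confirms it).
* Greedy metric matching can under-count pairs relative to optimal
  assignment on contrived geometries.
* The classifier ships untrained; map-based tracing with random weights
  exercises plumbing, not biology. Training infrastructure is out of
  scope.
* Dense K×K transition handling bounds alignment to a few thousand
  candidate states.
* The density simulator has no atomic form factors, solvent, or noise
  model; it is a geometric stand-in.
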