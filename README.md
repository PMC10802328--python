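# catrace

De novo C-alpha backbone tracing from cryo-EM density maps.

## The problem

Cryo-electron microscopy produces 3D density maps of protein complexes. At
medium and high resolution (~2-4 Å) the backbone is visible in the density,
but turning a map plus the chain sequences into an atomic model — without
homologous or predicted template structures — remains hard: the atoms must
first be *found* in the density, and then *connected* into chains with the
right amino-acid identity assigned to each position (sequence registering).

`catrace` implements this two-stage pipeline for researchers working on
automated map interpretation:

1. **Voxel classification.** A UNETR-style 3D transformer scores every
   voxel of a 32×32×32 map sub-grid. One head assigns backbone-atom
   classes (Cα, C, N, no atom), another assigns amino-acid classes (20
   residues + none/unknown). Training uses a weighted cross-entropy in
   which class *c* carries weight `w_c = 1 − n_c / Σ_k n_k` to counter the
   overwhelming no-atom majority. Voxels with p(Cα) > 0.4 become
   candidates, and candidates within a 2 Å radius are single-linkage
   clustered into one representative Cα site each.

2. **HMM sequence-to-structure alignment.** The clustered sites become the
   hidden states of an HMM λ = (γ, δ, Π). Transition probabilities depend
   only on inter-site distance *x* through a widened Gaussian

       f(x) = 1/(Λσ√(2π)) · exp(−(x−μ)² / (2(Λσ)²)),

   with μ = 3.8047 Å and σ = 0.036 Å (the consecutive Cα-Cα spacing
   statistics of known structures) and Λ = 10, row-normalized with zero
   diagonal. Emissions blend the classifier's per-site amino-acid
   probabilities *a* with background composition *b* by a normalized
   geometric mean √(a·b). Each chain sequence is decoded by a **unique-
   state Viterbi** — a Viterbi variant in which a hidden state may occur
   at most once in a path, since one Cα site can host only one residue —
   and the states a chain consumes are removed before the next chain is
   aligned. The result is a connected, fully registered Cα backbone.

The package also provides the evaluation metrics used for such models
(Cα recall/precision/F1 within 3 Å, Cα match score, sequence match score,
and the coverage-aware Cα quality score = match × n_pred / n_true), and a
synthetic-data module that generates ground-truth backbones, noisy
classifier outputs, and density maps so the entire pipeline is testable
without external data or trained weights.

## Worked example

Generate a synthetic two-chain protein, trace it from the (noise-free)
candidate table, and score the result against the ground truth:

```bash
catrace simulate --residues 60 --chains 2 --seed 7 --outdir demo
catrace trace --fasta demo/chains.fasta --candidates demo/candidates.tsv \
              --out demo/model.pdb
catrace eval --model demo/model.pdb --reference demo/reference.pdb
```

The trace step prints a run summary (abbreviated):

```json
{
  "n_candidates_input": 120,
  "n_candidates_above_threshold": 120,
  "n_clusters": 120,
  "n_chains": 2,
  "chain_log_scores": {"chain_A": -45.574288, "chain_B": -43.278149},
  "n_residues_placed": 120,
  "runtime_s": 0.079
}
```

All 120 residues of the two 60-residue chains were placed; the per-chain
log-scores are the log-probabilities of the decoded state paths. The
evaluation then reports

```json
{
  "recall": 1.0,
  "precision": 1.0,
  "f1": 1.0,
  "ca_match_score": 1.0,
  "seq_match_score": 1.0,
  "ca_quality_score": 1.0
}
```

i.e. every Cα of the model lies within 3 Å of its true position, with the
correct residue identity — the expected closure on noise-free input. With
emission noise, dropped sites, and false positives (see
`catrace simulate --help`) the scores degrade gracefully; the test suite
quantifies this.

A density map can be supplied instead of a candidate table
(`--map in.mrc`); the map is tiled into 32³ sub-grids, classified, and the
per-voxel probabilities stitched back before extraction. Without trained
weights this path exercises the plumbing with seeded random weights.

## Layout

| module | contents |
|---|---|
| `catrace.voxnet`, `catrace.nn` | 3D transformer classifier, NumPy layers |
| `catrace.losses` | class weights, weighted cross-entropy |
| `catrace.candidates` | thresholding, 2 Å clustering, candidate tables |
| `catrace.hmm` | HMM construction, unique-state Viterbi, chain alignment |
| `catrace.map_io` | MRC/CCP4, FASTA, PDB/mmCIF, tiling/stitching |
| `catrace.evaluation` | matching and model-quality metrics |
| `catrace.synthetic` | backbone/noise/density generators |
| `catrace.pipeline`, `catrace.cli` | orchestration and the `catrace` CLI |

See `docs/methods.md` for the model details, parameter choices, and known
limitations.
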