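# Methods

This note documents the modelling choices, defaults and limitations of the
package; the README describes the architecture itself.

## Structure parsing

Only `ATOM` records are read (fixed PDB v3.3 columns); HETATM, waters and
hydrogens are discarded, and elements are restricted to C, N, O, S. For
multi-model (NMR) files only the first model is used — the model treats one
conformation per protein. Alternate locations keep the highest-occupancy
record, ties resolved in favour of the earlier record in the file. Chains
are concatenated in file order with residue ordinals continuing
cumulatively, so a multi-chain file behaves like one sequence; atom order is
never changed anywhere in the pipeline, because the sequence-aware network
components give atom order semantic meaning. mmCIF is out of scope.

Unknown residue names keep their atoms but are flagged: their one-hot block
and physicochemical features are zero and a warning is emitted.

## Secondary structure and accessibility

The built-in assigner is a simplified Kabsch–Sander procedure. Amide
hydrogens are reconstructed 1 Å from N along the preceding C=O direction;
a hydrogen bond exists when the electrostatic energy
`0.084·(1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN)·332` falls below −0.5 kcal/mol.
Helices are residues covered by two consecutive n-turns (n = 3, 4, 5;
DSSP G/H/I), sheets are residues in parallel/antiparallel bridge patterns
(DSSP E/B), with helix taking precedence on overlap; everything else is
"other". Only this two-group collapse feeds the features, so full DSSP
fidelity (ladders, bends, chirality) is deliberately not reproduced.
A precomputed classic-format DSSP file can be imported instead, in which
case only the two-group mapping is applied. Residues missing backbone atoms
are labeled "other" with a warning.

Accessibility is Shrake–Rupley: 960 golden-spiral points per atom (an exact
analytic sphere when unoccluded; ≤1% quadrature error verified against a
Monte-Carlo oracle), probe radius 1.4 Å, van der Waals radii C 1.70 /
N 1.55 / O 1.52 / S 1.80 Å. Residue ASA is normalized by the theoretical
per-residue-type maximum (Tien et al. 2013 Gly-X-Gly values) and clipped to
[0, 1] — a residue-size-independent burial measure — rather than min-max
scaled per dataset.

## Featurization choices

* *Distance from the N-terminus* is `residue_ordinal / L`. The alternative
  reading "atom index / L" exceeds 1 for any multi-atom residue and would
  violate the feature's stated [0, 1] range, so the residue reading is used.
* *PSSM squashing* is the elementwise logistic, the common convention in
  fold-recognition feature pipelines; it is data-independent, maps the raw
  log-odds 0 to 0.5, and keeps the 20 columns in (0, 1).
* *Missing PSSM* files yield an all-zero score matrix (flagged synthetic),
  mirroring the zero-fill convention for missing B factors; after the
  logistic these columns sit at the uninformative midpoint 0.5.
* *B factors* are min-max scaled by the pooled training range and clipped;
  zero-filled (missing) B factors stay at 0 because the training minimum is
  never negative.
* Physicochemical scales (isoelectric point for charge, Grantham polarity,
  Charton polarizability, Kyte–Doolittle hydrophobicity) are embedded as
  versioned constants, normalized once at import to [0, 1] (charge to
  [−1, 1]).

## Normalization

Fitting uses training clouds only: each protein is centered at its own
centroid, the radii of all training atoms are pooled, and the single global
scale is the 95th percentile (linear interpolation) of that pool. Applying
divides every protein by the same scale, so between-protein size ratios are
exact and ~95% of training atoms land inside the unit sphere; non-globular
outliers extend beyond it by design. A degenerate training set (scale 0)
is an error.

## Sampling and augmentation

Clouds are reduced to the network's fixed input size by uniform random
subsampling followed by re-sorting into original atom order; clouds smaller
than the target are padded by cyclic repetition. Each training epoch draws a
fresh subsample and augmentation; evaluation clouds are sampled once with a
fixed seed and never augmented. Augmentation composes R_z·R_y·R_x rotations
with angles uniform on [0, 2π), uniform scaling in [0.9, 1.1], per-axis
translation uniform in ±0.1 (normalized units), and Gaussian jitter
σ = 0.005 clipped at ±0.02 — "slight" perturbations sized to the unit
sphere. Only coordinate columns are touched.

## Network defaults

Published descriptions of this architecture family leave hidden widths
open; defaults follow PointNet++ conventions and are fully overridable via
`ModelConfig`:

* set-abstraction MLPs (64, 64, 128), (128, 128, 256), (256, 512, 1024)
  with S = 512/128/1 centroids and K = 32 kNN grouping (ball query is not
  used; the grouping contract is "K nearest points", ties to lower index);
* inception modules with 16 filters per branch (kernels 1/3/5/7);
* dense head (512, 256) before the logits;
* ReLU nonlinearities and batch normalization after every convolution and
  dense layer except logit layers; He-normal initialization;
* Adam with lr 1e-3, β = (0.9, 0.999), batch size 32.

Local region coordinates are expressed relative to their centroid before
the shared MLP. Centroids enter the temporal network sorted by ascending
original atom index, restoring sequence semantics after farthest-point
sampling destroys order. The temporal network pools by 2 after each of its
six modules (512 → 8 rows before global average pooling); the first-level
centroid count must therefore be divisible by 2⁶.

Ablation switches remove a component's features from all downstream
concatenations and its auxiliary head; the remaining loss weights are
renormalized to sum to 1. Missing slots are omitted, never zero-filled.
With the structure extractor off, the temporal network receives
farthest-point-sampled points carrying raw + sequence features only.

"Plateau" is operationalized as a fixed epoch budget with last-20-epoch
summarization (population standard deviation), not early stopping.

## Synthetic data

The generator emulates the full input surface — PDB text, PSI-BLAST ASCII
PSSMs, a manifest — with parametric backbones built from ideal peptide
internal coordinates (NeRF construction): helices at (φ, ψ) = (−57°, −47°)
(1.5 Å rise, 100°/residue twist), extended strands near (−139°, 135°)
(≈3.3 Å/residue), and an antiparallel hairpin whose per-residue dihedral
table was fitted once so the classic alternating O(i)···N(2n+1−i) register
satisfies the package's own hydrogen-bond criterion; the table is sliced
symmetrically around the turn for shorter hairpins. Backbone atoms
N/CA/C/O plus CB are emitted (no side chains: the features need element
identity and geometry, not rotamers). Instances get Gaussian coordinate
noise (default σ 0.2 Å), B factors from U(5, 60), unit occupancy, a random
global rotation and translation, and a uniformly random sequence — class
identity is purely topological, never compositional, so the benchmark
rewards structural and order learning. Synthetic PSSMs draw self scores
around −2 + 8·conservation and background scores around −2
(conservation 0.9 by default; with random sequences the profile carries no
class signal and simply exercises the evolutionary feature path).

The three default classes are an all-α bundle and two mixed folds
(`ab_tail`, `ba_head`) with identical element composition — two helices
plus one β-hairpin — traversed in opposite order, so distinguishing them
requires sequence-order information. Coil linker dihedrals are drawn per
instance from a broad basin, varying packing within a class; a clash check
retries with fresh linkers up to 10 times.

What the generator does **not** emulate: side-chain packing, realistic
loop geometry at element seams, crystallographic noise structure,
sequence–structure correlation, or real SCOP fold diversity. Passing the
synthetic benchmark therefore demonstrates that the implementation learns
geometric/topological class structure end-to-end, not that it reproduces
published accuracies on curated fold datasets, which require the original
data and long GPU training.

## Benchmark scale

The end-to-end benchmark (3 classes × 30 structures, seed 7) uses the
`ModelConfig.reduced` preset — 256 input points, S = 64/16/1 centroids,
K = 16/8 neighbors, MLPs capped at 256, 8 filters per inception branch,
head (128, 64) — and 60 epochs at batch size 16. These sizes keep a full
run in the low minutes on a single CPU while preserving every architectural
mechanism of the default configuration; the default (1024-point, 1024-d)
architecture is exercised by forward-pass probes. On this benchmark the
full model reaches a last-20-epoch mean class accuracy ≥ 0.9 and removing
the temporal network lowers it; both models sit near the ceiling of this
deliberately separable task, so the ablation gap is small (the ordering,
not its magnitude, is the meaningful scaled-down observation).

## Numerical notes

* Forward/backward passes run in float32; the autodiff engine is
  dtype-agnostic and gradient-checked in float64.
* Farthest-point sampling starts deterministically at index 0 and breaks
  ties toward lower indices; kNN grouping uses stable sorts for the same
  tie-break. Max pooling distributes gradient over exact ties.
* Scatter-adds in gather backward use a sort/reduceat kernel; convolutions
  are sums of shifted slices — no Python loops over points.
* Training is bitwise reproducible given a seed: all randomness flows from
  `numpy.random.default_rng(seed)` streams, and batch-norm running
  statistics update deterministically.

## Known limitations

* The per-atom charge feature is a residue-level isoelectric-point scale,
  not a pKa- or atom-level charge.
* The simplified secondary-structure assigner can under-call sheets in
  noisy or irregular geometry compared to full DSSP.
* The NumPy implementation trains comfortably at benchmark scale but is not
  intended for GPU-scale training of the full 1024-point architecture on
  thousands of proteins.
* Checkpoints store flat parameter lists keyed by construction order; they
  are versioned but not portable across architecture changes.
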