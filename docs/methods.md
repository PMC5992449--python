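# Methods

`rpistack` predicts whether a non-coding RNA and a protein interact, from
their sequences alone. The model is a two-level stacked ensemble over three
feature views of a candidate pair; this note records the underlying model,
the numerical conventions, and the design choices made where more than one
reasonable construction existed.

## Feature encoders

### RNA: k-mer occurrence matrix reduced by SVD

A sequence of length L over {A, C, G, U} is scanned with a window of k
nucleotides (default k = 4), yielding the binary occurrence matrix
M ∈ {0,1}^(4^k × (L−k+1)) with

    M[i, j] = 1  iff the k-mer starting at position j is the i-th k-mer
                 in lexicographic order (A < C < G < U),

so every column holds exactly one 1. M retains composition, position and
order information; its row sums are the k-mer counts. The fixed-length
descriptor is the best rank-1 left factor of M: the leading left singular
vector u₁ scaled by the leading singular value σ₁, a 4^k-vector (256 at
k = 4) independent of L. Only the left factor lives in k-mer space, which
is why it — rather than a right factor or the singular values — is the
length-free choice. Singular vectors are defined up to sign; the sign is
fixed so the largest-magnitude component is positive. When σ₁ is
degenerate (ties occur for short or highly repetitive sequences) the
returned vector is a unit-norm element of the leading singular subspace
scaled by σ₁. Computation goes through the symmetric eigendecomposition
of the small 4^k × 4^k Gram matrix M Mᵀ rather than an iterative sparse
SVD solver: iterative solvers are not bitwise reproducible run to run,
and exact repeatability under a fixed seed is a contract of this package.

### Protein: pseudo-Zernike moments of the PSSM

A protein of length L is represented by its L×20 position-specific scoring
matrix (PSSM). With a local PSI-BLAST installation and a protein database
the profile is produced by `pssm_from_psiblast` (3 iterations, E-value
0.001, ASCII PSSM output; only the log-odds block of the file is parsed,
remapped to the library's alphabetical column order). Fully offline, the
BLOSUM62 pseudo-profile substitutes each residue's substitution-matrix row;
it carries composition and position structure but no alignment-derived
conservation, and is the default in tests and simulations.

The profile is treated as an image: scores pass through the logistic
function into (0,1) (so an uninformative zero profile becomes a flat 0.5
image), and the L×20 grid is mapped onto the unit disk by affinely scaling
each axis to [−1, 1] about the grid centroid. This is the standard
convention for image moments on rectangular rasters: the disk is inscribed
in the mapped bounding box, and pixels whose centres land at radius > 1
(the corners) are masked out. The anisotropic scaling means the "rotation"
to which the moment magnitudes are invariant is a rotation of the mapped
square image, not of the physical L×20 grid; the magnitudes should be read
as robust summaries of the profile's spatial structure rather than as
literal rotation invariants of the protein.

Pseudo-Zernike moments up to order n = 30 are computed by discrete
summation over in-mask pixels,

    A_nm = (n+1)/π · ΔA · Σ f(ρ, θ) R_nm(ρ) e^(−imθ),   0 ≤ m ≤ n,

with pixel area ΔA. Unlike ordinary Zernike moments there is no parity
constraint, so order ≤ 30 yields 496 moments. The radial polynomials are
evaluated through the Jacobi representation

    R_nm(ρ) = ρ^m · P_{n−m}^{(0, 2m+1)}(2ρ − 1),

whose three-term recurrence is stable at n = 30, where the alternating
factorial sum loses all precision (its leading coefficients reach ~10^17
while the result is O(1)). The factorial formula is retained as a
low-order test oracle; the two agree to 10⁻⁹ for n ≤ 10.

The protein descriptor is the first 240 moment magnitudes |A_nm| in fixed
(n ascending, m ascending) enumeration — orders 0–20 completely plus the
first nine moments of order 21. Truncating the 496 available magnitudes to
a fixed 240 preserves the printed descriptor-length contract while keeping
the enumeration unambiguous; magnitudes are non-negative by construction.
Two discretisation facts matter when interpreting these features: on an
L×20 grid, radial orders much above ~20 oscillate faster than the 20-pixel
axis resolves, so high-order magnitudes contain deterministic
discretisation residue rather than pure signal; and moment magnitudes are
exactly rotation-invariant only on square grids (verified to 10⁻⁶ relative
on synthetic square images).

The candidate-pair vector is the concatenation of the RNA and protein
blocks: 256 + 240 = 496 values.

### Raw composition features

The third view is the classic RPISeq-style pairing: normalised
sliding-window RNA 4-mer frequencies (256 values, same indexing as the
k-mer matrix) and protein conjoint-triad frequencies, where residues are
first reduced to the canonical 7 physicochemical classes
{AGV}, {ILFP}, {YMTS}, {HNQW}, {RK}, {DE}, {C} and 3-mer class frequencies
are counted over the 343 possible triads (599 values per pair in total).
Both vectors are probability distributions (sum 1) whenever the sequence
has at least one window.

## Stacked sparse auto-encoder

Each layer computes h = σ(xW + b) and is pretrained greedily as an
auto-encoder with a linear decoder, minimising the per-sample loss

    L = ‖x̂ − x‖² + λ Σ_j |h_j|

by Adam (mini-batches, default batch 100, 100 epochs; reduced epoch counts
are used in tests and the acceptance run, where 20 epochs suffice for the
loss to plateau on the simulated data). The L1 term drives most hidden
units towards zero activation; λ defaults to 10⁻⁴ and raising it to 10
measurably shrinks mean |h| on random data. An optional denoising
corruption (input masking) exists but is off by default, as no corruption
level is part of the default model. Default architecture: two hidden
layers of 256 and 128 units between the 496-dimensional pair input and the
forests.

Supervised fine-tuning deep-copies the pretrained stack, switches the
deepest hidden layer to ReLU, appends a 2-class soft-max head, and updates
all parameters by SGD with momentum (defaults 0.01 / 0.9) on the
cross-entropy, with inverted dropout (p = 0.5) on hidden activations during
training only — inference is dropout-free and deterministic. Both phases
draw all randomness (initialisation, batch order, dropout masks) from a
single seeded generator, so training is exactly reproducible.

Because the encoder units are sigmoids, the pair-feature block is min-max
scaled into [0,1] (parameters fit on the training split only) before
entering the auto-encoder; raw SVD magnitudes and moment magnitudes would
otherwise saturate the units. The raw composition view is already in
[0,1] and feeds its forest unscaled.

## Ensemble and evaluation

Three random forests (default 500 trees each, seeded) emit interaction
probabilities from the pretrained-SAE view, the fine-tuned-SAE view and the
raw composition view. The level-1 combiner is a logistic regression on the
probability triple p:

    P(+1 | p) = 1 / (1 + exp(−wᵀp − b)).

Equal weights make the stacked score a strictly monotone transform of the
column average, so stacking degenerates to averaging (identical rankings
and ROC); a single dominant weight approaches voting by one predictor.
Averaging and majority voting are implemented as alternative strategies
for comparison.

To keep the level-1 weights honest, they are fit on out-of-fold level-0
probabilities from an inner 3-fold stratified CV of the forests within the
training split, never on resubstitution probabilities. The two
auto-encoders are fit once per training split (the pretrained one uses no
labels; refitting the fine-tuned stack inside every inner fold was judged
not worth tripling the cost for the benefit of slightly less optimistic
level-1 inputs — the outer evaluation folds remain strictly untouched
either way).

Evaluation is stratified 5-fold cross-validation: accuracy, sensitivity,
specificity, precision and MCC from the 0.5-thresholded confusion table,
plus AUC from the trapezoidal ROC (equal to the tie-corrected
Mann–Whitney statistic). Zero-denominator rates are reported as NaN with
a warning and excluded from means; a zero-denominator MCC is defined as 0.
Fold assignment is stratified (plain random splitting destabilises small
minority classes) and seeded; the whole pipeline is deterministic under
one master seed.

## Synthetic data generator

The generator emulates a curated interaction table: `n_rna` RNAs and
`n_protein` proteins with i.i.d. uniform residues, lengths uniform in the
configured ranges (defaults 100–300 for both — typical desk-scale lengths
for ncRNA fragments and protein chains), and `n_pairs` distinct pairs
sampled uniformly. A pair is latently interacting exactly when its RNA
contains the RNA motif and its protein the protein motif (6-mers by
default); motifs are implanted with probability √(positive_rate) per
sequence, corrected for the chance of background occurrence, so the
latent positive fraction lands near the target rate (default 0.5).
Observed labels flip independently with probability `noise`. Both feature
families are composition-sensitive, so the planted signal is learnable by
every stage — that is the property pipeline-level tests rely on.

What the generator does **not** emulate: binding energetics, RNA secondary
structure, protein domains, homology and redundancy between sequences, the
skewed reuse of a few proteins across many pairs in real databases, or
class imbalance. A high cross-validated AUC on simulated data therefore
demonstrates that the machinery can extract a sequence-composition signal
end-to-end, not that it attains any particular accuracy on curated
benchmark datasets, which additionally require alignment-derived PSSMs.

## Problem sizes and defaults

Pipeline-level tests and the acceptance script use 500 pairs over 120 RNAs
and 120 proteins at 5% label noise, 20 pretraining/fine-tuning epochs, and
the default 500-tree forests; unit tests use smaller draws. These sizes
give stable fold metrics (SD of the stacked AUC ≈ 0.02) while keeping a
full 5-fold run plus its shuffled-label control in the minutes range on a
single CPU. Encoder defaults: k = 4, moment order 30, 240 protein
features. All defaults are overridable through `TrainConfig`,
`EnsembleConfig` and `SimulationConfig`.

## Known limitations

- The BLOSUM62 pseudo-profile is a stand-in for alignment-derived PSSMs;
  evolutionary conservation signal is absent offline, and the SA branches
  are correspondingly weaker than the raw-composition branch on simulated
  data.
- The 240-of-496 moment truncation and the disk-mapping convention are
  fixed library conventions; other conventions would yield different (but
  equally valid) descriptors.
- High-order moment magnitudes on short proteins (L close to 20) are
  dominated by grid discretisation.
- The level-1 logistic sees level-0 probabilities from forests refit in
  inner folds, but from auto-encoders fit once per training split (see
  above).
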