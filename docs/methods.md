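# Methods

This note documents the models, algorithms, and design choices behind the
package, in the spirit of a methods supplement: what is computed, under what
assumptions, and what the desk-scale experiments do and do not demonstrate.

## Problem setting

Hi-C assays measure genome-wide chromatin contact frequencies, but are
expensive enough that contact maps are missing for most cell types and
patient samples. The package implements a sequence-plus-epigenetics
predictor: given one-hot DNA and two 1D signal tracks (CTCF occupancy and
ATAC accessibility) over a fixed genomic window, it predicts the
log-transformed, normalized Hi-C contact map of that window at a fixed bin
size. Training is multi-task: the network simultaneously reconstructs the
contact map of a target cell type and classifies which cell type an input
track pair came from, with Gaussian noise augmentation of the target cell's
signals. The auxiliary classification task and the noise perturbation both
push the encoder to represent cell-type-specific signal features rather
than memorize the training cell's maps, which is what makes cross-cell-type
prediction work.

## Data model and conventions

* Coordinates are 0-based, half-open (BED convention) everywhere.
* A window of length `L` bp carries `n_bins = L / bin_size` bins; the
  divisibility is enforced, never rounded.
* Signal tracks are non-negative; missing coverage reads as 0. The
  "reversible natural logarithm" used throughout is the shifted log
  `y = ln(1 + x)` with inverse `x = exp(y) - 1`, which is finite at zero and
  exactly invertible; contact maps and epigenetic tracks are compared and
  learned on this log scale.
* Contact maps are symmetric; any operation that could break symmetry ends
  with an explicit `(M + M^T) / 2`.
* Chromosome-level dataset splits assign every window to exactly one of
  train/validation/test by its chromosome; windows never straddle splits.
* Re-binning a contact matrix between grids (e.g. 10 kb source to 8,192 bp
  model bins) uses area-weighted averaging: each target cell is the
  overlap-length-weighted mean of the intersecting source cells. This is
  grid-exact and conserves total contact mass; a nearest-source-cell
  variant is available behind a flag.

## Network

All tensor computation runs on a small reverse-mode automatic
differentiation core written on numpy (`chromnet.nn`): float64 throughout,
deterministic given seeds, with fused convolution primitives (sums of
shifted GEMMs) for speed. The package trains desk-scale models in minutes
on one CPU; it does not target GPU-scale runs.

The model has three units:

**Chromatin feature encoder.** Three stride-1, same-padded 1D convolutions
(default channels 7 -> 16 -> 32 -> 64, kernel 3), each followed by a
fixed-factor mean pooling stage; then two top-k pooling layers (per
non-overlapping patch, keep the mean of the k largest entries; k defaults
to 10 and is clipped to the patch length) that adapt the feature length to
the output bin grid; then a bidirectional LSTM (total hidden 256 by
default) whose per-bin states are linearly projected to the sequence
dimension (128). Pairwise interactions are formed as per-channel outer
products `P[c,i,j] = f[i,c] * f[j,c]`, giving a symmetric 2D stack with one
channel per feature dimension.

The only hard geometric constraint is that the encoder's total
downsampling — the product of the conv pooling factors and the two top-k
patch lengths — equals the bin size, so that exactly one feature vector
remains per output bin. The printed patch length of 10 cannot tile a
power-of-two bin size, so the default configurations use patch 4 at both
top-k stages (8·8·8·4·4 = 8,192 for the full-scale geometry; 4·4·4·4·4 =
1,024 for the toy geometry) and the chain is configurable.

**Chromatin interaction reconstructor.** A U-Net-style 2D decoder over the
pairwise stack: an initial 3x3 convolution (128 -> 256 channels by
default), then groups of pre-activation residual blocks (default five
groups at 256/128/64/32/16 channels, five blocks each) with dilations
cycling 1, 2, 4, 8, 16 across the blocks of a group; spatial mean-pool x2
and a 1x1 channel-reduction between groups; the decode path upsamples
(nearest) with skip connections and a 3x3 refinement per level, restores
256 channels, and a final 1x1 convolution yields the single-channel map,
symmetrized at the output. `n_bins` must be divisible by
`2^(groups - 1)`.

**Cell-type classifier.** The LSTM hidden states (the encoder's 256-wide
representation) pass through two 1D convolutions (256 -> 128 -> 64), global
mean pooling over bins, and two fully connected layers (-> 256 -> number of
cell types). Attaching the classifier after the LSTM (rather than before)
was a judgement call; the pre-LSTM alternative would see less context.

Open choices resolved here: pooling inside the reduction module is mean
pooling (top-k with k = patch degrades to it, making the chain coherent);
the LSTM is bidirectional with the two directions concatenated; prediction
symmetrization is applied at the head rather than learned.

## Training

Per training window the batch contains: the target cell's clean tracks
with the clean log-scale label; the target cell's noise-perturbed tracks
(Gaussian, mean 0, sd 0.1, added to log-transformed signals) paired with a
label whose *valid* entries — nonzero in the raw map — receive the same
Gaussian perturbation, noised on the upper triangle and mirrored so the
label stays symmetric; and each auxiliary cell's clean tracks with no
reconstruction label. Auxiliary items carry only classification
supervision, and only target-cell items are ever noised.

The joint loss is an unweighted sum, `L = L_recon + L_class`, with MSE on
log-scale maps and cross-entropy on logits (the conventional choices for
these heads). Optimization is Adam under linear warm-up (default 5 % of
steps) followed by cosine annealing to zero. Validation and inference use
clean target-cell inputs only. Ablation switches reproduce the reduced
configurations: `no_noise`, `no_aux` (both together give the
single-cell-type baseline), `only_ctcf`, `only_atac`.

Defaults that the printed record does not fix and that are therefore this
package's choices: base learning rate 5e-3 for toy models (1e-4 would suit
full scale), epochs per experiment as listed below, batch = one window's
item set, early stopping off unless configured.

## Evaluation

* **Insulation profile**: `score[i]` is the mean of the `w x w` submatrix
  spanning rows `i-w..i-1` and columns `i..i+w-1` (the square of contacts
  crossing bin boundary i); edge bins without a full square are NaN. Mean
  (not sum) aggregation keeps scores comparable across window sizes;
  the two are monotonically equivalent for correlation purposes. Default
  `w` = 10 bins, always recorded in reports. Lower score = stronger
  boundary; strict local minima are the boundary calls.
* **Insulation correlation**: Pearson and Spearman over bins scorable in
  both maps (ties get average ranks).
* **Distance-stratified correlation**: for each offset d up to 2 Mb /
  bin_size, Pearson/Spearman between the d-th superdiagonals;
  zero-variance diagonals give NaN with a warning.
* **Differential insulation and DTW**: profiles are z-scored (population
  sd) per vector; the differential profile is the elementwise difference of
  two z-scored profiles; DTW aligns two differential profiles with local
  cost `|x_i - y_j|`, no constraint band, the three standard moves
  (monotonic, continuous), ties preferring the diagonal; the distance is
  the cost sum along the optimal path.
* **Effect sizes**: Cohen's d with the pooled (n_a + n_b - 2) denominator;
  coefficient of variation as population sd over mean.

## Synthetic scenarios

The generator emulates the structures the method exploits, with analytic
ground truth:

* contacts: `M[i,j] = exp(-gamma |i-j|) * beta^{[same TAD]}` with optional
  multiplicative lognormal noise (symmetric field), gamma = 0.08/bin,
  beta = 3, noise sd 0.1 by default;
* CTCF: Gaussian peaks (height 8, sd 1 bin) centred on each cell type's
  boundary bins over a small shared baseline noise floor; ATAC: plateaus
  (height 4) over a per-cell-type "active" subset of TADs;
* at least two cell types share a configurable fraction of boundaries
  (shared peaks are bit-identical across cell types) and differ at private
  ones; optionally each cell type carries a global multiplicative track
  gain `exp(N(0, cell_gain_sd^2))` emulating assay-efficiency and depth
  differences between samples — the signal-level variation that noise
  augmentation is designed to absorb. The gain defaults to 0 and is
  enabled (0.3) in the cross-cell-type experiments.

With contact noise off, the insulation profile of a rendered map attains
its strict local minima exactly at the generator's boundary bins (TADs are
kept at least `min_gap` bins long so every boundary has a full insulation
square inside its flanking TADs). This is the cross-module fixture that
anchors boundary-recovery tests.

What the generator does not emulate: unmappable bins, translocations,
compartment-scale (plaid) structure, loop anchors, read-level noise.
Passing desk-scale tests therefore demonstrates that the implementation is
correct and that the training mechanisms behave as designed on TAD-like
structure; it does not certify real-genome accuracy.

## Desk-scale experiment geometry

Chosen so every experiment runs in minutes on one CPU:

* Toy model: 64 bins x 1,024 bp (window 65,536 bp), encoder channels
  8/12/16, pool factors 4/4/4, top-k patch 4, LSTM 48 hidden / 32 sequence
  dim, reconstructor groups 24/12 with 2 blocks each. The wide contextual
  stage matters: narrower LSTM/pairwise settings reconstruct the distance
  decay but blur TAD boundaries (insulation r plateaus near 0.65 instead
  of >= 0.9 on the overfit fixture).
* Overfit fixture: one 288-bin chromosome, 12 boundaries, 8 windows
  (500-kb-step analogue: 32-bin step).
* Cross-cell and perturbation fixtures: 32-bin windows over a 96-bin
  chromosome (5 windows, step 16 bins), 4 boundaries, shared fraction 0.5,
  per-cell track gain sd 0.3 and per-cell coverage noise sd 1.0 (the
  signal-level variation between cell types that noise augmentation
  targets); "held-out" windows for classification are the half-step-offset
  windows never used in training; 50 epochs per run.
* Full-scale geometry (256 bins x 8,192 bp, all printed channel widths) is
  exercised for shape and symmetry contracts only, untrained.

## What the desk-scale training experiments show

The overfit fixture verifies that the architecture has the capacity and the
trainer the correctness to drive reconstruction error far below its
starting point and recover the training cell's insulation profile
(Pearson >= 0.9). The cross-cell fixture compares, on matched seeds, the
noise + auxiliary-cell training configuration against the single-cell
baseline when predicting a cell type whose Hi-C was never used as
supervision. At this scale the comparison is informative but not flattering
to the full method: noise augmentation alone improves transfer under
per-cell signal variation, while the auxiliary classification task — whose
gradient pushes the two cell types' encoder features apart although
reconstruction is supervised only at target-cell features — often costs
more than it contributes at these model widths. The acceptance suite
reports this comparison as measured rather than asserting the full-scale
outcome; the corresponding test documents per-seed values on failure.

## Known limitations

* The autodiff core is single-threaded per op (BLAS may thread GEMMs) and
  holds the whole graph in memory; it is sized for desk-scale models.
* bigWig I/O requires pyBigWig; dense-text matrices stand in for cooler
  files (one matrix per window or chromosome with a coordinate header).
* The LSTM processes bins sequentially, so very long windows pay a Python
  loop cost per bin.
* Absolute insulation-score magnitudes depend on the (externally chosen)
  insulation window; only correlations and rankings are comparable across
  tools.
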