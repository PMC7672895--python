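# Methods

## The model

`deepfragk` recognizes protein folds in two stages built on the premise that
recurring backbone fragments of 4–20 residues act as structural "keywords":
a fold is characterized less by global sequence similarity than by the
mixture of fragment classes its sequence tends to form.

**Stage 1 — fragment classification.** Every sliding window of 4–20
residues (all lengths, stride 1) is mapped to a probability distribution
over a library of fragment classes (100 in the default configuration).
Each window is described by three feature groups:

| group | blocks (dimension) | total |
|---|---|---|
| sequence composition | functional-group frequencies (10), residue/dipeptide entropy (2), mean relative positions (20), group transitions (45) | 77 |
| physicochemical | type-1 pseudo amino acid composition (40), wavelet statistics of property profiles (42) | 82 |
| evolutionary | P-PSSM, PSSM-DC, Bi-gram PSSM, ED-PSSM (400 each) | 1600 |

Each group passes through its own stack of restricted Boltzmann machines
(RBMs) pretrained greedily with contrastive divergence (CD-1); the top
representations are concatenated and fused by a jointly pretrained RBM,
then classified by two fully-connected layers of width 1000 and a softmax
over the fragment classes. Pretraining uses logistic units (CD requires a
probabilistic unit); the fine-tuned feed-forward pass uses leaky-ReLU
(slope 0.01) throughout, with inverted dropout after every hidden layer in
training only. The first RBM of each stack has Gaussian visible units over
per-column standardized features (statistics from the training split,
stored in the checkpoint); deeper RBMs are Bernoulli–Bernoulli. After
generative pretraining the whole network is fine-tuned end to end with
cross-entropy — whether the fusion layer should also be fine-tuned is
genuinely open; we fine-tune it because it consistently helps on the
synthetic benchmarks and keeps the training loop uniform.

**Stage 2 — fold classification.** The per-window softmax outputs are
averaged into a per-sequence *fragment vector* (soft aggregation; a
hard argmax-histogram mode exists for ablation). A small CNN maps this
vector to fold probabilities: 10 one-dimensional filters of kernel 10
(COV1), overlapping max-pool of width 10 and stride 1 (MP1), a stacking
layer that arranges the 10 channel outputs as the rows of a 2-D map, 100
two-dimensional 10×10 filters spanning the full stack height (COV2),
max-pool of width 5 and stride 5 (MP2), two fully-connected layers of
width 100 and a softmax. All convolutions are 'valid' (no padding), which
is the only choice under which the printed kernel/stride values produce a
consistent shape chain; for the default 100-long input it is
100 → 91×10 → 82×10 → 10×82 → 1×73×100 → 1×14×100 → 1400. The MP2 window
is nominally 5×5 with stride 5, but the map after COV2 has height 1, so
the pool height is clipped to 1; the pool width is likewise clipped when
the map is narrower than 5. The minimum admissible input length is 28
(COV2 needs at least 10 columns after MP1).

## Tunable parameters

| parameter | default | notes |
|---|---|---|
| learning rate (Adam) | 1e-4 | full-scale protocol; desk-scale profile uses 1e-3 |
| batch size | 500 | desk-scale profile uses 100 |
| dropout | 0.5 after each hidden layer | desk-scale 0.2 |
| early stopping | patience 10 epochs on validation cross-entropy, min-delta 1e-4 | constants are ours; only the strategy is fixed |
| CD steps (k) | 1 | standard for pretraining |
| PseAAC weight w | 0.05 | conventional default |
| PseAAC max lag λ | 19 | a fragment of ≤20 residues supports lags ≤19; the block is zero-padded to the fixed width 40 = 20 + 20 |
| ED-PSSM lag d | 1 | configurable |
| modality layer widths | 77→256→128, 82→256→128, 1600→512→256; fusion 512 | not fixed by the method's description; chosen to taper toward the fusion layer and fully configurable |

The desk-scale profile (`deepfragk.benchmarks.reduced_train_config`,
widths 32/32/64, fusion 64, head 64×64) is the package's scaling of the
protocol to synthetic datasets of ~10³ samples, where batches of 500 give
two updates per epoch and heavy dropout slows convergence without
compensating benefit.

## Feature definitions and numerical choices

* **Functional groups.** Ten side-chain chemistry classes — {G}, {A,V,L,I},
  {S,T}, {C}, {M}, {P}, {F,W,Y}, {N,Q}, {D,E}, {K,R,H}. Ten groups are
  forced by the block dimensions (10 frequencies, C(10,2)=45 unordered
  transition pairs). Same-group adjacencies contribute to no transition.
* **Relative positions.** 1-based i/L (the last residue maps to 1.0),
  avoiding a 0/0 at L=1; absent residue types are exactly 0.
* **Entropies** are in bits (base-2), with 0·log 0 := 0.
* **PseAAC** is the classic type-1 form: Θ is the mean squared difference
  of three property values (Kyte–Doolittle hydropathy, Hopp–Woods
  hydrophilicity, classic side-chain masses), each standardized to zero
  mean and unit variance over the 20 residues (population sd); all entries
  share the denominator Σf + w·Σθ, so the populated prefix sums to 1.
* **Wavelet block.** Each of three profiles (hydropathy,
  Bhaskaran–Ponnuswamy flexibility, Rose mean accessible surface area) is
  linearly resampled to 32 points, decomposed by a 3-level orthonormal Haar
  transform (periodized), and summarized by {mean, sd, max} of the four
  sub-bands A3/D3/D2/D1 plus total coefficient energy and the Shannon
  entropy of the normalized squared coefficients: 14 statistics × 3
  profiles = 42. The recipe is length-invariant across 4–20 residue windows
  and orthonormal, so Parseval equality is a testable invariant. The
  statistic set itself is our choice; only the transform's name and the
  dimension 42 are fixed by the method.
* **PSSM blocks.** The literature defines PSSM dipeptide composition and
  bi-gram PSSM nearly identically; we deliberately distinguish them by
  input normalization — sigmoid-transformed scores with 1/(L−1) averaging
  for PSSM-DC, softmax row-stochastic profiles without averaging for
  Bi-gram (making it shift-invariant in the raw scores, whereas the
  sigmoid blocks are not) — so the two 400-dim blocks carry non-duplicated
  information. Sigmoid rather than min-max normalization keeps 4-residue
  windows comparable across fragments. ED-PSSM is the lag-d mean squared
  difference; it is non-negative and zero iff the compared value streams
  coincide.
* **Ties** in fold probabilities resolve to the lowest fold index (argmax
  convention).

## Metrics

Following this method's literature, "specificity" is per-class precision
(TP/(TP+FP)) and "sensitivity" is recall (TP/(TP+FN)); both are
macro-averaged (unweighted class means), with classes never predicted (or
never true) contributing 0 and flagged. The conventional TN-based
specificity is reported alongside. Cross-validation is stratified 10-fold;
the report carries both the fold-averaged and the pooled out-of-fold
metrics, since which of the two a summary number refers to is often
ambiguous.

## Synthetic data: what it emulates and what it does not

The generator encodes the two modelling premises directly:

* a **fragment class** is a consensus sequence of 4–20 residues plus
  per-position categorical noise; `motif_strength` is the probability mass
  on the consensus residue (1.0 collapses the class to its consensus,
  `motif_strength ≥ 0.8` is what the benchmarks mean by "well-separated");
* a **fold** is a mixture over fragment classes; sequences are built by
  concatenating sampled fragments to a target length (the last fragment is
  truncated);
* a **profile** for any sequence is the BLOSUM62 row of each residue plus
  rounded Gaussian noise (sd = `pssm_noise`, default 1.0), giving integer
  scores in the exact ASCII dialect.

Every generator is a pure function of (spec, seed). What this does *not*
emulate: real position-specific conservation (rows depend only on the
residue identity plus noise, not on alignment depth or position), SCOP-like
fold statistics, domain architecture, or length distributions of real
proteins. Passing the recovery benchmarks therefore shows the pipeline is
correctly wired and can extract class structure its features represent —
not that it attains any particular accuracy on natural sequences, which
additionally requires a real fragment library and database-search profiles.

## Benchmarks and their design choices

* **Stage-1 recovery** (`benchmarks.stage1_recovery`): 10 classes ×
  100 samples, motif strength 0.9, 80/20 stratified split, reduced widths.
  The negative control shuffles labels *before* the train/test split and
  averages over 5 independent shuffles: shuffling only training labels
  leaves a consistent ~1/k correctly-labelled subset from which a flexible
  model can genuinely learn class structure, biasing the control above
  chance; and a single noise-fit model's accuracy is a high-variance
  statistic.
* **End-to-end fold recovery** (`benchmarks.fold_recovery`): 32 fragment
  classes × 50 samples and 4 folds × 40 sequences of 40–56 residues, each
  fold concentrating 80% of its mixture mass on a disjoint block of 8
  classes. 32 classes (not 10) because the stage-2 CNN needs a fragment
  vector of ≥ 28 entries; 40–56 residues because a sequence is only a few
  fragment draws long, and much shorter sequences realize their fold's
  mixture too noisily for any classifier on top.
* **Determinism**: all randomness flows through seeded numpy generators,
  so identically-seeded runs (data generation, pretraining, fine-tuning,
  prediction) are bit-reproducible; verified by byte-comparing prediction
  tables of two full pipeline runs.

## Known limitations

* The exact 10-group partition, property tables, wavelet statistic set and
  PSSM-block constants used in the original method are not recoverable from
  its description; our choices reproduce every printed dimension but not
  necessarily the original feature values.
* RBM pretraining buys little on the well-separated synthetic benchmarks
  (supervised fine-tuning dominates); its value on real, noisier data is
  untested here.
* Whether fragment profiles should be excised from whole-protein profiles
  or computed per fragment is unspecified in the method; both paths are
  supported (`excise_profile` slices rows), and the pipeline uses excision
  for sliding windows.
* Windows whose profile slice is unavailable are dropped with a warning
  rather than zero-filled; stage-2 training uses all windows of a sequence,
  including mutually overlapping ones.
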