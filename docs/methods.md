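# Methods

## Problem and model

Chromatin loops called from HiChIP-style assays are region-level: each loop
anchor may contain several candidate enhancers, so an observed contact between
two anchors is ambiguous about *which* enhancer pair actually touches.
`encontact` addresses this with a sequence-only classifier. Anchor pairs with
exactly one enhancer per side ("1v1") provide unambiguous positive training
examples; anchor pairs with several enhancers on a side ("mvm") are expanded
into their inter-anchor cross product and fine-mapped by scoring every
candidate with the trained model.

The classifier reads the one-hot encoded sequences (L x 4, channels A, C, G,
T; N encodes as an all-zero row so convolutions contribute nothing there) of
the two enhancers through two *independent* convolution towers. Each tower
applies full-width kernels

    Conv(X)_i = ReLU( sum_{m=1..M} sum_{n=1..4} w_{mn} x_{i+m-1,n} ),

i.e. every kernel spans all four channels and slides along the sequence only,
followed by non-overlapping max-pooling of window W (a trailing partial
window is reduced over its members). The two pooled feature sequences are
concatenated along the *time* axis, so the subsequent bidirectional LSTM
traverses both enhancers in one pass; batch normalization and dropout sit
between the merge and the BLSTM. Attention pooling computes per-step scores
f(h_t) = tanh(w . h_t + b), softmax-normalizes them into weights

    alpha_t = exp{f(h_t)} / sum_k exp{f(h_k)},    theta = sum_t alpha_t h_t,

and the pooled state feeds a ReLU dense layer ending in a single logistic
unit: the probability the two enhancers are in contact. A pair is *called*
positive when its probability strictly exceeds 0.5.

The network is implemented directly on NumPy arrays with hand-derived
backward passes (convolution as an im2col matmul, standard LSTM
backpropagation through time, softmax-attention Jacobian); every layer and
the assembled model are verified against central finite differences in the
test suite. Training minimizes binary cross-entropy with Adam on shuffled
mini-batches and early-stops on a stratified 10% validation carve-out,
restoring the best-validation weights. Two deliberate choices make the
procedure well-behaved under uninformative labels: the logistic output
layer is zero-initialized, so the untrained model predicts exactly 0.5 for
every input, and that untrained state is itself an early-stopping
candidate — training that never beats the uninformative predictor on
validation is discarded rather than kept. An optional L1 penalty on the
convolution weights (`conv_l1`, default 0) is available to encourage
sparser kernels.

### Hyperparameters

Layer sizes are deliberately configurable; the defaults are the package's
own choice of a reasonable operating point, not published values:

| parameter | default | notes |
|---|---|---|
| enhancer length L | 2,000 bp | intervals re-centered on their midpoint |
| kernels per tower | 64 | benchmark tests use 16 |
| kernel length M | 8 bp | motif-scale receptive field |
| pool window W | 10 | benchmark tests use 5 |
| BLSTM units | 50/direction | benchmark tests use 16 |
| dense units | 128 | benchmark tests use 32 |
| dropout | 0.5 | benchmark tests use 0.15 |
| optimizer | Adam, lr 1e-3 | benchmark tests use 3e-3 |
| batch / epochs / patience | 64 / 50 / 5 | validation fraction 0.1 |

The two towers are untied and therefore order-sensitive; an optional swap
augmentation trains each pair in both orientations. A channel-axis merge is
available behind a flag as an alternative to the default time-axis merge.

## Dataset construction

Coordinates are 0-based half-open throughout. Anchor annotation counts any
>= 1 bp overlap between the (pre-normalization) enhancer interval and the
anchor; interactions with an enhancer-free anchor are dropped. 1v1 positives
are deduplicated as unordered pairs. Distances are midpoint-to-midpoint of
the normalized enhancers, and all pair sampling is restricted to single
chromosomes (distance is undefined across chromosomes).

Three negative backgrounds of increasing difficulty are provided:

* **random pairs** — uniform distinct same-chromosome enhancer pairs;
* **random enhancers** — one end of each positive kept (chosen uniformly),
  the other redrawn from the same chromosome;
* **random contacts** — distance-matched: positive distances are split into
  five equal-count quantile bins (ties at edges assigned to the lower bin)
  and each bin receives exactly as many negatives, drawn by rejection
  sampling among same-chromosome pairs whose distance falls in the bin.

All three exclude observed positives (as unordered pairs), are exactly
reproducible under a fixed seed, and fail loudly after a bounded retry
budget (100x the requested count) rather than looping forever.

Splits: a stratified random k-fold split (group 0 = test; an unstratified
mode exists behind a flag) and a by-chromosome split (default train =
chr1-chr18) that shares no enhancer between train and test.

## Motif read-out

A trained kernel is interpreted by scanning it without rectification,
S_i = sum_{m,n} w_{mn} x_{i+m-1,n}; positions with S_i strictly above half
the per-sequence maximum are *activated*, and their aligned length-M
subsequences are counted into a position weight matrix with a pseudocount of
0.5 per nucleotide. Sequences whose maximum score is not positive contribute
no sites, and kernels supported by fewer than 10 sites are discarded; both
constants are configurable. The scan corpus is the positive-labeled training
enhancers of the pair end matching the tower the kernel belongs to (scanning
a first-end kernel over second-end sequences only adds background sites),
forward strand only. PWMs are exported
in MEME minimal motif format for external matching, e.g.
`tomtom -thresh 0.1 kernels.meme JASPAR.meme`; TOMTOM itself is not wrapped.

## Accessibility and activity scores

Per-site openness is the depth-cancelling fold change O = N / (M/W): the
read count at the site over the mean per-site density of a W = 1 Mb window
centered on it. At chromosome ends the window is clipped but W in the
denominator stays nominal (configurable); a zero background defines O = 0.
The window includes the site/peak itself by default (a flag excludes it).
The co-opening degree of a pair is |Pearson r| of the replicate-averaged
openness vectors, flagged significant at p < 0.05 from the standard
correlation t-test. Constant vectors leave the correlation undefined and the
flag false.

Peak activity is the analogous density fold change PAS = (N/P)/(M/W); an
enhancer's activity score is the maximum PAS over overlapping peaks (EAS = 0
with no overlap) and the enhancer is *active* iff EAS > 1, strictly.
Activity across cell lines is the count of experiments in which an enhancer
is active.

Predicted positive pairs form an undirected simple graph (duplicates
collapse; multiplicity from repeated source regions is ignored); hub
enhancers are the ceil(0.1 n) highest-degree nodes, with ties at the cutoff
broken by enhancer id (an include-all-ties mode exists). Group contrasts use
the one-sided Wilcoxon rank-sum test in its normal approximation with tie
correction.

## Synthetic study conditions

The generator emulates the post-loop-calling representation of the assay; it
does not model Hi-C distance decay, ligation artifacts, GC composition, or
repeat structure, so passing tests demonstrate that the machinery recovers
signal it is designed for, not performance on real genomes.

* **Genome/enhancers** — i.i.d. uniform-composition chromosomes (default
  2 x 1 Mb); enhancers placed on a non-overlapping grid with jitter.
* **Pairs** — 40% of enhancers carry an instance of motif A, 40% of motif B,
  20% neither. Instances are sampled from sharp consensus PWMs (dominant
  base 0.94, information content about 1.6 bits/column) with a sharpening
  temperature of 0.5 and written into the central 80% of the enhancer, clear
  of pooling-edge effects. Positives pair an A-carrier (first end) with a
  same-chromosome B-carrier (second end); negatives never contain both
  motifs (patterns: no motif, a single carrier on either end, or the same
  motif on both ends) and are drawn to mirror the positive distance
  distribution across five quantile bins, so distance carries no label
  signal. Default 1,000 positives + 1,000 negatives; the benchmark used by
  the tests and the acceptance script is 1,250 + 1,250 500-bp enhancers
  split 2,000 train / 500 test.
* **Ambiguous regions** — each of 200 regions wraps one true pair with 1-3
  contiguous decoy neighbors per anchor, decoys chosen so exactly one
  candidate in the cross product is true and anchors never overlap.
* **Tracks** — per-site Poisson counts, rate = background plus a rectified
  smoothed Gaussian field per enhancer (correlation length L/150). Members
  of a designated co-opening pair mix a shared latent field with weight rho
  (default 0.9), giving field correlation exactly rho before Poisson
  thinning; replicates are conditionally independent draws.
* **Peaks** — 500-bp peaks over every enhancer; planted-active enhancers at
  5x background density (activity score well above 1), the rest at 0.7x
  (below 1 with high probability), so the planted active set is recoverable.

Every generator is a pure function of (config, seed) and byte-reproducible.
On the synthetic 1 Mb chromosomes the tests and the acceptance script use
background windows of 20-100 kb for the activity/openness scores — the 1 Mb
default is proportioned to real genomes, where clipping at chromosome ends
is rare — and lay enhancers out away from chromosome ends when measuring
activity recovery, since the nominal-W convention inflates fold changes in
clipped windows.

## Numerical choices and edge cases

* Softmax attention subtracts the per-sequence maximum score (shift
  invariance is exact); weights are strictly positive by construction.
* The logistic output is computed from the logit for loss purposes (no
  clipped probabilities in the gradient).
* Max-pooling breaks ties by the first maximal position (argmax).
* BatchNorm uses running statistics (momentum 0.9, eps 1e-5) at inference.
* Training is bit-reproducible for a fixed seed: one generator drives
  initialization, shuffling, dropout masks, and the validation carve-out.
* Sampling exhaustion, single-class training sets, constant openness
  vectors, inter-chromosomal distances, unknown chromosomes, and malformed
  BED lines all raise typed errors naming the offending entity.

## Known limitations

* **Kernel interpretability is bounded at small scale.** The kernel→PWM
  read-out is exact for sharp kernels (an ideal log-odds kernel of the
  planted motif recovers it with per-column correlation 1.0), but the
  kernels this architecture actually learns on the desk-scale benchmark are
  soft, distributed sub-motif detectors: the per-sequence half-max
  activation threshold then admits many background sites, and the extracted
  PWM reflects the kernel's own preference, which aligns with the planted
  motif at roughly 0.6-0.8 per-column correlation depending on
  configuration. Sweeping training length, dropout, kernel count and width,
  pooling width, batch normalization, and L1 strength moves this only
  within that range. Permissive motif matching (TOMTOM-style) is the
  appropriate downstream use; exact recovery of a planted PWM is not
  guaranteed.

* No GPU path and no framework backend; training beyond ~10^4 pairs of 2-kb
  enhancers is slow by design of scope.
* Reverse-strand information is ignored end to end (encoding, scanning,
  PWM counting); a reverse-complement augmentation would need both.
* The mvm expansion scores candidates independently; no joint model of
  competing candidates within a region.
* Hub degree ignores edge multiplicity from repeated source regions.
* The co-opening significance convention is p < 0.05 (a configuration
  switch can invert it); the test is the plain correlation t-test with no
  spatial autocorrelation correction, so on strongly smoothed tracks its
  p-values are optimistic.
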