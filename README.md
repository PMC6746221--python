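# encontact

Sequence-based prediction of enhancer–enhancer (E–E) chromatin contacts, with
fine-mapping of ambiguous region-level loops, motif read-out of learned
convolution kernels, and downstream accessibility/activity statistics.

## Who this is for

Chromatin loops called from HiChIP-style data are *region-level*: a loop
anchor often contains several candidate enhancers, so the observed contact is
ambiguous about which enhancer pair actually touches. `encontact` is for
regulatory-genomics analysts who want to

1. build labeled E–E training sets from loops (BEDPE) and enhancer
   annotations (BED) — unambiguous one-enhancer-per-anchor loops become
   positives, with negatives drawn from three backgrounds (random pairs,
   random enhancers, distance-matched "random contacts");
2. train a sequence-only neural classifier and use it to **fine-map** the
   ambiguous ("mvm") loops to enhancer resolution;
3. interpret the model by converting its convolution kernels into PWMs
   (MEME format, TOMTOM-ready); and
4. characterize predicted interactions: co-opening of enhancer pairs from
   DNase-style tracks, hub enhancers from the predicted network, and
   activity of hubs across experiments.

## The model

Each enhancer of a pair is one-hot encoded (L×4, channels A,C,G,T) and read
by its own convolution tower,

    Conv(X)_i = ReLU( Σ_m Σ_n w_mn · x_{i+m−1,n} ),   i = 1 … L−M+1,

followed by non-overlapping max-pooling. The two pooled feature sequences
are concatenated along the time axis, batch-normalized, and passed through a
bidirectional LSTM; attention pooling

    α_t = exp{f(h_t)} / Σ_k exp{f(h_k)},   f(h) = tanh(w·h + b),
    θ   = Σ_t α_t h_t

summarizes the hidden states, and a ReLU dense layer with a logistic output
gives P(contact). Pairs with probability strictly above 0.5 are called
positive. The network is implemented in NumPy with hand-derived backward
passes (verified against finite differences in the test suite); training is
Adam on binary cross-entropy with early stopping on a stratified validation
carve-out.

Downstream statistics: per-site openness O = N/(M/W) (read count over the
1-Mb-window background density — a depth-free fold change); co-opening
degree = |Pearson r| of two enhancers' openness vectors; peak activity
PAS = (N/P)/(M/W); enhancer activity EAS = max PAS over overlapping peaks,
"active" iff EAS > 1; hub enhancers = top 10% of degree in the predicted
interaction network. See `docs/methods.md` for every convention and default.

## Worked example

Everything runs on self-contained synthetic fixtures in which contact truth
is carried by a planted motif pair (motif A in one end, motif B in the
other; negatives never carry both, and their genomic distances mirror the
positives, so sequence is the only usable signal):

```sh
encontact synth   --outdir demo --seed 1 --n-enhancers 400 \
                  --enhancer-length 500 --n-pos 1250 --n-neg 1250
encontact train   --pairs demo/pairs.tsv --fasta demo/genome.fa \
                  --enhancers demo/enhancers.bed --config model.yaml \
                  --outdir demo/run --seed 1
encontact evaluate --model demo/run/model.npz --pairs demo/pairs.tsv \
                  --fasta demo/genome.fa --enhancers demo/enhancers.bed \
                  --outdir demo/eval
encontact finemap --model demo/run/model.npz --interactions demo/mvm.bedpe \
                  --enhancers demo/enhancers.bed --fasta demo/genome.fa \
                  --outdir demo/finemap
```

With the benchmark configuration (16 kernels of width 8, pool window 5, 16
BLSTM units per direction; 2,000 training and 500 held-out pairs) the run
reported by `scripts/acceptance.py --seed 1` prints

```
test_auroc                    = 0.98   held-out discrimination of true contacts
label_shuffled_control_auroc  = 0.53   training on scrambled labels learns ~nothing
finemap_top1_recovery         = 0.92   fraction of ambiguous regions whose
                                       top-scored candidate is the planted pair
negative_sampling_ks_pass_rate= 1.00   distance-matched negatives are
                                       indistinguishable from positives (KS, α=0.01)
coopening_degree_linked_mean  = 0.69   |r| for pairs sharing a latent
coopening_degree_null_mean    = 0.10     accessibility program vs independent pairs
active_enhancer_recovery_accuracy = 1.00  planted-active set recovered from peaks
```

An AUROC near 1 on held-out pairs together with a chance-level shuffled
control says the model discriminates through the planted sequence signal and
nothing else; the fine-mapping rate is the fraction of region-level loops
correctly resolved to their true enhancer pair at single-candidate rank.

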