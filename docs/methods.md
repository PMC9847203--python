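# Methods

## The prediction problem

DNA N4-methylcytosine (4mC) is an epigenetic modification of cytosine.
Benchmarks for 4mC-site prediction present the task as binary
classification of fixed-length sequence windows: a 41-nt window with the
candidate cytosine at the central position (0-based index 20) is labeled
positive when that cytosine is methylated.  `mc4pred` implements a deep
sequence classifier for such windows together with its evaluation
protocol and a synthetic benchmark generator, so the whole pipeline runs
and is testable without any external downloads.

## Encoding

Windows are validated (length, {A,C,G,T} alphabet after uppercasing,
center `C`; the center check can be relaxed for exploratory inputs) and
encoded with the integer map A→0, G→1, C→2, T→3.  Encoding is a per-symbol
bijection; decoding inverts it exactly.  Any other character — including N,
U, gaps and IUPAC ambiguity codes — is rejected rather than imputed, since
the map defines only four symbols and silent imputation would corrupt the
signal.  A `skip_invalid` mode drops failing records with a logged count
for bulk screening.  Coordinates are 0-based internally; no
reverse-complement augmentation is applied — windows are taken as written.

## Architecture

The stack, in order (default hyperparameters in parentheses):

1. **Adaptive embedding** (width 8): a learned lookup from the 4 integer
   codes to continuous vectors, trained end-to-end with the classifier —
   as opposed to fixed one-hot or pretrained word vectors.
2. **Bi-LSTM** (6 units per direction) returning the full sequence;
   forward and backward per-position outputs are concatenated (width 12).
   Cell equations use one bias vector per gate (order: candidate, input,
   forget, output), so the layer carries 2·4·(8+6+1)·6 = 720 parameters.
3. **Multi-scale CNN**: parallel stride-1 1-D convolutions with kernel
   widths 3, 5 and 7 (9 filters each), no padding, ReLU, then dropout
   (rate 0.3) per branch.  Output lengths are 41−k+1 = 39/37/35.
4. **Concatenation along the length axis** (39+37+35 = 111 positions × 9
   channels) and flatten (999 features).  Length-axis concatenation is
   forced by the printed output shapes; the branches share a channel count,
   not a length.
5. **Dense head**: 27 (ReLU) → dropout 0.3 → 9 (ReLU) → 1 (sigmoid), the
   output being the 4mC probability.

No pooling layers are used: the branch output lengths above are only
consistent with unpooled stride-1 convolutions.  Total trainable
parameters: 29,661.  The per-layer ledger is exposed by
`count_parameters`/`summary_table` and counted from the realised weight
arrays, never from formulas.

Activation choices (ReLU internally, sigmoid output) are the standard ones
for a binary sequence CNN; the probability output forces the sigmoid.
Note that many framework LSTM implementations keep two bias vectors per
gate; this implementation keeps one, matching the cell equations and the
720-parameter count.

## Numerical implementation

The network, backpropagation and Adam are implemented directly in numpy:
parameters live in a flat dict of arrays, the forward pass caches
activations, and gradients are computed analytically (verified against
central finite differences to ~1e-10 relative error in the test suite).
Convolution uses `sliding_window_view` + einsum.  The sigmoid and the
binary cross-entropy are computed in their numerically stable log1p forms.

Initialisation: embedding ~ N(0, 1); Glorot-uniform input, convolution and
dense kernels; orthogonal LSTM recurrent kernels; zero biases except the
LSTM forget-gate bias (1.0).  The unit-scale embedding is load-bearing: a
small-range uniform init starves the LSTM of input variance and the whole
stack can sit on the chance plateau for tens of epochs, sometimes
permanently at higher learning rates.  All initial weights derive from a
single integer seed.

## Training

Binary cross-entropy (forced by the sigmoid output), minibatch Adam
(learning rate 3e-3, batch 32, up to 150 epochs), and an L2 weight penalty
of 3e-3 on every weight matrix and the embedding (not biases).  A
stratified 20% of the training data is held out as a validation set;
early stopping monitors validation loss with patience 40 and the weights
of the best epoch are restored.  The long patience is deliberate: the
validation loss of this model moves in plateaus, and short-patience
stopping systematically returns an undertrained model.  With fewer than
~1000 training windows the weight penalty is what separates motif learning
from memorisation — without it the model reaches zero training loss at
chance-level held-out accuracy.

One master seed derives, via `numpy.random.SeedSequence`, the independent
seeds for weight init, the validation split, epoch shuffling/dropout and
fold assignment, so a single integer reproduces a whole run bit-exactly.

Cross-validation follows the standard 10-fold protocol: stratified folds
(sizes within each class differ by at most 1, via scikit-learn's
`StratifiedKFold`), a freshly initialised model per fold trained on the
other nine, evaluation on the held-out fold at threshold 0.5.  Per-fold
metrics are averaged arithmetically; pooled-prediction metrics are also
reported, since the two aggregations differ in general.

## Evaluation

Sensitivity Sn = TP/(TP+FN), specificity Sp = TN/(TN+FP), accuracy
Acc = (TP+TN)/N and the Matthews correlation coefficient
MCC = (TP·TN − FP·FN)/√((TP+FP)(TP+FN)(TN+FP)(TN+FN)).  Conventions,
fixed for bit-reproducibility:

- a probability equal to the threshold is called **positive** (`>=`);
- any metric with a zero denominator is defined as 0 (relevant at sweep
  extremes where one class empties);
- reported values are rounded **half-up** to 4 decimals (so 137/160 =
  0.85625 prints as 0.8563); internal values stay full-precision;
- the default operating threshold is 0.5; the sweep grid is 0.1–0.9 in
  steps of 0.1.

## Synthetic data

The generator emulates the shape of curated 4mC benchmarks: balanced
classes, 41-nt windows, forced center `C`, and a class-discriminating
sequence signal.  Defaults are 746+746 windows (the size of the standard
mouse training set), uniform background, and a length-6 consensus motif
(`GAGTCA`) planted in positives only.

Signal strength is one dial, `match_prob` ∈ [0.25, 1]: each motif position
emits its consensus base with that probability and one of the other three
bases uniformly otherwise.  At 0.25 with uniform background the planted
positions are exactly uniform — the classes are exchangeable and any
classifier's expected accuracy is 0.5.  At 1.0 every positive carries the
exact consensus.  The motif start is drawn uniformly from the positions
within `placement_halfwidth` (default 5) of the anchor (default: ten
positions left of center) that keep the motif inside the window and off
the center; with the defaults that is starts 5–14 (a start of 15 would
cover the center, so it is excluded — the center must stay uninformative).
A degenerate consensus with i.i.d. per-position corruption was chosen over
a full position weight matrix as the simplest generator whose strength is
a single interpretable number; a PWM would be a natural extension.

What the generator does **not** emulate: homology structure between
windows (real benchmarks are identity-clustered), non-uniform genomic
base composition, sequencing-chemistry error profiles, or multiple/partial
motifs.  Passing tests on this data therefore show that the pipeline can
extract a planted localised signal — not that it attains any particular
accuracy on real genomes.

### Information limit of the planted signal

The generative model admits an exact likelihood-ratio classifier: score a
window by the mean over valid offsets of the product over motif positions
of P(base | consensus, match_prob)/P(base | background).  Monte-Carlo
evaluation of this Bayes-optimal rule at the default settings with
`match_prob = 0.9` gives accuracy ≈ 0.92 (Sn ≈ 0.89, Sp ≈ 0.96): with a
length-6 motif at 90% per-position fidelity, about 11% of positives are
simply not distinguishable from background.  Trained-model accuracies on
this data must be read against that ceiling, and the learnability test in
the acceptance suite sits close to it by construction.

## Problem sizes in tests

The test suite trains at 600+600 train / 150+150 test (three seeds) for
the learnability and null-safety checks, and uses scaled-down windows
(15 nt) and architectures for contract tests, keeping the default suite
in the minutes range on one CPU.  The acceptance script itself only
builds the model and counts parameters, which is instantaneous.

## Known limitations

- CPU-scale only; no GPU path (the model is small enough not to need one).
- No attention/Transformer variants, no one-hot/word-vector comparison
  encoders, no ROC/AUC or calibration analysis.
- Windows must be pre-cut; the package does not scan whole genomes.
- The LSTM loop is per-timestep Python; adequate at this model size but
  not competitive with framework kernels for much larger configurations.
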