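# mc4pred

Prediction of DNA N4-methylcytosine (4mC) sites from 41-nt
cytosine-centered sequence windows, with a multi-scale convolutional
network over a bidirectional LSTM, plus the full evaluation protocol
(Sn/Sp/Acc/MCC, threshold sweeps, stratified 10-fold cross-validation)
and a synthetic planted-motif benchmark generator.

4mC is an epigenetic cytosine modification; benchmark datasets frame its
detection as binary classification of fixed-length windows — a 41-nt
window with the candidate cytosine at the center (position 21) is
positive when that cytosine is methylated.  The package is for
bioinformaticians who want a self-contained, CPU-scale, fully
reproducible implementation of this classifier family: every stage from
FASTA to metrics runs locally, and a synthetic data generator with a
tunable signal dial makes the whole pipeline testable without downloads.

## Model

Windows are encoded with the integer map A→0, G→1, C→2, T→3 and passed
through:

    learned embedding (4 → 8)
      → Bi-LSTM, 6 units/direction, full sequence      (41 × 12)
      → three parallel 1-D convolutions, kernels 3/5/7,
        9 filters each, stride 1, no padding, ReLU,
        dropout 0.3                                    (39/37/35 × 9)
      → concatenation along the length axis            (111 × 9)
      → flatten                                        (999)
      → dense 27 (ReLU) → dropout 0.3 → dense 9 (ReLU)
      → dense 1 (sigmoid)  =  P(4mC)

The LSTM uses one bias vector per gate, so the stack carries exactly
29,661 trainable parameters (embedding 32, Bi-LSTM 720, conv branches
333/549/765, dense head 27,000/252/10).  The network, backpropagation
and the Adam optimizer are implemented in numpy; gradients are verified
against finite differences in the test suite.

Evaluation uses sensitivity Sn = TP/(TP+FN), specificity Sp = TN/(TN+FP),
accuracy, and the Matthews correlation coefficient

    MCC = (TP·TN − FP·FN) / √((TP+FP)(TP+FN)(TN+FP)(TN+FN)),

at a decision threshold (default 0.5, probability ≥ threshold ⇒ positive)
or across a threshold grid.

## Worked example

`examples/03_train_and_evaluate.py` simulates a balanced dataset whose
positives carry the exact consensus GAGTCA at a random offset in the left
flank (300+300 training, 100+100 test windows), trains the default model,
and sweeps the decision threshold:

```
trained 80 epochs, best validation loss 0.1305 at epoch 70

   t      Sn      Sp     Acc     MCC
 0.1    0.99    0.97    0.98  0.9602
 0.2    0.99    0.97    0.98  0.9602
 0.3    0.98    0.99   0.985    0.97
 0.4    0.97    0.99    0.98  0.9602
 0.5    0.96    0.99   0.975  0.9504
 0.6    0.93    0.99    0.96  0.9217
 0.7    0.91    0.99    0.95  0.9029
 0.8     0.9    0.99   0.945  0.8936
 0.9    0.85    0.99    0.92  0.8484
```

Each row is the confusion matrix re-thresholded at t: as t rises,
sensitivity falls and specificity rises; the model recovers the planted
motif almost perfectly (97.5% accuracy at the default threshold).  The
other examples print the per-layer parameter ledger (`01`), show what the
generator plants (`02`), and run 5-fold cross-validation (`04`).

The same workflow is available from the shell:

```
mc4pred simulate --n-pos 300 --n-neg 300 --match-prob 1.0 --seed 1 --out-dir data/
mc4pred train --fasta-pos data/pos.fasta --fasta-neg data/neg.fasta \
              --seed 0 --out-model runs/model.npz
mc4pred evaluate --model runs/model.npz --fasta-pos data/pos.fasta \
                 --fasta-neg data/neg.fasta --sweep --out sweep.tsv
mc4pred summary        # per-layer parameter table, total 29661
```

`mc4pred predict` writes per-record probabilities for unlabeled FASTA.
See `docs/methods.md` for the model's assumptions, the generator's design
and its information limit, and all numerical conventions.

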