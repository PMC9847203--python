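"""Train the predictor on synthetic data and evaluate with a threshold sweep.

Uses a reduced dataset (300+300 train, 100+100 test) and a noiseless motif
so the run finishes in about a minute while still showing the full
train -> predict -> sweep workflow.  The sweep table mirrors the standard
Sn/Sp/Acc/MCC report: as the decision threshold rises, sensitivity falls
and specificity rises.
"""

from mc4pred import (
    SimConfig, TrainConfig, build_model, encode, fit, simulate, threshold_sweep,
)

train_w, _ = simulate(SimConfig(n_pos=300, n_neg=300, match_prob=1.0, seed=1))
test_w, _ = simulate(SimConfig(n_pos=100, n_neg=100, match_prob=1.0, seed=2))

model = build_model(seed=0)
trained, history = fit(model, encode(train_w), TrainConfig(epochs=80, seed=0))
print(f"trained {len(history['train_loss'])} epochs, "
      f"best validation loss {history['best_val_loss']:.4f} "
      f"at epoch {history['best_epoch']}")

probs = trained.predict_proba(encode(test_w))
labels = encode(test_w).labels
print(f"\n{'t':>4} {'Sn':>7} {'Sp':>7} {'Acc':>7} {'MCC':>7}")
for report in threshold_sweep(probs, labels):
    r = report.rounded()
    print(f"{r['threshold']:>4} {r['Sn']:>7} {r['Sp']:>7} {r['Acc']:>7} {r['MCC']:>7}")
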