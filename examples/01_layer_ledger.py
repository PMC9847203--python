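"""Print the per-layer trainable-parameter ledger of the default model.

The default architecture — embedding width 8 over a 4-letter alphabet,
Bi-LSTM with 6 units per direction, convolution branches with kernels
3/5/7 and 9 filters each, dense head 27/9/1 — carries 29,661 trainable
parameters.  Each row shows a layer, its parameter count, and its output
shape per input window (batch dimension omitted).
"""

from mc4pred import build_model, total_parameters
from mc4pred.model_core import summary_table

model = build_model(seed=0)
print(summary_table(model))
print()
print(f"Total trainable parameters: {total_parameters(model)}")
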