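"""Architecture definition, construction, parameter accounting, inference.

The model classifies integer-encoded DNA windows as 4mC / non-4mC.  Stack,
in order: a learned ("adaptive") nucleotide embedding, a bidirectional LSTM
returning the full sequence (forward and backward hidden states concatenated
per position), three parallel stride-1 valid 1-D convolution branches with
different kernel widths whose ReLU outputs are concatenated along the length
axis, a flatten, and a small dense head ending in a single sigmoid unit.

With the default configuration (41 positions, 4-symbol vocabulary, embedding
width 8, 6 LSTM units per direction, kernels [3, 5, 7] with 9 filters each,
dense widths 27/9/1) the trainable-parameter ledger is:

    embedding 32, Bi-LSTM 720, conv branches 333/549/765,
    dense 27000/252/10 — total 29661.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from ._nn import MultiScaleNet, init_params
from .seqcodec import EncodedBatch


class ConfigError(ValueError):
    """Architecture configuration violates a structural constraint."""


@dataclass
class ArchitectureConfig:
    """Every hyperparameter of the layer stack.

    Attributes
    ----------
    seq_len : window length in nucleotides.
    vocab_size : alphabet size (4 for DNA).
    embed_dim : width of the learned embedding vectors.
    lstm_units : hidden units per LSTM direction (output width is twice this).
    kernel_sizes : ascending, distinct 1-D convolution kernel widths.
    filters : output channels of every convolution branch.
    branch_dropout : dropout rate applied after each convolution branch.
    dense_widths : hidden dense-layer widths, in order.
    head_dropout : dropout rate after the first dense layer.
    output_units : size of the output layer (1: a single 4mC probability).
    """

    seq_len: int = 41
    vocab_size: int = 4
    embed_dim: int = 8
    lstm_units: int = 6
    kernel_sizes: list[int] = field(default_factory=lambda: [3, 5, 7])
    filters: int = 9
    branch_dropout: float = 0.3
    dense_widths: list[int] = field(default_factory=lambda: [27, 9])
    head_dropout: float = 0.3
    output_units: int = 1

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.seq_len < 1 or self.vocab_size < 1:
            raise ConfigError("seq_len and vocab_size must be positive")
        if self.embed_dim < 1 or self.lstm_units < 1 or self.filters < 1:
            raise ConfigError("embed_dim, lstm_units and filters must be positive")
        if not self.kernel_sizes:
            raise ConfigError("at least one kernel size is required")
        for k in self.kernel_sizes:
            if not 1 <= k <= self.seq_len:
                raise ConfigError(f"kernel size {k} outside [1, seq_len={self.seq_len}]")
        if sorted(set(self.kernel_sizes)) != list(self.kernel_sizes):
            raise ConfigError("kernel_sizes must be distinct and ascending")
        if not all(w >= 1 for w in self.dense_widths) or self.output_units < 1:
            raise ConfigError("dense widths must be positive")
        for rate in (self.branch_dropout, self.head_dropout):
            if not 0.0 <= rate < 1.0:
                raise ConfigError(f"dropout rate {rate} outside [0, 1)")

    @property
    def branch_lengths(self) -> list[int]:
        """Valid-convolution output length per branch: seq_len - k + 1."""
        return [self.seq_len - k + 1 for k in self.kernel_sizes]

    @property
    def concat_length(self) -> int:
        return sum(self.branch_lengths)

    @property
    def flatten_width(self) -> int:
        return self.concat_length * self.filters

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ArchitectureConfig":
        return cls(**d)


@dataclass
class LayerSummary:
    """One row of the per-layer parameter ledger."""

    layer_name: str
    trainable_params: int
    output_shape: tuple[int, ...]


@dataclass
class ModelHandle:
    """A built (possibly trained) model: config + parameter arrays + seed."""

    config: ArchitectureConfig
    params: dict[str, np.ndarray]
    seed: int

    def predict_proba(self, batch: EncodedBatch | np.ndarray) -> np.ndarray:
        return predict_proba(self, batch)

    def copy(self) -> "ModelHandle":
        return ModelHandle(
            config=self.config,
            params={k: v.copy() for k, v in self.params.items()},
            seed=self.seed,
        )


def build_model(cfg: ArchitectureConfig | None = None, seed: int = 0) -> ModelHandle:
    """Construct the model with freshly initialised weights.

    All randomness in the weight initialisation is governed by ``seed``;
    two calls with the same config and seed yield identical parameters.
    """
    cfg = cfg or ArchitectureConfig()
    cfg.validate()
    return ModelHandle(config=cfg, params=init_params(cfg, seed), seed=seed)


def count_parameters(m: ModelHandle) -> list[LayerSummary]:
    """Per-layer trainable-parameter counts and output shapes.

    Counting conventions: the Bi-LSTM carries exactly one bias vector per
    gate and direction, i.e. 2*4*(embed_dim + lstm_units + 1)*lstm_units in
    total; each convolution filter and dense unit has one bias.  Dropout,
    concatenation and flatten layers are parameter-free.  Counts are taken
    from the realised parameter arrays, not recomputed from formulas.
    """
    cfg = m.config
    p = m.params
    L, F = cfg.seq_len, cfg.filters
    rows = [
        LayerSummary("adaptive_embedding", p["emb"].size, (L, cfg.embed_dim)),
        LayerSummary(
            "bidirectional_lstm",
            sum(p[f"lstm_{d}_{part}"].size for d in "fb" for part in ("Wx", "Wh", "b")),
            (L, 2 * cfg.lstm_units),
        ),
    ]
    for k, out_len in zip(cfg.kernel_sizes, cfg.branch_lengths):
        rows.append(
            LayerSummary(
                f"conv_k{k}",
                p[f"conv{k}_W"].size + p[f"conv{k}_b"].size,
                (out_len, F),
            )
        )
    for k, out_len in zip(cfg.kernel_sizes, cfg.branch_lengths):
        rows.append(LayerSummary(f"dropout_k{k}", 0, (out_len, F)))
    rows.append(LayerSummary("concat", 0, (cfg.concat_length, F)))
    rows.append(LayerSummary("flatten", 0, (cfg.flatten_width,)))
    widths = [*cfg.dense_widths, cfg.output_units]
    for i, w in enumerate(widths, start=1):
        rows.append(
            LayerSummary(
                f"dense_{w}",
                p[f"dense{i}_W"].size + p[f"dense{i}_b"].size,
                (w,),
            )
        )
        if i == 1:
            rows.append(LayerSummary("dropout_head", 0, (w,)))
    return rows


def total_parameters(m: ModelHandle) -> int:
    """Sum of trainable parameters over all layers."""
    return sum(row.trainable_params for row in count_parameters(m))


def predict_proba(m: ModelHandle, batch: EncodedBatch | np.ndarray) -> np.ndarray:
    """4mC probability per row, input order preserved, dropout disabled."""
    X = batch.matrix if isinstance(batch, EncodedBatch) else np.asarray(batch)
    if X.ndim != 2 or X.shape[1] != m.config.seq_len:
        raise ValueError(
            f"batch has {X.shape[1] if X.ndim == 2 else '?'} columns, "
            f"model expects {m.config.seq_len}"
        )
    if X.shape[0] == 0:
        return np.empty(0)
    net = MultiScaleNet(m.config)
    probs, _, _ = net.forward(m.params, X, train=False)
    return probs


def save_model(m: ModelHandle, path: str | Path) -> Path:
    """Persist config + weights to a single ``.npz`` archive."""
    path = Path(path)
    if path.suffix != ".npz":
        path = Path(str(path) + ".npz")
    meta = json.dumps({"config": m.config.to_dict(), "seed": m.seed})
    np.savez(path, __meta__=np.array(meta), **m.params)
    return path


def load_model(path: str | Path) -> ModelHandle:
    with np.load(path, allow_pickle=False) as data:
        meta = json.loads(str(data["__meta__"]))
        params = {k: data[k].copy() for k in data.files if k != "__meta__"}
    return ModelHandle(
        config=ArchitectureConfig.from_dict(meta["config"]),
        params=params,
        seed=meta["seed"],
    )


def summary_table(m: ModelHandle) -> str:
    """Human-readable per-layer ledger with a total line."""
    rows = count_parameters(m)
    name_w = max(len(r.layer_name) for r in rows)
    lines = [f"{'Layer':<{name_w}}  {'Params':>8}  Output shape"]
    for r in rows:
        shape = "(" + ", ".join(str(d) for d in r.output_shape) + ")"
        lines.append(f"{r.layer_name:<{name_w}}  {r.trainable_params:>8,}  {shape}")
    lines.append(f"{'total':<{name_w}}  {sum(r.trainable_params for r in rows):>8,}")
    return "\n".join(lines)
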