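"""Model fitting and the 10-fold cross-validation protocol.

Training minimises the binary cross-entropy with minibatch Adam.  A
stratified fraction of the training data (default 20%) is held out as a
validation set; early stopping monitors the validation loss and the weights
from the best epoch are restored.  Cross-validation partitions the samples
into K stratified folds, trains a freshly initialised model on K-1 folds,
and evaluates on the held-out fold at threshold 0.5.

One master seed deterministically derives every other seed in a run
(weight initialisation, the validation split, epoch shuffling and dropout,
fold assignment), so a single integer reproduces the whole computation.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
from sklearn.model_selection import StratifiedKFold, train_test_split

from ._nn import Adam, MultiScaleNet, bce_loss_and_grad
from .evaluation import MetricsReport, evaluate_at, mean_report
from .model_core import ArchitectureConfig, ModelHandle, build_model
from .seqcodec import EncodedBatch


@dataclass
class TrainConfig:
    """Optimisation settings.

    ``weight_decay`` is an L2 penalty added to the gradient of every weight
    matrix and the embedding (never biases); with fewer than ~1000 training
    windows it is what keeps the 29k-parameter model from memorising.
    """

    epochs: int = 150
    batch_size: int = 32
    learning_rate: float = 3e-3
    weight_decay: float = 3e-3
    optimizer_name: str = "adam"
    validation_fraction: float = 0.2
    early_stop_patience: int | None = 40
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.validation_fraction < 1.0:
            raise ValueError("validation_fraction must lie in (0, 1)")
        if self.batch_size < 1 or self.epochs < 1:
            raise ValueError("batch_size and epochs must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.weight_decay < 0:
            raise ValueError("weight_decay must be non-negative")
        if self.optimizer_name.lower() != "adam":
            raise ValueError(f"unsupported optimizer '{self.optimizer_name}'")


@dataclass
class FoldAssignment:
    """Stratified fold index per sample (values in [0, K))."""

    fold_index: np.ndarray
    K: int

    def test_indices(self, k: int) -> np.ndarray:
        return np.flatnonzero(self.fold_index == k)

    def train_indices(self, k: int) -> np.ndarray:
        return np.flatnonzero(self.fold_index != k)


@dataclass
class CrossValResult:
    fold_reports: list[MetricsReport]
    mean: MetricsReport
    pooled: MetricsReport
    folds: FoldAssignment


def derive_seeds(master: int, n: int, salt: int = 0) -> list[int]:
    """Derive ``n`` independent 31-bit seeds from one master seed."""
    ss = np.random.SeedSequence([int(master), int(salt)])
    return [int(s) for s in ss.generate_state(n) % (2**31)]


def fit(
    m: ModelHandle, batch: EncodedBatch, tcfg: TrainConfig | None = None
) -> tuple[ModelHandle, dict]:
    """Train on a labeled batch; return (best model, per-epoch history).

    The model with the lowest validation loss is returned (the final state
    when early stopping is disabled and never improved).  History holds
    ``train_loss`` and ``val_loss`` lists and ``best_epoch``.
    """
    tcfg = tcfg or TrainConfig()
    if batch.labels is None:
        raise ValueError("training requires labels on the batch")
    y = np.asarray(batch.labels, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("training requires at least one sample of each class")
    X = batch.matrix

    split_seed, shuffle_seed = derive_seeds(tcfg.seed, 2, salt=1)
    idx_train, idx_val = train_test_split(
        np.arange(X.shape[0]),
        test_size=tcfg.validation_fraction,
        random_state=split_seed,
        stratify=y,
    )
    Xtr, ytr = X[idx_train], y[idx_train]
    Xva, yva = X[idx_val], y[idx_val]

    net = MultiScaleNet(m.config)
    params = {k: v.copy() for k, v in m.params.items()}
    opt = Adam(params, lr=tcfg.learning_rate)
    rng = np.random.default_rng(shuffle_seed)

    history: dict = {"train_loss": [], "val_loss": []}
    best_val = np.inf
    best_params = {k: v.copy() for k, v in params.items()}
    best_epoch = -1
    patience_left = tcfg.early_stop_patience

    n = Xtr.shape[0]
    for epoch in range(tcfg.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, tcfg.batch_size):
            sel = order[start : start + tcfg.batch_size]
            _, logits, cache = net.forward(params, Xtr[sel], train=True, rng=rng)
            loss, dlogits = bce_loss_and_grad(logits, ytr[sel])
            if not np.isfinite(loss):
                raise RuntimeError(f"training diverged (non-finite loss) at epoch {epoch}")
            epoch_loss += loss * len(sel)
            grads = net.backward(params, cache, dlogits)
            if tcfg.weight_decay:
                for key in grads:
                    if key.endswith("_W") or key == "emb":
                        grads[key] = grads[key] + tcfg.weight_decay * params[key]
            opt.step(params, grads)
        _, va_logits, _ = net.forward(params, Xva, train=False)
        val_loss, _ = bce_loss_and_grad(va_logits, yva)
        if not np.isfinite(val_loss):
            raise RuntimeError(f"training diverged (non-finite loss) at epoch {epoch}")
        history["train_loss"].append(epoch_loss / n)
        history["val_loss"].append(float(val_loss))

        if val_loss < best_val:
            best_val = float(val_loss)
            best_params = {k: v.copy() for k, v in params.items()}
            best_epoch = epoch
            patience_left = tcfg.early_stop_patience
        elif tcfg.early_stop_patience is not None:
            patience_left -= 1
            if patience_left <= 0:
                break

    if best_epoch < 0:  # early stopping disabled and no improvement tracked
        best_params = params
        best_epoch = len(history["train_loss"]) - 1
    history["best_epoch"] = best_epoch
    history["best_val_loss"] = best_val
    return ModelHandle(config=m.config, params=best_params, seed=m.seed), history


def make_folds(labels, K: int = 10, seed: int = 0) -> FoldAssignment:
    """Stratified K-fold partition: within each class fold sizes differ by <= 1."""
    y = np.asarray(labels, dtype=int)
    if K < 2:
        raise ValueError("K must be >= 2")
    _, counts = np.unique(y, return_counts=True)
    if counts.min() < K:
        raise ValueError(
            f"smallest class has {counts.min()} samples, fewer than K={K} folds"
        )
    skf = StratifiedKFold(n_splits=K, shuffle=True, random_state=int(seed) % (2**31))
    fold_index = np.empty(len(y), dtype=int)
    for k, (_, test_idx) in enumerate(skf.split(np.zeros(len(y)), y)):
        fold_index[test_idx] = k
    return FoldAssignment(fold_index=fold_index, K=K)


def cross_validate(
    cfg: ArchitectureConfig,
    batch: EncodedBatch,
    tcfg: TrainConfig | None = None,
    K: int = 10,
    threshold: float = 0.5,
) -> CrossValResult:
    """K-fold cross-validation with a fresh model per fold.

    Returns per-fold metric reports, their arithmetic mean, and metrics of
    the pooled out-of-fold predictions.
    """
    tcfg = tcfg or TrainConfig()
    if batch.labels is None:
        raise ValueError("cross-validation requires labels on the batch")
    y = np.asarray(batch.labels)
    fold_seed = derive_seeds(tcfg.seed, 1, salt=2)[0]
    folds = make_folds(y, K=K, seed=fold_seed)
    init_seeds = derive_seeds(tcfg.seed, K, salt=3)
    fit_seeds = derive_seeds(tcfg.seed, K, salt=4)

    reports: list[MetricsReport] = []
    pooled_probs = np.empty(len(y), dtype=float)
    for k in range(K):
        tr = folds.train_indices(k)
        te = folds.test_indices(k)
        sub = EncodedBatch(
            matrix=batch.matrix[tr],
            ids=[batch.ids[i] for i in tr],
            labels=y[tr],
        )
        model = build_model(cfg, seed=init_seeds[k])
        fold_tcfg = TrainConfig(**{**asdict(tcfg), "seed": fit_seeds[k]})
        trained, _ = fit(model, sub, fold_tcfg)
        probs = trained.predict_proba(batch.matrix[te])
        pooled_probs[te] = probs
        reports.append(evaluate_at(probs, y[te], threshold))
    return CrossValResult(
        fold_reports=reports,
        mean=mean_report(reports),
        pooled=evaluate_at(pooled_probs, y, threshold),
        folds=folds,
    )
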