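"""Fold construction, seeded determinism, and the fit contract.

Heavier learnability checks live in the acceptance suite; here the models
are scaled down (short windows, few epochs) so contracts can be verified
in seconds.
"""

import numpy as np
import pytest

from mc4pred import (
    ArchitectureConfig,
    EncodedBatch,
    SimConfig,
    TrainConfig,
    build_model,
    cross_validate,
    encode,
    fit,
    make_folds,
    simulate,
)

TINY_ARCH = ArchitectureConfig(
    seq_len=15, embed_dim=4, lstm_units=3, kernel_sizes=[3, 5], filters=4,
    dense_widths=[8, 4],
)


def tiny_batch(n_per_class=40, seed=0):
    cfg = SimConfig(
        n_pos=n_per_class, n_neg=n_per_class, seq_len=15, motif="GTAC",
        match_prob=1.0, anchor_start=2, placement_halfwidth=1, seed=seed,
    )
    windows, _ = simulate(cfg)
    return encode(windows)


class TestMakeFolds:
    def test_paper_scale_fold_sizes(self):
        # 746 + 746 samples in 10 folds: sizes 149 or 150, balanced per class
        labels = np.array([1] * 746 + [0] * 746)
        folds = make_folds(labels, K=10, seed=0)
        for k in range(10):
            te = folds.test_indices(k)
            assert len(te) in (149, 150)
            n_pos = int(labels[te].sum())
            assert abs(n_pos - (len(te) - n_pos)) <= 1

    def test_two_fold_minimal_case(self):
        labels = np.array([1, 1, 0, 0])
        folds = make_folds(labels, K=2, seed=0)
        for k in range(2):
            te = folds.test_indices(k)
            assert len(te) == 2 and labels[te].sum() == 1

    def test_partition_property(self, rng):
        labels = rng.integers(0, 2, 137)
        while min((labels == 0).sum(), (labels == 1).sum()) < 5:
            labels = rng.integers(0, 2, 137)
        folds = make_folds(labels, K=5, seed=3)
        all_test = np.concatenate([folds.test_indices(k) for k in range(5)])
        assert sorted(all_test) == list(range(137))

    def test_train_test_disjoint(self):
        labels = np.array([0, 1] * 30)
        folds = make_folds(labels, K=6, seed=1)
        for k in range(6):
            assert not set(folds.train_indices(k)) & set(folds.test_indices(k))

    def test_deterministic_given_seed(self):
        labels = np.array([0, 1] * 50)
        a = make_folds(labels, K=10, seed=4)
        b = make_folds(labels, K=10, seed=4)
        np.testing.assert_array_equal(a.fold_index, b.fold_index)

    def test_class_smaller_than_k_raises(self):
        labels = np.array([1] * 3 + [0] * 20)
        with pytest.raises(ValueError, match="fewer than K"):
            make_folds(labels, K=5, seed=0)


class TestFit:
    def test_single_class_input_raises(self):
        batch = tiny_batch()
        batch.labels[:] = 1
        model = build_model(TINY_ARCH, seed=0)
        with pytest.raises(ValueError, match="each class"):
            fit(model, batch, TrainConfig(epochs=1))

    def test_missing_labels_raise(self):
        batch = tiny_batch()
        batch.labels = None
        with pytest.raises(ValueError, match="labels"):
            fit(build_model(TINY_ARCH, seed=0), batch, TrainConfig(epochs=1))

    def test_seeded_runs_are_bit_identical(self):
        batch = tiny_batch()
        tcfg = TrainConfig(epochs=3, seed=11)
        runs = []
        for _ in range(2):
            model = build_model(TINY_ARCH, seed=5)
            trained, history = fit(model, batch, tcfg)
            runs.append((trained, history))
        (m1, h1), (m2, h2) = runs
        assert h1 == h2
        for key in m1.params:
            np.testing.assert_array_equal(m1.params[key], m2.params[key])

    def test_history_tracks_losses_and_best_epoch(self):
        batch = tiny_batch()
        trained, history = fit(
            build_model(TINY_ARCH, seed=0), batch, TrainConfig(epochs=4, seed=0)
        )
        assert len(history["train_loss"]) == len(history["val_loss"]) == 4
        assert 0 <= history["best_epoch"] < 4
        assert history["best_val_loss"] == min(history["val_loss"])

    def test_returns_state_of_best_validation_epoch(self):
        batch = tiny_batch(seed=2)
        model = build_model(TINY_ARCH, seed=1)
        trained, history = fit(model, batch, TrainConfig(epochs=5, seed=1))
        # retraining for best_epoch+1 epochs with the same seeds reproduces it
        retrained, _ = fit(
            model, batch, TrainConfig(epochs=history["best_epoch"] + 1, seed=1)
        )
        for key in trained.params:
            np.testing.assert_array_equal(trained.params[key], retrained.params[key])

    def test_learns_a_noiseless_planted_motif(self):
        # exact motif vs background on short windows: quickly separable
        batch = tiny_batch(n_per_class=120, seed=3)
        test = tiny_batch(n_per_class=60, seed=4)
        model = build_model(TINY_ARCH, seed=0)
        trained, _ = fit(model, batch, TrainConfig(epochs=40, seed=0))
        probs = trained.predict_proba(test)
        acc = ((probs >= 0.5).astype(int) == test.labels).mean()
        assert acc >= 0.9

    def test_shuffled_labels_give_chance_accuracy(self, rng):
        # label-permutation null: destroying the label-sequence association
        # must leave nothing to learn
        batch = tiny_batch(n_per_class=120, seed=8)
        test = tiny_batch(n_per_class=60, seed=9)
        batch.labels = rng.permutation(batch.labels)
        trained, _ = fit(
            build_model(TINY_ARCH, seed=0), batch, TrainConfig(epochs=30, seed=0)
        )
        probs = trained.predict_proba(test)
        acc = ((probs >= 0.5).astype(int) == test.labels).mean()
        assert 0.35 <= acc <= 0.65

    def test_validation_fraction_bounds(self):
        with pytest.raises(ValueError):
            TrainConfig(validation_fraction=0.0)
        with pytest.raises(ValueError):
            TrainConfig(validation_fraction=1.0)


@pytest.fixture(scope="module")
def cv_result():
    batch = tiny_batch(n_per_class=60, seed=5)
    return cross_validate(
        TINY_ARCH, batch, TrainConfig(epochs=3, seed=7), K=3
    ), batch


class TestCrossValidate:
    def test_fold_test_sets_are_the_partition(self, cv_result):
        result, batch = cv_result
        sizes = [len(result.folds.test_indices(k)) for k in range(3)]
        assert sum(sizes) == batch.n_records
        assert max(sizes) - min(sizes) <= 1

    def test_mean_is_arithmetic_mean_of_folds(self, cv_result):
        result, _ = cv_result
        for attr in ("Sn", "Sp", "Acc", "MCC"):
            vals = [getattr(r, attr) for r in result.fold_reports]
            assert getattr(result.mean, attr) == pytest.approx(np.mean(vals))

    def test_pooled_counts_cover_every_sample_once(self, cv_result):
        result, batch = cv_result
        assert result.pooled.counts.total == batch.n_records

    def test_reproducible_given_seed(self):
        batch = tiny_batch(n_per_class=30, seed=6)
        a = cross_validate(TINY_ARCH, batch, TrainConfig(epochs=2, seed=3), K=2)
        b = cross_validate(TINY_ARCH, batch, TrainConfig(epochs=2, seed=3), K=2)
        assert [r.Acc for r in a.fold_reports] == [r.Acc for r in b.fold_reports]
        assert a.mean == b.mean
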