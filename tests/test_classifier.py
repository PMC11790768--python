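"""Model construction, the two-phase training schedule contracts, logit
prediction, and CV hyperparameter selection."""

import time

import numpy as np
import pytest

from ribfrac.classifier import (
    CVCandidate,
    ModelConfig,
    PhaseSpec,
    TrainSchedule,
    build_model,
    dataset_arrays,
    predict_logits,
    select_hyperparameters,
    train_two_phase,
)
from ribfrac.errors import ConfigError, DataError
from ribfrac.partition import GroupedDataset, group_split


@pytest.fixture(scope="module")
def split_tiny(tiny_dataset):
    train, val = group_split(tiny_dataset, test_fraction=0.25, seed=0, tolerance=None)
    return train, val


def _short_schedule(**kw):
    base = dict(
        phase1=PhaseSpec(True, 1e-3, 4),
        phase2=PhaseSpec(False, 2e-4, 3),
        early_stop_patience=15,
        plateau_patience=2,
        plateau_factor=0.1,
    )
    base.update(kw)
    return TrainSchedule(**base)


class TestBuildModel:
    def test_output_shape_and_eval_determinism(self):
        model = build_model(ModelConfig(), seed=1)
        x = np.random.default_rng(0).random((3, 1, 99, 99), dtype=np.float32)
        out1 = model.forward(x)
        out2 = model.forward(x)
        assert out1.shape == (3, 5)
        assert np.array_equal(out1, out2)  # dropout off at inference

    def test_unknown_backbone_rejected(self):
        with pytest.raises(ConfigError):
            ModelConfig(backbone="resnet152")

    def test_small_convnet_batch_under_one_second(self):
        model = build_model(ModelConfig(), seed=0)
        x = np.zeros((16, 1, 99, 99), dtype=np.float32)
        model.forward(x)  # warm-up
        t0 = time.perf_counter()
        model.forward(x)
        assert time.perf_counter() - t0 < 1.0

    def test_residual_backbone_builds(self):
        model = build_model(ModelConfig(backbone="residual"), seed=0)
        assert model.forward(np.zeros((2, 1, 99, 99), np.float32)).shape == (2, 5)


class TestTrainTwoPhase:
    def test_frozen_phase_leaves_backbone_bit_identical(self, split_tiny):
        fit, val = split_tiny
        model = build_model(ModelConfig(), seed=3)
        before = [p.value.copy() for p in model.backbone.params()]
        # both phases frozen: backbone must come out bit-identical
        sched = _short_schedule(phase2=PhaseSpec(True, 1e-4, 1))
        model, _ = train_two_phase(model, fit, val, sched, seed=3)
        after = [p.value for p in model.backbone.params()]
        assert all(np.array_equal(b, a) for b, a in zip(before, after))

    def test_unfrozen_phase_updates_backbone(self, split_tiny):
        fit, val = split_tiny
        model = build_model(ModelConfig(), seed=3)
        before = [p.value.copy() for p in model.backbone.params()]
        model, _ = train_two_phase(model, fit, val, _short_schedule(), seed=3)
        after = [p.value for p in model.backbone.params()]
        assert any(not np.array_equal(b, a) for b, a in zip(before, after))

    def test_lr_non_increasing_and_history_fields(self, split_tiny):
        fit, val = split_tiny
        model = build_model(ModelConfig(), seed=4)
        sched = _short_schedule(
            phase1=PhaseSpec(True, 5e-3, 6), phase2=PhaseSpec(False, 1e-3, 4)
        )
        _, history = train_two_phase(model, fit, val, sched, seed=4)
        for phase in (1, 2):
            lrs = [h["lr"] for h in history if h["phase"] == phase]
            assert lrs, "phase produced no epochs"
            assert all(a >= b for a, b in zip(lrs, lrs[1:]))
        assert {"phase", "epoch", "train_loss", "val_loss", "val_f1", "lr"} <= set(history[0])

    def test_early_stopping_restores_best_validation_weights(self, split_tiny):
        # a deliberately unstable learning rate makes the validation loss
        # bump; the returned model must score the best epoch's loss exactly
        from ribfrac import nn

        fit, val = split_tiny
        model = build_model(ModelConfig(), seed=5)
        sched = _short_schedule(
            phase1=PhaseSpec(True, 1e-3, 2), phase2=PhaseSpec(False, 5e-3, 8)
        )
        model, history = train_two_phase(model, fit, val, sched, seed=5)
        x_val, y_val = dataset_arrays(val)
        loss, _ = nn.softmax_cross_entropy(model.predict_scores(x_val), y_val)
        best_phase2 = min(h["val_loss"] for h in history if h["phase"] == 2)
        assert loss == pytest.approx(best_phase2, abs=1e-6)

    def test_seeded_training_reproducible(self, split_tiny):
        fit, val = split_tiny
        sched = _short_schedule(phase1=PhaseSpec(True, 1e-3, 2), phase2=PhaseSpec(False, 2e-4, 2))
        histories = []
        for _ in range(2):
            model = build_model(ModelConfig(), seed=6)
            _, h = train_two_phase(model, fit, val, sched, seed=6)
            histories.append(h)
        assert histories[0] == histories[1]

    def test_empty_data_rejected(self, split_tiny):
        fit, _ = split_tiny
        empty = GroupedDataset.from_samples([])
        with pytest.raises(DataError):
            train_two_phase(build_model(ModelConfig(), 0), fit, empty, _short_schedule(), 0)


class TestPredictLogits:
    def test_records_order_scores_and_argmax(self, split_tiny):
        fit, val = split_tiny
        model = build_model(ModelConfig(), seed=7)
        records = predict_logits(model, val)
        assert len(records) == len(val)
        for r, s in zip(records, val.samples):
            assert r.sample is s
            assert r.predicted_label == int(np.argmax(r.scores))
            # scores are pre-softmax: normalizing them yields a distribution
            e = np.exp(r.scores - r.scores.max())
            p = e / e.sum()
            assert p.sum() == pytest.approx(1.0, abs=1e-6)
            # argmax invariant under adding a constant to all scores
            assert int(np.argmax(r.scores + 3.7)) == r.predicted_label


class TestSelectHyperparameters:
    @staticmethod
    def _hist(f1s):
        return [
            {"phase": 1, "epoch": i + 1, "train_loss": 1.0, "val_loss": 1.0, "val_f1": f, "lr": 1e-4}
            for i, f in enumerate(f1s)
        ]

    def test_single_candidate_returned(self):
        cand = CVCandidate("cfg-A", [self._hist([0.5, 0.7])])
        assert select_hyperparameters([cand]) == "cfg-A"

    def test_mean_best_f1_with_epoch_tiebreak(self):
        # A: folds peak at 0.9 and 0.9 (epoch 2); B: 0.8 and 1.0 (epoch 3).
        # Equal means (0.9) -> A wins on fewer epochs to best.
        a = CVCandidate("A", [self._hist([0.1, 0.9]), self._hist([0.2, 0.9])])
        b = CVCandidate("B", [self._hist([0.1, 0.2, 0.8]), self._hist([0.3, 0.2, 1.0])])
        assert select_hyperparameters([a, b]) == "A"

    def test_higher_mean_wins_regardless_of_epochs(self):
        a = CVCandidate("A", [self._hist([0.6])])
        b = CVCandidate("B", [self._hist([0.1, 0.1, 0.9])])
        assert select_hyperparameters([a, b]) == "B"

    def test_failed_fold_disqualifies(self):
        good = CVCandidate("good", [self._hist([0.5]), self._hist([0.6])])
        bad = CVCandidate("bad", [self._hist([0.99]), None])
        assert select_hyperparameters([bad, good]) == "good"
        with pytest.raises(DataError):
            select_hyperparameters([bad])

    def test_empty_results_rejected(self):
        with pytest.raises(DataError):
            select_hyperparameters([])
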