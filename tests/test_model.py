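"""Hybrid network and linear baseline: learning, determinism, controls."""

import numpy as np
import pytest

from beetlerisk import nn
from beetlerisk.dataset import ExampleSet, build_examples, split_by_years, split_random
from beetlerisk.metrics import confusion, metric_report, select_threshold
from beetlerisk.model import (
    FeatureEncoder,
    ModelConfig,
    TrainedClassifier,
    build_classifier,
    fit_linear_baseline,
    predict_proba,
    train,
)
from beetlerisk.simulate import SimulationConfig, simulate_outbreak

MINI = ModelConfig.small(conv_channels=(4,), conv_strides=(2,), dense_widths=(16,),
                         epochs=3, batch_size=1024)


def _mini(seed=0, epochs=3):
    return ModelConfig.small(conv_channels=(4,), conv_strides=(2,),
                             dense_widths=(16,), epochs=epochs,
                             batch_size=1024, seed=seed)


@pytest.fixture(scope="module")
def separable_model(separable_examples):
    train_set, test_set = split_by_years(separable_examples, [2007])
    cfg = ModelConfig.small(epochs=5, seed=0)
    trained = train(build_classifier(cfg), train_set, test_set, cfg)
    return trained, train_set, test_set


class TestBuild:
    def test_identical_seeds_give_identical_initial_weights(self):
        cfg = ModelConfig.small(seed=12)
        a, b = build_classifier(cfg), build_classifier(cfg)
        for la, lb in zip(a.state(), b.state()):
            for k in la:
                np.testing.assert_array_equal(la[k], lb[k])

    def test_different_seeds_differ(self):
        a = build_classifier(ModelConfig.small(seed=1))
        b = build_classifier(ModelConfig.small(seed=2))
        assert not np.array_equal(a.head.params["W"], b.head.params["W"])

    def test_default_architecture_has_positive_parameter_count(self):
        net = build_classifier(ModelConfig())
        assert net.n_params > 0
        assert len(net.config.conv_channels) == 5
        assert len(net.config.dense_widths) == 5

    def test_softmax_rows_sum_to_one(self):
        net = build_classifier(_mini())
        rng = np.random.default_rng(0)
        img = rng.random((32, 3, 19, 19)).astype(np.float32)
        aux = rng.random((32, 4)).astype(np.float32)
        probs = nn.softmax(net.forward(img, aux, train=False))
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_inconsistent_config_rejected(self):
        with pytest.raises(ValueError, match="lengths differ"):
            ModelConfig(conv_channels=(8, 16), conv_strides=(1,))
        with pytest.raises(ValueError, match="dropout"):
            ModelConfig(dropout_rate=1.0)

    def test_untrained_net_near_half_on_neutral_input(self):
        cfg = _mini()
        net = build_classifier(cfg)
        n = 64
        es = ExampleSet(
            windows=np.zeros((n, 19, 19), np.int8),
            temperature=np.zeros(n, np.float32),
            stage=np.zeros(n, np.int8),
            labels=np.zeros(n, np.int8),
            focal=np.zeros((n, 3), np.int32),
        )
        trained = TrainedClassifier(cfg, net, FeatureEncoder(cfg.input_mode), [], 0)
        probs = predict_proba(trained, es)
        assert np.all(np.abs(probs - 0.5) < 0.2)


class TestTraining:
    def test_separable_problem_learned_to_perfection(self, separable_model):
        trained, train_set, _ = separable_model
        best = trained.history[trained.selected_epoch - 1]["eval_accuracy"]
        assert best == pytest.approx(1.0)
        probs = predict_proba(trained, train_set)
        acc = np.mean((probs >= 0.5).astype(int) == train_set.labels)
        assert acc == pytest.approx(1.0)

    def test_selected_epoch_is_argmax_of_eval_accuracy(self, separable_model):
        trained, _, _ = separable_model
        accs = [h["eval_accuracy"] for h in trained.history]
        assert trained.selected_epoch == int(np.argmax(accs)) + 1

    def test_duplicated_examples_get_identical_probabilities(self, separable_model):
        trained, _, test_set = separable_model
        dup = test_set.subset(np.array([0, 0, 1, 1]))
        probs = predict_proba(trained, dup)
        assert probs[0] == probs[1] and probs[2] == probs[3]

    def test_fixed_seed_reproduces_history_bitwise(self, tiny_examples):
        train_set, eval_set = split_random(tiny_examples, 0.3, seed=0)
        runs = []
        for _ in range(2):
            cfg = _mini(seed=9, epochs=2)
            trained = train(build_classifier(cfg), train_set, eval_set, cfg)
            runs.append(trained)
        assert runs[0].history == runs[1].history
        np.testing.assert_array_equal(
            predict_proba(runs[0], eval_set), predict_proba(runs[1], eval_set)
        )

    def test_single_class_training_set_rejected(self, tiny_examples):
        idx = np.flatnonzero(tiny_examples.labels == 0)[:50]
        negatives = tiny_examples.subset(idx)
        cfg = _mini()
        with pytest.raises(ValueError, match="single class"):
            train(build_classifier(cfg), negatives, negatives, cfg)

    def test_checkpoint_round_trip_preserves_predictions(self, tmp_path, separable_model):
        trained, _, test_set = separable_model
        path = tmp_path / "model.npz"
        trained.save(path)
        back = TrainedClassifier.load(path)
        np.testing.assert_array_equal(
            predict_proba(back, test_set), predict_proba(trained, test_set)
        )
        assert back.selected_epoch == trained.selected_epoch


def _signal_landscape(seed, n=60, n_years=10):
    cfg = SimulationConfig(n_rows=n, n_cols=n, n_years=n_years, seed=seed,
                           forcing=tuple(np.full(n_years, 2.2)))
    return simulate_outbreak(cfg)


class TestSkillControls:
    def test_label_shuffling_destroys_skill(self):
        """Training on permuted labels leaves no holdout skill (negative control)."""
        for seed in (0, 1, 2):
            series = _signal_landscape(seed)
            examples = build_examples(series)
            train_set, test_set = split_random(examples, 0.25, seed=seed)
            rng = np.random.default_rng(seed)
            shuffled = train_set.labels.copy()
            rng.shuffle(shuffled)
            train_set = ExampleSet(
                windows=train_set.windows, temperature=train_set.temperature,
                stage=train_set.stage, labels=shuffled, focal=train_set.focal,
            )
            cfg = _mini(seed=seed)
            trained = train(build_classifier(cfg), train_set, test_set, cfg)
            thr = select_threshold(predict_proba(trained, train_set), train_set.labels)
            pred = (predict_proba(trained, test_set) >= thr).astype(int)
            rep = metric_report(confusion(test_set.labels, pred))
            tss = rep.true_skill_statistic
            assert np.isnan(tss) or abs(tss) < 0.1

    def test_more_training_data_does_not_hurt_holdout_f1(self):
        """Expected holdout F1 is non-decreasing in training-set size."""
        f1_small, f1_large = [], []
        for seed in (0, 1, 2):
            series = _signal_landscape(seed, n=80)
            examples = build_examples(series)
            pool, test_set = split_random(examples, 0.25, seed=seed)
            rng = np.random.default_rng(seed)
            for size, sink in ((4000, f1_small), (16000, f1_large)):
                idx = rng.choice(len(pool), size=size, replace=False)
                sub = pool.subset(np.sort(idx))
                cfg = _mini(seed=seed)
                trained = train(build_classifier(cfg), sub, test_set, cfg)
                thr = select_threshold(predict_proba(trained, sub), sub.labels)
                pred = (predict_proba(trained, test_set) >= thr).astype(int)
                sink.append(metric_report(confusion(test_set.labels, pred)).f1)
        assert np.mean(f1_large) >= np.mean(f1_small) - 0.05


class TestLinearBaseline:
    def test_separable_problem_fit_perfectly(self, separable_examples):
        train_set, _ = split_by_years(separable_examples, [2007])
        baseline = fit_linear_baseline(train_set)
        pred = (baseline.predict_proba(train_set) >= 0.5).astype(int)
        assert np.mean(pred == train_set.labels) == pytest.approx(1.0)

    def test_identical_inputs_give_constant_probability(self, tiny_examples):
        pos = np.flatnonzero(tiny_examples.labels == 1)[:5]
        neg = np.flatnonzero(tiny_examples.labels == 0)[:5]
        train_set = tiny_examples.subset(np.concatenate([pos, neg]))
        baseline = fit_linear_baseline(train_set)
        clone = tiny_examples.subset(np.array([0] * 8))
        probs = baseline.predict_proba(clone)
        assert np.ptp(probs) == 0.0

    def test_single_class_rejected(self, tiny_examples):
        neg = tiny_examples.subset(np.flatnonzero(tiny_examples.labels == 0)[:40])
        with pytest.raises(ValueError, match="single class"):
            fit_linear_baseline(neg)
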