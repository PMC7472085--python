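"""Split protocol, training loop, confusion matrices and spectra reports."""

import numpy as np
import pandas as pd
import pytest

from emochart import nn, trainer
from emochart.trainer import ConfusionMatrix, TrainConfig, random_split


class TestRandomSplit:
    def test_amigos_sized_split_gives_13642_test(self):
        tr, te = random_split(45_474, 0.7, seed=0)
        assert len(te) == 13_642 and len(tr) == 31_832

    def test_dreamer_sized_split_gives_7452_test(self):
        tr, te = random_split(24_840, 0.7, seed=0)
        assert len(te) == 7452 and len(tr) == 17_388

    def test_disjoint_and_exhaustive(self):
        tr, te = random_split(1000, 0.7, seed=3)
        assert len(np.intersect1d(tr, te)) == 0
        assert len(np.union1d(tr, te)) == 1000

    def test_same_seed_identical_partition(self):
        a = random_split(500, 0.7, seed=11)
        b = random_split(500, 0.7, seed=11)
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])

    def test_different_seed_differs(self):
        a = random_split(500, 0.7, seed=1)
        b = random_split(500, 0.7, seed=2)
        assert not np.array_equal(a[0], b[0])

    def test_stratified_preserves_class_fractions(self):
        labels = np.repeat([0, 1, 2, 3], 100)
        tr, te = random_split(400, 0.7, seed=0, stratify=labels)
        for c in range(4):
            assert (labels[tr] == c).sum() == 70

    def test_too_small_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            random_split(1)

    def test_subject_split_keeps_subjects_whole(self):
        prov = pd.DataFrame({"subject": np.repeat(np.arange(10), 30)})
        tr, te = trainer.subject_split(prov, 0.7, seed=0)
        train_subj = set(prov["subject"].iloc[tr])
        test_subj = set(prov["subject"].iloc[te])
        assert train_subj.isdisjoint(test_subj)
        assert len(train_subj) == 7 and len(test_subj) == 3
        assert len(tr) + len(te) == 300

    def test_subject_split_needs_two_subjects(self):
        prov = pd.DataFrame({"subject": np.zeros(10, int)})
        with pytest.raises(ValueError, match="2 subjects"):
            trainer.subject_split(prov)


class TestTrainConfig:
    def test_defaults_match_protocol(self):
        cfg = TrainConfig()
        assert cfg.batch_size == 240
        assert cfg.learning_rate == pytest.approx(1e-3)
        assert cfg.beta2 == pytest.approx(0.99)
        assert cfg.split_fraction == pytest.approx(0.7)

    def test_invalid_values_rejected(self):
        with pytest.raises(ValueError):
            TrainConfig(split_fraction=1.2)
        with pytest.raises(ValueError):
            TrainConfig(batch_size=0)


def _toy_model(seed=0):
    rng = np.random.default_rng(seed)
    return nn.Sequential([nn.Dense(8, 16, rng, name="h"), nn.ReLU(), nn.Dense(16, 4, rng, name="o")])


def _toy_data(n=400, seed=0):
    rng = np.random.default_rng(seed)
    y = rng.integers(0, 4, n)
    centers = rng.standard_normal((4, 8)) * 3
    x = centers[y] + rng.standard_normal((n, 8)) * 0.3
    return x, y


class TestTrain:
    def test_loss_decreases_on_separable_data(self):
        x, y = _toy_data()
        curve = trainer.train(_toy_model(), x, y, TrainConfig(batch_size=64, epochs=20, seed=0))
        assert curve[-1] < 0.5 * curve[0]

    def test_same_seed_reproduces_training_curve_exactly(self):
        x, y = _toy_data()
        cfg = TrainConfig(batch_size=64, epochs=5, seed=4)
        c1 = trainer.train(_toy_model(1), x, y, cfg)
        c2 = trainer.train(_toy_model(1), x, y, cfg)
        assert c1 == c2  # bitwise: numpy ops are deterministic

    def test_zero_epochs_leaves_model_unchanged_and_at_chance(self):
        x, y = _toy_data()
        model = _toy_model()
        before = [p.v.copy() for p in model.params()]
        trainer.train(model, x, y, TrainConfig(epochs=0))
        for p, b in zip(model.params(), before):
            assert np.array_equal(p.v, b)
        # against labels drawn independently of x, any fixed predictor is at chance
        rand_y = np.random.default_rng(9).integers(0, 4, len(x))
        cm, _ = trainer.evaluate(model, x, rand_y)
        assert abs(cm.accuracy - 0.25) < 0.10

    def test_empty_training_set_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            trainer.train(_toy_model(), np.zeros((0, 8)), np.zeros(0, dtype=int))


class TestConfusionMatrix:
    def test_perfect_predictor_is_diagonal(self):
        y = np.repeat([0, 1, 2, 3], 25)
        cm = ConfusionMatrix.from_predictions(y, y)
        assert cm.accuracy == 1.0
        assert np.trace(cm.counts) == 100
        assert np.all(cm.counts == np.diag(np.diag(cm.counts)))

    def test_matches_brute_force_tally(self):
        rng = np.random.default_rng(5)
        pred, target = rng.integers(0, 4, 200), rng.integers(0, 4, 200)
        cm = ConfusionMatrix.from_predictions(pred, target)
        for i in range(4):
            for j in range(4):
                assert cm.counts[i, j] == int(np.sum((pred == i) & (target == j)))
        assert cm.accuracy == pytest.approx(np.mean(pred == target))

    def test_constant_predictor_accuracy_is_majority_share(self):
        target = np.array([0] * 60 + [1] * 25 + [2] * 15)
        pred = np.zeros_like(target)
        cm = ConfusionMatrix.from_predictions(pred, target)
        assert cm.accuracy == pytest.approx(0.60)

    def test_percentages_sum_to_100(self):
        rng = np.random.default_rng(0)
        cm = ConfusionMatrix.from_predictions(rng.integers(0, 4, 321), rng.integers(0, 4, 321))
        assert cm.percent.sum() == pytest.approx(100.0, abs=0.2)

    def test_frame_has_total_margins(self):
        cm = ConfusionMatrix.from_predictions(np.array([0, 1]), np.array([0, 1]))
        frame = cm.to_frame()
        assert list(frame.columns)[-1] == "Total" and list(frame.index)[-1] == "Total"
        assert frame.loc["Total", "Total"] == "100.0%"

    def test_evaluate_consistency_with_per_segment_mean(self):
        x, y = _toy_data(200)
        model = _toy_model()
        trainer.train(model, x, y, TrainConfig(batch_size=64, epochs=10, seed=0))
        cm, preds = trainer.evaluate(model, x, y)
        assert cm.accuracy == pytest.approx(
            np.mean(preds["predicted"] == preds["target"]))

    def test_empty_test_set_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            trainer.evaluate(_toy_model(), np.zeros((0, 8)), np.zeros(0, dtype=int))


class TestPowerSpectrumReport:
    def test_selection_matches_exhaustive_scan(self):
        rng = np.random.default_rng(8)
        n = 40
        segs = rng.standard_normal((n, 128))
        probs = rng.dirichlet(np.ones(4), size=n)
        targets = rng.integers(0, 4, n)
        rep = trainer.power_spectrum_report(segs, probs, targets)
        for cls in np.unique(targets):
            idx = np.flatnonzero(targets == cls)
            best = rep[(rep["class"] == trainer.QUADRANTS[cls]) & (rep["which"] == "best")]
            worst = rep[(rep["class"] == trainer.QUADRANTS[cls]) & (rep["which"] == "worst")]
            assert best["index"].iloc[0] == idx[probs[idx, cls].argmax()]
            assert worst["index"].iloc[0] == idx[probs[idx, cls].argmin()]

    def test_single_class_set_uses_only_that_class(self):
        rng = np.random.default_rng(1)
        rep = trainer.power_spectrum_report(
            rng.standard_normal((10, 128)), rng.dirichlet(np.ones(4), 10),
            np.full(10, 2))
        assert set(rep["class"]) == {"LVHA"}
        assert len(rep) == 2

    def test_pure_tone_peaks_at_its_frequency(self):
        t = np.arange(128) / 128.0
        seg = np.sin(2 * np.pi * 10 * t)[None, :]
        rep = trainer.power_spectrum_report(seg, np.array([[1.0, 0, 0, 0]]), np.array([0]))
        f, psd = rep["freqs"].iloc[0], rep["psd"].iloc[0]
        assert f[np.argmax(psd)] == pytest.approx(10.0, abs=1.0)

    def test_missing_probabilities_rejected(self):
        with pytest.raises(ValueError, match="probabilities"):
            trainer.power_spectrum_report(np.zeros((5, 128)), np.zeros(5), np.zeros(5, int))
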