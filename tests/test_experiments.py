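"""Training loop, splits, cross-validation and the signed-rank comparison."""

import itertools

import numpy as np
import pytest
from scipy import stats as sps

from cffemg import models
from cffemg.experiments import (
    ComparisonResult,
    NOT_REACHED,
    History,
    TrainConfig,
    TrainingError,
    efficiency_report,
    evaluate,
    kfold_cv,
    split_by_repetition,
    split_random_window,
    train,
    wilcoxon_compare,
)

SMALL = dict(conv_filters=8, fc_sizes=(16, 16, 8), lstm_units=12)


def toy_frames(n=40, seed=0):
    rng = np.random.default_rng(seed)
    X = 0.1 * rng.normal(size=(n, 5, 10, 4))
    y = np.arange(n) % 2
    X[y == 0, :, :, 0] += 1.0
    X[y == 1, :, :, 1] += 1.0
    return X, y


class TestTrain:
    def test_smoke_one_epoch_finite_loss(self):
        X, y = toy_frames()
        m = models.build_model(models.ModelSpec("rcnn", (5, 10, 4), 2, **SMALL), 0)
        hist = train(m, X, y, TrainConfig(epochs=1, seed=0))
        assert len(hist) == 1 and np.isfinite(hist.train_loss[0])

    def test_same_seed_reproduces_epoch_losses(self):
        X, y = toy_frames()
        losses = []
        for _ in range(2):
            m = models.build_model(
                models.ModelSpec("cff_rcnn", (5, 10, 4), 2, **SMALL), 7)
            hist = train(m, X, y, TrainConfig(epochs=2, seed=7))
            losses.append(hist.train_loss)
        assert losses[0] == losses[1]

    def test_history_has_one_record_per_epoch_with_validation(self):
        X, y = toy_frames(30)
        Xv, yv = toy_frames(10, seed=1)
        m = models.build_model(models.ModelSpec("rcnn", (5, 10, 4), 2, **SMALL), 0)
        hist = train(m, X, y, TrainConfig(epochs=3, seed=0), Xv, yv)
        assert len(hist.val_acc) == len(hist.train_loss) == 3
        assert len(hist.epoch_seconds) == 3

    def test_empty_split_raises(self):
        m = models.build_model(models.ModelSpec("rcnn", (5, 10, 4), 2, **SMALL), 0)
        with pytest.raises(TrainingError):
            train(m, np.zeros((0, 5, 10, 4)), np.zeros(0, int),
                  TrainConfig(epochs=1))

    def test_loss_decreases_over_first_epochs_across_seeds(self):
        drops = 0
        for seed in range(5):
            X, y = toy_frames(seed=seed)
            m = models.build_model(
                models.ModelSpec("rcnn", (5, 10, 4), 2, **SMALL), seed)
            hist = train(m, X, y, TrainConfig(epochs=4, seed=seed))
            drops += hist.train_loss[-1] < hist.train_loss[0]
        assert drops >= 4

    def test_evaluate_matches_manual_accuracy(self):
        X, y = toy_frames(20, seed=3)
        m = models.build_model(models.ModelSpec("rcnn", (5, 10, 4), 2, **SMALL), 3)
        _, acc = evaluate(m, X, y)
        probs, labels = models.predict(m, X)
        assert acc == np.mean(labels == y)


class TestSplits:
    def test_random_window_partitions_disjoint_and_stratified(self):
        y = np.repeat([0, 1, 2], 40)
        tr, va, te = split_random_window(y, (0.8, 0.1, 0.1), seed=0)
        all_idx = np.sort(np.concatenate([tr, va, te]))
        np.testing.assert_array_equal(all_idx, np.arange(120))
        for cls in range(3):
            assert np.sum(y[tr] == cls) == 32

    def test_by_repetition_no_repetition_straddles_partitions(self):
        y = np.repeat([0, 1], 60)
        reps = np.tile(np.repeat(np.arange(1, 7), 10), 2)
        tr, va, te = split_by_repetition(y, reps, seed=1)
        for cls in (0, 1):
            sets = [set(reps[idx[y[idx] == cls]]) for idx in (tr, va, te)]
            assert not (sets[0] & sets[1]) and not (sets[0] & sets[2]) \
                and not (sets[1] & sets[2])
            assert sets[1] and sets[2]  # nonzero fractions got a repetition

    def test_altering_test_data_never_changes_training_statistics(self):
        # leakage audit: normalization stats depend on the training split only
        from cffemg.windowing import standardize
        rng = np.random.default_rng(2)
        train_frames = rng.normal(size=(30, 4, 5, 3))
        t1 = rng.normal(size=(10, 4, 5, 3))
        t2 = 1e3 * rng.normal(size=(10, 4, 5, 3))
        *_, s1 = standardize(train_frames, t1)
        *_, s2 = standardize(train_frames, t2)
        np.testing.assert_array_equal(s1.mean, s2.mean)
        np.testing.assert_array_equal(s1.std, s2.std)


class TestKFold:
    def test_folds_partition_100_windows_into_20s(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(100, 4))
        y = np.repeat(np.arange(5), 20)
        seen = []

        def fp(Xtr, ytr, Xte):
            seen.append(len(Xte))
            from sklearn.neighbors import KNeighborsClassifier
            return KNeighborsClassifier(3).fit(Xtr, ytr).predict(Xte)

        accs, mean, sd = kfold_cv(X, y, fp, k=5, seed=0)
        assert seen == [20] * 5
        assert len(accs) == 5 and 0 <= mean <= 1 and sd >= 0

    def test_separable_data_every_fold_perfect(self):
        rng = np.random.default_rng(1)
        y = np.repeat([0, 1], 30)
        X = rng.normal(size=(60, 4)) + 10 * y[:, None]

        def fp(Xtr, ytr, Xte):
            from sklearn.neighbors import KNeighborsClassifier
            return KNeighborsClassifier(3).fit(Xtr, ytr).predict(Xte)

        accs, mean, _ = kfold_cv(X, y, fp, k=5, seed=1)
        assert mean == 1.0 and np.all(accs == 1.0)


def brute_force_signed_rank_p(diffs):
    """Enumerate all 2^n sign assignments of the ranked |differences|."""
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    ranks = sps.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    n = d.size
    ws = [sum(r for r, s in zip(ranks, signs) if s)
          for signs in itertools.product([0, 1], repeat=n)]
    ws = np.asarray(ws, dtype=float)
    p_le = np.mean(ws <= w_obs)
    p_ge = np.mean(ws >= w_obs)
    return min(1.0, 2 * min(p_le, p_ge))


class TestWilcoxon:
    def test_identical_vectors_degenerate(self):
        r = wilcoxon_compare([0.9] * 6, [0.9] * 6)
        assert r.degenerate and r.p_value == 1.0 and not r.significant

    def test_ten_positive_pairs_exact_p(self):
        a = np.linspace(0.8, 0.9, 10)
        r = wilcoxon_compare(a + 0.01, a)
        assert np.isclose(r.p_value, 2 / 2**10)
        assert r.significant

    def test_alternating_equal_magnitude_differences_p_near_one(self):
        a = np.full(8, 0.5)
        d = 0.01 * np.array([1, -1, 1, -1, 1, -1, 1, -1])
        r = wilcoxon_compare(a + d, a)
        assert r.p_value > 0.5 and not r.significant

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_bruteforce_enumeration_random_inputs(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 13))
        a = rng.uniform(0.5, 1.0, n)
        b = a + rng.choice([-1, 1], n) * rng.integers(0, 4, n) * 0.01
        if np.all(a == b):
            b[0] += 0.01
        r = wilcoxon_compare(a, b)
        assert np.isclose(r.p_value, brute_force_signed_rank_p(a - b))

    def test_matches_scipy_exact_when_no_ties(self):
        rng = np.random.default_rng(99)
        a = rng.normal(size=12)
        b = a + rng.normal(size=12) * 0.3
        r = wilcoxon_compare(a, b)
        ref = sps.wilcoxon(a - b, alternative="two-sided", method="exact").pvalue
        assert np.isclose(r.p_value, ref)

    def test_zero_differences_dropped(self):
        a = np.array([0.5, 0.6, 0.7, 0.8, 0.81, 0.82])
        b = a.copy()
        b[3:] -= 0.05
        r = wilcoxon_compare(a, b)
        ref = brute_force_signed_rank_p((a - b)[3:])
        assert np.isclose(r.p_value, ref)


class TestEfficiencyReport:
    def hist(self, accs):
        h = History()
        h.val_acc = list(accs)
        h.epoch_seconds = [1.0] * len(accs)
        h.train_loss = [0.0] * len(accs)
        return h

    def test_epochs_to_threshold_definitional(self):
        rows = efficiency_report(
            {"m": self.hist([0.5, 0.7, 0.85, 0.88, 0.9, 0.92, 0.91])}, [0.9])
        assert rows[0]["epochs_to_threshold"] == 5

    def test_unreached_threshold_sentinel(self):
        rows = efficiency_report({"m": self.hist([0.5, 0.6])}, [0.99])
        assert rows[0]["epochs_to_threshold"] == NOT_REACHED
        assert rows[0]["seconds_to_threshold"] is None

    def test_two_models_compared_per_threshold(self):
        rows = efficiency_report(
            {"a": self.hist([0.5, 0.9]), "b": self.hist([0.9, 0.9])},
            [0.9, 0.95])
        assert len(rows) == 4
        by = {(r["threshold"], r["model"]): r["epochs_to_threshold"] for r in rows}
        assert by[(0.9, "a")] == 2 and by[(0.9, "b")] == 1


class TestRobustnessRun:
    def test_pooled_subjects_both_models_above_chance(self):
        from cffemg.experiments import robustness_run
        out = robustness_run(3, epochs=6, seed=0)
        assert out["rcnn"] > 0.55 and out["cff_rcnn"] > 0.55
        assert out["n_subjects"] == 3 and out["subject_disjoint"] is False

    def test_subject_disjoint_split_flagged_in_report(self):
        from cffemg.experiments import robustness_run
        out = robustness_run(2, epochs=1, seed=1, subject_disjoint=True)
        assert out["subject_disjoint"] is True
        assert 0.0 <= out["rcnn"] <= 1.0 and 0.0 <= out["cff_rcnn"] <= 1.0
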