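"""Metrics, U-test, offline experiment and the simulated real-time protocol."""

import itertools
import math

import numpy as np
import pytest

from emgh.evaluation import (
    RealtimeTrial,
    accuracy,
    bonferroni_gate,
    confusion,
    f1_per_class,
    macro_f1,
    mann_whitney_u,
    mcr,
    online_accuracy,
    run_offline_experiment,
    run_realtime_experiment,
    simulate_stream,
    trial_completed,
)
from emgh.classifiers import TrainConfig
from emgh.hierarchy import Prediction
from emgh.model import HierarchicalEmgModel
from emgh.signal_model import ForceLevel, MotionClass, MotionClass11
from emgh.synthgen import SessionSpec, SubjectProfile, generate_session, generate_stream


class TestConfusionAndF1:
    def test_perfect_predictions(self):
        y = np.array([1, 2, 3, 1, 2, 3])
        cm = confusion(y, y, (1, 2, 3))
        assert np.array_equal(cm.counts, 2 * np.eye(3, dtype=int))
        assert accuracy(cm) == 1.0
        assert all(v == 1.0 for v in f1_per_class(cm).values())

    def test_two_class_hand_arithmetic(self):
        # TP=8, FP=2, FN=2, TN=8 for class 1 -> F1 = 16/20 = 0.8 both ways
        y_true = np.array([1] * 10 + [2] * 10)
        y_pred = np.array([1] * 8 + [2] * 2 + [2] * 8 + [1] * 2)
        cm = confusion(y_true, y_pred, (1, 2))
        f1 = f1_per_class(cm)
        assert f1[1] == pytest.approx(0.8)
        assert f1[2] == pytest.approx(0.8)

    def test_constant_predictor_on_balanced_seven_classes(self):
        y_true = np.repeat(np.arange(1, 8), 10)
        y_pred = np.ones_like(y_true)
        cm = confusion(y_true, y_pred, tuple(range(1, 8)))
        assert accuracy(cm) == pytest.approx(1 / 7)

    def test_label_outside_class_set_rejected(self):
        with pytest.raises(ValueError, match="outside class set"):
            confusion([1, 9], [1, 1], (1, 2))

    def test_row_sums_conserved_under_prediction_permutation(self, rng):
        y_true = rng.integers(1, 5, size=200)
        y_pred = rng.integers(1, 5, size=200)
        cm1 = confusion(y_true, y_pred, (1, 2, 3, 4))
        cm2 = confusion(y_true, rng.permutation(y_pred), (1, 2, 3, 4))
        assert np.array_equal(cm1.counts.sum(axis=1), cm2.counts.sum(axis=1))

    def test_metrics_agree_with_brute_force_counting(self, rng):
        """Accuracy, confusion and per-class F1 vs naive counting on 200
        randomized small instances."""
        for _ in range(200):
            k = int(rng.integers(2, 6))
            n = int(rng.integers(5, 40))
            classes = tuple(range(1, k + 1))
            y_true = rng.integers(1, k + 1, size=n)
            y_pred = rng.integers(1, k + 1, size=n)
            cm = confusion(y_true, y_pred, classes)
            # brute-force counting
            assert accuracy(cm) == pytest.approx(
                sum(t == p for t, p in zip(y_true, y_pred)) / n
            )
            f1 = f1_per_class(cm)
            for c in classes:
                tp = sum(1 for t, p in zip(y_true, y_pred) if t == c and p == c)
                fp = sum(1 for t, p in zip(y_true, y_pred) if t != c and p == c)
                fn = sum(1 for t, p in zip(y_true, y_pred) if t == c and p != c)
                prec = tp / (tp + fp) if tp + fp else 0.0
                rec = tp / (tp + fn) if tp + fn else 0.0
                expect = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
                assert f1[c] == pytest.approx(expect)
                assert cm.counts[c - 1, c - 1] == tp


def _exact_mw_p(a, b):
    """Full enumeration of the Mann-Whitney null over all label assignments."""
    a, b = list(a), list(b)
    pooled = a + b
    n1 = len(a)

    def u_stat(sample_a, sample_b):
        return sum(
            (x > y_) + 0.5 * (x == y_) for x in sample_a for y_ in sample_b
        )

    u_obs = u_stat(a, b)
    mean_u = n1 * len(b) / 2.0
    count = total = 0
    for comb in itertools.combinations(range(len(pooled)), n1):
        sa = [pooled[i] for i in comb]
        sb = [pooled[i] for i in range(len(pooled)) if i not in comb]
        u = u_stat(sa, sb)
        total += 1
        if abs(u - mean_u) >= abs(u_obs - mean_u) - 1e-12:
            count += 1
    return count / total


class TestMannWhitney:
    def test_identical_samples_not_significant(self):
        _, p = mann_whitney_u([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p >= 0.99

    def test_fully_separated_triples(self):
        u, p = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        assert p == pytest.approx(0.1)  # 2 * (1/20)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_exact_p_matches_full_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(size=rng.integers(3, 6))
        b = rng.normal(1.0, size=rng.integers(3, 6))
        _, p = mann_whitney_u(a, b)
        assert p == pytest.approx(_exact_mw_p(a, b), abs=1e-9)

    @pytest.mark.parametrize("n", [9, 10, 11, 12])
    def test_exact_and_normal_approximation_consistent(self, n):
        """|p_exact - p_asymptotic| < 0.02 band for moderate tie-free samples."""
        from scipy.stats import mannwhitneyu

        rng = np.random.default_rng(n)
        a = rng.normal(size=n)
        b = rng.normal(0.5, size=n)
        p_exact = mannwhitneyu(a, b, alternative="two-sided", method="exact").pvalue
        p_asym = mannwhitneyu(a, b, alternative="two-sided", method="asymptotic").pvalue
        assert abs(p_exact - p_asym) < 0.02

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])

    def test_bonferroni_gate(self):
        # the three-way comparison gate: alpha/m = 0.05/3 = 0.0167
        decisions = bonferroni_gate([0.02, 0.001, 0.0166], m=3)
        assert list(decisions) == [False, True, True]


class TestOfflineExperiment:
    def test_same_seed_gives_identical_reports(self, small_session):
        kwargs = dict(algorithm="lda", fe=True, seed=5, per_rep_keep=400)
        a = run_offline_experiment(small_session, **kwargs)
        b = run_offline_experiment(small_session, **kwargs)
        for name in a.reports:
            assert a.reports[name].accuracy == b.reports[name].accuracy
            assert np.array_equal(
                a.reports[name].confusion.counts, b.reports[name].confusion.counts
            )

    def test_reports_cover_all_three_classifiers(self, small_session):
        exp = run_offline_experiment(
            small_session, algorithm="lda", fe=True, seed=0, per_rep_keep=400
        )
        assert set(exp.reports) == {"gesture", "spherical_force", "tip_force"}
        assert len(exp.reports["gesture"].f1) == 7
        assert len(exp.reports["spherical_force"].f1) == 3

    def test_unknown_algorithm_rejected(self, small_session):
        with pytest.raises(ValueError, match="unknown algorithm"):
            run_offline_experiment(small_session, algorithm="svm", per_rep_keep=400)


def _const_trial(target, flags, stride_ms=90.0):
    preds = []
    for ok in flags:
        if ok:
            preds.append(Prediction(target.gesture, target.force))
        else:
            preds.append(Prediction(MotionClass.REST))
    return RealtimeTrial(
        target=target, predictions=preds,
        times_s=list(np.arange(len(flags)) * stride_ms / 1000.0),
        stride_ms=stride_ms,
    )


class TestOnlineMetrics:
    def test_all_correct_trial(self):
        t = _const_trial(MotionClass11(MotionClass.POINT), [True] * 54)
        assert online_accuracy(t) == 100.0
        assert mcr([t]) == 100.0

    def test_partial_trial_counting(self):
        flags = [True] * 20 + [False] * 34
        t = _const_trial(MotionClass11(MotionClass.POINT), flags)
        assert online_accuracy(t) == pytest.approx(100 * 20 / 54)
        assert trial_completed(t)  # 20 ticks x 90 ms = 1.8 s >= 1 s

    def test_completion_needs_cumulative_second(self):
        barely = _const_trial(MotionClass11(MotionClass.POINT), [True] * 12 + [False] * 42)
        short = _const_trial(MotionClass11(MotionClass.POINT), [True] * 11 + [False] * 43)
        assert trial_completed(barely)  # 12 x 90 ms = 1.08 s
        assert not trial_completed(short)  # 11 x 90 ms = 0.99 s

    def test_mcr_counts_completed_fraction(self):
        target = MotionClass11(MotionClass.TIP, ForceLevel.LOW)
        trials = [
            _const_trial(target, [True] * 54),
            _const_trial(target, [False] * 54),
            _const_trial(target, [False] * 54),
        ]
        assert mcr(trials) == pytest.approx(100 / 3)

    def test_grasp_accuracy_requires_gesture_and_force_match(self):
        target = MotionClass11(MotionClass.TIP, ForceLevel.HIGH)
        wrong_force = RealtimeTrial(
            target=target,
            predictions=[Prediction(MotionClass.TIP, ForceLevel.LOW)] * 10,
            times_s=list(range(10)),
        )
        assert online_accuracy(wrong_force) == 0.0

    def test_empty_trial_rejected(self):
        t = RealtimeTrial(MotionClass11(MotionClass.REST), [], [])
        with pytest.raises(ValueError):
            online_accuracy(t)


@pytest.fixture(scope="module")
def lda_results(small_session):
    model = HierarchicalEmgModel(small_session, algorithm="lda", per_rep_keep=400)
    return model.fit(seed=1)


class TestStreamSimulation:
    def test_five_second_stream_yields_54_decisions(self, lda_results, default_profile):
        stream = generate_stream(default_profile, MotionClass11(MotionClass.POINT))
        trial = simulate_stream(lda_results.hierarchy, stream)
        assert len(trial.predictions) == 54

    def test_stride_equal_to_stream_gives_single_decision(
        self, lda_results, default_profile
    ):
        stream = generate_stream(default_profile, MotionClass11(MotionClass.POINT))
        trial = simulate_stream(lda_results.hierarchy, stream, stride_ms=5000.0)
        assert len(trial.predictions) == 1

    def test_short_stream_rejected(self, lda_results, default_profile):
        stream = generate_stream(
            default_profile, MotionClass11(MotionClass.POINT), duration_s=0.1
        )
        with pytest.raises(ValueError, match="shorter than one analysis window"):
            simulate_stream(lda_results.hierarchy, stream)

    def test_noise_free_stream_is_predicted_perfectly(self, noise_free_profile):
        recs = generate_session(noise_free_profile, SessionSpec(n_reps=3, hold_s=1.2))
        res = HierarchicalEmgModel(recs, algorithm="lda", per_rep_keep=400).fit(seed=0)
        stream = generate_stream(noise_free_profile, MotionClass11(MotionClass.POINT))
        trial = simulate_stream(res.hierarchy, stream)
        assert all(
            p.gesture == MotionClass.POINT and p.force is None
            for p in trial.predictions
        )

    def test_realtime_experiment_covers_11_classes_3_trials(
        self, lda_results, default_profile
    ):
        report = run_realtime_experiment(lda_results.hierarchy, default_profile)
        assert len(report.online_accuracy) == 11
        assert report.n_trials == 3
        frame = report.to_frame()
        assert len(frame) == 11
        assert frame["n_trials"].sum() == 33
        assert ((frame["mcr"] >= 0) & (frame["mcr"] <= 100)).all()

    def test_noise_free_profile_completes_every_motion(self, noise_free_profile):
        recs = generate_session(noise_free_profile, SessionSpec(n_reps=3, hold_s=1.2))
        res = HierarchicalEmgModel(recs, algorithm="lda", per_rep_keep=400).fit(seed=0)
        report = run_realtime_experiment(res.hierarchy, noise_free_profile)
        assert all(v == 100.0 for v in report.mcr.values())
        assert all(v == 100.0 for v in report.online_accuracy.values())
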