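"""Offline metrics, statistical comparison and the simulated real-time protocol.

Offline: accuracy, per-class one-vs-rest F1 and confusion matrices on the
30% test split, for any of the three algorithms (LR, NLR, LDA) with or
without feature extraction.  Statistics: two-sided Mann-Whitney U with a
Bonferroni gate.  Real-time: a trained hierarchical classifier is driven by
synthetic 5-s streams, producing a new decision from the most recent 150 ms
window every 90 ms; per-motion-class online accuracy and motion completion
rate (MCR) are aggregated over three trials per class.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from .classifiers import LdaModel, LogisticModel, TrainConfig, lda_fit, train_ova
from .features import FeatureTable, WindowConfig, featurize
from .hierarchy import HierarchicalClassifier, Prediction
from .signal_model import (
    DEFAULT_PER_REP_KEEP,
    EmgRecording,
    ForceLevel,
    GRASP_CLASSES,
    LabeledDataset,
    MotionClass,
    MotionClass11,
    assemble_dataset,
    split_dataset,
)
from . import synthgen

DEFAULT_STRIDE_MS = 90.0
#: a trial counts as completed once the target is predicted for this much
#: cumulative time within the 5-s trial
COMPLETION_S = 1.0


# ---------------------------------------------------------------------------
# Offline metrics
# ---------------------------------------------------------------------------


@dataclass
class ConfusionMatrix:
    """Counts with rows = true class, columns = predicted class."""

    counts: np.ndarray
    class_set: tuple

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        k = len(self.class_set)
        if self.counts.shape != (k, k):
            raise ValueError("counts must be square over class_set")
        if np.any(self.counts < 0):
            raise ValueError("counts must be nonnegative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.class_set, columns=self.class_set)


def confusion(y_true, y_pred, class_set: Sequence) -> ConfusionMatrix:
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    classes = list(class_set)
    index = {c: i for i, c in enumerate(classes)}
    counts = np.zeros((len(classes), len(classes)), dtype=int)
    for t, p in zip(y_true, y_pred):
        if t not in index:
            raise ValueError(f"true label {t} outside class set {classes}")
        if p not in index:
            raise ValueError(f"predicted label {p} outside class set {classes}")
        counts[index[t], index[p]] += 1
    return ConfusionMatrix(counts, tuple(classes))


def accuracy(cm: ConfusionMatrix) -> float:
    return float(np.trace(cm.counts) / cm.total) if cm.total else 0.0


def f1_per_class(cm: ConfusionMatrix) -> dict:
    """One-vs-rest F1 per class; 0 when precision + recall is 0."""
    out = {}
    for i, c in enumerate(cm.class_set):
        tp = cm.counts[i, i]
        fp = cm.counts[:, i].sum() - tp
        fn = cm.counts[i, :].sum() - tp
        denom = 2 * tp + fp + fn
        out[c] = float(2 * tp / denom) if denom else 0.0
    return out


def macro_f1(cm: ConfusionMatrix) -> float:
    return float(np.mean(list(f1_per_class(cm).values())))


@dataclass
class OfflineReport:
    """Test-split performance of one classifier."""

    accuracy: float
    f1: dict
    macro_f1: float
    confusion: ConfusionMatrix
    mode: str  # "fe" or "raw"
    algorithm: str  # "lr", "nlr" or "lda"
    classifier: str  # "gesture", "spherical_force" or "tip_force"

    def summary_row(self) -> dict:
        return {
            "classifier": self.classifier,
            "algorithm": self.algorithm,
            "mode": self.mode,
            "accuracy": self.accuracy,
            "macro_f1": self.macro_f1,
            **{f"f1_{c}": v for c, v in self.f1.items()},
        }


# ---------------------------------------------------------------------------
# Statistics
# ---------------------------------------------------------------------------


def mann_whitney_u(a, b) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    Exact null enumeration when both samples are small (min n <= 8) and tie
    free; tie-corrected normal approximation otherwise.  Returns (U, p)
    where U counts pairs in which ``a`` exceeds ``b``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("samples must be non-empty")
    has_ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
    method = "exact" if (min(a.size, b.size) <= 8 and not has_ties) else "asymptotic"
    res = mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def bonferroni_gate(p_values, m: Optional[int] = None, alpha: float = 0.05):
    """Significance decisions at the Bonferroni-corrected level alpha/m."""
    p_values = np.asarray(p_values, dtype=float)
    m = m if m is not None else p_values.size
    if m < 1:
        raise ValueError("m must be >= 1")
    return p_values < (alpha / m)


# ---------------------------------------------------------------------------
# Offline experiment
# ---------------------------------------------------------------------------


def select_gesture_recordings(
    recordings: Sequence[EmgRecording], reps_per_class: int = 6
) -> list[EmgRecording]:
    """Pick the gesture-classifier training recordings from a session.

    Non-grasp gestures contribute all their repetitions.  Grasps recorded at
    all three force levels contribute ``reps_per_class // 3`` repetitions per
    level (the lowest repetition numbers), so every class contributes the
    same number of recordings and grasp training still spans all force
    intensities.
    """
    out: list[EmgRecording] = []
    for g in MotionClass:
        recs_g = [r for r in recordings if r.label == g]
        if g.is_grasp and any(r.force is not None for r in recs_g):
            per_level = max(reps_per_class // len(ForceLevel), 1)
            for level in ForceLevel:
                level_recs = sorted(
                    (r for r in recs_g if r.force == level), key=lambda r: r.repetition
                )
                out.extend(level_recs[:per_level])
        else:
            out.extend(recs_g)
    return out


def _fit(algorithm: str, X, y, cfg: TrainConfig, class_set):
    if algorithm == "lr":
        return train_ova(X, y, cfg, degree=1, class_set=class_set)
    if algorithm == "nlr":
        return train_ova(X, y, cfg, degree=2, class_set=class_set)
    if algorithm == "lda":
        return lda_fit(X, y, class_set=class_set)
    raise ValueError(f"unknown algorithm {algorithm!r}; expected lr, nlr or lda")


def _train_and_report(
    ds: LabeledDataset,
    algorithm: str,
    fe: bool,
    window: WindowConfig,
    cfg: TrainConfig,
    seed: int,
    classifier_name: str,
    class_set,
):
    if fe:
        table = featurize(ds, window)
        ft_ds = LabeledDataset(
            table.X, table.y, "extracted", None, tuple(int(c) for c in class_set)
        )
        train, test = split_dataset(ft_ds, 0.7, seed)
    else:
        train, test = split_dataset(ds, 0.7, seed)
    model = _fit(algorithm, train.X, train.y, cfg, tuple(int(c) for c in class_set))
    y_pred = model.predict(test.X)
    cm = confusion(test.y, y_pred, tuple(int(c) for c in class_set))
    report = OfflineReport(
        accuracy=accuracy(cm),
        f1=f1_per_class(cm),
        macro_f1=macro_f1(cm),
        confusion=cm,
        mode="fe" if fe else "raw",
        algorithm=algorithm,
        classifier=classifier_name,
    )
    return model, report


@dataclass
class OfflineExperiment:
    """Fitted models and reports for the three classifiers of one run."""

    gesture_model: Union[LogisticModel, LdaModel]
    spherical_model: Union[LogisticModel, LdaModel]
    tip_model: Union[LogisticModel, LdaModel]
    reports: dict
    window: WindowConfig
    feature_mode: str

    def hierarchy(self) -> HierarchicalClassifier:
        return HierarchicalClassifier(
            gesture_clf=self.gesture_model,
            spherical_force_clf=self.spherical_model,
            tip_force_clf=self.tip_model,
            window=self.window,
            feature_mode=self.feature_mode,
        )


def run_offline_experiment(
    recordings: Sequence[EmgRecording],
    algorithm: str = "lr",
    fe: bool = True,
    window: WindowConfig | None = None,
    train_cfg: TrainConfig | None = None,
    seed: int = 0,
    per_rep_keep: int = DEFAULT_PER_REP_KEEP,
) -> OfflineExperiment:
    """Train and evaluate the three classifiers of the hierarchy.

    Assembles the gesture DataSet (balanced repetitions per class) and the
    two grasp-only force datasets, splits each 70/30 (stratified, seeded),
    optionally extracts window features, trains the requested algorithm and
    reports test-split accuracy, per-class F1 and confusion matrices.
    """
    window = window or WindowConfig()
    train_cfg = train_cfg or TrainConfig()

    gesture_recs = select_gesture_recordings(recordings)
    gesture_ds = assemble_dataset(gesture_recs, per_rep_keep, label_by="gesture")
    models, reports = {}, {}
    models["gesture"], reports["gesture"] = _train_and_report(
        gesture_ds, algorithm, fe, window, train_cfg, seed, "gesture",
        tuple(int(g) for g in MotionClass),
    )
    for grasp, name in ((MotionClass.SPHERICAL, "spherical_force"), (MotionClass.TIP, "tip_force")):
        grasp_recs = [r for r in recordings if r.label == grasp and r.force is not None]
        if not grasp_recs:
            raise ValueError(
                f"no force-labeled recordings for grasp class {grasp.name.lower()}"
            )
        grasp_ds = assemble_dataset(grasp_recs, per_rep_keep, label_by="force")
        models[name], reports[name] = _train_and_report(
            grasp_ds, algorithm, fe, window, train_cfg, seed, name,
            tuple(int(f) for f in ForceLevel),
        )
    return OfflineExperiment(
        gesture_model=models["gesture"],
        spherical_model=models["spherical_force"],
        tip_model=models["tip_force"],
        reports=reports,
        window=window,
        feature_mode="extracted" if fe else "raw",
    )


def evaluate_models(
    recordings: Sequence[EmgRecording],
    gesture_model,
    spherical_model,
    tip_model,
    fe: bool = True,
    window: WindowConfig | None = None,
    seed: int = 0,
    per_rep_keep: int = DEFAULT_PER_REP_KEEP,
) -> dict:
    """Score already-fitted classifiers on the seeded 30% test split.

    Reconstructs the same datasets and splits as
    :func:`run_offline_experiment` for the given seed, but evaluates the
    supplied models instead of training new ones.
    """
    window = window or WindowConfig()
    reports = {}
    jobs = [
        ("gesture", gesture_model,
         select_gesture_recordings(recordings), "gesture",
         tuple(int(g) for g in MotionClass)),
        ("spherical_force", spherical_model,
         [r for r in recordings if r.label == MotionClass.SPHERICAL and r.force is not None],
         "force", tuple(int(f) for f in ForceLevel)),
        ("tip_force", tip_model,
         [r for r in recordings if r.label == MotionClass.TIP and r.force is not None],
         "force", tuple(int(f) for f in ForceLevel)),
    ]
    for name, model, recs, label_by, class_set in jobs:
        ds = assemble_dataset(recs, per_rep_keep, label_by=label_by)
        if fe:
            table = featurize(ds, window)
            ds = LabeledDataset(table.X, table.y, "extracted", None, class_set)
        _, test = split_dataset(ds, 0.7, seed)
        y_pred = model.predict(test.X)
        cm = confusion(test.y, y_pred, class_set)
        algorithm = "lda" if isinstance(model, LdaModel) else (
            "lr" if getattr(model, "degree", 1) == 1 else "nlr"
        )
        reports[name] = OfflineReport(
            accuracy=accuracy(cm),
            f1=f1_per_class(cm),
            macro_f1=macro_f1(cm),
            confusion=cm,
            mode="fe" if fe else "raw",
            algorithm=algorithm,
            classifier=name,
        )
    return reports


# ---------------------------------------------------------------------------
# Simulated real-time protocol
# ---------------------------------------------------------------------------


@dataclass
class RealtimeTrial:
    """One simulated 5-s streaming trial against a target motion class."""

    target: MotionClass11
    predictions: list  # of Prediction
    times_s: list
    stride_ms: float = DEFAULT_STRIDE_MS

    def correct_mask(self) -> np.ndarray:
        return np.array(
            [
                p.gesture == self.target.gesture and p.force == self.target.force
                for p in self.predictions
            ]
        )


def simulate_stream(
    h: HierarchicalClassifier,
    stream: EmgRecording,
    stride_ms: float = DEFAULT_STRIDE_MS,
) -> RealtimeTrial:
    """Drive the hierarchy over a stream, one decision every ``stride_ms``.

    At each stride tick the most recent full analysis window is classified;
    the first decision fires once one full window is available, so a stream
    of n samples yields floor((n - win) / stride) + 1 decisions.
    """
    fs = stream.fs
    win = h.window.win_samples
    stride = int(round(stride_ms * fs / 1000.0))
    n = stream.n_samples
    if n < win:
        raise ValueError(
            f"stream of {n} samples is shorter than one analysis window ({win})"
        )
    preds, times = [], []
    for end in range(win, n + 1, stride):
        window = stream.samples[end - win : end]
        preds.append(h.predict_window(window))
        times.append(end / fs)
    target = MotionClass11(stream.label, stream.force)
    return RealtimeTrial(target=target, predictions=preds, times_s=times, stride_ms=stride_ms)


def online_accuracy(trial: RealtimeTrial) -> float:
    """Percent of decision ticks whose prediction equals the target
    (gesture AND force level for grasp targets)."""
    if not trial.predictions:
        raise ValueError("trial has no predictions")
    mask = trial.correct_mask()
    return 100.0 * float(mask.mean())


def trial_completed(trial: RealtimeTrial, completion_s: float = COMPLETION_S) -> bool:
    """A trial is completed once the target has been predicted for a
    cumulative ``completion_s`` seconds (>= 12 of 54 ticks at defaults)."""
    n_correct = int(trial.correct_mask().sum())
    return n_correct * trial.stride_ms / 1000.0 >= completion_s


def mcr(trials: Sequence[RealtimeTrial], completion_s: float = COMPLETION_S) -> float:
    """Motion completion rate: percent of attempted trials completed."""
    if not trials:
        raise ValueError("no trials given")
    done = sum(trial_completed(t, completion_s) for t in trials)
    return 100.0 * done / len(trials)


@dataclass
class RealtimeReport:
    """Per-motion-class online accuracy and MCR over repeated trials."""

    online_accuracy: dict  # MotionClass11 -> percent
    mcr: dict  # MotionClass11 -> percent
    n_trials: int

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "motion_class": str(k),
                "online_accuracy": self.online_accuracy[k],
                "mcr": self.mcr[k],
                "n_trials": self.n_trials,
            }
            for k in self.online_accuracy
        ]
        return pd.DataFrame(rows)

    def mean_online_accuracy(self) -> float:
        return float(np.mean(list(self.online_accuracy.values())))

    def mean_mcr(self) -> float:
        return float(np.mean(list(self.mcr.values())))


def run_realtime_experiment(
    h: HierarchicalClassifier,
    profile: "synthgen.SubjectProfile",
    n_trials: int = 3,
    duration_s: float = 5.0,
    stride_ms: float = DEFAULT_STRIDE_MS,
) -> RealtimeReport:
    """Simulate the online validation: ``n_trials`` streams per each of the
    11 motion classes (33 trials at defaults), aggregated per class."""
    acc, rates = {}, {}
    for target in MotionClass11.all_classes():
        trials = []
        for t in range(1, n_trials + 1):
            stream = synthgen.generate_stream(
                profile, target, duration_s=duration_s, trial=t
            )
            trials.append(simulate_stream(h, stream, stride_ms))
        acc[target] = float(np.mean([online_accuracy(t) for t in trials]))
        rates[target] = mcr(trials)
    return RealtimeReport(online_accuracy=acc, mcr=rates, n_trials=n_trials)


def plot_f1_boxes(reports: Sequence[OfflineReport], ax=None):
    """Bar panel of per-class F1 for one or more offline reports."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 3.5))
    width = 0.8 / max(len(reports), 1)
    for i, rep in enumerate(reports):
        classes = list(rep.f1.keys())
        xs = np.arange(len(classes)) + i * width
        ax.bar(xs, list(rep.f1.values()), width=width,
               label=f"{rep.classifier} {rep.algorithm} ({rep.mode})")
    ax.set_xticks(np.arange(len(classes)) + 0.4 - width / 2)
    ax.set_xticklabels([str(c) for c in classes])
    ax.set_ylabel("F1 score")
    ax.set_ylim(0, 1.05)
    ax.legend(fontsize=7)
    return ax
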