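"""Gesture-to-force cascade, force-threshold calibration and prosthesis commands.

A hierarchical classifier runs the seven-gesture classifier on every
analysis window; if and only if the predicted gesture is spherical or tip,
the matching three-level force classifier runs on the same feature vector
and its level is attached to the prediction.  Predictions map to prosthesis
commands: grasps close the hand at a PWM duty cycle of 25/50/75% for
low/medium/high (nominal grip forces of roughly 7.5/15/30 N), the other
active gestures drive the hand or wrist at 50% PWM, and rest issues no
command.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Union

import numpy as np

from .classifiers import LdaModel, LogisticModel
from .features import WindowConfig, window_features
from .signal_model import (
    ForceLevel,
    ForceRecording,
    GRASP_CLASSES,
    MotionClass,
    MotionClass11,
)

BAND_TOLERANCE = 0.10  # the +/-10% calibration band half-width
METHOD1_FRACTIONS = (0.30, 0.60, 0.90)  # of maximum voluntary force
PWM_BY_LEVEL = {ForceLevel.LOW: 25, ForceLevel.MEDIUM: 50, ForceLevel.HIGH: 75}
NOMINAL_FORCE_N = {ForceLevel.LOW: 7.5, ForceLevel.MEDIUM: 15.0, ForceLevel.HIGH: 30.0}


class CalibrationError(ValueError):
    """Raised when dynamometer calibration violates level ordering."""


@dataclass(frozen=True)
class Prediction:
    """One hierarchical decision; a valid 11-way motion class."""

    gesture: MotionClass
    force: Optional[ForceLevel] = None

    def __post_init__(self) -> None:
        if self.gesture.is_grasp and self.force is None:
            raise ValueError("grasp prediction requires a force level")
        if not self.gesture.is_grasp and self.force is not None:
            raise ValueError("non-grasp prediction cannot carry a force level")

    def as_motion11(self) -> MotionClass11:
        return MotionClass11(self.gesture, self.force)


@dataclass
class ForceThresholds:
    """Per-grasp low/medium/high force bands from dynamometer calibration.

    ``low``/``medium``/``high`` are the mean plateau forces (N); bands are
    [0.9L, 1.1L], [0.9M, 1.1M] and [0.9H, f_max].
    """

    grasp: MotionClass
    low: float
    medium: float
    high: float
    f_max: float

    def __post_init__(self) -> None:
        bad = []
        if not self.low < self.medium:
            bad.append("medium <= low")
        if not self.medium < self.high:
            bad.append("high <= medium")
        if not self.high <= self.f_max:
            bad.append("f_max < high")
        if bad:
            raise CalibrationError(
                f"{self.grasp.name.lower()} calibration not monotone: "
                + "; ".join(bad)
            )
        if self.bands[ForceLevel.LOW][1] > self.bands[ForceLevel.MEDIUM][0]:
            warnings.warn(
                f"{self.grasp.name.lower()}: low and medium force bands overlap"
            )

    @property
    def bands(self) -> dict[ForceLevel, tuple[float, float]]:
        t = BAND_TOLERANCE
        return {
            ForceLevel.LOW: ((1 - t) * self.low, (1 + t) * self.low),
            ForceLevel.MEDIUM: ((1 - t) * self.medium, (1 + t) * self.medium),
            ForceLevel.HIGH: ((1 - t) * self.high, self.f_max),
        }

    def to_dict(self) -> dict:
        return {
            "grasp": self.grasp.name.lower(),
            "low": self.low,
            "medium": self.medium,
            "high": self.high,
            "f_max": self.f_max,
            "bands": {k.name.lower(): list(v) for k, v in self.bands.items()},
        }


def _plateau_mean(trace: np.ndarray) -> float:
    """Mean over the central 80% of a trace (ramp-insensitive plateau)."""
    n = trace.size
    lo = int(round(0.1 * n))
    hi = max(int(round(0.9 * n)), lo + 1)
    return float(np.mean(trace[lo:hi]))


def calibrate_thresholds(
    recs: Union[Mapping[ForceLevel, Sequence[ForceRecording]], Sequence[ForceRecording]],
    grasp: MotionClass,
) -> ForceThresholds:
    """Derive the low/medium/high force bands from calibration traces.

    Each level's threshold is the mean over repetitions of the per-trace
    plateau mean (central 80% of the trace); ``f_max`` is the maximum force
    observed anywhere.  Raises :class:`CalibrationError` when the perceived
    levels are not monotone.
    """
    if grasp not in GRASP_CLASSES:
        raise ValueError(f"calibration applies to grasp classes only, got {grasp.name}")
    if not isinstance(recs, Mapping):
        grouped: dict[ForceLevel, list[ForceRecording]] = {}
        for r in recs:
            grouped.setdefault(r.perceived_level, []).append(r)
        recs = grouped
    means = {}
    f_max = 0.0
    for level in ForceLevel:
        level_recs = list(recs.get(level, []))
        if not level_recs:
            raise ValueError(f"no calibration repetitions for level {level.name.lower()}")
        means[level] = float(
            np.mean([_plateau_mean(r.trace) for r in level_recs])
        )
        f_max = max(f_max, max(float(r.trace.max()) for r in level_recs))
    return ForceThresholds(
        grasp=grasp,
        low=means[ForceLevel.LOW],
        medium=means[ForceLevel.MEDIUM],
        high=means[ForceLevel.HIGH],
        f_max=f_max,
    )


def method1_thresholds(f_max: float, grasp: MotionClass = MotionClass.SPHERICAL) -> ForceThresholds:
    """Thresholds at 30/60/90% of the maximum voluntary force.

    The alternative calibration rule; the perceived-force method
    (:func:`calibrate_thresholds`) proved more repeatable in practice and is
    the default elsewhere in the package.
    """
    if f_max <= 0:
        raise ValueError("f_max must be positive")
    lo, med, hi = (frac * f_max for frac in METHOD1_FRACTIONS)
    return ForceThresholds(grasp=grasp, low=lo, medium=med, high=hi, f_max=f_max)


@dataclass(frozen=True)
class ProsthesisCommand:
    """One actuator command: degree of freedom, action, PWM duty cycle."""

    dof: str  # "hand" or "wrist"
    action: str
    pwm: int
    nominal_force_n: Optional[float] = None


def map_to_command(p: Prediction) -> Optional[ProsthesisCommand]:
    """Map a hierarchical prediction to a prosthesis command.

    Grasps close the hand at 25/50/75% PWM for low/medium/high (nominal
    7.5/15/30 N); platform/point drive the hand and supination/pronation the
    wrist at 50% PWM; rest returns ``None`` (the null command).
    """
    g = p.gesture
    if g is MotionClass.REST:
        return None
    if g.is_grasp:
        action = "close_spherical" if g is MotionClass.SPHERICAL else "close_tip"
        return ProsthesisCommand(
            dof="hand",
            action=action,
            pwm=PWM_BY_LEVEL[p.force],
            nominal_force_n=NOMINAL_FORCE_N[p.force],
        )
    if g is MotionClass.PLATFORM:
        return ProsthesisCommand(dof="hand", action="open", pwm=50)
    if g is MotionClass.POINT:
        return ProsthesisCommand(dof="hand", action="point", pwm=50)
    if g is MotionClass.SUPINATION:
        return ProsthesisCommand(dof="wrist", action="supinate", pwm=50)
    return ProsthesisCommand(dof="wrist", action="pronate", pwm=50)


@dataclass
class HierarchicalClassifier:
    """Gesture classifier gating the two grasp-force classifiers.

    All three sub-classifiers consume the same per-window feature vector
    (30 time-domain features in ``extracted`` mode, the 6 window-mean
    envelope amplitudes in ``raw`` mode).
    """

    gesture_clf: Union[LogisticModel, LdaModel]
    spherical_force_clf: Union[LogisticModel, LdaModel]
    tip_force_clf: Union[LogisticModel, LdaModel]
    window: WindowConfig = field(default_factory=WindowConfig)
    feature_mode: str = "extracted"

    def __post_init__(self) -> None:
        if self.feature_mode not in ("raw", "extracted"):
            raise ValueError("feature_mode must be 'raw' or 'extracted'")
        for name, clf in (
            ("spherical", self.spherical_force_clf),
            ("tip", self.tip_force_clf),
        ):
            if tuple(clf.class_set) != tuple(int(f) for f in ForceLevel):
                raise ValueError(
                    f"{name} force classifier must have class set "
                    f"{tuple(int(f) for f in ForceLevel)}"
                )

    def window_vector(self, window: np.ndarray) -> np.ndarray:
        window = np.asarray(window, dtype=float)
        if self.feature_mode == "extracted":
            return window_features(window)
        return window.mean(axis=0)

    def predict_window(self, window: np.ndarray) -> Prediction:
        """Classify one raw sample window hierarchically."""
        x = self.window_vector(window)
        gesture = MotionClass(int(self.gesture_clf.predict_one(x)))
        if gesture is MotionClass.SPHERICAL:
            level = ForceLevel(int(self.spherical_force_clf.predict_one(x)))
            return Prediction(gesture, level)
        if gesture is MotionClass.TIP:
            level = ForceLevel(int(self.tip_force_clf.predict_one(x)))
            return Prediction(gesture, level)
        return Prediction(gesture)


def predict_hierarchical(h: HierarchicalClassifier, window: np.ndarray) -> Prediction:
    """Functional alias for :meth:`HierarchicalClassifier.predict_window`."""
    return h.predict_window(window)
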