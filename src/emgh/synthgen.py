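"""Synthetic enveloped-sEMG session, force-calibration and stream generator.

Emulates the acquisition protocol the classifiers are trained on: seven
gestures held for 3 s, six repetitions each, with the two grasp gestures
(spherical, tip) repeated at three perceived force levels; three 3-s
dynamometer repetitions per force level for threshold calibration; and 5-s
continuous streams for simulated real-time evaluation.

The signal model is deliberately an *envelope* model, not raw EMG: each
channel is a per-gesture mean activation, scaled by a force gain for grasps
and a per-repetition factor, multiplied by smooth positive (log-normal)
noise and shaped by 200 ms onset/offset ramps.  Amplitudes are arbitrary
sensor units and always nonnegative.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .signal_model import (
    DEFAULT_FS,
    GRASP_CLASSES,
    EmgRecording,
    ForceLevel,
    ForceRecording,
    MotionClass,
    MotionClass11,
    N_CHANNELS,
)

#: Each gesture activates 2-3 dominant channels on a low common floor, so
#: that distinct gestures have well-separated envelope patterns while rest
#: stays near the noise floor (rows: gestures 1..7, cols: channels 1..6).
DEFAULT_ACTIVATION = np.array(
    [
        [0.30, 0.30, 0.30, 0.30, 0.30, 0.30],  # rest
        [4.50, 3.50, 0.80, 0.80, 2.50, 0.80],  # spherical
        [0.80, 4.00, 3.20, 0.80, 0.80, 2.20],  # platform
        [0.80, 0.80, 4.20, 3.00, 0.80, 0.80],  # point
        [2.80, 0.80, 0.80, 4.30, 3.10, 0.80],  # tip
        [0.80, 2.40, 0.80, 0.80, 4.10, 3.30],  # supination
        [3.40, 0.80, 2.30, 0.80, 0.80, 4.40],  # pronation
    ]
)

DEFAULT_FORCE_GAIN = {ForceLevel.LOW: 0.6, ForceLevel.MEDIUM: 1.0, ForceLevel.HIGH: 1.6}

#: plateau grip force (N) at medium level, per grasp; low/high scale by the
#: force gains (a whole-hand power grasp is roughly twice as strong as a
#: thumb-index pinch)
DEFAULT_FORCE_NEWTONS = {MotionClass.SPHERICAL: 18.0, MotionClass.TIP: 9.0}

RAMP_MS = 200.0
NOISE_SMOOTH_MS = 50.0


@dataclass
class SubjectProfile:
    """Per-subject generative parameters for the synthetic session."""

    activation: np.ndarray = field(default_factory=lambda: DEFAULT_ACTIVATION.copy())
    force_gain: dict = field(default_factory=lambda: dict(DEFAULT_FORCE_GAIN))
    noise_cv: float = 0.15
    rep_jitter: float = 0.05
    seed: int = 0
    subject_id: str = "SYN"
    force_newtons: dict = field(default_factory=lambda: dict(DEFAULT_FORCE_NEWTONS))

    def __post_init__(self) -> None:
        self.activation = np.asarray(self.activation, dtype=float)
        if self.activation.shape != (len(MotionClass), N_CHANNELS):
            raise ValueError(
                f"activation must be {len(MotionClass)}x{N_CHANNELS}, got "
                f"{self.activation.shape}"
            )
        if np.any(self.activation < 0):
            raise ValueError("activation amplitudes must be nonnegative")
        for a in range(self.activation.shape[0]):
            for b in range(a + 1, self.activation.shape[0]):
                if np.allclose(self.activation[a], self.activation[b]):
                    raise ValueError(
                        f"activation rows {a + 1} and {b + 1} are identical"
                    )
        gains = [self.force_gain[f] for f in ForceLevel]
        if not (gains[0] < gains[1] < gains[2]):
            raise ValueError("force_gain must be strictly increasing with level")
        if self.noise_cv < 0 or self.rep_jitter < 0:
            raise ValueError("noise_cv and rep_jitter must be >= 0")


@dataclass
class SessionSpec:
    """Shape of one acquisition session."""

    n_reps: int = 6
    hold_s: float = 3.0
    fs: float = DEFAULT_FS
    grasp_levels: bool = True

    def __post_init__(self) -> None:
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")
        if self.hold_s <= 0 or self.fs <= 0:
            raise ValueError("hold_s and fs must be positive")


def _rng_for(profile: SubjectProfile, *stream_key: int) -> np.random.Generator:
    # independent, reproducible substream per (gesture, level, rep, kind)
    return np.random.default_rng([profile.seed & 0x7FFFFFFF, *stream_key])


def _smooth(x: np.ndarray, width: int) -> np.ndarray:
    if width <= 1 or x.shape[0] <= 1:
        return x
    kernel = np.ones(width) / width
    pad = width // 2
    xp = np.pad(x, [(pad, width - 1 - pad)] + [(0, 0)] * (x.ndim - 1), mode="reflect")
    if x.ndim == 1:
        return np.convolve(xp, kernel, mode="valid")
    return np.stack(
        [np.convolve(xp[:, c], kernel, mode="valid") for c in range(x.shape[1])],
        axis=1,
    )


def _envelope_noise(
    rng: np.random.Generator, n: int, n_ch: int, cv: float, fs: float
) -> np.ndarray:
    """Positive multiplicative noise with unit mean and the given CV,
    low-pass smoothed over 50 ms to mimic an already-enveloped sensor."""
    if cv == 0:
        return np.ones((n, n_ch))
    sigma2 = np.log1p(cv * cv)
    raw = rng.lognormal(mean=-sigma2 / 2.0, sigma=np.sqrt(sigma2), size=(n, n_ch))
    return _smooth(raw, max(int(round(NOISE_SMOOTH_MS * fs / 1000.0)), 1))


def _ramp(n: int, fs: float) -> np.ndarray:
    ramp_len = min(int(round(RAMP_MS * fs / 1000.0)), n // 2)
    env = np.ones(n)
    if ramp_len > 0:
        env[:ramp_len] = np.linspace(0.0, 1.0, ramp_len, endpoint=False)
        env[-ramp_len:] = np.linspace(1.0, 0.0, ramp_len, endpoint=False)[::-1]
    return env


def _rep_factor(rng: np.random.Generator, jitter: float) -> float:
    if jitter == 0:
        return 1.0
    return float(max(1.0 + jitter * rng.standard_normal(), 0.0))


def _synth_block(
    profile: SubjectProfile,
    gesture: MotionClass,
    force: Optional[ForceLevel],
    n: int,
    fs: float,
    rng: np.random.Generator,
    rep_factor: float,
    with_ramps: bool,
) -> np.ndarray:
    mean = profile.activation[int(gesture) - 1].copy()
    if force is not None and gesture.is_grasp:
        mean = mean * profile.force_gain[force]
    noise = _envelope_noise(rng, n, N_CHANNELS, profile.noise_cv, fs)
    samples = mean[None, :] * rep_factor * noise
    if with_ramps:
        samples = samples * _ramp(n, fs)[:, None]
    return np.clip(samples, 0.0, None)


def generate_session(
    profile: SubjectProfile, spec: SessionSpec | None = None
) -> list[EmgRecording]:
    """Generate one full training session.

    One recording per (gesture, repetition), with the grasp gestures
    repeated at all three force levels when ``spec.grasp_levels`` is set:
    5 non-grasp x n_reps + 2 grasps x 3 levels x n_reps recordings
    (66 at the defaults).  Deterministic for a fixed profile seed.
    """
    spec = spec or SessionSpec()
    n = int(round(spec.hold_s * spec.fs))
    out: list[EmgRecording] = []
    for gesture in MotionClass:
        levels: Sequence[Optional[ForceLevel]]
        if gesture.is_grasp and spec.grasp_levels:
            levels = list(ForceLevel)
        else:
            levels = [None]
        for force in levels:
            for rep in range(1, spec.n_reps + 1):
                key = (1, int(gesture), int(force) if force else 0, rep)
                rng = _rng_for(profile, *key)
                rep_f = _rep_factor(rng, profile.rep_jitter)
                samples = _synth_block(
                    profile, gesture, force, n, spec.fs, rng, rep_f, with_ramps=True
                )
                out.append(
                    EmgRecording(
                        samples=samples,
                        fs=spec.fs,
                        label=gesture,
                        force=force,
                        repetition=rep,
                        subject_id=profile.subject_id,
                    )
                )
    return out


def generate_force_calibration(
    profile: SubjectProfile,
    grasp: MotionClass,
    level: ForceLevel,
    n_reps: int = 3,
    hold_s: float = 3.0,
    fs: float = DEFAULT_FS,
) -> list[ForceRecording]:
    """Generate dynamometer traces for one grasp at one perceived level.

    Plateau mean is proportional to the profile's force gain for that level;
    three 3-s repetitions by default, matching the calibration protocol.
    """
    if grasp not in GRASP_CLASSES:
        raise ValueError(
            f"force calibration applies to grasp classes only, got {grasp.name}"
        )
    n = int(round(hold_s * fs))
    mean_n = profile.force_newtons[grasp] * profile.force_gain[level]
    out = []
    for rep in range(1, n_reps + 1):
        rng = _rng_for(profile, 2, int(grasp), int(level), rep)
        rep_f = _rep_factor(rng, profile.rep_jitter)
        noise = _envelope_noise(rng, n, 1, profile.noise_cv, fs)[:, 0]
        trace = np.clip(mean_n * rep_f * noise * _ramp(n, fs), 0.0, None)
        out.append(
            ForceRecording(
                trace=trace, fs=fs, grasp=grasp, perceived_level=level, repetition=rep
            )
        )
    return out


def generate_stream(
    profile: SubjectProfile,
    target: MotionClass11,
    duration_s: float = 5.0,
    fs: float = DEFAULT_FS,
    trial: int = 1,
) -> EmgRecording:
    """Generate one continuous labeled stream of the target motion.

    The stream models a hold already in progress (no onset/offset ramps) and
    is consumed by the real-time simulator; ``trial`` separates the noise
    substreams of repeated trials of the same target.
    """
    n = int(round(duration_s * fs))
    rng = _rng_for(
        profile, 3, int(target.gesture), int(target.force) if target.force else 0, trial
    )
    rep_f = _rep_factor(rng, profile.rep_jitter)
    samples = _synth_block(
        profile, target.gesture, target.force, n, fs, rng, rep_f, with_ramps=False
    )
    return EmgRecording(
        samples=samples,
        fs=fs,
        label=target.gesture,
        force=target.force,
        repetition=trial,
        subject_id=profile.subject_id,
    )
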