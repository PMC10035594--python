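"""Core data types for enveloped-sEMG recordings and labeled datasets.

The acquisition protocol this package models records six enveloped sEMG
channels per arm at 1 kHz while the subject holds one of seven hand/wrist
gestures; the two grasp gestures (spherical, tip) are additionally performed
at three perceived force levels.  Recordings are assembled into a row-wise
sample matrix (the "DataSet matrix") for classifier training.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

N_CHANNELS = 6
DEFAULT_FS = 1000.0
#: samples retained per repetition when assembling the DataSet matrix; with
#: 6 reps/class this yields the protocol's 4,800 samples per class.
DEFAULT_PER_REP_KEEP = 800


class MotionClass(enum.IntEnum):
    """The seven hand/wrist gestures, coded 1-7."""

    REST = 1
    SPHERICAL = 2
    PLATFORM = 3
    POINT = 4
    TIP = 5
    SUPINATION = 6
    PRONATION = 7

    @property
    def is_grasp(self) -> bool:
        """Spherical and tip are the only grasps (force-modulated classes)."""
        return self in (MotionClass.SPHERICAL, MotionClass.TIP)

    @classmethod
    def from_name(cls, name: str) -> "MotionClass":
        try:
            return cls[name.strip().upper()]
        except KeyError:
            valid = ", ".join(m.name.lower() for m in cls)
            raise ValueError(
                f"unknown motion class {name!r}; valid labels: {valid}"
            ) from None


GRASP_CLASSES = (MotionClass.SPHERICAL, MotionClass.TIP)


class ForceLevel(enum.IntEnum):
    """Relative grasp-force level, totally ordered low < medium < high."""

    LOW = 1
    MEDIUM = 2
    HIGH = 3

    @classmethod
    def from_name(cls, name: str) -> "ForceLevel":
        try:
            return cls[name.strip().upper()]
        except KeyError:
            valid = ", ".join(f.name.lower() for f in cls)
            raise ValueError(
                f"unknown force level {name!r}; valid levels: {valid}"
            ) from None


@dataclass(frozen=True)
class MotionClass11:
    """One of the 11 motion classes used in real-time evaluation.

    Five non-grasp gestures plus each grasp at each of the three force
    levels.  ``force`` is present if and only if the gesture is a grasp.
    """

    gesture: MotionClass
    force: Optional[ForceLevel] = None

    def __post_init__(self) -> None:
        if self.gesture.is_grasp and self.force is None:
            raise ValueError(f"grasp class {self.gesture.name} requires a force level")
        if not self.gesture.is_grasp and self.force is not None:
            raise ValueError(
                f"non-grasp class {self.gesture.name} cannot carry a force level"
            )

    @staticmethod
    def all_classes() -> tuple["MotionClass11", ...]:
        out = []
        for g in MotionClass:
            if g.is_grasp:
                out.extend(MotionClass11(g, f) for f in ForceLevel)
            else:
                out.append(MotionClass11(g))
        return tuple(out)

    def __str__(self) -> str:
        if self.force is None:
            return self.gesture.name.lower()
        return f"{self.gesture.name.lower()}/{self.force.name.lower()}"


@dataclass
class EmgRecording:
    """One labeled multi-channel enveloped-EMG hold.

    ``samples`` is an ``(n_samples, 6)`` array of nonnegative envelope
    amplitudes (arbitrary sensor units) sampled at ``fs`` Hz.
    """

    samples: np.ndarray
    label: MotionClass
    fs: float = DEFAULT_FS
    force: Optional[ForceLevel] = None
    repetition: int = 1
    subject_id: str = "S0"

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2 or self.samples.shape[1] != N_CHANNELS:
            raise ValueError(
                f"expected {N_CHANNELS} channels, got array of shape "
                f"{self.samples.shape}"
            )
        if self.samples.shape[0] < 1:
            raise ValueError("recording must contain at least one sample")
        if np.any(self.samples < 0):
            raise ValueError("envelope amplitudes must be nonnegative")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if self.force is not None and not self.label.is_grasp:
            raise ValueError(
                f"force level given for non-grasp class {self.label.name}"
            )
        if self.repetition < 1:
            raise ValueError("repetition must be >= 1")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs


@dataclass
class ForceRecording:
    """One dynamometer calibration trace (newtons) for a grasp hold."""

    trace: np.ndarray
    grasp: MotionClass
    perceived_level: ForceLevel
    fs: float = DEFAULT_FS
    repetition: int = 1

    def __post_init__(self) -> None:
        self.trace = np.asarray(self.trace, dtype=float).ravel()
        if self.trace.size < 1:
            raise ValueError("force trace must contain at least one sample")
        if np.any(self.trace < 0):
            raise ValueError("force values must be nonnegative")
        if self.grasp not in GRASP_CLASSES:
            raise ValueError(
                f"force calibration applies to grasp classes only, got "
                f"{self.grasp.name}"
            )


@dataclass
class LabeledDataset:
    """Row-wise sample (or window-feature) matrix with class labels.

    ``feature_mode`` is ``"raw"`` (rows are envelope samples, 6 columns) or
    ``"extracted"`` (rows are window feature vectors, 30 columns).  ``meta``
    carries per-row provenance (subject, gesture, force, repetition).
    """

    X: np.ndarray
    y: np.ndarray
    feature_mode: str = "raw"
    meta: Optional[pd.DataFrame] = None
    class_set: tuple = ()

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=int)
        if self.X.ndim != 2:
            raise ValueError("X must be 2-D")
        if len(self.y) != self.X.shape[0]:
            raise ValueError("y length must equal number of rows in X")
        if self.feature_mode not in ("raw", "extracted"):
            raise ValueError("feature_mode must be 'raw' or 'extracted'")
        if self.feature_mode == "raw" and self.X.shape[1] != N_CHANNELS:
            raise ValueError(
                f"raw datasets must have {N_CHANNELS} columns, got {self.X.shape[1]}"
            )
        if not self.class_set:
            self.class_set = tuple(sorted(np.unique(self.y)))
        unknown = set(np.unique(self.y)) - set(int(c) for c in self.class_set)
        if unknown:
            raise ValueError(f"labels outside declared class set: {sorted(unknown)}")
        if self.meta is not None and len(self.meta) != self.X.shape[0]:
            raise ValueError("meta must have one row per dataset row")

    @property
    def n_rows(self) -> int:
        return self.X.shape[0]

    def subset(self, idx: np.ndarray) -> "LabeledDataset":
        meta = self.meta.iloc[idx].reset_index(drop=True) if self.meta is not None else None
        return LabeledDataset(
            self.X[idx], self.y[idx], self.feature_mode, meta, self.class_set
        )


def _central_segment(a: np.ndarray, keep: int) -> np.ndarray:
    start = (a.shape[0] - keep) // 2
    return a[start : start + keep]


def assemble_dataset(
    recordings: Sequence[EmgRecording],
    per_rep_keep: int = DEFAULT_PER_REP_KEEP,
    label_by: str = "gesture",
) -> LabeledDataset:
    """Stack the central steady-state segment of each recording into a matrix.

    From each recording the central contiguous ``per_rep_keep`` samples are
    retained (discarding onset/offset transients), and rows are stacked in
    (class, force, repetition) order.  With the default protocol (7 gestures
    x 6 repetitions, 800 samples kept per repetition) this reproduces the
    33,600 x 6 DataSet matrix, 4,800 samples per class.

    ``label_by`` selects the label column: ``"gesture"`` (motion-class codes)
    or ``"force"`` (force-level codes, for grasp-only force classifiers).
    """
    if not recordings:
        raise ValueError("no recordings given")
    if per_rep_keep < 1:
        raise ValueError("per_rep_keep must be >= 1")
    fs0 = recordings[0].fs
    for rec in recordings:
        if rec.samples.shape[1] != N_CHANNELS:
            raise ValueError("mixed channel counts in recordings")
        if rec.fs != fs0:
            raise ValueError("recordings have mixed sampling rates")
        if rec.n_samples < per_rep_keep:
            raise ValueError(
                f"recording (class={rec.label.name}, rep={rec.repetition}) has "
                f"{rec.n_samples} samples, fewer than per_rep_keep={per_rep_keep}"
            )
    if label_by not in ("gesture", "force"):
        raise ValueError("label_by must be 'gesture' or 'force'")
    if label_by == "force" and any(r.force is None for r in recordings):
        raise ValueError("label_by='force' requires a force level on every recording")

    order = sorted(
        range(len(recordings)),
        key=lambda i: (
            int(recordings[i].label),
            int(recordings[i].force) if recordings[i].force is not None else 0,
            recordings[i].repetition,
        ),
    )
    blocks, labels, meta_rows = [], [], []
    for i in order:
        rec = recordings[i]
        seg = _central_segment(rec.samples, per_rep_keep)
        blocks.append(seg)
        lab = int(rec.label) if label_by == "gesture" else int(rec.force)
        labels.append(np.full(per_rep_keep, lab, dtype=int))
        meta_rows.append(
            pd.DataFrame(
                {
                    "subject": rec.subject_id,
                    "gesture": int(rec.label),
                    "force": int(rec.force) if rec.force is not None else 0,
                    "repetition": rec.repetition,
                },
                index=range(per_rep_keep),
            )
        )
    X = np.vstack(blocks)
    y = np.concatenate(labels)
    meta = pd.concat(meta_rows, ignore_index=True)
    return LabeledDataset(X, y, "raw", meta)


def split_dataset(
    ds: LabeledDataset, train_frac: float, seed: int
) -> tuple[LabeledDataset, LabeledDataset]:
    """Stratified random train/test split.

    Each class contributes ``round(train_frac * n_class)`` rows to the
    training part (ties rounded toward training), so per-class proportions
    stay within one row of ``train_frac``.  Deterministic for a fixed seed.
    """
    if not (0.0 < train_frac < 1.0):
        raise ValueError("train_frac must be in (0, 1)")
    rng = np.random.default_rng(seed)
    train_idx, test_idx = [], []
    for c in ds.class_set:
        idx = np.flatnonzero(ds.y == c)
        if idx.size < 2:
            raise ValueError(f"class {c} has fewer than 2 rows; cannot split")
        perm = rng.permutation(idx)
        n_train = int(np.floor(train_frac * idx.size + 0.5))
        n_train = min(max(n_train, 1), idx.size - 1)
        train_idx.append(perm[:n_train])
        test_idx.append(perm[n_train:])
    tr = np.sort(np.concatenate(train_idx))
    te = np.sort(np.concatenate(test_idx))
    return ds.subset(tr), ds.subset(te)


# ---------------------------------------------------------------------------
# CSV + JSON-sidecar I/O
# ---------------------------------------------------------------------------

_CHANNEL_COLS = [f"channel_{i}" for i in range(1, N_CHANNELS + 1)]


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def write_recording_csv(rec: EmgRecording, path) -> None:
    """Write a recording as CSV (channel_1..channel_6) plus a JSON sidecar.

    Floats are written with 17 significant digits so a write/read round trip
    reproduces the samples bit-exactly.
    """
    path = Path(path)
    df = pd.DataFrame(rec.samples, columns=_CHANNEL_COLS)
    df.to_csv(path, index=False, float_format="%.17g")
    meta = {
        "fs": rec.fs,
        "label": rec.label.name.lower(),
        "force": rec.force.name.lower() if rec.force is not None else None,
        "repetition": rec.repetition,
        "subject_id": rec.subject_id,
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=2))


def read_recording_csv(path) -> EmgRecording:
    """Read a recording written by :func:`write_recording_csv`."""
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    if list(df.columns) != _CHANNEL_COLS:
        raise ValueError(
            f"{path}: expected {N_CHANNELS} channels "
            f"({', '.join(_CHANNEL_COLS)}), got columns {list(df.columns)}"
        )
    samples = df.to_numpy(dtype=float)
    neg = np.argwhere(samples < 0)
    if neg.size:
        r, c = neg[0]
        raise ValueError(
            f"{path}: negative amplitude at row {int(r) + 2} "
            f"(column {_CHANNEL_COLS[int(c)]})"
        )
    side = _sidecar_path(path)
    if not side.exists():
        raise FileNotFoundError(f"metadata sidecar not found: {side}")
    meta = json.loads(side.read_text())
    label = MotionClass.from_name(meta["label"])
    force = (
        ForceLevel.from_name(meta["force"]) if meta.get("force") is not None else None
    )
    return EmgRecording(
        samples=samples,
        fs=float(meta["fs"]),
        label=label,
        force=force,
        repetition=int(meta["repetition"]),
        subject_id=str(meta["subject_id"]),
    )
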