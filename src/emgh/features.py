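"""Sliding-window segmentation and the five time-domain EMG features.

Windows are 150 ms with 50 ms overlap by default (step 100 ms).  Per window
and channel, five time-domain descriptors are computed: enhanced mean
absolute value (EMAV), enhanced wavelength (EWL), slope sign change count
(SSC), root mean square (RMS) and sample variance (VAR), giving a 30-column
feature vector over the six channels.

EMAV and EWL weight samples by a position-dependent exponent p(i): with
1-based index i in a window of length N, p(i) = 0.75 for 0.2N < i < 0.8N
and 0.5 otherwise, emphasising the central portion of the window.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .signal_model import DEFAULT_FS, EmgRecording, LabeledDataset, N_CHANNELS

FEATURE_NAMES = ("emav", "ewl", "ssc", "rms", "var")
N_FEATURES = len(FEATURE_NAMES) * N_CHANNELS  # 30


@dataclass(frozen=True)
class WindowConfig:
    """Analysis-window geometry.

    ``overlap_ms`` is the span shared by consecutive windows, so the hop is
    ``win_ms - overlap_ms`` (100 ms at the defaults).
    """

    win_ms: float = 150.0
    overlap_ms: float = 50.0
    fs: float = DEFAULT_FS

    def __post_init__(self) -> None:
        if not (0 <= self.overlap_ms < self.win_ms):
            raise ValueError("require 0 <= overlap_ms < win_ms")
        if self.fs <= 0:
            raise ValueError("fs must be positive")

    @property
    def step_ms(self) -> float:
        return self.win_ms - self.overlap_ms

    @property
    def win_samples(self) -> int:
        return int(round(self.win_ms * self.fs / 1000.0))

    @property
    def step_samples(self) -> int:
        return int(round(self.step_ms * self.fs / 1000.0))


def segment_windows(
    rec: Union[EmgRecording, np.ndarray], cfg: WindowConfig
) -> np.ndarray:
    """Cut a recording into overlapping windows.

    Returns an ``(n_windows, win_samples, n_channels)`` array; windows start
    at multiples of the hop and a trailing partial window is discarded:
    ``n_windows = floor((n - win) / step) + 1``.
    """
    x = rec.samples if isinstance(rec, EmgRecording) else np.asarray(rec, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    n = x.shape[0]
    win, step = cfg.win_samples, cfg.step_samples
    if n < win:
        raise ValueError(
            f"recording of {n} samples is shorter than one window ({win} samples)"
        )
    n_windows = (n - win) // step + 1
    idx = np.arange(win)[None, :] + step * np.arange(n_windows)[:, None]
    return x[idx]


def _p_exponents(n: int) -> np.ndarray:
    """Positional exponent p(i) for 1-based i: 0.75 strictly inside
    (0.2N, 0.8N), 0.5 at and outside the boundaries."""
    i = np.arange(1, n + 1, dtype=float)
    return np.where((i > 0.2 * n) & (i < 0.8 * n), 0.75, 0.5)


def feat_emav(x: np.ndarray) -> float:
    """Enhanced mean absolute value: mean of |x_i|^p(i)."""
    x = np.asarray(x, dtype=float).ravel()
    if x.size < 1:
        raise ValueError("empty window")
    return float(np.mean(np.abs(x) ** _p_exponents(x.size)))


def feat_ewl(x: np.ndarray) -> float:
    """Enhanced wavelength: sum over i=2..N of |x_i - x_{i-1}|^p(i)."""
    x = np.asarray(x, dtype=float).ravel()
    if x.size < 2:
        raise ValueError("EWL needs at least 2 samples")
    p = _p_exponents(x.size)[1:]
    return float(np.sum(np.abs(np.diff(x)) ** p))


def feat_ssc(x: np.ndarray, dead_zone: float = 0.0) -> int:
    """Slope-sign-change count with a dead-zone threshold.

    Counts interior samples where (x_i - x_{i-1})(x_i - x_{i+1}) exceeds
    ``dead_zone``; with dead_zone = 0 a strict sign change is required
    (the product must be > 0), so constant segments never count.
    """
    x = np.asarray(x, dtype=float).ravel()
    if x.size < 3:
        raise ValueError("SSC needs at least 3 samples")
    if dead_zone < 0:
        raise ValueError("dead_zone must be >= 0")
    prod = (x[1:-1] - x[:-2]) * (x[1:-1] - x[2:])
    if dead_zone == 0:
        return int(np.count_nonzero(prod > 0))
    return int(np.count_nonzero(prod >= dead_zone))


def feat_rms(x: np.ndarray) -> float:
    """Root mean square amplitude."""
    x = np.asarray(x, dtype=float).ravel()
    if x.size < 1:
        raise ValueError("empty window")
    return float(np.sqrt(np.mean(x * x)))


def feat_var(x: np.ndarray) -> float:
    """Sample variance (mean-subtracted, N-1 denominator)."""
    x = np.asarray(x, dtype=float).ravel()
    if x.size < 2:
        raise ValueError("variance needs at least 2 samples")
    return float(np.var(x, ddof=1))


def window_features(win: np.ndarray, dead_zone: float = 0.0) -> np.ndarray:
    """Five features per channel for one ``(win_len, n_ch)`` window,
    flattened feature-major: emav ch1..6, ewl ch1..6, ssc, rms, var."""
    win = np.asarray(win, dtype=float)
    out = np.empty(len(FEATURE_NAMES) * win.shape[1])
    n_ch = win.shape[1]
    for c in range(n_ch):
        x = win[:, c]
        out[0 * n_ch + c] = feat_emav(x)
        out[1 * n_ch + c] = feat_ewl(x)
        out[2 * n_ch + c] = feat_ssc(x, dead_zone)
        out[3 * n_ch + c] = feat_rms(x)
        out[4 * n_ch + c] = feat_var(x)
    return out


def _features_vectorized(wins: np.ndarray, dead_zone: float) -> np.ndarray:
    """All five features for a stack of windows ``(n_win, win_len, n_ch)``."""
    n_win, n, n_ch = wins.shape
    p = _p_exponents(n)[None, :, None]
    emav = np.mean(np.abs(wins) ** p, axis=1)
    d = np.abs(np.diff(wins, axis=1))
    ewl = np.sum(d ** p[:, 1:, :], axis=1)
    prod = (wins[:, 1:-1, :] - wins[:, :-2, :]) * (wins[:, 1:-1, :] - wins[:, 2:, :])
    if dead_zone == 0:
        ssc = np.count_nonzero(prod > 0, axis=1).astype(float)
    else:
        ssc = np.count_nonzero(prod >= dead_zone, axis=1).astype(float)
    rms = np.sqrt(np.mean(wins * wins, axis=1))
    var = np.var(wins, axis=1, ddof=1)
    return np.concatenate([emav, ewl, ssc, rms, var], axis=1)


def feature_columns(n_ch: int = N_CHANNELS) -> list[str]:
    return [f"{f}_ch{c}" for f in FEATURE_NAMES for c in range(1, n_ch + 1)]


@dataclass
class FeatureTable:
    """Window-level feature matrix with labels and optional normalization.

    Columns are ordered feature-major: emav_ch1..emav_ch6, ewl_ch1.., ssc..,
    rms.., var_ch6.  ``norm`` holds per-column (mean, sd) fitted on training
    windows; constant columns keep sd = 1 so normalization leaves them
    centred but unscaled.
    """

    X: np.ndarray
    y: np.ndarray
    meta: Optional[pd.DataFrame] = None
    norm: Optional[tuple[np.ndarray, np.ndarray]] = None
    class_set: tuple = ()

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=int)
        if len(self.y) != self.X.shape[0]:
            raise ValueError("y length must equal number of windows")
        if not self.class_set:
            self.class_set = tuple(sorted(np.unique(self.y)))

    @property
    def columns(self) -> list[str]:
        return feature_columns(self.X.shape[1] // len(FEATURE_NAMES))

    def subset(self, idx: np.ndarray) -> "FeatureTable":
        meta = self.meta.iloc[idx].reset_index(drop=True) if self.meta is not None else None
        return FeatureTable(self.X[idx], self.y[idx], meta, self.norm, self.class_set)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.X, columns=self.columns)
        df["label"] = self.y
        return df


def fit_norm(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-column z-score parameters; zero-variance columns get sd = 1."""
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    sd = np.where(sd > 0, sd, 1.0)
    return mean, sd


def apply_norm(X: np.ndarray, norm: tuple[np.ndarray, np.ndarray]) -> np.ndarray:
    mean, sd = norm
    return (X - mean) / sd


def featurize(
    source: Union[Sequence[EmgRecording], LabeledDataset],
    cfg: WindowConfig | None = None,
    dead_zone: float = 0.0,
) -> FeatureTable:
    """Build the window-feature table from recordings or a raw dataset.

    For a raw :class:`LabeledDataset`, windows are cut within each contiguous
    same-label block (a 4,800-sample class block yields 47 windows at the
    defaults).  For a sequence of recordings, windows are cut per recording.
    Window labels are inherited from the source block/recording.
    """
    cfg = cfg or WindowConfig()
    blocks: list[tuple[np.ndarray, int, dict]] = []
    if isinstance(source, LabeledDataset):
        if source.feature_mode != "raw":
            raise ValueError("featurize expects a raw dataset")
        y = source.y
        # contiguous same-label runs
        bounds = np.flatnonzero(np.diff(y)) + 1
        for start, stop in zip(
            np.concatenate([[0], bounds]), np.concatenate([bounds, [len(y)]])
        ):
            blocks.append((source.X[start:stop], int(y[start]), {}))
    else:
        for rec in source:
            lab = int(rec.label)
            info = {
                "gesture": int(rec.label),
                "force": int(rec.force) if rec.force is not None else 0,
                "repetition": rec.repetition,
            }
            blocks.append((rec.samples, lab, info))

    feats, labels, meta_rows = [], [], []
    for x, lab, info in blocks:
        wins = segment_windows(x, cfg)
        feats.append(_features_vectorized(wins, dead_zone))
        labels.append(np.full(wins.shape[0], lab, dtype=int))
        for _ in range(wins.shape[0]):
            meta_rows.append(info)
    X = np.vstack(feats)
    y = np.concatenate(labels)
    meta = pd.DataFrame(meta_rows) if meta_rows and meta_rows[0] else None
    return FeatureTable(X, y, meta)
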