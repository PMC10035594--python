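"""One-vs-all logistic regression (linear and polynomial) and LDA.

The probability a window belongs to class c is P(c|x) = 1 / (1 + e^{-(th^T
x~ + th0)}) where x~ is the (optionally degree-2 polynomial expanded)
z-scored feature vector.  One binary model is trained per class by
full-batch gradient descent on L2-regularised cross-entropy; a per-class
decision threshold is then chosen on a held-out validation carve-out as the
grid value maximising that class's one-vs-rest F1.  LDA uses the
closed-form pooled-covariance discriminants and predicts by the argmax of
the affine class scores.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from scipy.special import expit

from .features import apply_norm, fit_norm

MODEL_FORMAT_VERSION = 1
DEFAULT_THRESHOLD_GRID = tuple(np.round(np.arange(0.05, 0.951, 0.05), 2))


@dataclass
class TrainConfig:
    """Gradient-descent and threshold-selection hyperparameters.

    ``learning_rate`` assumes z-scored inputs (the trainer normalizes
    internally); ``tol`` is the relative loss-change stopping tolerance;
    ``val_frac`` is the stratified carve-out of the training part used for
    threshold selection.
    """

    learning_rate: float = 0.1
    max_iter: int = 5000
    tol: float = 1e-7
    l2: float = 1e-4
    seed: int = 0
    threshold_grid: tuple = DEFAULT_THRESHOLD_GRID
    val_frac: float = 0.2

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if not all(0.0 < t < 1.0 for t in self.threshold_grid):
            raise ValueError("threshold_grid values must lie in (0, 1)")
        if not (0.0 < self.val_frac < 1.0):
            raise ValueError("val_frac must be in (0, 1)")


def logistic(z):
    """The logistic function 1 / (1 + e^{-z})."""
    return expit(np.asarray(z, dtype=float))


def poly_expand(X: np.ndarray, degree: int) -> np.ndarray:
    """Polynomial feature expansion without the constant term.

    Degree 1 returns the input unchanged; degree 2 appends all pairwise
    products and squares in the fixed order [x_1..x_d, x_i*x_j (i<j,
    lexicographic), x_1^2..x_d^2], giving d + d(d+1)/2 columns.
    """
    if degree < 1:
        raise ValueError("degree must be >= 1")
    X = np.asarray(X, dtype=float)
    one_dim = X.ndim == 1
    if one_dim:
        X = X[None, :]
    if degree == 1:
        out = X
    elif degree == 2:
        d = X.shape[1]
        iu, ju = np.triu_indices(d, k=1)
        out = np.concatenate([X, X[:, iu] * X[:, ju], X * X], axis=1)
    else:
        raise NotImplementedError("only degrees 1 and 2 are supported")
    return out[0] if one_dim else out


def expanded_dim(d: int, degree: int) -> int:
    return d if degree == 1 else d + d * (d + 1) // 2


def _xent_loss(theta, theta0, X, y, l2):
    z = X @ theta + theta0
    # numerically stable log(1 + e^z) - y z
    loss = np.mean(np.logaddexp(0.0, z) - y * z)
    return loss + 0.5 * l2 * float(theta @ theta)


def gd_train_binary(
    X: np.ndarray, y01: np.ndarray, cfg: TrainConfig
) -> tuple[np.ndarray, float]:
    """Full-batch gradient descent on L2-regularised logistic cross-entropy.

    Returns ``(theta, theta0)``.  The bias is not penalised.  Each step is
    accepted only if the loss does not increase; otherwise the step size is
    halved (up to 40 times) before giving up, so the loss trajectory is
    non-increasing.  Deterministic (zero initialisation).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y01, dtype=float).ravel()
    if X.ndim != 2 or X.shape[0] != y.size:
        raise ValueError("X must be 2-D with one row per label")
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("both classes must be present in y01")
    if not set(classes) <= {0.0, 1.0}:
        raise ValueError("y01 must contain only 0/1 labels")

    n, d = X.shape
    theta = np.zeros(d)
    theta0 = 0.0
    lr = cfg.learning_rate
    loss = _xent_loss(theta, theta0, X, y, cfg.l2)
    for _ in range(cfg.max_iter):
        p = expit(X @ theta + theta0)
        resid = p - y
        g_theta = X.T @ resid / n + cfg.l2 * theta
        g_theta0 = float(np.mean(resid))
        step = lr
        for _halve in range(40):
            cand_t = theta - step * g_theta
            cand_t0 = theta0 - step * g_theta0
            cand_loss = _xent_loss(cand_t, cand_t0, X, y, cfg.l2)
            if not np.isfinite(cand_loss):
                raise FloatingPointError(
                    "loss diverged during gradient descent; try a smaller "
                    "learning_rate"
                )
            if cand_loss <= loss:
                break
            step *= 0.5
        else:
            break  # no descent direction at machine precision: converged
        theta, theta0 = cand_t, cand_t0
        if loss - cand_loss < cfg.tol * max(abs(loss), 1e-12):
            loss = cand_loss
            break
        loss = cand_loss
    return theta, theta0


def _f1_binary(y_true01: np.ndarray, y_pred01: np.ndarray) -> float:
    tp = int(np.sum((y_true01 == 1) & (y_pred01 == 1)))
    fp = int(np.sum((y_true01 == 0) & (y_pred01 == 1)))
    fn = int(np.sum((y_true01 == 1) & (y_pred01 == 0)))
    denom = 2 * tp + fp + fn
    return 2 * tp / denom if denom else 0.0


@dataclass
class LogisticModel:
    """One-vs-all logistic classifier (LR at degree 1, NLR at degree 2)."""

    thetas: np.ndarray  # (n_classes, expanded_dim)
    theta0s: np.ndarray  # (n_classes,)
    degree: int
    thresholds: np.ndarray  # (n_classes,)
    class_set: tuple
    norm: Optional[tuple[np.ndarray, np.ndarray]] = None

    def __post_init__(self) -> None:
        self.thetas = np.asarray(self.thetas, dtype=float)
        self.theta0s = np.asarray(self.theta0s, dtype=float)
        self.thresholds = np.asarray(self.thresholds, dtype=float)
        if self.degree < 1:
            raise ValueError("degree must be >= 1")
        if np.any((self.thresholds <= 0) | (self.thresholds >= 1)):
            raise ValueError("thresholds must lie in (0, 1)")

    def _expand(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if self.norm is not None:
            X = apply_norm(X, self.norm)
        Xe = poly_expand(X, self.degree)
        if Xe.shape[1] != self.thetas.shape[1]:
            raise ValueError(
                f"expected {self.thetas.shape[1]} expanded features, got {Xe.shape[1]}"
            )
        return Xe

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Per-class one-vs-rest probabilities (rows need not sum to 1)."""
        Xe = self._expand(X)
        return expit(Xe @ self.thetas.T + self.theta0s)

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Thresholded one-vs-all decision.

        Among classes whose probability reaches their threshold, the most
        probable wins; if none does, fall back to the globally most probable
        class.  Ties break toward the lowest class code.
        """
        P = self.predict_proba(X)
        above = P >= self.thresholds[None, :]
        masked = np.where(above, P, -np.inf)
        best_masked = np.argmax(masked, axis=1)
        best_global = np.argmax(P, axis=1)
        idx = np.where(above.any(axis=1), best_masked, best_global)
        classes = np.asarray(self.class_set)
        return classes[idx]

    def predict_one(self, x: np.ndarray):
        return self.predict(np.atleast_2d(x))[0]


def select_thresholds(
    model: LogisticModel,
    X_val: np.ndarray,
    y_val: np.ndarray,
    grid: Sequence[float] | None = None,
) -> np.ndarray:
    """Per-class decision threshold maximising one-vs-rest F1 on validation.

    Ties break toward 0.5, then toward the lower threshold.  A class absent
    from the validation labels keeps the default 0.5 (with a warning).
    """
    grid = sorted(grid if grid is not None else DEFAULT_THRESHOLD_GRID)
    if not grid:
        raise ValueError("threshold grid must be non-empty")
    P = model.predict_proba(X_val)
    y_val = np.asarray(y_val)
    out = np.empty(len(model.class_set))
    for k, c in enumerate(model.class_set):
        y01 = (y_val == c).astype(int)
        if y01.sum() == 0:
            warnings.warn(
                f"class {c} absent from validation data; threshold defaults to 0.5"
            )
            out[k] = 0.5
            continue
        f1s = np.array([_f1_binary(y01, (P[:, k] >= t).astype(int)) for t in grid])
        best = np.flatnonzero(f1s == f1s.max())
        # tie-break toward 0.5, then toward the lower threshold
        cands = [grid[i] for i in best]
        dmin = min(abs(t - 0.5) for t in cands)
        out[k] = min(t for t in cands if abs(t - 0.5) == dmin)
    return out


def _stratified_carve(y: np.ndarray, frac: float, seed: int):
    rng = np.random.default_rng(seed)
    fit_idx, val_idx = [], []
    for c in np.unique(y):
        idx = rng.permutation(np.flatnonzero(y == c))
        n_val = max(int(round(frac * idx.size)), 1)
        n_val = min(n_val, idx.size - 1) if idx.size > 1 else 0
        val_idx.append(idx[:n_val])
        fit_idx.append(idx[n_val:])
    return np.concatenate(fit_idx), np.concatenate(val_idx)


def train_ova(
    X: np.ndarray,
    y: np.ndarray,
    cfg: TrainConfig | None = None,
    degree: int = 1,
    class_set: Sequence | None = None,
) -> LogisticModel:
    """Train a one-vs-all logistic model (LR if degree 1, NLR if 2).

    A stratified ``cfg.val_frac`` share of the rows is held out; the binary
    models are fitted on the remainder (z-scored, then expanded) and the
    per-class thresholds are selected on the held-out part.
    """
    cfg = cfg or TrainConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).ravel()
    classes = tuple(class_set) if class_set is not None else tuple(sorted(np.unique(y)))
    if len(classes) < 2:
        raise ValueError("need at least two classes")

    fit_idx, val_idx = _stratified_carve(y, cfg.val_frac, cfg.seed)
    norm = fit_norm(X[fit_idx])
    Xe_fit = poly_expand(apply_norm(X[fit_idx], norm), degree)
    thetas, theta0s = [], []
    for c in classes:
        y01 = (y[fit_idx] == c).astype(float)
        th, th0 = gd_train_binary(Xe_fit, y01, cfg)
        thetas.append(th)
        theta0s.append(th0)
    model = LogisticModel(
        thetas=np.vstack(thetas),
        theta0s=np.array(theta0s),
        degree=degree,
        thresholds=np.full(len(classes), 0.5),
        class_set=classes,
        norm=norm,
    )
    if val_idx.size:
        model.thresholds = select_thresholds(
            model, X[val_idx], y[val_idx], cfg.threshold_grid
        )
    return model


# ---------------------------------------------------------------------------
# LDA
# ---------------------------------------------------------------------------


@dataclass
class LdaModel:
    """Linear discriminant classifier: label = argmax_c (beta_c^T x + b0_c)."""

    betas: np.ndarray  # (n_classes, d)
    beta0s: np.ndarray  # (n_classes,)
    class_set: tuple

    def __post_init__(self) -> None:
        self.betas = np.asarray(self.betas, dtype=float)
        self.beta0s = np.asarray(self.beta0s, dtype=float)

    def scores(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.betas.shape[1]:
            raise ValueError(
                f"expected {self.betas.shape[1]} features, got {X.shape[1]}"
            )
        return X @ self.betas.T + self.beta0s

    def predict(self, X: np.ndarray) -> np.ndarray:
        # np.argmax takes the first maximum, i.e. the lowest class code
        idx = np.argmax(self.scores(X), axis=1)
        return np.asarray(self.class_set)[idx]

    def predict_one(self, x: np.ndarray):
        return self.predict(np.atleast_2d(x))[0]


def lda_fit(
    X: np.ndarray,
    y: np.ndarray,
    class_set: Sequence | None = None,
    ridge_rel: float = 1e-6,
) -> LdaModel:
    """Closed-form LDA from class means, pooled covariance and priors.

    beta_c = Sigma^{-1} mu_c and b0_c = -mu_c^T Sigma^{-1} mu_c / 2 +
    log pi_c, with the pooled within-class covariance regularised by
    ``ridge_rel * trace(Sigma)/d`` on the diagonal.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).ravel()
    classes = tuple(class_set) if class_set is not None else tuple(sorted(np.unique(y)))
    if len(classes) < 2:
        raise ValueError("need at least two classes")
    n, d = X.shape
    means, priors, scatter = [], [], np.zeros((d, d))
    for c in classes:
        Xc = X[y == c]
        if Xc.shape[0] == 0:
            raise ValueError(f"class {c} has no rows")
        mu = Xc.mean(axis=0)
        means.append(mu)
        priors.append(Xc.shape[0] / n)
        dev = Xc - mu
        scatter += dev.T @ dev
    pooled = scatter / max(n - len(classes), 1)
    # absolute floor keeps the zero-covariance (noise-free) case solvable,
    # where LDA degenerates to the nearest-class-mean rule
    ridge = max(ridge_rel * np.trace(pooled) / d, 1e-12)
    pooled_r = pooled + ridge * np.eye(d)
    try:
        pinv = np.linalg.inv(pooled_r)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "pooled within-class covariance is singular even after ridge "
            "regularisation"
        ) from exc
    betas = np.vstack([pinv @ mu for mu in means])
    beta0s = np.array(
        [
            -0.5 * float(mu @ pinv @ mu) + np.log(pi)
            for mu, pi in zip(means, priors)
        ]
    )
    return LdaModel(betas=betas, beta0s=beta0s, class_set=classes)


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------


def save_model(model, path) -> None:
    """Serialize a LogisticModel or LdaModel to JSON (full precision)."""
    path = Path(path)
    if isinstance(model, LogisticModel):
        payload = {
            "format_version": MODEL_FORMAT_VERSION,
            "family": "logistic",
            "class_set": [int(c) for c in model.class_set],
            "degree": model.degree,
            "thetas": model.thetas.tolist(),
            "theta0s": model.theta0s.tolist(),
            "thresholds": model.thresholds.tolist(),
            "norm": None
            if model.norm is None
            else {"mean": model.norm[0].tolist(), "sd": model.norm[1].tolist()},
        }
    elif isinstance(model, LdaModel):
        payload = {
            "format_version": MODEL_FORMAT_VERSION,
            "family": "lda",
            "class_set": [int(c) for c in model.class_set],
            "betas": model.betas.tolist(),
            "beta0s": model.beta0s.tolist(),
        }
    else:
        raise TypeError(f"cannot serialize model of type {type(model).__name__}")
    path.write_text(json.dumps(payload))


def load_model(path):
    """Load a model saved by :func:`save_model`."""
    path = Path(path)
    try:
        payload = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise ValueError(f"{path}: not a valid model file ({exc})") from exc
    version = payload.get("format_version")
    if version != MODEL_FORMAT_VERSION:
        raise ValueError(
            f"{path}: unsupported model format version {version!r} "
            f"(expected {MODEL_FORMAT_VERSION})"
        )
    family = payload.get("family")
    if family == "logistic":
        norm = payload.get("norm")
        return LogisticModel(
            thetas=np.array(payload["thetas"]),
            theta0s=np.array(payload["theta0s"]),
            degree=int(payload["degree"]),
            thresholds=np.array(payload["thresholds"]),
            class_set=tuple(payload["class_set"]),
            norm=None
            if norm is None
            else (np.array(norm["mean"]), np.array(norm["sd"])),
        )
    if family == "lda":
        return LdaModel(
            betas=np.array(payload["betas"]),
            beta0s=np.array(payload["beta0s"]),
            class_set=tuple(payload["class_set"]),
        )
    raise ValueError(f"{path}: unknown model family {family!r}")
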