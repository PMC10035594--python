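"""Model/Results front end for the hierarchical sEMG classifier.

:class:`HierarchicalEmgModel` is built from a session of labeled
recordings (or generated synthetically via :meth:`from_synthetic_session`);
``fit`` trains the gesture classifier and the two grasp-force classifiers
and returns a :class:`HierarchicalEmgResults` carrying the fitted cascade,
the test-split reports and a ``summary()`` table.  Real-time simulation
hangs off the results object.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import pandas as pd

from .classifiers import TrainConfig
from .evaluation import (
    OfflineExperiment,
    RealtimeReport,
    run_offline_experiment,
    run_realtime_experiment,
)
from .features import WindowConfig
from .hierarchy import HierarchicalClassifier
from .signal_model import DEFAULT_PER_REP_KEEP, EmgRecording
from .synthgen import SessionSpec, SubjectProfile, generate_session


class HierarchicalEmgModel:
    """Hierarchical gesture + grasp-force classification model.

    Parameters
    ----------
    recordings
        One acquisition session: labeled gesture holds, with the grasp
        gestures (spherical, tip) recorded at all three force levels.
    algorithm
        ``"lr"`` (logistic regression), ``"nlr"`` (degree-2 polynomial
        logistic regression) or ``"lda"``.
    feature_extraction
        When true (default), classify 30 time-domain window features;
        otherwise feed raw envelope samples.
    """

    def __init__(
        self,
        recordings: Sequence[EmgRecording],
        algorithm: str = "lr",
        feature_extraction: bool = True,
        window: Optional[WindowConfig] = None,
        train_config: Optional[TrainConfig] = None,
        per_rep_keep: int = DEFAULT_PER_REP_KEEP,
    ) -> None:
        if algorithm not in ("lr", "nlr", "lda"):
            raise ValueError("algorithm must be 'lr', 'nlr' or 'lda'")
        self.recordings = list(recordings)
        self.algorithm = algorithm
        self.feature_extraction = feature_extraction
        self.window = window or WindowConfig()
        self.train_config = train_config or TrainConfig()
        self.per_rep_keep = per_rep_keep

    @classmethod
    def from_synthetic_session(
        cls,
        profile: Optional[SubjectProfile] = None,
        session: Optional[SessionSpec] = None,
        **kwargs,
    ) -> "HierarchicalEmgModel":
        """Build the model on a generated synthetic acquisition session."""
        profile = profile or SubjectProfile()
        recs = generate_session(profile, session)
        model = cls(recs, **kwargs)
        model.profile = profile
        return model

    def fit(self, seed: int = 0) -> "HierarchicalEmgResults":
        """Train all three classifiers and evaluate on the 30% test split."""
        exp = run_offline_experiment(
            self.recordings,
            algorithm=self.algorithm,
            fe=self.feature_extraction,
            window=self.window,
            train_cfg=self.train_config,
            seed=seed,
            per_rep_keep=self.per_rep_keep,
        )
        return HierarchicalEmgResults(model=self, experiment=exp, seed=seed)


@dataclass
class HierarchicalEmgResults:
    """Fitted cascade plus offline test-split diagnostics."""

    model: HierarchicalEmgModel
    experiment: OfflineExperiment
    seed: int

    @property
    def reports(self) -> dict:
        return self.experiment.reports

    @property
    def hierarchy(self) -> HierarchicalClassifier:
        return self.experiment.hierarchy()

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame([r.summary_row() for r in self.reports.values()])

    def summary(self) -> str:
        """Plain-text summary of the three classifiers' test performance."""
        lines = [
            "Hierarchical sEMG classifier"
            f" | algorithm={self.model.algorithm}"
            f" | features={'on' if self.model.feature_extraction else 'off'}"
            f" | seed={self.seed}",
            "-" * 72,
            f"{'classifier':<18}{'accuracy':>10}{'macro F1':>10}   per-class F1",
        ]
        for rep in self.reports.values():
            per_class = " ".join(f"{c}:{v:.3f}" for c, v in rep.f1.items())
            lines.append(
                f"{rep.classifier:<18}{rep.accuracy:>10.4f}{rep.macro_f1:>10.4f}   {per_class}"
            )
        return "\n".join(lines)

    def simulate_realtime(
        self,
        profile: Optional[SubjectProfile] = None,
        n_trials: int = 3,
        duration_s: float = 5.0,
        stride_ms: float = 90.0,
    ) -> RealtimeReport:
        """Run the simulated online protocol against the fitted cascade."""
        profile = profile or getattr(self.model, "profile", None) or SubjectProfile()
        return run_realtime_experiment(
            self.hierarchy, profile, n_trials=n_trials,
            duration_s=duration_s, stride_ms=stride_ms,
        )
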