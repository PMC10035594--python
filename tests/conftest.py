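import numpy as np
import pytest

from emgh.classifiers import TrainConfig
from emgh.model import HierarchicalEmgModel
from emgh.synthgen import SessionSpec, SubjectProfile, generate_session


@pytest.fixture(scope="session")
def default_profile():
    """The shipped generator defaults (seed 7)."""
    return SubjectProfile(seed=7)


@pytest.fixture(scope="session")
def default_session(default_profile):
    """Full protocol session: 7 gestures x 6 reps x 3 s, grasps at 3 levels."""
    return generate_session(default_profile, SessionSpec())


@pytest.fixture(scope="session")
def noise_free_profile():
    return SubjectProfile(seed=7, noise_cv=0.0, rep_jitter=0.0)


@pytest.fixture(scope="session")
def small_session_spec():
    """Reduced session for fast training tests."""
    return SessionSpec(n_reps=3, hold_s=1.2)


@pytest.fixture(scope="session")
def small_session(default_profile, small_session_spec):
    return generate_session(default_profile, small_session_spec)


@pytest.fixture(scope="session")
def fitted_lr_fe(default_session):
    """LR + feature extraction fitted on the full default session (seed 7)."""
    model = HierarchicalEmgModel(default_session, algorithm="lr", feature_extraction=True)
    return model.fit(seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
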