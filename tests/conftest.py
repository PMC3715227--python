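import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from calibmc.glucose_model import RegressionModel, fit_model
from calibmc.session_io import DatasetManifest, ManifestEntry, Session, split_dataset
from calibmc.simulator import SimulationConfig, simulate_sessions

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

#: compact study used across the suite: 6 subjects × 2 sessions, 16 channels
SMALL_STUDY = dict(
    n_subjects=6,
    n_sessions=12,
    n_channels=16,
    n_glucose_channels=6,
    sweat_channel=3,
    seed=11,
)


def split_by_subject(sessions, seed):
    """Identification/test partition of in-memory sessions."""
    manifest = DatasetManifest(
        [ManifestEntry(s.session_id, s.subject_id, "", "") for s in sessions]
    )
    split_dataset(manifest, seed)
    part1 = {e.session_id for e in manifest.entries if e.split == "part1"}
    ident = [s for s in sessions if s.session_id in part1]
    test = [s for s in sessions if s.session_id not in part1]
    return ident, test


def toy_session(
    rbg_times,
    rbg_values,
    n_channels=1,
    duration_s=8 * 3600.0,
    dt_s=20.0,
    fill=0.0,
    session_id="toy",
):
    """Minimal valid session with constant channels."""
    n = int(round(duration_s / dt_s))
    t = np.arange(n) * dt_s
    X = np.full((n_channels, n), fill, dtype=float)
    return Session(session_id, "subj", t, X, np.asarray(rbg_times, float),
                   np.asarray(rbg_values, float))


def constant_model(n_channels=1, intercept=0.0):
    return RegressionModel(
        beta=np.zeros(n_channels), intercept=intercept, lam=0.0,
        channel_count=n_channels,
    )


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(**SMALL_STUDY)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    sessions, truths, profiles = simulate_sessions(small_config)
    return sessions, truths, profiles


@pytest.fixture(scope="session")
def small_split(small_dataset):
    sessions, _, _ = small_dataset
    return split_by_subject(sessions, seed=3)


@pytest.fixture(scope="session")
def small_model(small_split):
    ident, _ = small_split
    return fit_model(ident, seed=0)
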