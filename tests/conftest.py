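import numpy as np
import pytest

from sedmet.io import LabeledMinute
from sedmet.synth import GeneratorConfig, generate_study

RATE = 30.0
N = int(60 * RATE)


def make_minute(emg=None, accel=None, cal=None, posture="sitting", task="typing",
                participant="P01", met=None, met_category=None) -> LabeledMinute:
    """Build a LabeledMinute from raw arrays, filling defaults."""
    if emg is None:
        emg = np.zeros((8, N))
    if accel is None:
        accel = np.zeros((3, N))
    if cal is None:
        cal = np.full(6, 1.4)
    return LabeledMinute(
        minute_index=0,
        participant_id=participant,
        task=task,
        posture=posture,
        emg=np.asarray(emg, dtype=float),
        accel=np.asarray(accel, dtype=float),
        calorimeter=np.asarray(cal, dtype=float),
        met=met,
        met_category=met_category,
    )


@pytest.fixture(scope="session")
def small_study():
    """A 4-participant synthetic study shared across tests (seeded)."""
    return generate_study(GeneratorConfig(seed=7, n_participants=4))


@pytest.fixture(scope="session")
def small_minutes(small_study):
    return small_study.labeled_minutes()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
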