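import datetime as dt

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from stageflow.ingest import PatientHistory, RawEvent
from stageflow.simulate import make_fixture_model


@pytest.fixture(scope="session")
def fixture_model():
    """The canonical K=3, W=2, N=6 ground-truth model."""
    return make_fixture_model()


@pytest.fixture(scope="session")
def small_cohort(fixture_model):
    from stageflow.simulate import generate_cohort

    return generate_cohort(fixture_model, 500, seed=20260901)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_events(rows):
    """rows: iterable of (patient_id, iso_date, code)."""
    return [RawEvent(p, dt.date.fromisoformat(d), c) for p, d, c in rows]


def make_history(pid, slices):
    return PatientHistory(pid, tuple((y, frozenset(f)) for y, f in slices))


@pytest.fixture
def two_slice_history():
    return make_history("t0", [(0, {0}), (1, {0, 2})])
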