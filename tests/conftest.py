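import numpy as np
import pytest
from hypothesis import settings

from solestress import (
    StressProfile,
    default_layout,
    extract_features,
    generate_session,
)

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def layout():
    return default_layout()


@pytest.fixture(scope="session")
def session_default(layout):
    """One default-profile synthetic session plus its feature table."""
    insole, ankle, meta, truth = generate_session(101)
    table = extract_features(insole, ankle, meta, layout, mode="training")
    return {
        "insole": insole,
        "ankle": ankle,
        "meta": meta,
        "truth": truth,
        "table": table,
    }


@pytest.fixture(scope="session")
def short_plan():
    """A small two-task plan for cheap stream-level tests."""
    return [(130.0, "stress"), (130.0, "relax")]


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def pressure_window(rng):
    """A random non-negative 500-sample pressure window."""
    return rng.uniform(0.0, 10.0, size=(500, 16))
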