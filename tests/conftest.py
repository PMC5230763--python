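import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

sys.path.insert(0, str(Path(__file__).parent))

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=40,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def utc_minutes(start: str, values) -> pd.Series:
    """Minute-grid UTC series starting at ``start``."""
    idx = pd.date_range(pd.Timestamp(start, tz="UTC"), periods=len(values), freq="min")
    return pd.Series(np.asarray(values, dtype=float), index=idx)


@pytest.fixture
def minute_series():
    return utc_minutes


@pytest.fixture
def small_participant():
    """A 20-day synthetic participant, shared across tests (session-scoped
    would hide accidental mutation, so keep it per-test but cheap)."""
    import cohwear as cw

    return cw.simulate_participant(cw.SimParams(n_days=20, seed=42, missingness=0.0))
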