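import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_log(rows):
    """Raw sensor-log DataFrame from (timestamp, channel, value) tuples."""
    df = pd.DataFrame(rows, columns=["timestamp", "channel", "value"])
    return df.sort_values("timestamp", kind="stable", ignore_index=True)


@pytest.fixture(scope="session")
def simulated_subject():
    """One subject's (normal, anomalous) feature tables at desk scale."""
    from ockra import synthetic

    data = synthetic.generate_dataset(
        n_subjects=1, seconds_per_subject=1200, master_seed=3
    )
    return data["S1"]
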