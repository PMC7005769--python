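import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "flexlens",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("flexlens")


def brute_force_runs(series):
    """Independent maximal-run scanner used as the oracle for run encodings."""
    seq = list(series)
    runs = []
    i = 0
    while i < len(seq):
        j = i
        while j < len(seq) and seq[j] == seq[i]:
            j += 1
        runs.append((seq[i], j - i))
        i = j
    return runs


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)
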