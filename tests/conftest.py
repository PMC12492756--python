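import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def brute_force_non_wear(counts, epoch_s, min_duration_min=60):
    """Independent all-runs scanner: walk the series, collect every maximal
    zero-run, keep those lasting at least the threshold."""
    min_len = min_duration_min * 60 // epoch_s
    runs = []
    i, n = 0, len(counts)
    while i < n:
        if counts[i] == 0:
            j = i
            while j < n and counts[j] == 0:
                j += 1
            if j - i >= min_len:
                runs.append((i, j))
            i = j
        else:
            i += 1
    return runs
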