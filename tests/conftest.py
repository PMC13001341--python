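import numpy as np
import pytest

from sleepermeta.behavior import ActivityTrace, call_sleep


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)


def make_trace(counts, fly_id="f1", condition_id="c1", t0=0):
    return ActivityTrace(fly_id=fly_id, condition_id=condition_id,
                         counts=np.asarray(counts, dtype=np.int64), t0=t0)


def make_series(counts, **kw):
    return call_sleep(make_trace(counts, **kw))


@pytest.fixture(scope="session")
def small_sim():
    """A reduced simulated study shared by read-only tests."""
    from sleepermeta.synthetic import simulate_study

    return simulate_study(3, n_genes=300, flies_per_condition=6)


def brute_force_sleep(counts, min_bout=5):
    """Independent maximal-zero-run scan: the sleep-calling oracle."""
    n = len(counts)
    asleep = [False] * n
    i = 0
    while i < n:
        if counts[i] == 0:
            j = i
            while j < n and counts[j] == 0:
                j += 1
            if j - i >= min_bout:
                for m in range(i, j):
                    asleep[m] = True
            i = j
        else:
            i += 1
    return np.array(asleep)
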