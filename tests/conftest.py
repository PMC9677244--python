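import numpy as np
import pytest

from spikewm.core import Session, Trial, Unit


def poisson_session(
    n_units=10,
    n_trials=20,
    rate_hz=5.0,
    seed=0,
    region="hippocampus",
    set_sizes=(4, 6, 8),
    response_time=1.0,
):
    """Homogeneous Poisson session: the universal null fixture."""
    rng = np.random.default_rng(seed)
    units = [Unit(unit_id=f"u{i:03d}", region=region) for i in range(n_units)]
    trials = [
        Trial(
            trial_id=j,
            set_size=set_sizes[j % len(set_sizes)],
            correct=True,
            response_time=response_time,
        )
        for j in range(n_trials)
    ]
    spikes = {}
    for u in units:
        for t in trials:
            n = rng.poisson(rate_hz * 8.0)
            spikes[(u.unit_id, t.trial_id)] = np.sort(rng.uniform(0.0, 8.0, n))
    return Session("s0", "p0", units, trials, spikes)


@pytest.fixture
def small_session():
    return poisson_session(n_units=4, n_trials=10, seed=1)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
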