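import numpy as np
import pytest

from aonpop import simulate as sim


@pytest.fixture(scope="session")
def small_session():
    """Compact synthetic session shared by read-only tests."""
    return sim.generate_session(n_units=10, n_per_condition=6, seed=11,
                                with_snippets=False)


@pytest.fixture(scope="session")
def exe_trials(small_session):
    from aonpop import workflows as wk
    return wk.task_trials(small_session.trials, "EXE")


def poisson_spikes(rng, rate, t_stop):
    """Homogeneous Poisson spike train on [0, t_stop)."""
    n = rng.poisson(rate * t_stop)
    return np.sort(rng.uniform(0.0, t_stop, n))


@pytest.fixture
def null_spike_maker():
    """Factory: (trials, rate, seed) -> unmodulated spike trains per trial."""
    def make(trials, rate, seed):
        rng = np.random.default_rng(seed)
        return {row.trial_id:
                poisson_spikes(rng, rate, row.t_go_signal + 2.0)
                for _, row in trials.iterrows()}
    return make
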