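import numpy as np
import pytest

from pednhl_cea import (
    ModelParams,
    ScheduleVariant,
    TrialConfig,
    build_schedule,
    generate_cost_records,
    generate_trial,
)
from pednhl_cea.survival_transitions import CURE_MONTHS, TransitionSchedule
from pednhl_cea.synthetic_trial import CONTROL, INTERVENTION


@pytest.fixture(scope="session")
def trial_config():
    return TrialConfig(seed=1)


@pytest.fixture(scope="session")
def dataset(trial_config):
    return generate_cost_records(generate_trial(trial_config), trial_config)


@pytest.fixture(scope="session")
def params():
    return ModelParams()


@pytest.fixture(scope="session")
def schedule(dataset, params):
    return build_schedule(dataset, params, ScheduleVariant(horizon_cycles=36))


def make_schedule(p_event_c=0.0, p_death_ef=0.0, p_death_pe=0.0,
                  horizon=36, hr=1.0, rng=None):
    """Hand-built schedule; scalars broadcast over months 1..18, or pass
    an rng for uniformly random monthly probabilities in [0, 0.15]."""
    def arr(value, n=horizon):
        a = np.zeros(n + 1)
        if rng is not None:
            a[1:CURE_MONTHS + 1] = rng.uniform(0, 0.15, CURE_MONTHS)
        else:
            a[1:CURE_MONTHS + 1] = value
        return a

    sched = TransitionSchedule(horizon_cycles=horizon)
    p_c = arr(p_event_c)
    p_i = np.zeros(horizon + 1)
    p_i[1:CURE_MONTHS + 1] = 1 - (1 - p_c[1:CURE_MONTHS + 1]) ** hr
    sched.p_event[CONTROL] = p_c
    sched.p_event[INTERVENTION] = p_i
    for arm in (CONTROL, INTERVENTION):
        sched.p_death_ef[arm] = arr(p_death_ef)
        sched.p_death_pe[arm] = arr(p_death_pe, n=CURE_MONTHS)
    sched.validate()
    return sched
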