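import numpy as np
import pandas as pd
import pytest

from discountfit import (ModelSpec, PopulationConfig, ScheduleConfig,
                         simulate_cohort)


def small_schedules(n_trials=60, session=2):
    """Compact single-session schedules for fast fits."""
    return {t: ScheduleConfig.for_task(t, n_trials=n_trials, sessions=(session,))
            for t in ("NV", "SV", "LV")}


@pytest.fixture(scope="session")
def small_cohort():
    """6 subjects x 3 tasks x 60 trials with known ground truth."""
    pop = PopulationConfig(n_subjects=6)
    dataset, agents = simulate_cohort(pop, schedules=small_schedules(), seed=11)
    return dataset, agents, pop


@pytest.fixture(scope="session")
def medium_cohort():
    """20 subjects x 3 tasks x 60 trials, used by the hierarchical tests."""
    pop = PopulationConfig(n_subjects=20)
    dataset, agents = simulate_cohort(pop, schedules=small_schedules(), seed=42)
    return dataset, agents, pop


def truth_matrix(agents, tasks=("NV", "SV", "LV")):
    return np.array([[a.logk[t] for t in tasks] for a in agents])


def toy_trials(rows):
    """Build a minimal trials table from (subjid, task, session, trial,
    later_mag, later_delay, unit, chose_later) tuples."""
    recs = []
    for subjid, task, session, trial, mag, delay, unit, chose in rows:
        recs.append(dict(subjid=subjid, task=task, session=session, block=1,
                         trial=trial, sooner_mag=4.0, later_mag=mag,
                         later_delay=delay, delay_unit=unit, chose_later=chose))
    return pd.DataFrame(recs)
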