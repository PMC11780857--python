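import numpy as np
import pytest

from omt.cohort import GROUP_PRESETS, sample_response
from omt.task_design import TrialSpec, Stimulus, make_session_schedule


def make_trial(
    set_size=3,
    delay_s=1.0,
    locs=((0.3, 0.3), (0.7, 0.3), (0.5, 0.7)),
    target_index=0,
    trial_id=0,
):
    """Hand-built trial with fixed geometry."""
    items = tuple(
        (Stimulus(i, 0), tuple(map(float, locs[i]))) for i in range(set_size)
    )
    return TrialSpec(
        trial_id=trial_id,
        block=1,
        set_size=set_size,
        delay_s=delay_s,
        items=items,
        target_index=target_index,
        foil=Stimulus(48, 3),
    )


@pytest.fixture(scope="session")
def default_schedule():
    return make_session_schedule(12345)


@pytest.fixture(scope="session")
def ehc_participant_trials(default_schedule):
    """One simulated EHC participant on the default 120-trial session."""
    _, test = default_schedule
    rng = np.random.default_rng(777)
    params = GROUP_PRESETS["EHC"]
    return [(t, sample_response(t, params, rng)) for t in test]
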