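import numpy as np
import pandas as pd
import pytest

from rewardsdt.behavior import TRIAL_COLUMNS
from rewardsdt.synth import (
    choice_observer,
    make_reward_schedule,
    simulate_observer,
    space_observer,
)


def toy_trials(rows: list[dict]) -> pd.DataFrame:
    """Build a minimal valid trial table from per-trial dict fragments."""
    defaults = {
        "participant_id": "p1",
        "session_type": "space_specific",
        "block_idx": 1,
        "block_valence": "gain",
        "miniblock_idx": 1,
        "contingency": "VR_gt_FX",
        "fx_side": "left",
        "probe_side": "VR",
        "change_fx": False,
        "change_vr": False,
        "response": "no",
        "rt_ms": 600.0,
        "payoff": 0.0,
    }
    out = pd.DataFrame([{**defaults, **r} for r in rows])
    return out[TRIAL_COLUMNS]


@pytest.fixture(scope="session")
def space_session():
    """One simulated space-specific session with the default planted effects."""
    sch = make_reward_schedule("space_specific", seed=11)
    return sch, simulate_observer(sch, space_observer(), seed=12, participant_id="p1")


@pytest.fixture(scope="session")
def choice_session():
    sch = make_reward_schedule("choice_specific", seed=21)
    return sch, simulate_observer(sch, choice_observer(), seed=22, participant_id="p1")


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
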