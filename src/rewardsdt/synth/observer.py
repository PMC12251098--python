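"""SDT observers that complete a schedule into full trial records.

On each trial the observer evaluates the probed side only.  Evidence is drawn
from the equal-variance SDT model, ``x ~ N(d' * 1[change], 1)``, and the
observer reports Yes iff ``x > d'/2 + c`` for the (side, contingency) cell the
trial belongs to — this placement of the decision threshold makes the
generative criterion coincide with the value recovered by
:func:`rewardsdt.behavior.estimate_sdt`.  Occasional lapses respond uniformly.
Reaction times are base + per-(side, contingency) offset + an optional
bias-choice advantage (choice-specific sessions, VR side) + positive gamma
noise.  Payoffs are read from the schedule's payoff matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from rewardsdt.behavior import CONTINGENCIES
from rewardsdt.synth.schedule import RewardSchedule


@dataclass
class ObserverSpec:
    """Generative twin of the estimated SDT parameters.

    ``d_prime`` and ``criterion`` map (side, contingency) -> value; ``side`` is
    the FX/VR role, not the hemifield.  ``rt_offsets_ms`` maps the same cells to
    additive RT offsets; ``rt_choice_bias_ms`` is added when the emitted VR-side
    response is the high-reward (bias-consistent) choice in a choice-specific
    session.
    """

    d_prime: dict[tuple[str, str], float]
    criterion: dict[tuple[str, str], float]
    lapse_rate: float = 0.0
    rt_base_ms: float = 530.0
    rt_offsets_ms: dict[tuple[str, str], float] = field(default_factory=dict)
    rt_choice_bias_ms: float = 0.0
    rt_noise_shape: float = 4.0
    rt_noise_scale_ms: float = 25.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.lapse_rate <= 0.1:
            raise ValueError("lapse_rate must lie in [0, 0.1]")
        if any(v < 0 for v in self.d_prime.values()):
            raise ValueError("d' must be non-negative")


def space_observer(
    d_mean: float = 0.7,
    c_mean: float = 0.12,
    delta_d_vr: float = 0.5,
    delta_d_fx: float = -0.5,
    delta_c_vr: float = 0.0,
    delta_c_fx: float = 0.0,
    delta_rt_vr: float = -20.0,
    delta_rt_fx: float = 34.0,
    lapse_rate: float = 0.0,
) -> ObserverSpec:
    """Observer for a space-specific session with planted per-side modulations.

    Each ``delta_*`` is the (VR_gt_FX minus VR_lt_FX) modulation planted
    symmetrically around the corresponding mean.
    """
    c1, c2 = CONTINGENCIES["space_specific"]
    d = {
        ("VR", c1): d_mean + delta_d_vr / 2, ("VR", c2): d_mean - delta_d_vr / 2,
        ("FX", c1): d_mean + delta_d_fx / 2, ("FX", c2): d_mean - delta_d_fx / 2,
    }
    c = {
        ("VR", c1): c_mean + delta_c_vr / 2, ("VR", c2): c_mean - delta_c_vr / 2,
        ("FX", c1): c_mean + delta_c_fx / 2, ("FX", c2): c_mean - delta_c_fx / 2,
    }
    rt = {
        ("VR", c1): delta_rt_vr / 2, ("VR", c2): -delta_rt_vr / 2,
        ("FX", c1): delta_rt_fx / 2, ("FX", c2): -delta_rt_fx / 2,
    }
    return ObserverSpec(d_prime=d, criterion=c, rt_offsets_ms=rt, lapse_rate=lapse_rate)


def choice_observer(
    d_mean: float = 0.7,
    c_mean: float = 0.12,
    delta_c_vr: float = -0.5,
    delta_c_fx: float = 0.0,
    delta_d_vr: float = 0.0,
    delta_d_fx: float = 0.0,
    rt_choice_bias_ms: float = -24.0,
    lapse_rate: float = 0.0,
) -> ObserverSpec:
    """Observer for a choice-specific session: criterion modulated on VR only.

    ``delta_c_vr`` is the (liberal minus conservative) criterion modulation; the
    default makes the observer more liberal (lower c) when Yes responses carry
    higher expected reward.
    """
    c1, c2 = CONTINGENCIES["choice_specific"]
    d = {
        ("VR", c1): d_mean + delta_d_vr / 2, ("VR", c2): d_mean - delta_d_vr / 2,
        ("FX", c1): d_mean + delta_d_fx / 2, ("FX", c2): d_mean - delta_d_fx / 2,
    }
    c = {
        ("VR", c1): c_mean + delta_c_vr / 2, ("VR", c2): c_mean - delta_c_vr / 2,
        ("FX", c1): c_mean + delta_c_fx / 2, ("FX", c2): c_mean - delta_c_fx / 2,
    }
    return ObserverSpec(
        d_prime=d, criterion=c, rt_choice_bias_ms=rt_choice_bias_ms, lapse_rate=lapse_rate
    )


_RESP_TYPE = {
    (True, True): "H", (True, False): "M", (False, True): "FA", (False, False): "CR",
}


def simulate_observer(
    schedule: RewardSchedule,
    observer: ObserverSpec,
    seed: int | None = None,
    participant_id: str = "sim",
) -> pd.DataFrame:
    """Complete a schedule's trial skeletons with responses, RTs, and payoffs."""
    trials = schedule.trials.copy()
    conts = CONTINGENCIES[schedule.session_type]
    for side in ("FX", "VR"):
        for cont in conts:
            if (side, cont) not in observer.d_prime or (side, cont) not in observer.criterion:
                raise ValueError(f"observer parameters missing for cell ({side}, {cont})")

    rng = np.random.default_rng(seed)
    n = len(trials)
    probe_vr = (trials["probe_side"] == "VR").to_numpy()
    cont = trials["contingency"].to_numpy()
    change = np.where(probe_vr, trials["change_vr"].to_numpy(), trials["change_fx"].to_numpy())

    d = np.empty(n)
    c = np.empty(n)
    rt_off = np.zeros(n)
    for side in ("FX", "VR"):
        side_mask = probe_vr if side == "VR" else ~probe_vr
        for co in conts:
            m = side_mask & (cont == co)
            d[m] = observer.d_prime[(side, co)]
            c[m] = observer.criterion[(side, co)]
            rt_off[m] = observer.rt_offsets_ms.get((side, co), 0.0)

    evidence = rng.standard_normal(n) + d * change
    yes = evidence > d / 2 + c
    lapse = rng.random(n) < observer.lapse_rate
    yes = np.where(lapse, rng.random(n) < 0.5, yes)

    correct = yes == change
    resp_type = np.where(change, np.where(yes, "H", "M"), np.where(yes, "FA", "CR"))
    valence = trials["block_valence"].to_numpy()
    side_role = np.where(probe_vr, "VR", "FX")
    # vectorised payoff lookup via a small code table
    resp_codes = {"H": 0, "M": 1, "FA": 2, "CR": 3}
    cont_codes = {co: i for i, co in enumerate(conts)}
    table = np.zeros((2, 4, 2, 2))
    for (s, r, co, v), val in schedule.payoffs.items():
        table[int(s == "VR"), resp_codes[r], cont_codes[co], int(v == "loss")] = val
    r_idx = np.select([resp_type == k for k in resp_codes], list(resp_codes.values()))
    co_idx = np.select([cont == k for k in cont_codes], list(cont_codes.values()))
    payoff = table[probe_vr.astype(int), r_idx, co_idx, (valence == "loss").astype(int)]

    bias_bonus = np.zeros(n)
    if schedule.session_type == "choice_specific" and observer.rt_choice_bias_ms:
        high_bias_yes = cont == "liberal"
        consistent = probe_vr & (yes == high_bias_yes)
        bias_bonus[consistent] = observer.rt_choice_bias_ms

    rt = (
        observer.rt_base_ms
        + rt_off
        + bias_bonus
        + rng.gamma(observer.rt_noise_shape, observer.rt_noise_scale_ms, n)
    )

    trials["participant_id"] = participant_id
    trials["response"] = np.where(yes, "yes", "no")
    trials["rt_ms"] = rt
    trials["payoff"] = payoff
    trials["correct"] = correct
    return trials
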