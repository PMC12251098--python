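"""Task schedule generation: blocks, mini-blocks, contingencies, and payoffs.

A session is 12 blocks of 48 trials.  Half the blocks are gain blocks (correct
responses rewarded, errors not penalised), half are loss blocks (errors
penalised, correct responses not rewarded), pseudorandomly interleaved.  Within
a block the reward contingency is constant on the FX side, while on the VR side
it alternates between the session's two contingencies across mini-blocks of
10-16 trials (mean 12).  Orientation changes are independent Bernoulli(0.5) per
side and the response probe falls on either side equally often, balanced within
each block.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from rewardsdt.behavior import CONTINGENCIES, TRIAL_COLUMNS

MINIBLOCK_SUPPORT = np.arange(10, 17)
RESPONSE_TYPES = ("H", "M", "FA", "CR")


def _miniblock_pmf(tau: float) -> np.ndarray:
    w = np.exp(-(MINIBLOCK_SUPPORT - 10) / tau)
    return w / w.sum()


def _solve_tau(target_mean: float = 12.0) -> float:
    """Decay constant of the discretised truncated exponential with the target mean."""
    f = lambda tau: float(_miniblock_pmf(tau) @ MINIBLOCK_SUPPORT) - target_mean
    return brentq(f, 0.5, 50.0)


_TAU = _solve_tau()
_PMF = _miniblock_pmf(_TAU)


def sample_miniblock_lengths(n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw mini-block lengths from the discretised truncated exponential on 10..16."""
    return rng.choice(MINIBLOCK_SUPPORT, size=n, p=_PMF)


def default_payoffs(session_type: str) -> dict:
    """Payoff matrix: (side, response_type, contingency, valence) -> INR.

    Gain blocks reward only correct responses (H, CR); loss blocks penalise only
    errors (M, FA).  Space-specific sessions pay both correct (or penalise both
    incorrect) response types equally but at a side-dependent level; the
    choice-specific sessions pay the two response types unequally on the VR side
    only, with equal per-side expected value.
    """
    hi, mid, lo = 8.0, 5.0, 2.0
    p: dict[tuple[str, str, str, str], float] = {}
    for cont in CONTINGENCIES[session_type]:
        for valence in ("gain", "loss"):
            rewarded = ("H", "CR") if valence == "gain" else ("M", "FA")
            sign = 1.0 if valence == "gain" else -1.0
            for side in ("FX", "VR"):
                for rt in RESPONSE_TYPES:
                    if rt not in rewarded:
                        p[(side, rt, cont, valence)] = 0.0
                        continue
                    if side == "FX":
                        value = mid
                    elif session_type == "space_specific":
                        value = hi if cont == "VR_gt_FX" else lo
                    else:  # choice_specific: split across response types on VR
                        # liberal favours Yes: more reward for H / less penalty for FA
                        yes_favoured = cont == "liberal"
                        is_yes_resp = rt in ("H", "FA")
                        if valence == "gain":
                            value = hi if (is_yes_resp == yes_favoured) else lo
                        else:
                            # low |penalty| for the favoured response's error
                            value = lo if (is_yes_resp == yes_favoured) else hi
                    p[(side, rt, cont, valence)] = sign * value
    return p


@dataclass
class RewardSchedule:
    """A session's trial skeleton plus its payoff matrix."""

    session_type: str
    trials: pd.DataFrame  # TrialRecord skeleton: response/rt_ms/payoff unfilled
    payoffs: dict = field(repr=False)
    seed: int | None = None

    def payoff_for(self, side: str, resp_type: str, contingency: str, valence: str) -> float:
        return self.payoffs[(side, resp_type, contingency, valence)]


def make_reward_schedule(
    session_type: str,
    n_blocks: int = 12,
    trials_per_block: int = 48,
    seed: int | None = None,
    payoffs: dict | None = None,
) -> RewardSchedule:
    """Generate a reproducible session schedule.

    Mini-block lengths are drawn from the discretised truncated exponential on
    {10..16} (mean 12); the last mini-block of each block is set to the exact
    remainder (redrawing the block partition if the remainder falls outside the
    10-16 support), so mini-blocks tile the block exactly.  Contingencies
    alternate across mini-blocks starting from a random one; gain/loss valence
    and the FX hemifield are counterbalanced pseudorandomly across blocks.
    """
    if session_type not in CONTINGENCIES:
        raise ValueError(f"unknown session_type {session_type!r}")
    if n_blocks < 1 or trials_per_block < 10:
        raise ValueError("need at least 1 block and 10 trials per block")
    rng = np.random.default_rng(seed)
    conts = CONTINGENCIES[session_type]

    valences = np.array(["gain"] * (n_blocks // 2) + ["loss"] * (n_blocks - n_blocks // 2))
    rng.shuffle(valences)
    fx_sides = np.array(["left"] * (n_blocks // 2) + ["right"] * (n_blocks - n_blocks // 2))
    rng.shuffle(fx_sides)

    rows_block, rows_valence, rows_mb, rows_cont, rows_fx, rows_probe = [], [], [], [], [], []
    mb_counter = 0
    for b in range(n_blocks):
        # partition the block into mini-blocks of length 10..16
        while True:
            lengths: list[int] = []
            remaining = trials_per_block
            while remaining > 16:
                lengths.append(int(sample_miniblock_lengths(1, rng)[0]))
                remaining -= lengths[-1]
            if 10 <= remaining <= 16:
                lengths.append(remaining)
                break
        start = int(rng.integers(2))
        for i, ln in enumerate(lengths):
            mb_counter += 1
            rows_block.extend([b + 1] * ln)
            rows_valence.extend([valences[b]] * ln)
            rows_mb.extend([mb_counter] * ln)
            rows_cont.extend([conts[(start + i) % 2]] * ln)
            rows_fx.extend([fx_sides[b]] * ln)
        probe = np.array(["FX"] * (trials_per_block // 2) + ["VR"] * (trials_per_block - trials_per_block // 2))
        rng.shuffle(probe)
        rows_probe.extend(probe.tolist())

    n = len(rows_block)
    trials = pd.DataFrame(
        {
            "participant_id": "",
            "session_type": session_type,
            "block_idx": np.asarray(rows_block, dtype=int),
            "block_valence": rows_valence,
            "miniblock_idx": np.asarray(rows_mb, dtype=int),
            "contingency": rows_cont,
            "fx_side": rows_fx,
            "probe_side": rows_probe,
            "change_fx": rng.random(n) < 0.5,
            "change_vr": rng.random(n) < 0.5,
            "response": "none",
            "rt_ms": np.nan,
            "payoff": np.nan,
        },
        columns=TRIAL_COLUMNS,
    )
    trials.insert(0, "trial_idx", np.arange(n))
    return RewardSchedule(
        session_type=session_type,
        trials=trials,
        payoffs=payoffs if payoffs is not None else default_payoffs(session_type),
        seed=seed,
    )
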