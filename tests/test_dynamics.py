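"""Switch-trial identification, switch-locked series, conserved-resource fit."""

import numpy as np
import pandas as pd
import pytest

from rewardsdt.dynamics import (
    average_series,
    conserved_resource_r2,
    find_switch_trials,
    r2_permutation_test,
    sdt_metric,
    sdt_switch_series,
    series_points,
    switch_locked_series,
)
from rewardsdt.synth import (
    default_payoffs,
    make_reward_schedule,
    simulate_observer,
    space_observer,
)
from tests.conftest import toy_trials


def toy_block(rows):
    """A two-mini-block gain block with an explicit trial order."""
    base = {"block_idx": 1, "block_valence": "gain"}
    return toy_trials([{**base, **r} for r in rows])


class TestFindSwitchTrials:
    def test_first_correct_vr_probe_after_switch_is_informative(self):
        payoffs = default_payoffs("space_specific")
        rows = [
            {"miniblock_idx": 1, "contingency": "VR_gt_FX", "probe_side": "VR",
             "change_vr": True, "response": "yes", "payoff": 8.0},
            # new mini-block: first trial FX-probed (uninformative)
            {"miniblock_idx": 2, "contingency": "VR_lt_FX", "probe_side": "FX",
             "change_fx": True, "response": "yes", "payoff": 5.0},
            # hit on VR now pays 2 instead of 8 -> the switch trial
            {"miniblock_idx": 2, "contingency": "VR_lt_FX", "probe_side": "VR",
             "change_vr": True, "response": "yes", "payoff": 2.0},
        ]
        events = find_switch_trials(toy_block(rows), payoffs)
        assert len(events) == 1
        assert events[0].trial_idx == 2
        assert events[0].transition == ("VR_gt_FX", "VR_lt_FX")

    def test_incorrect_gain_trial_not_informative(self):
        # a miss earns 0 under both contingencies -> not a switch trial
        payoffs = default_payoffs("space_specific")
        rows = [
            {"miniblock_idx": 1, "contingency": "VR_gt_FX", "probe_side": "VR",
             "change_vr": True, "response": "yes", "payoff": 8.0},
            {"miniblock_idx": 2, "contingency": "VR_lt_FX", "probe_side": "VR",
             "change_vr": True, "response": "no", "payoff": 0.0},      # miss
            {"miniblock_idx": 2, "contingency": "VR_lt_FX", "probe_side": "VR",
             "change_vr": False, "response": "no", "payoff": 2.0},     # CR
        ]
        events = find_switch_trials(toy_block(rows), payoffs)
        assert len(events) == 1 and events[0].trial_idx == 2

    def test_choice_specific_equal_payoff_response_not_informative(self):
        # custom payoff table in which CRs pay the same under both contingencies
        payoffs = default_payoffs("choice_specific")
        for cont in ("liberal", "conservative"):
            payoffs[("VR", "CR", cont, "gain")] = 5.0
        sess = {"session_type": "choice_specific"}
        rows = [
            {**sess, "miniblock_idx": 1, "contingency": "liberal", "probe_side": "VR",
             "change_vr": True, "response": "yes", "payoff": 8.0},
            # CR: identical payoff under both contingencies -> NOT a switch
            {**sess, "miniblock_idx": 2, "contingency": "conservative", "probe_side": "VR",
             "change_vr": False, "response": "no", "payoff": 5.0},
            # hit: 2 under conservative vs 8 under liberal -> the switch
            {**sess, "miniblock_idx": 2, "contingency": "conservative", "probe_side": "VR",
             "change_vr": True, "response": "yes", "payoff": 2.0},
        ]
        events = find_switch_trials(toy_block(rows), payoffs)
        assert len(events) == 1 and events[0].trial_idx == 2

    def test_no_contingency_change_yields_no_events(self):
        payoffs = default_payoffs("space_specific")
        rows = [
            {"miniblock_idx": i + 1, "contingency": "VR_gt_FX", "probe_side": "VR",
             "change_vr": True, "response": "yes", "payoff": 8.0}
            for i in range(3)
        ]
        assert find_switch_trials(toy_block(rows), payoffs) == []

    def test_real_session_switch_count_matches_transitions(self, space_session):
        sch, trials = space_session
        events = find_switch_trials(trials, sch.payoffs)
        mb = trials.groupby("miniblock_idx").agg(
            cont=("contingency", "first"), block=("block_idx", "first")
        )
        n_transitions = sum(
            (blk["cont"].iloc[i] != blk["cont"].iloc[i + 1])
            for _, blk in mb.groupby("block")
            for i in range(len(blk) - 1)
        )
        assert 0 < len(events) <= n_transitions
        # every switch trial is VR-probed by construction
        for ev in events:
            assert trials.iloc[ev.trial_idx]["probe_side"] == "VR"


class TestSwitchSeries:
    def test_constant_metric_gives_flat_series(self, space_session):
        sch, trials = space_session
        events = find_switch_trials(trials, sch.payoffs)
        series = switch_locked_series(trials, events, lambda sub, side: 3.5)
        for vals in series.values.values():
            assert np.allclose(vals, 3.5)

    def test_normalization_is_scale_invariant(self, space_session):
        sch, trials = space_session
        events = find_switch_trials(trials, sch.payoffs)
        metric = sdt_metric("d_prime")
        doubled = lambda sub, side: (lambda v: None if v is None else 2.0 * v)(metric(sub, side))
        a = switch_locked_series(trials, events, metric, normalize_by_session_mean=True)
        b = switch_locked_series(trials, events, doubled, normalize_by_session_mean=True)
        for key in a.values:
            assert np.allclose(a.values[key], b.values[key], equal_nan=True)

    def test_step_change_visible_across_offsets(self):
        # strong planted step: d' 1.8 vs 0.2 across contingencies on VR
        payoffs = default_payoffs("space_specific")
        series = []
        for i in range(12):
            sch = make_reward_schedule("space_specific", seed=500 + i)
            trials = simulate_observer(
                sch, space_observer(d_mean=1.0, delta_d_vr=1.6, delta_d_fx=0.0), seed=600 + i
            )
            ev = find_switch_trials(trials, payoffs)
            series.append(sdt_switch_series(trials, ev, "d_prime"))
        avg = average_series(series)
        for (trans, side), vals in avg.values.items():
            if side != "VR":
                continue
            # offsets -2 and +4: the transition is cleanest here; windows at
            # larger offsets reach the next mini-block and revert
            pre, post = vals[0], vals[3]
            if trans == ("VR_gt_FX", "VR_lt_FX"):
                assert pre - post > 0.4
            else:
                assert post - pre > 0.4

    def test_shift_one_doubles_the_offset_grid(self, space_session):
        sch, trials = space_session
        events = find_switch_trials(trials, sch.payoffs)
        s2 = sdt_switch_series(trials, events, "d_prime", shift=2)
        s1 = sdt_switch_series(trials, events, "d_prime", shift=1)
        assert len(s2.offsets) == 9 and len(s1.offsets) == 17


class TestConservedResource:
    def test_perfect_anticorrelation_gives_r2_one(self):
        x = np.array([1.0, -2.0, 0.5, 3.0, -2.5])
        fit = conserved_resource_r2(x, -x)
        assert fit.r_squared == pytest.approx(1.0)

    def test_perfect_positive_correlation_gives_minus_one(self):
        x = np.array([1.0, -2.0, 0.5, 3.0, -2.5])
        fit = conserved_resource_r2(x, x)
        assert fit.r_squared == pytest.approx(-1.0)

    def test_independent_normals_have_mean_r2_near_zero(self, rng):
        # Monte-Carlo oracle: E[R^2] -> 0 for independent standard-normal sides
        r2s = [
            conserved_resource_r2(rng.standard_normal(17), rng.standard_normal(17)).r_squared
            for _ in range(1000)
        ]
        assert abs(np.mean(r2s)) < 0.03

    def test_degenerate_input_rejected(self):
        with pytest.raises(ValueError, match="zero total variation"):
            conserved_resource_r2(np.ones(5), np.ones(5))
        with pytest.raises(ValueError, match="3 paired"):
            conserved_resource_r2(np.array([1.0]), np.array([1.0]))


class TestR2Permutation:
    def test_identical_series_give_chance_p(self, rng):
        x = rng.standard_normal(17)
        y = rng.standard_normal(17)
        res = r2_permutation_test((x, y), (x.copy(), y.copy()), n_perm=500, seed=0)
        assert 0.2 < res["p"] <= 1.0  # observed difference 0 vs symmetric null

    def test_deterministic_under_seed(self, rng):
        a = (rng.standard_normal(17), rng.standard_normal(17))
        b = (rng.standard_normal(17), rng.standard_normal(17))
        p1 = r2_permutation_test(a, b, n_perm=300, seed=5)["p"]
        p2 = r2_permutation_test(a, b, n_perm=300, seed=5)["p"]
        assert p1 == p2

    def test_coupled_vs_independent_detected(self, rng):
        x = rng.standard_normal(17)
        coupled = (x, -x + rng.standard_normal(17) * 0.1)
        indep = (rng.standard_normal(17), rng.standard_normal(17))
        res = r2_permutation_test(coupled, indep, n_perm=500, seed=1)
        assert res["p"] < 0.05
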