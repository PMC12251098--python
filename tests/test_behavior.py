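"""SDT backbone: contingency tabulation, d'/c estimation, modulation indices."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import norm

from rewardsdt.behavior import (
    ContingencyCounts,
    MetricValue,
    NoTrialsError,
    estimate_sdt,
    modulation_index,
    read_trials,
    rt_summaries,
    sdt_modulations,
    tabulate_contingency,
    validate_trials,
    write_trials,
)
from tests.conftest import toy_trials


class TestTabulate:
    def test_one_of_each_response_type(self):
        trials = toy_trials(
            [
                {"change_vr": True, "response": "yes"},
                {"change_vr": True, "response": "no"},
                {"change_vr": False, "response": "yes"},
                {"change_vr": False, "response": "no"},
            ]
        )
        c = tabulate_contingency(trials, "VR", "VR_gt_FX")
        assert (c.n_hit, c.n_miss, c.n_fa, c.n_cr) == (1, 1, 1, 1)

    def test_none_responses_excluded(self):
        trials = toy_trials(
            [
                {"change_vr": True, "response": "yes"},
                {"change_vr": True, "response": "none", "rt_ms": np.nan},
            ]
        )
        c = tabulate_contingency(trials, "VR", "VR_gt_FX")
        assert c.n_hit == 1 and c.n_change == 1

    def test_classification_uses_probed_side(self):
        # change on the un-probed side must not count as a change event
        trials = toy_trials([{"probe_side": "FX", "change_vr": True, "response": "yes"}])
        c = tabulate_contingency(trials, "FX", "VR_gt_FX")
        assert c.n_fa == 1 and c.n_hit == 0

    def test_empty_selection_raises_naming_filter(self):
        trials = toy_trials([{"probe_side": "FX"}])
        with pytest.raises(NoTrialsError, match="side=VR"):
            tabulate_contingency(trials, "VR", "VR_gt_FX")

    def test_simulated_observer_rates_match_closed_form(self, rng):
        # observer with d'=1, c=0: HR = Phi(0.5), FAR = Phi(-0.5)
        n = 1000
        change = rng.random(n) < 0.5
        x = rng.standard_normal(n) + 1.0 * change
        trials = toy_trials(
            [
                {"change_vr": bool(ch), "response": "yes" if xx > 0.5 else "no"}
                for ch, xx in zip(change, x)
            ]
        )
        c = tabulate_contingency(trials, "VR", "VR_gt_FX")
        se = 3 * np.sqrt(0.25 / (n / 2))
        assert abs(c.hit_rate - norm.cdf(0.5)) < se
        assert abs(c.fa_rate - norm.cdf(-0.5)) < se

    def test_gain_loss_pooling_equals_concatenation(self, space_session):
        _, trials = space_session
        pooled = tabulate_contingency(trials, "VR", "VR_gt_FX", "pooled")
        gain = tabulate_contingency(trials, "VR", "VR_gt_FX", "gain")
        loss = tabulate_contingency(trials, "VR", "VR_gt_FX", "loss")
        assert pooled == gain + loss


class TestEstimateSdt:
    @pytest.mark.parametrize(
        "hr, far, d_exp, c_exp",
        [
            (0.5, 0.5, 0.0, 0.0),
            (0.69, 0.31, 0.9917, 0.0),       # probit oracle: Phi^-1(0.69) = 0.4959
            (0.9, 0.5, 1.2816, -0.6408),     # Phi^-1(0.9) = 1.2816
        ],
    )
    def test_known_rates(self, hr, far, d_exp, c_exp):
        n = 1000
        p = estimate_sdt(
            ContingencyCounts(int(hr * n), n - int(hr * n), int(far * n), n - int(far * n))
        )
        assert p.d_prime == pytest.approx(d_exp, abs=1e-3)
        assert p.criterion == pytest.approx(c_exp, abs=1e-3)

    def test_extreme_rates_corrected_and_flagged(self):
        p = estimate_sdt(ContingencyCounts(10, 0, 0, 10))
        assert np.isfinite(p.d_prime) and p.corrected
        # HR -> 1 - 1/20, FAR -> 1/20
        assert p.d_prime == pytest.approx(2 * norm.ppf(0.95), abs=1e-9)

    def test_zero_row_total_raises(self):
        with pytest.raises(ValueError):
            estimate_sdt(ContingencyCounts(0, 0, 5, 5))

    @given(
        h=st.integers(0, 50), m=st.integers(0, 50),
        f=st.integers(0, 50), r=st.integers(0, 50),
    )
    @settings(max_examples=200, deadline=None)
    def test_antisymmetry_under_rate_exchange(self, h, m, f, r):
        if h + m == 0 or f + r == 0:
            return
        a = estimate_sdt(ContingencyCounts(h, m, f, r))
        b = estimate_sdt(ContingencyCounts(f, r, h, m))   # HR and FAR exchanged
        assert a.d_prime == pytest.approx(-b.d_prime, abs=1e-10)
        # c(HR, FAR) = -c(1-FAR, 1-HR)
        c2 = estimate_sdt(ContingencyCounts(r, f, m, h))
        assert a.criterion == pytest.approx(-c2.criterion, abs=1e-10)

    @given(h=st.integers(1, 99))
    @settings(max_examples=50, deadline=None)
    def test_criterion_zero_iff_far_complements_hr(self, h):
        p = estimate_sdt(ContingencyCounts(h, 100 - h, 100 - h, h))
        assert p.criterion == pytest.approx(0.0, abs=1e-12)


class TestModulation:
    def test_subtraction_and_identity(self):
        assert modulation_index(1.2, 0.8, "VR", "d_prime").delta == pytest.approx(0.4)
        assert modulation_index(0.7, 0.7, "FX", "d_prime").delta == 0.0

    def test_mismatched_tags_raise(self):
        a = MetricValue(1.0, "VR", "d_prime")
        b = MetricValue(0.5, "FX", "d_prime")
        with pytest.raises(ValueError, match="mismatched"):
            modulation_index(a, b)

    def test_planted_modulation_recovered(self):
        # 2,000 probed trials/cell via a long synthetic session
        from rewardsdt.synth import make_reward_schedule, simulate_observer, space_observer

        sch = make_reward_schedule("space_specific", n_blocks=12, trials_per_block=1344, seed=5)
        trials = simulate_observer(sch, space_observer(delta_d_vr=0.5), seed=6)
        mods = sdt_modulations(trials)
        assert mods["d_prime_VR"].delta == pytest.approx(0.5, abs=0.1)


class TestRtSummaries:
    def test_median_of_three(self):
        trials = toy_trials(
            [
                {"change_vr": True, "response": "yes", "rt_ms": rt}
                for rt in (500.0, 600.0, 700.0)
            ]
        )
        out = rt_summaries(trials, "VR", "VR_gt_FX")
        assert out["median_rt"] == 600.0 and out["mean_rt"] == 600.0

    def test_delta_rt_zero_when_choices_equal(self):
        rows = []
        for cont in ("liberal", "conservative"):
            for resp in ("yes", "no"):
                rows.append(
                    {"session_type": "choice_specific", "contingency": cont,
                     "response": resp, "rt_ms": 600.0}
                )
        out = rt_summaries(toy_trials(rows), "VR", "liberal")
        assert out["delta_rt_by_choice_bias"] == pytest.approx(0.0)

    def test_planted_choice_bias_advantage_recovered(self):
        from rewardsdt.synth import choice_observer, make_reward_schedule, simulate_observer

        sch = make_reward_schedule("choice_specific", n_blocks=12, trials_per_block=480, seed=7)
        trials = simulate_observer(
            sch, choice_observer(rt_choice_bias_ms=-30.0), seed=8
        )
        out = rt_summaries(trials, "VR", "liberal")
        assert out["delta_rt_by_choice_bias"] == pytest.approx(-30.0, abs=8.0)

    def test_no_correct_trials_yields_absent_values(self):
        trials = toy_trials([{"change_vr": True, "response": "no"}])  # one miss
        out = rt_summaries(trials, "VR", "VR_gt_FX")
        assert out["median_rt"] is None


class TestTrialTableIO:
    def test_roundtrip(self, tmp_path, space_session):
        _, trials = space_session
        path = tmp_path / "trials.csv"
        write_trials(trials, path)
        back = read_trials(path)
        assert len(back) == len(trials)
        assert (back["response"] == trials["response"].to_numpy()).all()
        assert back["change_vr"].dtype == bool

    def test_validation_catches_bad_labels(self, space_session):
        _, trials = space_session
        bad = trials.copy()
        bad.loc[bad.index[0], "contingency"] = "liberal"  # wrong session vocabulary
        with pytest.raises(ValueError, match="contingency"):
            validate_trials(bad)

    def test_validation_catches_rt_on_none(self):
        trials = toy_trials([{"response": "none", "rt_ms": 500.0}])
        with pytest.raises(ValueError, match="rt_ms"):
            validate_trials(trials)
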