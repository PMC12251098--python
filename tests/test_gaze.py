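"""Gaze generator and microsaccade detection/rate analysis."""

import numpy as np
import pandas as pd
import pytest

from rewardsdt.gaze import (
    RateTrace,
    detect_all,
    detect_microsaccades,
    fixation_breach_mask,
    msc_quantify,
    msc_rate_trace,
)
from rewardsdt.synth import GazeEffectSpec, generate_gaze_traces, make_reward_schedule
from rewardsdt.synth.gaze import _inject_event

T = np.arange(-200.0, 800.0)


def _flat_trace(noise=0.0, rng=None):
    xy = np.zeros((len(T), 2))
    if noise and rng is not None:
        xy += rng.standard_normal(xy.shape) * noise
    return xy


def _with_event(onset=200.0, amplitude=0.5, duration=20.0, direction=0.0, noise=0.008, rng=None):
    xy = _flat_trace(noise, rng)
    _inject_event(xy, T, onset, duration, amplitude, direction)
    return xy


class TestGenerator:
    def test_zero_rate_zero_noise_is_flat(self):
        trials = make_reward_schedule("space_specific", n_blocks=1, seed=1).trials.head(3)
        effect = GazeEffectSpec(rate_default=0.0, noise_dva=0.0, drift_dva=0.0)
        traces, log = generate_gaze_traces(trials, effect, seed=2)
        assert len(log) == 0
        assert np.allclose(traces.data, 0.0)

    def test_injected_event_displaces_by_amplitude(self):
        xy = _with_event(amplitude=0.5, direction=0.0, noise=0.0)
        assert xy[-1, 0] == pytest.approx(0.5, abs=1e-3)
        assert np.allclose(xy[T < 150.0, 0], 0.0, atol=1e-3)

    def test_directional_rate_bias_in_ground_truth(self):
        trials = make_reward_schedule("space_specific", n_blocks=4, seed=3).trials
        effect = GazeEffectSpec(
            rate_toward={(s, c): (0.2 if s == "VR" else 0.1)
                         for s in ("FX", "VR") for c in ("VR_gt_FX", "VR_lt_FX")},
            noise_dva=0.0, drift_dva=0.0,
        )
        _, log = generate_gaze_traces(trials, effect, seed=4)
        counts = log["toward_side"].value_counts()
        ratio = counts["VR"] / counts["FX"]
        assert ratio == pytest.approx(2.0, rel=0.25)

    def test_csv_roundtrip(self, tmp_path):
        trials = make_reward_schedule("space_specific", n_blocks=1, seed=5).trials.head(2)
        traces, _ = generate_gaze_traces(trials, GazeEffectSpec(), seed=6)
        from rewardsdt.synth.gaze import GazeTraceSet

        path = tmp_path / "gaze.csv"
        traces.to_csv(path)
        back = GazeTraceSet.from_csv(path)
        assert np.allclose(back.data, traces.data)


class TestDetector:
    def test_constant_trace_yields_no_events(self):
        assert detect_microsaccades(T, _flat_trace()) == []

    def test_single_event_detected_with_accurate_onset(self, rng):
        xy = _with_event(onset=200.0, amplitude=0.5, rng=rng)
        events = detect_microsaccades(T, xy)
        assert len(events) == 1
        assert events[0].onset_ms == pytest.approx(200.0, abs=5.0)
        assert events[0].amplitude_dva == pytest.approx(0.5, abs=0.1)
        assert abs(events[0].direction_deg) < 20.0

    def test_close_pair_keeps_first_only(self, rng):
        xy = _flat_trace(0.008, rng)
        _inject_event(xy, T, 200.0, 20.0, 0.4, 0.0)
        # the second event's supra-threshold run begins < 12 ms after the first ends
        _inject_event(xy, T, 220.0, 20.0, 0.4, 180.0)
        events = detect_microsaccades(T, xy)
        assert len(events) == 1
        assert events[0].onset_ms == pytest.approx(200.0, abs=10.0)

    def test_large_deviation_rejected(self, rng):
        xy = _with_event(amplitude=1.5, rng=rng)
        assert detect_microsaccades(T, xy) == []

    def test_time_shift_equivariance(self, rng):
        xy = _with_event(onset=300.0, rng=rng)
        ev0 = detect_microsaccades(T, xy)
        ev1 = detect_microsaccades(T + 130.0, xy)
        assert len(ev0) == len(ev1) == 1
        assert ev1[0].onset_ms - ev0[0].onset_ms == pytest.approx(130.0)

    def test_axis_scaling_preserves_detection(self, rng):
        xy = _with_event(rng=rng)
        ev0 = detect_microsaccades(T, xy)
        ev1 = detect_microsaccades(T, xy * 0.5)
        assert len(ev0) == len(ev1) == 1
        assert ev1[0].amplitude_dva == pytest.approx(0.5 * ev0[0].amplitude_dva, rel=1e-6)
        assert ev1[0].peak_velocity_dva_per_s == pytest.approx(
            0.5 * ev0[0].peak_velocity_dva_per_s, rel=1e-6
        )

    def test_nonuniform_sampling_rejected(self):
        t = np.concatenate([T[:500], T[501:]])
        with pytest.raises(ValueError, match="uniform"):
            detect_microsaccades(t, np.zeros((len(t), 2)))

    def test_recall_precision_on_injected_events(self):
        # 30 seeded trials at default noise, amplitudes >= 0.3 dva
        trials = make_reward_schedule("space_specific", n_blocks=1, seed=7).trials.head(30)
        effect = GazeEffectSpec(rate_default=0.05, amplitude_range_dva=(0.3, 0.9))
        traces, log = generate_gaze_traces(trials, effect, seed=8)
        events = detect_all(traces)
        tp = fp = 0
        for tid, sub in events.groupby("trial_id"):
            truth = log.loc[log["trial_id"] == tid, "onset_ms"].to_numpy()
            for onset in sub["onset_ms"]:
                tp_hit = len(truth) and np.min(np.abs(truth - onset)) < 20.0
                tp += tp_hit
                fp += not tp_hit
        n_truth = len(log)
        assert tp / n_truth >= 0.9           # recall
        assert tp / max(tp + fp, 1) >= 0.9   # precision


class TestRates:
    def _events(self, rows):
        return pd.DataFrame(rows, columns=["trial_id", "onset_ms", "offset_ms",
                                           "amplitude_dva", "peak_vel", "direction_deg"])

    def _trials(self):
        t = make_reward_schedule("space_specific", n_blocks=1, seed=9).trials
        return t.assign(fx_side="left", trial_idx=np.arange(len(t))).set_index(
            pd.RangeIndex(len(t))
        )

    def test_cone_rule(self):
        trials = self._trials()
        # fx left => VR hemifield right: +10 deg counts toward VR, +60 deg toward neither
        events = self._events(
            [
                {"trial_id": 0, "onset_ms": 200.0, "offset_ms": 220.0,
                 "amplitude_dva": 0.4, "peak_vel": 30.0, "direction_deg": 10.0},
                {"trial_id": 0, "onset_ms": 300.0, "offset_ms": 320.0,
                 "amplitude_dva": 0.4, "peak_vel": 30.0, "direction_deg": 60.0},
            ]
        )
        rate = msc_rate_trace(events, trials)
        cont = trials["contingency"].iloc[0]
        total_vr = rate.rates[("VR", cont)].sum()
        total_fx = rate.rates[("FX", cont)].sum()
        assert total_vr > 0 and total_fx == 0
        # only the +10 deg event contributes (each event spans several windows)
        windows_per_event = int(100 / 25)
        n_cont = (trials["contingency"] == cont).sum()
        assert total_vr == pytest.approx(windows_per_event / n_cont)

    def test_planted_rate_ratio_recovered(self):
        trials = make_reward_schedule("space_specific", n_blocks=6, seed=10).trials
        effect = GazeEffectSpec(
            rate_toward={(s, c): (0.2 if s == "VR" else 0.1)
                         for s in ("FX", "VR") for c in ("VR_gt_FX", "VR_lt_FX")},
        )
        traces, _ = generate_gaze_traces(trials, effect, seed=11)
        events = detect_all(traces)
        rate = msc_rate_trace(events, trials)
        q = msc_quantify(rate, (150.0, 350.0))
        vr = np.mean([q["rates"][("VR", c)] for c in ("VR_gt_FX", "VR_lt_FX")])
        fx = np.mean([q["rates"][("FX", c)] for c in ("VR_gt_FX", "VR_lt_FX")])
        assert vr / fx == pytest.approx(2.0, rel=0.35)

    def test_quantify_flat_rate_and_zero_modulation(self):
        centers = np.arange(-150.0, 751.0, 25.0)
        rates = {(s, c): np.full(len(centers), 0.1)
                 for s in ("FX", "VR") for c in ("VR_gt_FX", "VR_lt_FX")}
        q = msc_quantify(RateTrace(centers_ms=centers, rates=rates))
        assert all(v == pytest.approx(0.1) for v in q["rates"].values())
        assert all(m.delta == pytest.approx(0.0) for m in q["modulation"].values())

    def test_fixation_breach_filter(self):
        trials = make_reward_schedule("space_specific", n_blocks=1, seed=12).trials.head(2)
        effect = GazeEffectSpec(rate_default=0.0, noise_dva=0.0, drift_dva=0.0)
        traces, _ = generate_gaze_traces(trials, effect, seed=13)
        traces.data[1, :, 0] += 1.5  # second trial fixates off-center
        keep = fixation_breach_mask(traces)
        assert keep.tolist() == [True, False]
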