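"""Synthetic 1 kHz monocular gaze traces with injected microsaccades.

Each trial yields a (-200..+800 ms) fixation trace built from slow Brownian
drift plus white measurement noise, with microsaccades injected as Gaussian
velocity-profile displacements (duration 15-25 ms, amplitude 0.1-0.9 dva).
Injection counts are Poisson with direction-resolved rates that may depend on
the trial's (side x contingency) cell, which is how attention-like directional
biases are planted.  The injected-event log is returned as ground truth so
detector recall/precision are computable exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class GazeEffectSpec:
    """Controls for the gaze generator.

    ``rate_toward`` maps (side_role, contingency) -> events per 100 ms injected
    toward that side's hemifield on trials with that contingency label;
    ``rate_default`` is used for missing cells.  Amplitudes are uniform within
    ``amplitude_range_dva`` (must stay < 1 dva so injected events satisfy the
    detector's final-deviation rule); durations uniform in
    ``duration_range_ms``; direction jitter is uniform within +/- ``cone_deg``
    of the horizontal meridian.
    """

    rate_toward: dict[tuple[str, str], float] = field(default_factory=dict)
    rate_default: float = 0.09
    amplitude_range_dva: tuple[float, float] = (0.1, 0.9)
    duration_range_ms: tuple[float, float] = (15.0, 25.0)
    cone_deg: float = 30.0
    noise_dva: float = 0.01
    drift_dva: float = 0.0015

    def __post_init__(self) -> None:
        if self.amplitude_range_dva[1] >= 1.0:
            raise ValueError("microsaccade amplitudes must stay below 1 dva")
        if any(r < 0 for r in self.rate_toward.values()) or self.rate_default < 0:
            raise ValueError("rates must be non-negative")


def space_gaze_effect(rate_attended: float = 0.12, rate_unattended: float = 0.06) -> GazeEffectSpec:
    """Directional rates biased toward the higher-reward location (space sessions)."""
    return GazeEffectSpec(
        rate_toward={
            ("VR", "VR_gt_FX"): rate_attended, ("FX", "VR_gt_FX"): rate_unattended,
            ("VR", "VR_lt_FX"): rate_unattended, ("FX", "VR_lt_FX"): rate_attended,
        }
    )


@dataclass
class GazeTraceSet:
    """1 kHz gaze traces for a set of trials, stimulus onset at t = 0."""

    t_ms: np.ndarray                # (n_samples,), uniform 1 ms grid
    data: np.ndarray                # (n_trials, n_samples, 2) x/y in dva
    trial_ids: np.ndarray           # (n_trials,)
    fs: float = 1000.0

    def trace(self, i: int) -> np.ndarray:
        return self.data[i]

    def to_csv(self, path) -> None:
        n_t, n_s, _ = self.data.shape
        df = pd.DataFrame(
            {
                "trial_id": np.repeat(self.trial_ids, n_s),
                "t_ms": np.tile(self.t_ms, n_t),
                "x_dva": self.data[:, :, 0].ravel(),
                "y_dva": self.data[:, :, 1].ravel(),
            }
        )
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "GazeTraceSet":
        df = pd.read_csv(path)
        trial_ids = df["trial_id"].unique()
        t_ms = np.sort(df.loc[df["trial_id"] == trial_ids[0], "t_ms"].to_numpy())
        n_s = len(t_ms)
        data = np.empty((len(trial_ids), n_s, 2))
        for i, tid in enumerate(trial_ids):
            sub = df.loc[df["trial_id"] == tid].sort_values("t_ms")
            data[i, :, 0] = sub["x_dva"].to_numpy()
            data[i, :, 1] = sub["y_dva"].to_numpy()
        return cls(t_ms=t_ms, data=data, trial_ids=np.asarray(trial_ids))


def _inject_event(
    trace: np.ndarray,
    t_ms: np.ndarray,
    onset_ms: float,
    duration_ms: float,
    amplitude_dva: float,
    direction_deg: float,
) -> None:
    """Add a Gaussian-velocity-profile displacement in place."""
    sigma = duration_ms / 4.0  # ~95% of the displacement within the nominal duration
    center = onset_ms + duration_ms / 2.0
    from scipy.stats import norm

    profile = amplitude_dva * norm.cdf((t_ms - center) / sigma)
    trace[:, 0] += profile * np.cos(np.deg2rad(direction_deg))
    trace[:, 1] += profile * np.sin(np.deg2rad(direction_deg))


def generate_gaze_traces(
    trials: pd.DataFrame,
    effect: GazeEffectSpec | None = None,
    fs: float = 1000.0,
    seed: int | None = None,
    t_range_ms: tuple[float, float] = (-200.0, 800.0),
) -> tuple[GazeTraceSet, pd.DataFrame]:
    """Generate one gaze trace per trial plus the injected-event ground truth log.

    The ground-truth DataFrame has columns trial_id, onset_ms, duration_ms,
    amplitude_dva, direction_deg, toward_side (FX/VR role).
    """
    if effect is None:
        effect = GazeEffectSpec()
    rng = np.random.default_rng(seed)
    dt = 1000.0 / fs
    t_ms = np.arange(t_range_ms[0], t_range_ms[1], dt)
    n_s = len(t_ms)
    epoch_windows = (t_range_ms[1] - t_range_ms[0]) / 100.0  # rate is per 100 ms

    trial_ids = (
        trials["trial_idx"].to_numpy() if "trial_idx" in trials.columns else np.arange(len(trials))
    )
    data = np.empty((len(trials), n_s, 2))
    log_rows = []
    fx_left = (trials["fx_side"] == "left").to_numpy()
    conts = trials["contingency"].to_numpy()

    min_gap_ms = 80.0  # intersaccadic refractory gap; keeps injections resolvable
    for i in range(len(trials)):
        drift = np.cumsum(rng.standard_normal((n_s, 2)) * effect.drift_dva, axis=0)
        noise = rng.standard_normal((n_s, 2)) * effect.noise_dva
        trace = drift + noise
        placed_onsets: list[float] = []
        for side_role in ("FX", "VR"):
            rate = effect.rate_toward.get((side_role, conts[i]), effect.rate_default)
            n_events = rng.poisson(rate * epoch_windows)
            side_is_left = fx_left[i] if side_role == "FX" else not fx_left[i]
            base_dir = 180.0 if side_is_left else 0.0
            for _ in range(n_events):
                duration = rng.uniform(*effect.duration_range_ms)
                onset = None
                for _attempt in range(20):
                    cand = rng.uniform(t_ms[0] + 20.0, t_ms[-1] - duration - 20.0)
                    if all(abs(cand - o) >= min_gap_ms for o in placed_onsets):
                        onset = cand
                        break
                if onset is None:
                    continue  # epoch saturated; drop the event
                placed_onsets.append(onset)
                amplitude = rng.uniform(*effect.amplitude_range_dva)
                direction = base_dir + rng.uniform(-effect.cone_deg, effect.cone_deg)
                _inject_event(trace, t_ms, onset, duration, amplitude, direction)
                log_rows.append(
                    {
                        "trial_id": trial_ids[i],
                        "onset_ms": onset,
                        "duration_ms": duration,
                        "amplitude_dva": amplitude,
                        "direction_deg": ((direction + 180.0) % 360.0) - 180.0,
                        "toward_side": side_role,
                    }
                )
        data[i] = trace

    log = pd.DataFrame(
        log_rows,
        columns=["trial_id", "onset_ms", "duration_ms", "amplitude_dva", "direction_deg", "toward_side"],
    )
    return GazeTraceSet(t_ms=t_ms, data=data, trial_ids=trial_ids), log
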