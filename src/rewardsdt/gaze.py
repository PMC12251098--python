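"""Microsaccade detection and directional rate analysis from 1 kHz gaze traces.

The detector is an elliptical velocity-threshold algorithm in the Engbert-
Kliegl family: bivariate velocities from 5-point smoothed differentiation, an
ellipse centered on the per-epoch median velocity with semi-axes ``k_sigma``
standard deviations per axis, supra-threshold runs as candidate events, a
12 ms temporal-proximity rule (the later event is discarded), a < 1 dva
final-deviation rule, and a peak-speed outlier rejection.  Directional rate
traces count events whose azimuthal displacement points into a side's
hemifield within +/-45 deg of the horizontal meridian, in 100 ms windows
sliding by 25 ms.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from rewardsdt.behavior import CONTINGENCIES, contingency_pair, modulation_index

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class MicrosaccadeEvent:
    onset_ms: float
    offset_ms: float
    amplitude_dva: float
    peak_velocity_dva_per_s: float
    direction_deg: float  # polar, 0 = rightward, CCW positive

    def __post_init__(self) -> None:
        if self.offset_ms <= self.onset_ms:
            raise ValueError("offset must follow onset")


@dataclass
class RateTrace:
    """Mean event counts per 100 ms window, per (side x contingency) cell."""

    centers_ms: np.ndarray
    rates: dict[tuple[str, str], np.ndarray]
    window_ms: float = 100.0

    def to_hz(self) -> dict[tuple[str, str], np.ndarray]:
        return {k: v * (1000.0 / self.window_ms) for k, v in self.rates.items()}


def _ek_velocity(pos: np.ndarray, dt_s: float) -> np.ndarray:
    """5-point smoothed differentiation (Engbert-Kliegl), dva/s."""
    v = np.zeros_like(pos)
    v[2:-2] = (pos[4:] + pos[3:-1] - pos[1:-3] - pos[:-4]) / (6.0 * dt_s)
    return v


def detect_microsaccades(
    t_ms: np.ndarray,
    xy_dva: np.ndarray,
    k_sigma: float = 5.0,
    merge_ms: float = 12.0,
    max_dev_dva: float = 1.0,
    outlier_sigma: float = 5.0,
    min_duration_ms: float = 6.0,
    dispersion: str = "median",
) -> list[MicrosaccadeEvent]:
    """Detect microsaccades in one epoch.

    ``dispersion`` selects the ellipse semi-axis estimator: 'median' (the
    robust median-based estimator of the original algorithm, the default) or
    'sd' (plain standard deviation of the velocities).  The robust default
    matters: the saccades themselves inflate the plain SD, which silently
    raises the threshold on busy epochs and costs recall for small events.
    An all-constant trace yields no events (sigma = 0 is guarded);
    non-uniform sampling raises.
    """
    t_ms = np.asarray(t_ms, dtype=float)
    xy = np.asarray(xy_dva, dtype=float)
    if xy.ndim != 2 or xy.shape[1] != 2 or len(t_ms) != len(xy):
        raise ValueError("xy_dva must be (n_samples, 2) matching t_ms")
    dts = np.diff(t_ms)
    if len(dts) == 0 or not np.allclose(dts, dts[0], rtol=0, atol=1e-6):
        raise ValueError("trace must be uniformly sampled")
    if t_ms[-1] - t_ms[0] < 100.0:
        raise ValueError("trace must be at least 100 ms long")
    dt_s = dts[0] / 1000.0

    v = _ek_velocity(xy, dt_s)
    center = np.median(v, axis=0)
    if dispersion == "sd":
        sig = v.std(axis=0)
    elif dispersion == "median":
        sig = np.sqrt(np.median(v**2, axis=0) - np.median(v, axis=0) ** 2)
    else:
        raise ValueError("dispersion must be 'sd' or 'median'")
    if np.any(sig <= 0):
        return []
    eta = k_sigma * sig
    crit = ((v[:, 0] - center[0]) / eta[0]) ** 2 + ((v[:, 1] - center[1]) / eta[1]) ** 2
    above = crit > 1.0

    # contiguous supra-threshold runs
    idx = np.flatnonzero(above)
    if len(idx) == 0:
        return []
    breaks = np.flatnonzero(np.diff(idx) > 1)
    run_starts = np.concatenate(([idx[0]], idx[breaks + 1]))
    run_ends = np.concatenate((idx[breaks], [idx[-1]]))

    min_samples = max(1, int(round(min_duration_ms / dts[0])))
    pad = max(1, int(round(8.0 / dts[0])))  # displacement tails fall below threshold
    candidates = []
    for s, e in zip(run_starts, run_ends):
        if e - s + 1 < min_samples:
            continue
        speed = np.hypot(v[s : e + 1, 0], v[s : e + 1, 1])
        disp = xy[min(e + pad, len(xy) - 1)] - xy[max(s - pad, 0)]
        candidates.append(
            {
                "onset": t_ms[s],
                "offset": t_ms[e],
                "amplitude": float(np.hypot(*disp)),
                "peak": float(speed.max()),
                "direction": float(np.degrees(np.arctan2(disp[1], disp[0]))),
            }
        )
    if not candidates:
        return []

    # temporal proximity: discard the later of two events closer than merge_ms
    merged = [candidates[0]]
    for ev in candidates[1:]:
        if ev["onset"] - merged[-1]["offset"] < merge_ms:
            continue
        merged.append(ev)

    kept = [ev for ev in merged if ev["amplitude"] < max_dev_dva]
    if not kept:
        return []
    peaks = np.array([ev["peak"] for ev in kept])
    cutoff = peaks.mean() + outlier_sigma * peaks.std()
    kept = [ev for ev in kept if ev["peak"] <= cutoff]

    return [
        MicrosaccadeEvent(
            onset_ms=ev["onset"],
            offset_ms=ev["offset"],
            amplitude_dva=ev["amplitude"],
            peak_velocity_dva_per_s=ev["peak"],
            direction_deg=ev["direction"],
        )
        for ev in kept
    ]


def detect_all(
    trace_set, trials: pd.DataFrame | None = None, **kwargs
) -> pd.DataFrame:
    """Run the detector on every trace of a GazeTraceSet; tidy events table."""
    rows = []
    for i, tid in enumerate(trace_set.trial_ids):
        for ev in detect_microsaccades(trace_set.t_ms, trace_set.data[i], **kwargs):
            rows.append(
                {
                    "trial_id": tid,
                    "onset_ms": ev.onset_ms,
                    "offset_ms": ev.offset_ms,
                    "amplitude_dva": ev.amplitude_dva,
                    "peak_vel": ev.peak_velocity_dva_per_s,
                    "direction_deg": ev.direction_deg,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["trial_id", "onset_ms", "offset_ms", "amplitude_dva", "peak_vel", "direction_deg"],
    )


def _toward_side(direction_deg: np.ndarray, side_is_left: np.ndarray, cone_deg: float) -> np.ndarray:
    """Event points into a side's hemifield within the horizontal cone."""
    d = np.mod(direction_deg + 180.0, 360.0) - 180.0
    toward_right = np.abs(d) <= cone_deg
    toward_left = np.abs(np.abs(d) - 180.0) <= cone_deg
    return np.where(side_is_left, toward_left, toward_right)


def msc_rate_trace(
    events: pd.DataFrame,
    trials: pd.DataFrame,
    direction_cone_deg: float = 45.0,
    window_ms: float = 100.0,
    step_ms: float = 25.0,
    t_range_ms: tuple[float, float] = (-200.0, 800.0),
) -> RateTrace:
    """Directional microsaccade rate per (side x contingency) cell.

    ``events`` is the tidy table from :func:`detect_all` (trial_id, onset_ms,
    direction_deg ...); ``trials`` provides fx_side and contingency per trial
    (indexed by trial_idx).  Rates are mean counts per window across all trials
    of the contingency cell.
    """
    if "fx_side" not in trials.columns or "contingency" not in trials.columns:
        raise ValueError("trials must carry fx_side and contingency columns")
    sess = trials["session_type"].iloc[0]
    conts = CONTINGENCIES[sess]
    starts = np.arange(t_range_ms[0], t_range_ms[1] - window_ms + step_ms / 2, step_ms)
    centers = starts + window_ms / 2.0

    key = "trial_idx" if "trial_idx" in trials.columns else None
    tinfo = trials.set_index(key) if key else trials
    ev = events.merge(
        tinfo[["fx_side", "contingency"]], left_on="trial_id", right_index=True, how="left"
    )
    if ev["fx_side"].isna().any():
        raise ValueError("events reference trials missing from the trial table")

    fx_left = (ev["fx_side"] == "left").to_numpy()
    rates: dict[tuple[str, str], np.ndarray] = {}
    for side in ("FX", "VR"):
        side_is_left = fx_left if side == "FX" else ~fx_left
        tw = _toward_side(ev["direction_deg"].to_numpy(), side_is_left, direction_cone_deg)
        for cont in conts:
            n_cell = int((tinfo["contingency"] == cont).sum())
            if n_cell == 0:
                raise ValueError(f"no trials with contingency {cont}")
            sel = ev.loc[tw & (ev["contingency"] == cont).to_numpy(), "onset_ms"].to_numpy()
            counts = (
                (sel[None, :] >= starts[:, None]) & (sel[None, :] < starts[:, None] + window_ms)
            ).sum(axis=1)
            rates[(side, cont)] = counts / n_cell
    return RateTrace(centers_ms=centers, rates=rates, window_ms=window_ms)


def msc_quantify(
    rate: RateTrace, window_ms: tuple[float, float] = (150.0, 350.0)
) -> dict:
    """Mean rate inside the quantification window per cell, plus per-side
    modulation indices (contingency order fixed per session type)."""
    in_win = (rate.centers_ms >= window_ms[0]) & (rate.centers_ms <= window_ms[1])
    if not in_win.any():
        raise ValueError(f"no rate windows inside {window_ms}")
    scalars = {cell: float(v[in_win].mean()) for cell, v in rate.rates.items()}
    conts = sorted({c for (_, c) in scalars})
    pair = None
    for sess, p in CONTINGENCIES.items():
        if set(conts) == set(p):
            pair = p
    if pair is None:
        raise ValueError("cells do not match a known session's contingencies")
    mods = {
        side: modulation_index(scalars[(side, pair[0])], scalars[(side, pair[1])], side, "msc_rate")
        for side in ("FX", "VR")
    }
    return {"rates": scalars, "modulation": mods}


def fixation_breach_mask(
    trace_set,
    limit_dva: float = 1.0,
    window_ms: tuple[float, float] = (-50.0, 200.0),
) -> np.ndarray:
    """True for trials whose azimuthal gaze stays within +/- limit over the window.

    Mirrors the fixation-control trial exclusion: gaze beyond +/-1 dva azimuth
    between 50 ms pre-stimulus and change offset rejects the trial.
    """
    in_win = (trace_set.t_ms >= window_ms[0]) & (trace_set.t_ms <= window_ms[1])
    keep = np.abs(trace_set.data[:, in_win, 0]).max(axis=1) <= limit_dva
    rate = 1.0 - keep.mean()
    logger.info("fixation-breach rejection rate: %.1f%%", 100 * rate)
    return keep
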