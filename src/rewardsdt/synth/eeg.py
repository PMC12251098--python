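"""Synthetic epoched EEG: 1/f noise + lateralised alpha + ERP-like deflections.

Each epoch spans -1000..+1000 ms around stimulus onset at 250 Hz.  Every
channel carries 1/f noise.  Occipitoparietal channels additionally carry an
alpha oscillation at the planted individual alpha frequency whose envelope on
channels contralateral to a stimulus side is scaled per (side x contingency) in
the pre- and post-stimulus windows — this is how attention-like alpha
suppression and decision-like pre-stimulus suppression are planted.  ERP-like
raised-cosine deflections (negative 150-210 ms "N2pc-like", positive 230-480 ms
"P300-like" on occipitoparietal channels; positive 150-210 ms "P2a-like" on
frontocentral channels) are added contralateral to each stimulus with
condition-dependent window-mean amplitudes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from rewardsdt.behavior import CONTINGENCIES
from rewardsdt.eeg import (
    COMPONENTS,
    DEFAULT_CHANNELS,
    EpochSet,
    FRONTOCENTRAL,
    OCCIPITOPARIETAL,
    hemisphere,
)


@dataclass
class EegEffectSpec:
    """Generator controls; amplitudes in microvolts, window-mean convention.

    ``erp_mean_uv`` maps component -> (side, contingency) -> the window-mean
    amplitude of the deflection evoked contralateral to that side under that
    contingency.  ``alpha_mod_post``/``alpha_mod_pre`` map (side, contingency)
    -> multiplicative envelope factors on contralateral occipitoparietal
    channels (1.0 = no effect; < 1 = suppression).
    """

    iaf_hz: float = 10.0
    alpha_amp_uv: float = 4.0
    alpha_mod_post: dict[tuple[str, str], float] = field(default_factory=dict)
    alpha_mod_pre: dict[tuple[str, str], float] = field(default_factory=dict)
    erp_mean_uv: dict[str, dict[tuple[str, str], float]] = field(default_factory=dict)
    noise_exponent: float = 1.0
    noise_scale_uv: float = 8.0

    def __post_init__(self) -> None:
        if not 7.5 <= self.iaf_hz <= 13.0:
            raise ValueError("iaf_hz must lie in [7.5, 13]")
        for d in (self.alpha_mod_post, self.alpha_mod_pre):
            if any(not np.isfinite(v) for v in d.values()):
                raise ValueError("alpha factors must be finite")


def _sym_mod(base: float, delta_vr: float, delta_fx: float, conts) -> dict:
    c1, c2 = conts
    return {
        ("VR", c1): base + delta_vr / 2, ("VR", c2): base - delta_vr / 2,
        ("FX", c1): base + delta_fx / 2, ("FX", c2): base - delta_fx / 2,
    }


def space_eeg_effect(
    iaf_hz: float = 10.0,
    delta_n2pc_uv: float = 0.75,
    delta_p300_uv: float = 0.75,
    alpha_suppression: float = 0.25,
) -> EegEffectSpec:
    """Attention-like effects: ERP gain and post-stimulus alpha suppression
    contralateral to the higher-reward location, anti-symmetric across sides."""
    conts = CONTINGENCIES["space_specific"]
    c1, c2 = conts
    return EegEffectSpec(
        iaf_hz=iaf_hz,
        erp_mean_uv={
            "N2pc": _sym_mod(-1.5, delta_n2pc_uv, -delta_n2pc_uv, conts),
            "P300": _sym_mod(2.0, delta_p300_uv, -delta_p300_uv, conts),
            "P2a": _sym_mod(1.0, 0.0, 0.0, conts),
        },
        alpha_mod_post={
            ("VR", c1): 1.0 - alpha_suppression, ("VR", c2): 1.0,
            ("FX", c1): 1.0, ("FX", c2): 1.0 - alpha_suppression,
        },
    )


def choice_eeg_effect(
    iaf_hz: float = 10.0, pre_alpha_suppression: float = 0.15
) -> EegEffectSpec:
    """Decision-like effects only: pre-stimulus alpha suppression on the VR side
    under the liberal contingency; no ERP or post-stimulus modulation."""
    conts = CONTINGENCIES["choice_specific"]
    c1, c2 = conts
    return EegEffectSpec(
        iaf_hz=iaf_hz,
        erp_mean_uv={
            "N2pc": _sym_mod(-1.5, 0.0, 0.0, conts),
            "P300": _sym_mod(2.0, 0.0, 0.0, conts),
            "P2a": _sym_mod(1.0, 0.0, 0.0, conts),
        },
        alpha_mod_pre={
            ("VR", c1): 1.0 - pre_alpha_suppression, ("VR", c2): 1.0,
            ("FX", c1): 1.0, ("FX", c2): 1.0,
        },
    )


def _one_over_f_noise(
    rng: np.random.Generator, shape: tuple, n_samples: int, fs: float,
    exponent: float, scale: float,
) -> np.ndarray:
    """1/f^exponent noise, std `scale`, generated spectrally."""
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / fs)
    gain = np.zeros_like(freqs)
    gain[1:] = freqs[1:] ** (-exponent / 2.0)
    white = rng.standard_normal(shape + (n_samples,))
    spec = np.fft.rfft(white, axis=-1) * gain
    x = np.fft.irfft(spec, n=n_samples, axis=-1)
    sd = x.std()
    return x * (scale / sd) if sd > 0 else x


def _raised_cosine(t_ms: np.ndarray, window: tuple[float, float]) -> np.ndarray:
    """Template with unit window-mean over its support."""
    t0, t1 = window
    w = np.zeros_like(t_ms)
    inside = (t_ms >= t0) & (t_ms <= t1)
    w[inside] = 1.0 - np.cos(2.0 * np.pi * (t_ms[inside] - t0) / (t1 - t0))
    return w


def generate_eeg_epochs(
    trials: pd.DataFrame,
    effect: EegEffectSpec | None = None,
    fs: float = 250.0,
    channels: list[str] | None = None,
    seed: int | None = None,
    t_range_ms: tuple[float, float] = (-1000.0, 1000.0),
) -> EpochSet:
    """Generate one epoch per trial with the planted effects of ``effect``."""
    if effect is None:
        sess = trials["session_type"].iloc[0]
        effect = space_eeg_effect() if sess == "space_specific" else choice_eeg_effect()
    channels = list(channels) if channels is not None else list(DEFAULT_CHANNELS)
    required = set(OCCIPITOPARIETAL) | set(FRONTOCENTRAL)
    missing = sorted(required - set(channels))
    if missing:
        raise ValueError(f"missing required channels: {missing}")

    rng = np.random.default_rng(seed)
    dt = 1000.0 / fs
    t_ms = np.arange(t_range_ms[0], t_range_ms[1], dt)
    n_s = len(t_ms)
    n_t = len(trials)
    n_c = len(channels)

    data = _one_over_f_noise(
        rng, (n_t, n_c), n_s, fs, effect.noise_exponent, effect.noise_scale_uv
    )

    # role of the hemifield each channel is contralateral to, per trial
    fx_left = (trials["fx_side"] == "left").to_numpy()
    cont = trials["contingency"].to_numpy()
    ch_hemi_left = np.array([hemisphere(ch) == "left" for ch in channels])
    # left-hemisphere channel <- right hemifield stimulus
    contra_is_fx = np.where(
        ch_hemi_left[None, :], ~fx_left[:, None], fx_left[:, None]
    )  # (trials, channels)

    def factor_matrix(mod: dict[tuple[str, str], float]) -> np.ndarray:
        out = np.ones((n_t, n_c))
        for (side, co), val in mod.items():
            m = (contra_is_fx == (side == "FX")) & (cont == co)[:, None]
            out[m] = val
        return out

    # alpha oscillation on occipitoparietal channels
    op_mask = np.array([ch in OCCIPITOPARIETAL for ch in channels])
    if op_mask.any() and effect.alpha_amp_uv > 0:
        pre_f = factor_matrix(effect.alpha_mod_pre)[:, op_mask]
        post_f = factor_matrix(effect.alpha_mod_post)[:, op_mask]
        ramp = np.clip((t_ms - 250.0) / 200.0, 0.0, 1.0)  # settle by 450 ms
        envelope = pre_f[:, :, None] * (1 - ramp) + post_f[:, :, None] * ramp
        phase = rng.uniform(0, 2 * np.pi, (n_t, op_mask.sum(), 1))
        osc = np.sin(2 * np.pi * effect.iaf_hz * t_ms[None, None, :] / 1000.0 + phase)
        data[:, op_mask, :] += effect.alpha_amp_uv * envelope * osc

    # ERP-like deflections, contralateral, condition-dependent window mean
    for comp, amp_map in effect.erp_mean_uv.items():
        reg = COMPONENTS[comp]
        comp_mask = np.array([ch in reg["channels"] for ch in channels])
        if not comp_mask.any():
            continue
        template = _raised_cosine(t_ms, reg["window"])
        amps = np.zeros((n_t, n_c))
        for (side, co), val in amp_map.items():
            m = (contra_is_fx == (side == "FX")) & (cont == co)[:, None]
            amps[m] = val
        data[:, comp_mask, :] += (
            amps[:, comp_mask, None] * template[None, None, :]
        )

    trial_ids = (
        trials["trial_idx"].to_numpy() if "trial_idx" in trials.columns else np.arange(n_t)
    )
    labels = trials.reset_index(drop=True)[
        [c for c in ("contingency", "fx_side", "probe_side", "session_type", "block_valence",
                     "miniblock_idx", "block_idx") if c in trials.columns]
    ]
    return EpochSet(
        data=data, fs=fs, t_ms=t_ms, channels=channels,
        trial_ids=np.asarray(trial_ids), labels=labels,
    )
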