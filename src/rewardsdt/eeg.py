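"""ERP component amplitudes, multitaper spectrograms, IAF-aligned alpha power.

Epoched EEG lives in :class:`EpochSet` (trials x channels x samples, microvolts)
with an HDF5 on-disk layout (`/data`, `/time_ms`, `/channels`, `/trial_ids`,
``fs_hz`` attribute).  Components are quantified from registered electrode sets
and windows (:data:`COMPONENTS`): waveforms are averaged over trials of a
(side x contingency) cell and over the channels contralateral to the stimulus
side, then the window mean is taken.  Spectral analysis uses a single-Slepian
multitaper sliding-window estimate (500 ms window, time-half-bandwidth 1,
zero-padded to a ~0.5 Hz grid); alpha power is quantified in IAF +/- 0.5 Hz,
normalised by the 15-35 Hz mean power of the pre-stimulus baseline window.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import h5py
import numpy as np
import pandas as pd
from scipy import signal

logger = logging.getLogger(__name__)

OCCIPITOPARIETAL = ["PO3", "PO4", "PO7", "PO8", "O1", "O2"]
FRONTOCENTRAL = ["F1", "F2", "F3", "F4", "C1", "C2", "C3", "C4", "FC1", "FC2"]
DEFAULT_CHANNELS = OCCIPITOPARIETAL + FRONTOCENTRAL

#: Component registry: electrode set, quantification window (ms), and the
#: polarity of the canonical deflection.  Electrode sets are data, not code:
#: they can be overridden from the YAML study config.
COMPONENTS = {
    "N2pc": {"channels": OCCIPITOPARIETAL, "window": (150.0, 210.0), "polarity": -1},
    "P2a": {"channels": FRONTOCENTRAL, "window": (150.0, 210.0), "polarity": +1},
    "P300": {"channels": OCCIPITOPARIETAL, "window": (230.0, 480.0), "polarity": +1},
}


def hemisphere(channel: str) -> str:
    """'left' or 'right' from the 10-10 label's trailing digit (odd = left)."""
    digits = "".join(ch for ch in channel if ch.isdigit())
    if not digits:
        raise ValueError(f"midline or unparsable channel {channel!r} has no hemisphere")
    return "left" if int(digits) % 2 == 1 else "right"


def contralateral_channels(channels: list[str], stimulus_hemifield: str) -> list[str]:
    """Channels of ``channels`` contralateral to a stimulus hemifield."""
    if stimulus_hemifield not in ("left", "right"):
        raise ValueError("stimulus_hemifield must be 'left' or 'right'")
    contra = "right" if stimulus_hemifield == "left" else "left"
    return [ch for ch in channels if hemisphere(ch) == contra]


@dataclass
class EpochSet:
    """Epoched multi-channel EEG with per-trial condition labels."""

    data: np.ndarray                 # (n_trials, n_channels, n_samples), microvolts
    fs: float
    t_ms: np.ndarray                 # (n_samples,)
    channels: list[str]
    trial_ids: np.ndarray
    labels: pd.DataFrame | None = None  # per-trial: contingency, fx_side, ...

    def __post_init__(self) -> None:
        if len(set(self.channels)) != len(self.channels):
            raise ValueError("channel names must be unique")
        if self.data.shape != (len(self.trial_ids), len(self.channels), len(self.t_ms)):
            raise ValueError("data shape inconsistent with trial_ids/channels/t_ms")

    def channel_index(self, names: list[str]) -> np.ndarray:
        missing = [n for n in names if n not in self.channels]
        if missing:
            raise KeyError(f"missing channels: {missing}")
        return np.array([self.channels.index(n) for n in names])

    def select_trials(self, mask: np.ndarray) -> "EpochSet":
        return EpochSet(
            data=self.data[mask],
            fs=self.fs,
            t_ms=self.t_ms,
            channels=self.channels,
            trial_ids=self.trial_ids[mask],
            labels=None if self.labels is None else self.labels.loc[mask].reset_index(drop=True),
        )

    def to_hdf5(self, path) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("data", data=self.data.astype(np.float32))
            f.create_dataset("time_ms", data=self.t_ms)
            f.create_dataset("channels", data=np.array(self.channels, dtype=object),
                             dtype=h5py.string_dtype("utf-8"))
            f.create_dataset("trial_ids", data=np.asarray(self.trial_ids, dtype=np.int64))
            f.attrs["fs_hz"] = self.fs

    @classmethod
    def from_hdf5(cls, path, labels: pd.DataFrame | None = None) -> "EpochSet":
        with h5py.File(path, "r") as f:
            return cls(
                data=f["data"][()].astype(float),
                fs=float(f.attrs["fs_hz"]),
                t_ms=f["time_ms"][()],
                channels=[c.decode() if isinstance(c, bytes) else str(c) for c in f["channels"][()]],
                trial_ids=f["trial_ids"][()],
                labels=labels,
            )


def read_edf_epochs(path, **kwargs) -> "EpochSet":
    """Adapter stub for EDF recordings; conversion to the HDF5 epoch layout
    is left to external tooling."""
    raise NotImplementedError(
        "EDF import is not implemented; epoch the recording externally and "
        "write the HDF5 layout consumed by EpochSet.from_hdf5"
    )


def read_brainvision_epochs(path, **kwargs) -> "EpochSet":
    """Adapter stub for BrainVision recordings (see :func:`read_edf_epochs`)."""
    raise NotImplementedError(
        "BrainVision import is not implemented; epoch the recording externally "
        "and write the HDF5 layout consumed by EpochSet.from_hdf5"
    )


@dataclass(frozen=True)
class ErpComponentResult:
    component: str
    side: str
    contingency: str
    amplitude_uv: float
    n_trials: int


@dataclass
class SpectralResult:
    """Sliding-window multitaper power: (trials, frequencies, window centers)."""

    power: np.ndarray
    freqs_hz: np.ndarray
    t_centers_ms: np.ndarray
    fs: float
    iaf_hz: float | None = None
    channel_sets: list[str] = field(default_factory=list)


def preprocess_epochs(
    epochs: EpochSet,
    band_hz: tuple[float, float] = (0.5, 35.0),
    order: int = 4,
    fs_out: float = 250.0,
    erp_trim_ms: tuple[float, float] | None = None,
    baseline_ms: tuple[float, float] = (-200.0, 0.0),
) -> EpochSet:
    """Zero-phase Butterworth band-pass, decimation, and average re-reference.

    With ``erp_trim_ms`` given (e.g. ``(-200, 700)``), the output is trimmed to
    that window and the per-trial/channel mean of ``baseline_ms`` is subtracted,
    matching ERP conventions.  The band edges must respect the output Nyquist.
    """
    nyq_in = epochs.fs / 2.0
    if band_hz[1] >= nyq_in or band_hz[1] >= fs_out / 2.0:
        raise ValueError(f"band {band_hz} outside Nyquist (fs_in={epochs.fs}, fs_out={fs_out})")
    sos = signal.butter(order, band_hz, btype="bandpass", fs=epochs.fs, output="sos")
    # generous padding: the low high-pass edge has a transient of ~1/(2 pi f_lo) s
    padlen = min(epochs.data.shape[-1] - 1, int(3.0 * epochs.fs / band_hz[0]))
    data = signal.sosfiltfilt(sos, epochs.data, axis=-1, padlen=padlen)

    decim = epochs.fs / fs_out
    if decim != 1.0:
        if abs(decim - round(decim)) > 1e-9:
            raise ValueError("fs_in must be an integer multiple of fs_out")
        q = int(round(decim))
        # band-pass at 35 Hz already anti-aliases for fs_out >= 100 Hz
        data = data[..., ::q]
        t_ms = epochs.t_ms[::q]
    else:
        t_ms = epochs.t_ms

    data = data - data.mean(axis=1, keepdims=True)  # average re-reference

    if erp_trim_ms is not None:
        keep = (t_ms >= erp_trim_ms[0]) & (t_ms <= erp_trim_ms[1])
        data = data[..., keep]
        t_ms = t_ms[keep]
        base = (t_ms >= baseline_ms[0]) & (t_ms < baseline_ms[1])
        data = data - data[..., base].mean(axis=-1, keepdims=True)

    return EpochSet(
        data=data, fs=fs_out, t_ms=t_ms, channels=list(epochs.channels),
        trial_ids=epochs.trial_ids, labels=epochs.labels,
    )


def _stimulus_hemifield(labels: pd.DataFrame, side: str) -> pd.Series:
    """Physical hemifield of the FX or VR stimulus, per trial."""
    if side == "FX":
        return labels["fx_side"]
    return labels["fx_side"].map({"left": "right", "right": "left"})


def erp_amplitude(
    epochs: EpochSet,
    component: str,
    side: str,
    contingency: str | None = None,
    registry: dict | None = None,
) -> ErpComponentResult:
    """Window-mean amplitude of a component, contralateral to the ``side`` stimulus.

    Trials are restricted to ``contingency`` when given.  The waveform is
    averaged over trials and over the channels of the component's electrode set
    that lie in the hemisphere contralateral to the stimulus hemifield (which
    may differ across trials when the FX side alternates across blocks).
    """
    reg = (registry or COMPONENTS)[component]
    if epochs.labels is None:
        raise ValueError("epochs must carry per-trial labels for ERP quantification")
    labels = epochs.labels
    mask = np.ones(len(labels), dtype=bool)
    if contingency is not None:
        mask &= (labels["contingency"] == contingency).to_numpy()
    if not mask.any():
        raise ValueError(f"no trials for side={side}, contingency={contingency}")

    window = reg["window"]
    in_win = (epochs.t_ms >= window[0]) & (epochs.t_ms <= window[1])
    hemifield = _stimulus_hemifield(labels, side)
    total = 0.0
    n = 0
    for hf in ("left", "right"):
        m = mask & (hemifield == hf).to_numpy()
        if not m.any():
            continue
        idx = epochs.channel_index(contralateral_channels(reg["channels"], hf))
        total += epochs.data[np.ix_(m, idx)][..., in_win].mean(axis=(1, 2)).sum()
        n += int(m.sum())
    return ErpComponentResult(
        component=component, side=side, contingency=contingency or "all",
        amplitude_uv=float(total / n), n_trials=n,
    )


def multitaper_spectrogram(
    epochs: EpochSet,
    channels: list[str] | None = None,
    window_ms: float = 500.0,
    step_ms: float = 25.0,
    time_halfbandwidth: float = 1.0,
    n_tapers: int = 1,
    pad_to_hz: float = 0.5,
) -> SpectralResult:
    """Single-Slepian sliding-window power, averaged over the given channels.

    Windows are zero-padded so the frequency grid is ~``pad_to_hz``; the step is
    rounded to an integer number of samples.  Power is in (input units)^2.
    Returns power of shape (trials, freqs, window centers).
    """
    nwin = int(round(window_ms * epochs.fs / 1000.0))
    if nwin > epochs.data.shape[-1]:
        raise ValueError("window longer than epoch")
    step = max(1, int(round(step_ms * epochs.fs / 1000.0)))
    nfft = int(2 ** np.ceil(np.log2(epochs.fs / pad_to_hz)))
    tapers = signal.windows.dpss(nwin, time_halfbandwidth, Kmax=max(1, n_tapers))
    if tapers.ndim == 1:
        tapers = tapers[None, :]

    ch_idx = (
        epochs.channel_index(channels) if channels is not None
        else np.arange(len(epochs.channels))
    )
    x = epochs.data[:, ch_idx, :]
    n_trials, n_ch, n_samp = x.shape
    starts = np.arange(0, n_samp - nwin + 1, step)
    centers = epochs.t_ms[starts] + (nwin - 1) / 2.0 * (1000.0 / epochs.fs)

    # (trials, channels, windows, nwin) strided view; FFT in trial chunks to
    # bound peak memory
    segs = np.lib.stride_tricks.sliding_window_view(x, nwin, axis=-1)[:, :, starts, :]
    power = np.empty((n_trials, nfft // 2 + 1, len(starts)))
    chunk = max(1, int(2e7 // (n_ch * len(starts) * nfft)))
    for lo in range(0, n_trials, chunk):
        sl = slice(lo, min(lo + chunk, n_trials))
        acc = 0.0
        for k in range(tapers.shape[0]):
            spec = np.fft.rfft(segs[sl] * tapers[k], n=nfft, axis=-1)
            acc = acc + (spec.real**2 + spec.imag**2).mean(axis=1)
        power[sl] = np.transpose(acc, (0, 2, 1))
    power /= tapers.shape[0] * epochs.fs  # PSD-like scaling, per taper average
    # one-sided correction (all bins except DC/Nyquist appear twice)
    power[:, 1:-1, :] *= 2.0
    freqs = np.fft.rfftfreq(nfft, d=1.0 / epochs.fs)
    return SpectralResult(
        power=power, freqs_hz=freqs, t_centers_ms=centers, fs=epochs.fs,
        channel_sets=[epochs.channels[i] for i in ch_idx],
    )


def estimate_iaf(
    spec: SpectralResult,
    search_band_hz: tuple[float, float] = (7.5, 13.0),
    baseline_window_ms: tuple[float, float] = (-500.0, 0.0),
) -> float:
    """Individual alpha frequency: peak of trial-mean baseline power in the band.

    Ties break toward the lowest frequency; a peak sitting on the band edge is
    returned with a warning (no strictly interior maximum).
    """
    in_base = (spec.t_centers_ms >= baseline_window_ms[0]) & (
        spec.t_centers_ms <= baseline_window_ms[1]
    )
    if not in_base.any():
        raise ValueError("baseline window outside epoch")
    in_band = (spec.freqs_hz >= search_band_hz[0]) & (spec.freqs_hz <= search_band_hz[1])
    profile = spec.power[:, :, in_base].mean(axis=(0, 2))[in_band]
    freqs = spec.freqs_hz[in_band]
    peak = int(np.argmax(profile))  # argmax returns the first (lowest-f) maximum
    if peak in (0, len(freqs) - 1):
        logger.warning("IAF peak on the %.1f-%.1f Hz band boundary", *search_band_hz)
    return float(freqs[peak])


def alpha_power(
    spec: SpectralResult,
    iaf_hz: float,
    window: str = "post",
    post_window_ms: tuple[float, float] = (450.0, 950.0),
    pre_window_ms: tuple[float, float] = (-500.0, 0.0),
    norm_band_hz: tuple[float, float] = (15.0, 35.0),
    baseline_window_ms: tuple[float, float] = (-500.0, 0.0),
) -> np.ndarray:
    """Per-trial normalised alpha power in IAF +/- 0.5 Hz over a window.

    Power is averaged over window centers inside the chosen window ('post' or
    'pre') and over the IAF band, then divided by the trial's mean baseline
    power in the 15-35 Hz band.  Returns one value per trial; average over
    trials of a (side x contingency) cell for the paper-style scalar.
    """
    if window not in ("post", "pre"):
        raise ValueError("window must be 'post' or 'pre'")
    win = post_window_ms if window == "post" else pre_window_ms
    in_alpha = np.abs(spec.freqs_hz - iaf_hz) <= 0.5
    if not in_alpha.any():
        raise ValueError("IAF +/- 0.5 Hz outside the frequency grid")
    in_win = (spec.t_centers_ms >= win[0]) & (spec.t_centers_ms <= win[1])
    if not in_win.any():
        raise ValueError(f"no spectrogram windows inside {win}")
    in_norm = (spec.freqs_hz >= norm_band_hz[0]) & (spec.freqs_hz <= norm_band_hz[1])
    in_base = (spec.t_centers_ms >= baseline_window_ms[0]) & (
        spec.t_centers_ms <= baseline_window_ms[1]
    )
    norm = spec.power[:, in_norm, :][:, :, in_base].mean(axis=(1, 2))
    if np.any(norm <= 0):
        raise ValueError("zero baseline normaliser")
    return spec.power[:, in_alpha, :][:, :, in_win].mean(axis=(1, 2)) / norm


def alpha_suppression_and_lateralization(
    alpha_by_cell: dict[tuple[str, str], float], contingency_pair: tuple[str, str]
) -> dict:
    """Suppression per side (c1 - c2 alpha power) and VR-FX lateralization."""
    c1, c2 = contingency_pair
    supp = {
        side: alpha_by_cell[(side, c1)] - alpha_by_cell[(side, c2)] for side in ("FX", "VR")
    }
    return {"suppression": supp, "lateralization": supp["VR"] - supp["FX"]}
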