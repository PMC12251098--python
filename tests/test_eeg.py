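"""EEG preprocessing, ERP quantification, multitaper spectra, and alpha power."""

import numpy as np
import pandas as pd
import pytest

from rewardsdt.eeg import (
    DEFAULT_CHANNELS,
    EpochSet,
    OCCIPITOPARIETAL,
    alpha_power,
    alpha_suppression_and_lateralization,
    contralateral_channels,
    erp_amplitude,
    estimate_iaf,
    hemisphere,
    multitaper_spectrogram,
    preprocess_epochs,
)

FS = 250.0
T = np.arange(-1000.0, 1000.0, 1000.0 / FS)


def make_epochs(data, labels=None, channels=None, t_ms=T, fs=FS):
    channels = channels or list(DEFAULT_CHANNELS)
    return EpochSet(
        data=data, fs=fs, t_ms=t_ms, channels=channels,
        trial_ids=np.arange(data.shape[0]), labels=labels,
    )


def two_trial_labels():
    return pd.DataFrame(
        {"contingency": ["VR_gt_FX", "VR_gt_FX"], "fx_side": ["left", "left"],
         "session_type": ["space_specific"] * 2}
    )


class TestGeometry:
    def test_hemisphere_parity(self):
        assert hemisphere("PO3") == "left" and hemisphere("PO4") == "right"
        assert hemisphere("O1") == "left" and hemisphere("FC2") == "right"
        with pytest.raises(ValueError):
            hemisphere("Cz")

    def test_contralateral_mapping_is_involution(self):
        left = contralateral_channels(OCCIPITOPARIETAL, "left")
        right = contralateral_channels(OCCIPITOPARIETAL, "right")
        assert set(left) | set(right) == set(OCCIPITOPARIETAL)
        assert set(left) & set(right) == set()
        assert left == ["PO4", "PO8", "O2"]


class TestPreprocess:
    def test_dc_offset_removed(self, rng):
        data = np.full((2, len(DEFAULT_CHANNELS), len(T)), 37.0)
        data += rng.standard_normal(data.shape) * 0.01
        out = preprocess_epochs(make_epochs(data), erp_trim_ms=(-200, 700))
        assert np.abs(out.data.mean()) < 0.1

    def test_50hz_tone_attenuated(self):
        # oracle: the zero-phase (forward-backward) magnitude response of the
        # order-4 Butterworth 0.5-35 Hz band-pass at 50 Hz
        from scipy import signal as sps_signal

        sos = sps_signal.butter(4, (0.5, 35.0), btype="bandpass", fs=FS, output="sos")
        _, h = sps_signal.sosfreqz(sos, worN=[50.0], fs=FS)
        assert np.abs(h[0]) ** 2 < 0.1  # > 20 dB for the double pass

        # and the epoch path attenuates the tone substantially end to end
        tone = np.sin(2 * np.pi * 50.0 * T / 1000.0)
        data = np.tile(tone, (1, len(DEFAULT_CHANNELS), 1))
        data[0, 1:, :] = 0.0  # one active channel against silence
        out = preprocess_epochs(make_epochs(data))
        interior = np.abs(out.t_ms) <= 800.0
        out_rms = np.sqrt((out.data[0, 0, interior] ** 2).mean())
        assert out_rms < np.sqrt((tone**2).mean()) / 3.0

    def test_baseline_window_zero_mean_after_correction(self, rng):
        data = rng.standard_normal((3, len(DEFAULT_CHANNELS), len(T)))
        out = preprocess_epochs(make_epochs(data), erp_trim_ms=(-200, 700))
        base = (out.t_ms >= -200) & (out.t_ms < 0)
        assert np.allclose(out.data[..., base].mean(axis=-1), 0.0, atol=1e-9)

    def test_band_outside_nyquist_rejected(self):
        data = np.zeros((1, len(DEFAULT_CHANNELS), len(T)))
        with pytest.raises(ValueError, match="Nyquist"):
            preprocess_epochs(make_epochs(data), band_hz=(0.5, 130.0))


class TestErp:
    def test_zero_signal_zero_amplitude(self):
        data = np.zeros((2, len(DEFAULT_CHANNELS), len(T)))
        res = erp_amplitude(make_epochs(data, two_trial_labels()), "N2pc", "VR", "VR_gt_FX")
        assert res.amplitude_uv == 0.0

    def test_planted_rectangle_window_mean(self):
        # -1 uV rectangle spanning exactly 150-210 ms on channels contralateral
        # to the VR stimulus (fx left => VR right hemifield => left hemisphere)
        data = np.zeros((2, len(DEFAULT_CHANNELS), len(T)))
        labels = two_trial_labels()
        idx = [DEFAULT_CHANNELS.index(c) for c in ("PO3", "PO7", "O1")]
        win = (T >= 150) & (T <= 210)
        for i in idx:
            data[:, i, win] = -1.0
        res = erp_amplitude(make_epochs(data, labels), "N2pc", "VR", "VR_gt_FX")
        assert res.amplitude_uv == pytest.approx(-1.0, abs=1e-12)
        # ipsilateral side sees nothing
        res_fx = erp_amplitude(make_epochs(data, labels), "N2pc", "FX", "VR_gt_FX")
        assert res_fx.amplitude_uv == 0.0

    def test_window_mean_linearity(self, rng):
        a = rng.standard_normal((2, len(DEFAULT_CHANNELS), len(T)))
        b = rng.standard_normal((2, len(DEFAULT_CHANNELS), len(T)))
        labels = two_trial_labels()
        amp = lambda d: erp_amplitude(make_epochs(d, labels), "P300", "VR", "VR_gt_FX").amplitude_uv
        assert amp(2.0 * a + 3.0 * b) == pytest.approx(2 * amp(a) + 3 * amp(b), rel=1e-9)

    def test_missing_channel_named(self):
        chans = [c for c in DEFAULT_CHANNELS if c != "PO3"]
        data = np.zeros((2, len(chans), len(T)))
        with pytest.raises(KeyError, match="PO3"):
            erp_amplitude(make_epochs(data, two_trial_labels(), channels=chans),
                          "N2pc", "VR", "VR_gt_FX")


class TestSpectrogram:
    def test_stationary_tone_peaks_at_frequency_in_every_window(self):
        tone = np.sin(2 * np.pi * 10.0 * T / 1000.0)
        data = np.tile(tone, (1, 2, 1))
        spec = multitaper_spectrogram(
            make_epochs(data, channels=["O1", "O2"])
        )
        for w in range(spec.power.shape[2]):
            f_peak = spec.freqs_hz[np.argmax(spec.power[0, :, w])]
            assert abs(f_peak - 10.0) <= 0.5

    def test_white_noise_spectrum_flat(self, rng):
        data = rng.standard_normal((40, 1, len(T)))
        spec = multitaper_spectrogram(make_epochs(data, channels=["O1"]))
        band = (spec.freqs_hz >= 5) & (spec.freqs_hz <= 30)
        mean_psd = spec.power[:, band, :].mean(axis=(0, 2))
        slope = np.polyfit(spec.freqs_hz[band], mean_psd / mean_psd.mean(), 1)[0]
        assert abs(slope) < 0.01  # normalised units per Hz

    def test_parseval_band_power_matches_variance(self, rng):
        data = rng.standard_normal((20, 1, len(T)))
        spec = multitaper_spectrogram(make_epochs(data, channels=["O1"]))
        df = spec.freqs_hz[1] - spec.freqs_hz[0]
        integrated = spec.power.sum(axis=1).mean() * df
        assert integrated == pytest.approx(1.0, rel=0.05)  # unit-variance input

    def test_window_longer_than_epoch_rejected(self):
        data = np.zeros((1, 1, 100))
        short = EpochSet(data=data, fs=FS, t_ms=T[:100], channels=["O1"],
                         trial_ids=np.arange(1))
        with pytest.raises(ValueError, match="window"):
            multitaper_spectrogram(short)


class TestIafAndAlpha:
    def _tone_epochs(self, freq, rng, n_trials=8, amp=4.0, noise=1.0):
        data = rng.standard_normal((n_trials, len(OCCIPITOPARIETAL), len(T))) * noise
        phase = rng.uniform(0, 2 * np.pi, (n_trials, 1, 1))
        data += amp * np.sin(2 * np.pi * freq * T[None, None, :] / 1000.0 + phase)
        return make_epochs(data, channels=list(OCCIPITOPARIETAL))

    @pytest.mark.parametrize("freq", [10.0, 7.8])
    def test_planted_iaf_recovered(self, freq, rng):
        spec = multitaper_spectrogram(self._tone_epochs(freq, rng))
        assert estimate_iaf(spec) == pytest.approx(freq, abs=0.5)

    def test_tie_breaks_to_lower_frequency(self):
        power = np.zeros((1, 100, 3))
        freqs = np.linspace(0, 40, 100)
        i, j = 30, 40
        power[0, [i, j], :] = 1.0
        from rewardsdt.eeg import SpectralResult

        spec = SpectralResult(power=power, freqs_hz=freqs,
                              t_centers_ms=np.array([-400.0, 0.0, 400.0]), fs=FS)
        band = (7.5, 13.0)
        est = estimate_iaf(spec, band) if band[0] <= freqs[i] <= band[1] else None
        # both peaks equal: estimate must be the lower in-band frequency
        in_band = freqs[(freqs >= band[0]) & (freqs <= band[1])]
        assert est == pytest.approx(min(f for f in (freqs[i], freqs[j]) if f in in_band))

    def test_identical_conditions_give_zero_suppression(self):
        cells = {("FX", "VR_gt_FX"): 1.3, ("FX", "VR_lt_FX"): 1.3,
                 ("VR", "VR_gt_FX"): 1.3, ("VR", "VR_lt_FX"): 1.3}
        out = alpha_suppression_and_lateralization(cells, ("VR_gt_FX", "VR_lt_FX"))
        assert out["suppression"]["VR"] == 0.0 and out["lateralization"] == 0.0

    def test_normalized_alpha_power_scale_invariant(self, rng):
        epochs = self._tone_epochs(10.0, rng, noise=1.0)
        spec1 = multitaper_spectrogram(epochs)
        doubled = make_epochs(epochs.data * 2.0, channels=list(OCCIPITOPARIETAL))
        spec2 = multitaper_spectrogram(doubled)
        a1 = alpha_power(spec1, 10.0, "post")
        a2 = alpha_power(spec2, 10.0, "post")
        assert np.allclose(a1, a2, rtol=1e-9)

    def test_empty_alpha_window_rejected(self, rng):
        spec = multitaper_spectrogram(self._tone_epochs(10.0, rng))
        with pytest.raises(ValueError, match="windows"):
            alpha_power(spec, 10.0, "post", post_window_ms=(5000.0, 6000.0))
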