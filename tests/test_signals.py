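"""Signal primitives: filtering, montage, analytic signal, transforms,
epoch extraction."""

import numpy as np
import pytest
from scipy import signal as sps

from ripplelock.core import Channel, TimeSeries
from ripplelock.signals import (
    InvalidBandError,
    MontageError,
    analytic_phase_amplitude,
    bandpass_filter,
    bipolar_montage,
    extract_epochs,
    morlet_transform,
    morlet_wavelet,
    stockwell_transform,
)
from ripplelock.signals import _stockwell_rows


def butter_filtfilt_gain(freq, f_lo, f_hi, fs, order=2):
    """Analytic forward-backward Butterworth band-pass magnitude at freq."""
    b, a = sps.butter(order, [f_lo, f_hi], btype="bandpass", fs=fs)
    _, h = sps.freqz(b, a, worN=[freq], fs=fs)
    return np.abs(h[0]) ** 2  # two passes square the magnitude response


class TestBandpass:
    def test_zero_signal_stays_zero(self):
        ts = TimeSeries(np.zeros(16000), 16000.0)
        assert np.allclose(bandpass_filter(ts, 200, 550).data, 0.0)

    @pytest.mark.parametrize("freq,inband", [(400.0, True), (50.0, False)])
    def test_tone_gain_matches_analytic_response(self, freq, inband):
        fs = 16000.0
        t = np.arange(0, 2.0, 1 / fs)
        ts = TimeSeries(np.sin(2 * np.pi * freq * t), fs)
        out = bandpass_filter(ts, 200, 550).data[0]
        amp = np.abs(out[8000:-8000]).max()
        gain = butter_filtfilt_gain(freq, 200, 550, fs)
        if inband:
            assert abs(amp - gain) < 0.01
        else:
            assert amp < gain * 1.5  # below the analytic stopband bound

    def test_band_outside_nyquist_rejected(self):
        ts = TimeSeries(np.zeros(4000), 1000.0)
        with pytest.raises(InvalidBandError):
            bandpass_filter(ts, 200, 600)

    def test_too_short_signal_rejected(self):
        from ripplelock.signals import TooShortError

        with pytest.raises(TooShortError):
            bandpass_filter(TimeSeries(np.zeros(10), 16000.0), 200, 550)

    def test_passband_idempotence(self):
        fs = 16000.0
        t = np.arange(0, 2.0, 1 / fs)
        ts = TimeSeries(np.sin(2 * np.pi * 370 * t), fs)
        once = bandpass_filter(ts, 200, 550)
        twice = bandpass_filter(once, 200, 550)
        a1 = np.abs(once.data[0][8000:-8000]).max()
        a2 = np.abs(twice.data[0][8000:-8000]).max()
        gain = butter_filtfilt_gain(370, 200, 550, fs)
        assert abs(a2 / a1 - gain) < 0.02


class TestBipolarMontage:
    def _probe(self, data, region="FC"):
        chans = [
            Channel(id=f"{region}{i}", region=region, depth_um=-100.0 - 50 * i)
            for i in range(data.shape[0])
        ]
        return TimeSeries(data, 1000.0, channels=chans)

    def test_common_mode_rejection(self, rng):
        x = rng.standard_normal(1000)
        out = bipolar_montage(self._probe(np.vstack([x, x])))
        assert np.allclose(out.data, 0.0)
        assert out.channels[0].montage == "bipolar"

    def test_constant_difference(self):
        c = 3.7
        data = np.vstack([np.full(500, c), np.zeros(500)])
        out = bipolar_montage(self._probe(data))
        assert np.allclose(out.data[0], c)

    def test_sixteen_contacts_brute_force(self, rng):
        data = rng.standard_normal((16, 512))
        out = bipolar_montage(self._probe(data))
        assert out.n_channels == 15
        for k in range(15):
            np.testing.assert_array_equal(out.data[k], data[k] - data[k + 1])
            assert out.channels[k].sources == (f"FC{k}", f"FC{k + 1}")

    def test_single_channel_rejected(self):
        with pytest.raises(MontageError):
            bipolar_montage(self._probe(np.zeros((1, 100))))


class TestAnalyticSignal:
    def test_cosine_phase_and_slope(self):
        fs = 1000.0
        t = np.arange(0, 5, 1 / fs)
        ts = TimeSeries(np.cos(2 * np.pi * 4 * t), fs)
        a = analytic_phase_amplitude(ts, (3, 5))
        # phase 0 at peaks (t = 0.25 k s away from edges)
        for tp in (1.0, 2.0, 3.0):
            assert abs(a.phase[int(tp * fs)]) < 0.05
        slope = np.polyfit(t[500:-500], np.unwrap(a.phase)[500:-500], 1)[0]
        assert abs(slope - 2 * np.pi * 4) / (2 * np.pi * 4) < 0.01

    def test_envelope_recovers_amplitude(self):
        fs = 1000.0
        t = np.arange(0, 5, 1 / fs)
        ts = TimeSeries(2.5 * np.cos(2 * np.pi * 4 * t), fs)
        a = analytic_phase_amplitude(ts, (3, 5))
        assert np.allclose(a.amplitude[1000:-1000], 2.5, rtol=0.01)

    def test_am_carrier_envelope_correlation(self):
        fs = 1000.0
        t = np.arange(0, 5, 1 / fs)
        mod = 1 + 0.5 * np.cos(2 * np.pi * 4 * t)
        ts = TimeSeries(mod * np.cos(2 * np.pi * 27 * t), fs)
        a = analytic_phase_amplitude(ts, (20, 34))
        r = np.corrcoef(a.amplitude[1000:-1000], mod[1000:-1000])[0, 1]
        assert r > 0.99

    def test_negated_signal_phase_shifts_by_pi(self, rng):
        fs = 1000.0
        x = rng.standard_normal(4000)
        a = analytic_phase_amplitude(TimeSeries(x, fs), (3, 6))
        b = analytic_phase_amplitude(TimeSeries(-x, fs), (3, 6))
        d = np.angle(np.exp(1j * (a.phase - b.phase)))
        assert np.allclose(np.abs(d[500:-500]), np.pi, atol=1e-6)


class TestStockwell:
    def test_constant_signal_concentrates_at_dc(self):
        ts = TimeSeries(np.full(256, 2.0), 256.0)
        tf = stockwell_transform(ts, 50)
        mags = np.abs(tf.values).mean(axis=1)
        assert np.argmax(mags) == 0
        # non-DC leakage bounded by the frequency-Gaussian tail exp(-2 pi^2)
        assert mags[1:].max() < 1e-6 * mags[0]

    def test_matches_brute_force_definition(self, rng):
        x = rng.standard_normal(128)
        fast = _stockwell_rows(x)
        N = 128
        H = np.fft.fft(x) / N
        m = np.fft.fftfreq(N) * N
        brute = np.zeros((N // 2 + 1, N), complex)
        brute[0] = x.mean()
        for n in range(1, N // 2 + 1):
            gauss = np.exp(-2 * np.pi**2 * m**2 / n**2)
            for j in range(N):
                brute[n, j] = np.sum(
                    np.roll(H, -n) * gauss * np.exp(2j * np.pi * m * j / N)
                )
        assert np.abs(fast - brute).max() < 1e-9

    def test_tone_localization(self):
        fs = 256.0
        t = np.arange(256) / fs
        tf = stockwell_transform(TimeSeries(np.sin(2 * np.pi * 10 * t), fs), 50)
        peak_row = np.argmax(np.abs(tf.values).mean(axis=1))
        assert tf.freqs[peak_row] == pytest.approx(10.0, abs=1.0)

    def test_fmax_above_nyquist_rejected(self):
        with pytest.raises(InvalidBandError):
            stockwell_transform(TimeSeries(np.zeros(128), 100.0), 80)


class TestMorlet:
    def test_tone_peak_at_nearest_bin(self):
        fs = 500.0
        t = np.arange(0, 4, 1 / fs)
        tf = morlet_transform(
            TimeSeries(np.sin(2 * np.pi * 11 * t), fs), freqs=np.arange(5.0, 20.0)
        )
        mid = slice(500, 1500)
        peak = np.argmax(np.abs(tf.values[:, mid]).mean(axis=1))
        assert tf.freqs[peak] == pytest.approx(11.0, abs=0.5)

    def test_zero_signal_zero_map(self):
        tf = morlet_transform(TimeSeries(np.zeros(1000), 500.0), freqs=[10.0])
        assert np.allclose(tf.values, 0.0)

    def test_matches_direct_convolution(self, rng):
        fs = 256.0
        x = rng.standard_normal(512)
        tf = morlet_transform(TimeSeries(x, fs), freqs=[10.0])
        w = morlet_wavelet(10.0, fs)
        half = (w.size - 1) // 2
        pad = min(half, x.size - 1)
        xp = np.pad(x, pad, mode="reflect")
        direct = np.convolve(xp, w, mode="same")[pad : pad + 512]
        assert np.abs(tf.values[0] - direct).max() < 1e-9

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            morlet_transform(TimeSeries(np.zeros(100), 100.0), freqs=[])


class TestExtractEpochs:
    def test_index_arithmetic(self):
        fs = 1000.0
        ts = TimeSeries(np.arange(5000, dtype=float), fs)
        eps = extract_epochs(ts, [1.0], (-0.2, 0.6))
        assert len(eps) == 1
        assert eps[0].n_samples == 800
        assert eps[0].data[0][0] == 800.0
        assert eps[0].t0 == pytest.approx(-0.2)

    def test_out_of_bounds_dropped(self):
        ts = TimeSeries(np.zeros(5000), 1000.0)
        assert extract_epochs(ts, [0.05], (-0.2, 0.6)) == []

    def test_empty_onsets_empty_result(self):
        ts = TimeSeries(np.zeros(1000), 1000.0)
        assert extract_epochs(ts, [], (-0.1, 0.1)) == []

    def test_epochs_match_direct_slices(self, rng):
        fs = 1000.0
        x = rng.standard_normal(20000)
        ts = TimeSeries(x, fs)
        onsets = rng.uniform(1.0, 19.0, 10)
        eps = extract_epochs(ts, onsets, (-0.2, 0.6))
        assert len(eps) == 10
        for t_on, ep in zip(onsets, eps):
            i = int(np.floor(t_on * fs + 1e-9))
            np.testing.assert_array_equal(ep.data[0], x[i - 200 : i + 600])
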