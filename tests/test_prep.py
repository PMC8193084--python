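import numpy as np
import pytest
from scipy.signal import butter, hilbert, sosfreqz

from eeglrtc.datatypes import TrialSet
from eeglrtc.errors import LengthError, ParameterError
from eeglrtc.prep import (alpha_envelope, bandpass, downsample, exp_smooth,
                          sliding_windows, stitch)

FS = 128.0


def _trialset(data, fs=FS, time0=384):
    data = np.asarray(data, dtype=float)
    if data.ndim == 1:
        data = data[None, None, :]
    n = data.shape[0]
    return TrialSet(data, fs, time0, np.array(["task"] * n),
                    tuple(f"ch{i}" for i in range(data.shape[1]))
                    if data.shape[1] != 3 else ("C3", "Cz", "C4"))


class TestBandpass:
    def test_in_band_passthrough(self):
        t = np.arange(int(10 * FS)) / FS
        x = np.sin(2 * np.pi * 10.0 * t)
        y = bandpass(x, 0.5, 45.0, FS)
        steady = y[int(2 * FS):-int(2 * FS)]
        amp = steady.max()
        assert 0.95 <= amp <= 1.05

    def test_out_of_band_attenuation(self):
        fs = 256.0
        t = np.arange(int(10 * fs)) / fs
        x = np.sin(2 * np.pi * 60.0 * t)
        y = bandpass(x, 0.5, 45.0, fs)
        steady = y[int(2 * fs):-int(2 * fs)]
        amp = np.sqrt(2.0) * np.sqrt(np.mean(steady ** 2))
        att_db = -20.0 * np.log10(max(amp, 1e-30))
        assert att_db >= 20.0
        # oracle: designed transfer function, doubled by the two passes
        sos = butter(4, [0.5, 45.0], "bandpass", fs=fs, output="sos")
        _, h = sosfreqz(sos, worN=[60.0], fs=fs)
        expected_db = -40.0 * np.log10(np.abs(h[0]))
        assert att_db >= min(expected_db, 60.0) - 3.0

    def test_zero_phase(self):
        n = int(6 * FS)
        k = n // 2 + 17
        t = np.arange(n)
        x = np.exp(-0.5 * ((t - k) / 10.0) ** 2)
        y = bandpass(x, 0.5, 45.0, FS)
        assert abs(int(np.argmax(y)) - k) <= 1

    def test_invalid_band(self):
        with pytest.raises(ParameterError):
            bandpass(np.zeros(512), 45.0, 0.5, FS)
        with pytest.raises(ParameterError):
            bandpass(np.zeros(512), 0.5, 70.0, FS)

    def test_too_short(self):
        with pytest.raises(LengthError):
            bandpass(np.zeros(5), 0.5, 45.0, FS)


class TestDownsample:
    def test_8_to_1(self):
        y = downsample(np.zeros(6144), 1024.0, 128.0)
        assert len(y) == 768

    def test_rational_5_to_4(self):
        y = downsample(np.zeros(1120), 160.0, 128.0)
        assert len(y) == 896

    def test_inband_amplitude(self):
        fs_in = 1024.0
        t = np.arange(int(8 * fs_in)) / fs_in
        x = np.sin(2 * np.pi * 10.0 * t)
        y = downsample(x, fs_in, 128.0)
        steady = y[256:-256]
        assert 0.9 <= steady.max() <= 1.1

    def test_upsample_rejected(self):
        with pytest.raises(ParameterError):
            downsample(np.zeros(100), 128.0, 256.0)


class TestSlidingWindows:
    def test_window_counts_6s(self):
        ts = _trialset(np.zeros((2, 3, 768)))
        ws = sliding_windows(ts, 2.0, 0.1)
        assert ws.windows.shape == (2, 3, 41, 256)

    def test_window_counts_7s(self):
        ts = _trialset(np.zeros((1, 3, 896)))
        ws = sliding_windows(ts, 2.0, 0.1)
        assert ws.n_windows == 51

    def test_first_end_time(self):
        ts = _trialset(np.zeros((1, 3, 768)), time0=384)
        ws = sliding_windows(ts)
        assert np.isclose(ws.window_end_times[0], -1.0)
        assert np.allclose(np.diff(ws.window_end_times), 0.1)

    def test_causal_content(self):
        rng = np.random.default_rng(0)
        data = rng.standard_normal((1, 3, 768))
        ts = _trialset(data)
        ws = sliding_windows(ts, taper="none")
        # window reported at t spans [t - 2 s, t]
        j = ws.time_index(0.0)
        start = 384 - 256
        assert np.array_equal(ws.windows[0, 1, j], data[0, 1, start:384])

    def test_no_taper_constant(self):
        ts = _trialset(np.full((1, 3, 768), 3.14))
        ws = sliding_windows(ts, taper="none")
        assert np.all(ws.windows == 3.14)

    def test_taper_endpoints_zeroed(self):
        ts = _trialset(np.ones((1, 3, 768)))
        ws = sliding_windows(ts, taper="hanning")
        assert np.allclose(ws.windows[..., 0], 0.0)

    def test_window_longer_than_trial(self):
        ts = _trialset(np.zeros((1, 3, 100)), time0=50)
        with pytest.raises(LengthError):
            sliding_windows(ts, 2.0, 0.1)


class TestAlphaEnvelope:
    def test_pure_sinusoid_amplitude(self):
        t = np.arange(768) / FS
        a = 2.5
        ts = _trialset(np.tile(a * np.sin(2 * np.pi * 10.0 * t), (1, 3, 1)))
        env = alpha_envelope(ts)
        interior = env.data[0, 0, 128:-128]
        assert np.all(np.abs(interior - a) / a < 0.05)

    def test_demodulation(self):
        t = np.arange(int(20 * FS)) / FS
        mod = 1.0 + 0.5 * np.sin(2 * np.pi * 0.5 * t)
        x = mod * np.sin(2 * np.pi * 10.0 * t)
        ts = _trialset(np.tile(x, (1, 3, 1)))
        env = alpha_envelope(ts)
        sl = slice(256, -256)
        r = np.corrcoef(env.data[0, 0, sl], mod[sl])[0, 1]
        assert r > 0.95

    def test_nonnegative(self, rng):
        ts = _trialset(rng.standard_normal((2, 3, 768)))
        env = alpha_envelope(ts)
        assert env.data.min() >= 0.0


class TestStitch:
    def _windows(self, n_trials, n_samples=768, value=None, seed=0):
        rng = np.random.default_rng(seed)
        data = (rng.standard_normal((n_trials, 3, n_samples))
                if value is None else np.full((n_trials, 3, n_samples), value))
        ts = _trialset(data)
        return sliding_windows(ts, taper="none"), data

    def test_40_trials_80s(self):
        ws, _ = self._windows(40)
        seg = stitch(ws, 0.0, 0)
        assert len(seg.series) == 10240
        assert seg.duration == 80.0

    def test_22_trials_44s(self):
        ws, _ = self._windows(22)
        seg = stitch(ws, 0.0, 0)
        assert len(seg.series) == 5632
        assert seg.duration == 44.0

    def test_two_identical_trials(self):
        ws, data = self._windows(1)
        ws2, _ = self._windows(2)
        ws2.windows[1] = ws2.windows[0]
        seg = stitch(ws2, 0.0, 2)
        assert np.array_equal(seg.series[:256], seg.series[256:])

    def test_roundtrip(self):
        ws, _ = self._windows(5, seed=3)
        j = ws.time_index(0.5)
        seg = stitch(ws, 0.5, 1)
        blocks = seg.series.reshape(5, 256)
        assert np.array_equal(blocks, ws.windows[:, 1, j, :])

    def test_tapered_rejected(self):
        ts = _trialset(np.zeros((3, 3, 768)))
        ws = sliding_windows(ts, taper="hanning")
        with pytest.raises(ParameterError):
            stitch(ws, 0.0, 0)

    def test_off_grid_time(self):
        ws, _ = self._windows(3)
        with pytest.raises(LookupError):
            stitch(ws, 0.123456, 0)


class TestExpSmooth:
    def test_identity_at_alpha_one(self, rng):
        v = rng.standard_normal(50)
        assert np.array_equal(exp_smooth(v, 1.0), v)

    def test_constant_input(self):
        v = np.full(20, 2.5)
        assert np.allclose(exp_smooth(v, 0.3), 2.5)

    def test_unit_step_closed_form(self):
        v = np.r_[0.0, np.ones(10)]
        s = exp_smooth(v, 0.5)
        # after the step: s_k = 1 - (1 - alpha)^k
        assert np.isclose(s[3], 0.875)
        assert np.isclose(s[2], 0.75)

    def test_along_axis(self, rng):
        v = rng.standard_normal((4, 30))
        s = exp_smooth(v, 0.3, axis=-1)
        assert np.allclose(s[2], exp_smooth(v[2], 0.3))

    @pytest.mark.parametrize("alpha", [0.0, -0.1, 1.5])
    def test_alpha_out_of_range(self, alpha):
        with pytest.raises(ParameterError):
            exp_smooth(np.ones(5), alpha)
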