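"""Filtering, resampling, windowing, alpha envelope, stitching, smoothing."""

from __future__ import annotations

from fractions import Fraction

import numpy as np
from scipy.signal import butter, hilbert, resample_poly, sosfiltfilt, lfilter

from .datatypes import StitchedSegment, TrialSet, WindowSeries
from .errors import LengthError, ParameterError

__all__ = ["bandpass", "downsample", "sliding_windows", "alpha_envelope",
           "stitch", "exp_smooth"]

BROADBAND = (0.5, 45.0)
ALPHA_BAND = (8.0, 13.0)

#: reflect padding added before filtfilt, in seconds per edge
PAD_SECONDS = 1.0


def _design(low: float, high: float, order: int, fs: float):
    if not (0.0 < low < high < fs / 2.0):
        raise ParameterError(
            f"band [{low}, {high}] Hz invalid for fs={fs} Hz")
    return butter(order, [low, high], btype="bandpass", fs=fs, output="sos")


def bandpass(series: np.ndarray, low: float, high: float, fs: float,
             order: int = 4, axis: int = -1) -> np.ndarray:
    """Forward-backward (zero-phase) Butterworth band-pass.

    ``order`` is the designed filter order; the two passes double the
    effective magnitude roll-off, as with any filtfilt application.
    """
    series = np.asarray(series, dtype=float)
    sos = _design(low, high, order, fs)
    n = series.shape[axis]
    padlen = min(n - 1, int(round(PAD_SECONDS * fs)))
    if n <= 3 * order:
        raise LengthError(f"series of length {n} too short to filter")
    return sosfiltfilt(sos, series, axis=axis, padlen=padlen)


def downsample(series: np.ndarray, fs_in: float, fs_out: float,
               axis: int = -1) -> np.ndarray:
    """Polyphase anti-aliased resampling to ``fs_out`` (rational ratios)."""
    if fs_out > fs_in:
        raise ParameterError("fs_out must not exceed fs_in")
    if fs_out == fs_in:
        return np.asarray(series, dtype=float)
    ratio = Fraction(fs_out / fs_in).limit_denominator(1000)
    return resample_poly(np.asarray(series, dtype=float),
                         ratio.numerator, ratio.denominator, axis=axis)


def sliding_windows(trialset: TrialSet, window: float = 2.0,
                    step: float = 0.1, taper: str = "hanning"
                    ) -> WindowSeries:
    """Cut causal sliding windows from every trial/channel.

    The window reported at end time ``t`` spans ``[t - window, t]``; the
    first window ends ``window`` seconds after the trial start. With
    ``taper="hanning"`` each window is multiplied by a Hann function.
    """
    if taper not in ("hanning", "none"):
        raise ParameterError("taper must be 'hanning' or 'none'")
    fs = trialset.fs
    wlen = int(round(window * fs))
    step_samp = step * fs  # may be fractional (100 ms at 128 Hz = 12.8)
    n = trialset.n_samples
    if wlen > n:
        raise LengthError(f"window of {wlen} samples exceeds trial length {n}")
    if step_samp < 1:
        raise ParameterError("step shorter than one sample")
    # windows sit on a nominal time grid; starts round to the nearest sample
    n_win = int(np.floor((n - wlen) / step_samp + 1e-9)) + 1
    starts = np.round(np.arange(n_win) * step_samp).astype(int)
    idx = starts[:, None] + np.arange(wlen)[None, :]
    wins = trialset.data[:, :, idx]  # (trials, channels, n_win, wlen)
    if taper == "hanning":
        wins = wins * np.hanning(wlen)
    end_times = ((wlen - trialset.time0_index) / fs
                 + np.arange(n_win) * step)
    return WindowSeries(wins, end_times, window, step, fs, taper,
                        trialset.channels, trialset.conditions.copy())


def alpha_envelope(trialset: TrialSet, band=ALPHA_BAND,
                   order: int = 4) -> TrialSet:
    """8-13 Hz amplitude envelope via the analytic signal.

    The band-pass and Hilbert transform run on the full trial, so
    envelope edge effects stay confined to the trial edges.
    """
    filt = bandpass(trialset.data, band[0], band[1], trialset.fs, order)
    env = np.abs(hilbert(filt, axis=-1))
    return trialset.copy_with(env)


def stitch(ws: WindowSeries, window_end_time: float, channel: int
           ) -> StitchedSegment:
    """Concatenate, in trial order, the window at one end time from every
    trial of one channel. Requires untapered windows (a taper would zero
    the seams and distort long-timescale DFA)."""
    if ws.taper != "none":
        raise ParameterError("stitching requires untapered windows")
    if ws.windows.shape[0] < 2:
        raise ParameterError("need at least 2 trials to stitch")
    j = ws.time_index(window_end_time)
    series = ws.windows[:, channel, j, :].reshape(-1)
    return StitchedSegment(series, ws.fs, float(ws.window_end_times[j]),
                           ws.windows.shape[0])


def exp_smooth(values: np.ndarray, alpha_smooth: float,
               axis: int = -1) -> np.ndarray:
    """Exponential smoothing: s1 = v1, s_k = a*v_k + (1-a)*s_{k-1}.

    NaNs propagate from their first occurrence; callers that need
    NaN-robust smoothing should mask first.
    """
    if not (0.0 < alpha_smooth <= 1.0):
        raise ParameterError("alpha_smooth must lie in (0, 1]")
    v = np.asarray(values, dtype=float)
    if alpha_smooth == 1.0:
        return v.copy()
    v = np.moveaxis(v, axis, -1)
    zi = (1.0 - alpha_smooth) * v[..., :1]
    out, _ = lfilter([alpha_smooth], [1.0, alpha_smooth - 1.0], v,
                     axis=-1, zi=zi)
    return np.moveaxis(out, -1, axis)
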