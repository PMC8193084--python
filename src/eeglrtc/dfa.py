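"""Detrended fluctuation analysis.

The series is mean-centred and integrated; the integrated profile is
partitioned into non-overlapping boxes which are linearly detrended;
the RMS residual per box size gives the fluctuation function, averaged
over a forward partition (boxes anchored at the start) and a backward
one (anchored at the end) so that every sample is covered even when the
length is not a multiple of the box size. The scaling exponent H is the
OLS slope of log2 F(n) against log2 n.
"""

from __future__ import annotations

import numpy as np

from .datatypes import (DFAResult, FeatureTimeCourse, FluctuationFunction,
                        StitchedSegment, WindowSeries)
from .errors import DataError, DegenerateSignalError, LengthError
from .prep import exp_smooth

__all__ = ["integrate_profile", "make_box_grid", "li_timescale_bounds",
           "fluctuation", "dfa_exponent", "dfa_exponent_batch",
           "h_timecourse", "stitched_dfa"]

DEFAULT_N_MIN = 10
DEFAULT_K_SIZES = 25
DEFAULT_SMOOTH_ALPHA = 0.3


def integrate_profile(x: np.ndarray) -> np.ndarray:
    """Cumulative sum of deviations from the mean: y(k) = sum_{i<=k}(x_i - xbar)."""
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or len(x) < 2:
        raise LengthError("need a 1-D series of length >= 2")
    if not np.all(np.isfinite(x)):
        raise DataError("series contains NaN or Inf")
    return np.cumsum(x - x.mean())


def make_box_grid(n_samples: int, n_min: int = DEFAULT_N_MIN,
                  k_sizes: int = DEFAULT_K_SIZES) -> np.ndarray:
    """Integer box sizes, log2-equidistant between ``n_min`` and ``N/4``.

    Nearest-integer rounding with order-preserving de-duplication; when
    collisions shrink the grid the realised count is returned as-is.
    """
    n_max = n_samples // 4
    if n_max <= n_min:
        raise LengthError(
            f"window too short for DFA: N={n_samples} gives N/4={n_max} "
            f"<= n_min={n_min}")
    sizes = np.round(2.0 ** np.linspace(np.log2(n_min), np.log2(n_max),
                                        k_sizes)).astype(int)
    return np.unique(sizes)


def li_timescale_bounds(fs: float, f_min: float, f_max: float,
                        n_samples: int, detrend_order: int = 1):
    """Admissible DFA box-size range for band-limited data:
    [max(k+2, fs/f_max), min(N/4, fs/f_min)] with k the detrending order."""
    lo = max(detrend_order + 2, fs / f_max)
    hi = min(n_samples / 4.0, fs / f_min)
    return lo, hi


def _fluctuation_batch(y: np.ndarray, sizes: np.ndarray) -> np.ndarray:
    """F(n) for a batch of integrated profiles, shape (B, N) -> (B, k)."""
    b_sz, n_samp = y.shape
    f = np.empty((b_sz, len(sizes)))
    for j, n in enumerate(sizes):
        nb = n_samp // n
        cov = nb * n
        t = np.arange(n, dtype=float)
        tc = t - t.mean()
        vt = float((tc ** 2).sum())
        halves = []
        for seg in (y[:, :cov].reshape(b_sz, nb, n),
                    y[:, n_samp - cov:].reshape(b_sz, nb, n)):
            slope = (seg * tc).sum(axis=2) / vt
            resid = (seg - seg.mean(axis=2, keepdims=True)
                     - slope[..., None] * tc)
            halves.append(np.sqrt((resid ** 2).sum(axis=(1, 2)) / cov))
        f[:, j] = 0.5 * (halves[0] + halves[1])
    return f


def fluctuation(x: np.ndarray, sizes=None) -> FluctuationFunction:
    """Forward/backward-averaged RMS fluctuation function of one series."""
    y = integrate_profile(x)
    if sizes is None:
        sizes = make_box_grid(len(y))
    sizes = np.asarray(sizes, dtype=int)
    if sizes.max() > len(y):
        raise LengthError("largest box exceeds series length")
    f = _fluctuation_batch(y[None, :], sizes)[0]
    return FluctuationFunction(sizes, f)


def _fit_loglog(sizes: np.ndarray, f: np.ndarray):
    lg_n = np.log2(sizes)
    lg_f = np.log2(f)
    slope, intercept = np.polyfit(lg_n, lg_f, 1)
    pred = slope * lg_n + intercept
    ss_res = float(((lg_f - pred) ** 2).sum())
    ss_tot = float(((lg_f - lg_f.mean()) ** 2).sum())
    r2 = 1.0 if ss_tot == 0.0 and ss_res == 0.0 else 1.0 - ss_res / ss_tot
    return float(slope), float(intercept), r2


def dfa_exponent(x: np.ndarray, sizes=None) -> DFAResult:
    """DFA scaling exponent of one series (slope of log2 F vs log2 n)."""
    flucs = fluctuation(x, sizes)
    if np.any(flucs.f <= 0.0):
        raise DegenerateSignalError(
            "zero fluctuation at some box size (constant or linear input)")
    h, intercept, r2 = _fit_loglog(flucs.sizes, flucs.f)
    return DFAResult(h, intercept, r2, flucs)


def dfa_exponent_batch(windows: np.ndarray, sizes=None):
    """Vectorised exponents for a stack of equal-length series.

    Parameters
    ----------
    windows : ndarray, shape (..., N)

    Returns
    -------
    h, r2 : ndarrays of shape ``windows.shape[:-1]``; degenerate windows
        (zero fluctuation at any box size) yield NaN.
    """
    w = np.asarray(windows, dtype=float)
    lead = w.shape[:-1]
    n = w.shape[-1]
    flat = w.reshape(-1, n)
    if sizes is None:
        sizes = make_box_grid(n)
    sizes = np.asarray(sizes, dtype=int)
    y = np.cumsum(flat - flat.mean(axis=1, keepdims=True), axis=1)
    f = _fluctuation_batch(y, sizes)
    ok = np.all(f > 0.0, axis=1) & np.all(np.isfinite(f), axis=1)
    h = np.full(flat.shape[0], np.nan)
    r2 = np.full(flat.shape[0], np.nan)
    if ok.any():
        lg_n = np.log2(sizes)
        lg_f = np.log2(f[ok])
        coef = np.polyfit(lg_n, lg_f.T, 1)
        pred = np.outer(lg_n, coef[0]) + coef[1]
        ss_res = ((lg_f.T - pred) ** 2).sum(axis=0)
        ss_tot = ((lg_f - lg_f.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
        h[ok] = coef[0]
        with np.errstate(divide="ignore", invalid="ignore"):
            r2[ok] = np.where(ss_tot > 0, 1.0 - ss_res / ss_tot, 1.0)
    return h.reshape(lead), r2.reshape(lead)


def h_timecourse(ws: WindowSeries, smooth_alpha: float = DEFAULT_SMOOTH_ALPHA,
                 sizes=None, condition: str = "") -> FeatureTimeCourse:
    """Per-window DFA exponents, exponentially smoothed along the window axis.

    Smoothing runs across consecutive windows of each trial/channel;
    ``smooth_alpha=1`` leaves the raw exponents untouched. Windows whose
    fluctuation function is degenerate propagate as NaN and are skipped
    by downstream statistics.
    """
    h, _ = dfa_exponent_batch(ws.windows, sizes)
    if smooth_alpha < 1.0:
        finite = np.isfinite(h)
        if finite.all():
            h = exp_smooth(h, smooth_alpha, axis=-1)
        else:
            sm = exp_smooth(np.where(finite, h, 0.0), smooth_alpha, axis=-1)
            h = np.where(finite, sm, np.nan)
    return FeatureTimeCourse(h, ws.window_end_times, condition, ws.channels)


def stitched_dfa(seg: StitchedSegment, timescale_bounds=(2.0, 20.0),
                 k_sizes: int = DEFAULT_K_SIZES) -> DFAResult:
    """DFA of a stitched segment on a log2-equidistant grid inside the
    given timescale bounds (seconds).

    Bounds are snapped to the enclosing powers of two in samples (the
    grid for [2, 20] s at 128 Hz spans box sizes [2^8, 2^11]; for
    [2, 8] s it spans [2^8, 2^10])."""
    lo_s, hi_s = timescale_bounds
    lo = int(round(lo_s * seg.fs))
    hi = int(round(hi_s * seg.fs))
    n = len(seg.series)
    hi = min(hi, n // 4)
    if hi >= 2 and lo >= 1:
        lo = 2 ** int(np.ceil(np.log2(lo) - 1e-9))
        hi = 2 ** int(np.floor(np.log2(hi) + 1e-9))
    if hi <= lo:
        raise LengthError(
            f"timescale bounds [{lo_s}, {hi_s}] s leave no grid inside "
            f"[{lo}, {n // 4}] samples for a {n}-sample segment")
    sizes = np.unique(np.round(
        2.0 ** np.linspace(np.log2(lo), np.log2(hi), k_sizes)).astype(int))
    return dfa_exponent(seg.series, sizes)
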