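"""Synthetic EEG-like data with ground-truth Hurst dynamics.

Two experimental paradigms are emulated:

* ``asynchronous_tap`` — self-initiated single taps; 6 s trials spanning
  [-3, +3] s around the (possibly jittered) movement onset.
* ``cued_continuous`` — cued continuous task; 7 s trials spanning
  [-3, +4] s around the cue.

Each channel is the sum of three components:

1. a broadband arrhythmic component realised as fractional Gaussian
   noise whose Hurst exponent ramps from ``h_rest`` to ``h_move`` around
   the task interval (cross-fade of two stationary fGn streams);
2. a 10 Hz oscillation amplitude-modulated by a strictly positive,
   slowly varying envelope whose fluctuations carry their own Hurst
   exponent, dropping from ``h_env_rest`` to ``h_env_move`` during the
   task (the same task profile drives both modulations, with opposite
   sign — broadband memory strengthens while envelope memory weakens);
3. additive white Gaussian noise.

Within each generated dataset the slow modulator streams are continuous
across all trials of a condition (trials are consecutive slices of one
session-long realisation), so long memory survives cross-trial
stitching, as it does for trials cut from a continuous recording.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.signal import butter, lfilter, sosfiltfilt

from .datatypes import DEFAULT_CHANNELS, TrialSet
from .errors import ParameterError

__all__ = [
    "SyntheticSpec", "GroundTruth", "gen_fgn", "gen_arfima",
    "gen_alpha_component", "gen_trial", "gen_dataset",
]

PARADIGMS = ("asynchronous_tap", "cued_continuous")
TASK, REST = "task", "rest"

#: moving-average length (s) applied to the raw envelope modulator
ENVELOPE_SMOOTH_S = 0.25
#: softplus operating point: envelope = softplus(bias + depth * modulator)
ENVELOPE_BIAS = 1.0
ENVELOPE_DEPTH = 1.2


@dataclass
class SyntheticSpec:
    """Parameters of a synthetic dataset. All Hurst exponents in [0.5, 1)."""

    fs: float = 128.0
    n_trials_per_condition: int = 40
    paradigm: str = "asynchronous_tap"
    t_pre: float = -3.0
    t_post: float = 3.0
    h_rest: float = 0.60
    h_move: float = 0.75
    h_env_rest: float = 0.80
    h_env_move: float = 0.60
    alpha_amp: float = 0.5
    task_duration: float = 1.5
    onset_jitter: float = 0.0
    pre_onset_lead: float = 1.0   # H starts rising this long before onset
    ramp: float = 0.5             # cross-fade length (s)
    noise_sd: float = 0.15
    notch_alpha_band: bool = True  # carve 7.5-13.5 Hz out of the fGn component
    seed: int = 0
    channels: tuple = DEFAULT_CHANNELS

    def __post_init__(self):
        for name in ("h_rest", "h_move", "h_env_rest", "h_env_move"):
            v = getattr(self, name)
            if not (0.5 <= v < 1.0):
                raise ParameterError(f"{name}={v} must lie in [0.5, 1)")
        if self.fs <= 90.0:
            raise ParameterError("fs must exceed twice the 45 Hz band edge")
        if not (self.t_pre < 0.0 < self.t_post):
            raise ParameterError("t_pre < 0 < t_post required")
        if self.task_duration <= 0:
            raise ParameterError("task_duration must be positive")
        if self.paradigm not in PARADIGMS:
            raise ParameterError(f"paradigm must be one of {PARADIGMS}")
        if self.onset_jitter < 0 or self.ramp <= 0:
            raise ParameterError("onset_jitter >= 0 and ramp > 0 required")

    @property
    def n_samples(self) -> int:
        return int(round((self.t_post - self.t_pre) * self.fs))

    @property
    def time0_index(self) -> int:
        return int(round(-self.t_pre * self.fs))

    def to_dict(self) -> dict:
        d = asdict(self)
        d["channels"] = list(self.channels)
        return d


@dataclass
class GroundTruth:
    """Per-trial truth recorded by the generator."""

    onsets: np.ndarray          # (n_trials,) true onset (s); NaN for rest
    h_bb: np.ndarray            # (n_trials, n_samples) broadband H profile
    h_env: np.ndarray           # (n_trials, n_samples) envelope H profile
    conditions: np.ndarray = field(default=None)

    def concat(self, other: "GroundTruth") -> "GroundTruth":
        return GroundTruth(
            np.concatenate([self.onsets, other.onsets]),
            np.concatenate([self.h_bb, other.h_bb]),
            np.concatenate([self.h_env, other.h_env]),
            np.concatenate([self.conditions, other.conditions]),
        )


def gen_fgn(n_samples: int, h: float, seed=None) -> np.ndarray:
    """Exact fractional Gaussian noise by circulant embedding.

    Zero mean, unit variance in expectation; deterministic given ``seed``
    (an int or a ``numpy.random.Generator``).
    """
    if not (0.0 < h < 1.0):
        raise ParameterError(f"H={h} must lie in (0, 1)")
    if n_samples < 2:
        raise ParameterError("n_samples must be >= 2")
    rng = np.random.default_rng(seed) if not isinstance(
        seed, np.random.Generator) else seed
    n = int(n_samples)
    m = 2 * n
    k = np.arange(n + 1, dtype=float)
    # autocovariance of fGn: gamma(k) = (|k+1|^2H - 2|k|^2H + |k-1|^2H)/2
    g = 0.5 * ((k + 1) ** (2 * h) - 2 * k ** (2 * h)
               + np.abs(k - 1) ** (2 * h))
    c = np.concatenate([g, g[-2:0:-1]])
    lam = np.fft.fft(c).real
    # the fGn embedding is provably non-negative definite; clip float dust
    if lam.min() < -1e-8 * lam.max():
        raise ParameterError("circulant embedding produced negative spectrum")
    lam = np.maximum(lam, 0.0)
    v = np.empty(m, dtype=complex)
    v[0] = np.sqrt(lam[0]) * rng.standard_normal()
    v[n] = np.sqrt(lam[n]) * rng.standard_normal()
    a = rng.standard_normal(n - 1)
    b = rng.standard_normal(n - 1)
    v[1:n] = np.sqrt(lam[1:n] / 2.0) * (a + 1j * b)
    v[n + 1:] = np.conj(v[1:n][::-1])
    return (np.fft.fft(v).real / np.sqrt(m))[:n]


def _frac_integrate_weights(n: int, d: float) -> np.ndarray:
    """Binomial weights of (1 - B)^{-d}, truncated at length n."""
    w = np.empty(n)
    w[0] = 1.0
    for j in range(1, n):
        w[j] = w[j - 1] * (j - 1 + d) / j
    return w


def gen_arfima(n_samples: int, ar_coeffs=(), d: float = 0.0,
               ma_coeffs=(), seed=None) -> np.ndarray:
    """Simulate ARFIMA(p, d, q) with standard-normal innovations.

    The ARMA(p, q) recursion is driven first, then fractionally
    integrated by the truncated binomial expansion of ``(1 - B)^{-d}``.
    With ``d > 0`` and no ARMA terms the DFA exponent of the output is
    approximately ``d + 0.5``.
    """
    if abs(d) >= 0.5:
        raise ParameterError("|d| must be < 0.5 for a stationary ARFIMA")
    if n_samples < 2:
        raise ParameterError("n_samples must be >= 2")
    ar = np.atleast_1d(np.asarray(ar_coeffs, dtype=float)) if len(
        np.atleast_1d(ar_coeffs)) else np.empty(0)
    ma = np.atleast_1d(np.asarray(ma_coeffs, dtype=float)) if len(
        np.atleast_1d(ma_coeffs)) else np.empty(0)
    if ar.size:
        roots = np.roots(np.r_[1.0, -ar][::-1])
        if np.any(np.abs(roots) <= 1.0 + 1e-12):
            raise ParameterError("AR polynomial is not stationary")
    if ma.size:
        roots = np.roots(np.r_[1.0, ma][::-1])
        if np.any(np.abs(roots) <= 1.0 + 1e-12):
            raise ParameterError("MA polynomial is not invertible")
    rng = np.random.default_rng(seed) if not isinstance(
        seed, np.random.Generator) else seed
    eps = rng.standard_normal(int(n_samples))
    arma = lfilter(np.r_[1.0, ma], np.r_[1.0, -ar], eps)
    if d == 0.0:
        return arma
    w = _frac_integrate_weights(int(n_samples), d)
    return lfilter(w, [1.0], arma)


def _smooth_modulator(m: np.ndarray, fs: float) -> np.ndarray:
    """Moving-average the modulator and standardise it."""
    win = max(2, int(round(ENVELOPE_SMOOTH_S * fs)))
    sm = np.convolve(m, np.ones(win) / win, mode="same")
    sd = sm.std()
    if sd > 0:
        sm = (sm - sm.mean()) / sd
    return sm


def _softplus_envelope(mod: np.ndarray, depth: float = ENVELOPE_DEPTH
                       ) -> np.ndarray:
    """Strictly positive envelope; quasi-affine around the operating point."""
    return np.logaddexp(0.0, ENVELOPE_BIAS + depth * mod)


def gen_alpha_component(n_samples: int, fs: float, envelope_h: float,
                        seed=None, amp: float = 1.0,
                        depth: float = ENVELOPE_DEPTH) -> np.ndarray:
    """10 Hz carrier modulated by a positive envelope with Hurst ``envelope_h``.

    ``depth=0`` degenerates to a constant envelope (pure sinusoid).
    """
    if not (0.5 <= envelope_h < 1.0):
        raise ParameterError("envelope_h must lie in [0.5, 1)")
    rng = np.random.default_rng(seed) if not isinstance(
        seed, np.random.Generator) else seed
    mod = _smooth_modulator(gen_fgn(n_samples, envelope_h, rng), fs)
    env = _softplus_envelope(mod, depth)
    t = np.arange(n_samples) / fs
    phase = rng.uniform(0.0, 2.0 * np.pi)
    return amp * env * np.cos(2.0 * np.pi * 10.0 * t + phase)


def _task_weight(spec: SyntheticSpec, onset: float) -> np.ndarray:
    """Cross-fade weight in [0, 1]: 1 inside the task-modulated interval.

    The rise starts ``pre_onset_lead + ramp`` before the onset so that the
    modulation is already elevated at the onset itself (movement
    intention precedes execution)."""
    t = (np.arange(spec.n_samples) - spec.time0_index) / spec.fs
    hi_start = onset - spec.pre_onset_lead
    hi_end = onset + spec.task_duration
    w = np.zeros_like(t)
    rise = (t >= hi_start - spec.ramp) & (t < hi_start)
    fall = (t >= hi_end) & (t < hi_end + spec.ramp)
    w[(t >= hi_start) & (t < hi_end)] = 1.0
    w[rise] = 0.5 - 0.5 * np.cos(np.pi * (t[rise] - hi_start + spec.ramp)
                                 / spec.ramp)
    w[fall] = 0.5 + 0.5 * np.cos(np.pi * (t[fall] - hi_end) / spec.ramp)
    return w


def _session(spec: SyntheticSpec, condition: str, n_trials: int,
             rng: np.random.Generator):
    """One channel-session: (n_trials, n_samples) signal + truth profiles."""
    tlen = spec.n_samples
    n = n_trials * tlen
    fs = spec.fs

    # per-trial onsets and task weights
    onsets = np.full(n_trials, np.nan)
    w = np.zeros((n_trials, tlen))
    if condition == TASK:
        if spec.paradigm == "asynchronous_tap" and spec.onset_jitter > 0:
            onsets[:] = rng.uniform(-spec.onset_jitter / 2,
                                    spec.onset_jitter / 2, n_trials)
        else:
            onsets[:] = 0.0
        for i in range(n_trials):
            w[i] = _task_weight(spec, onsets[i])
    wflat = w.ravel()

    # broadband: per-trial independent cross-fades of two fGn streams
    # (independence keeps trials exchangeable, which null-calibrated
    # statistics and cross-validation rely on)
    x_rest = np.stack([gen_fgn(tlen, spec.h_rest, rng)
                       for _ in range(n_trials)]).ravel()
    x_move = np.stack([gen_fgn(tlen, spec.h_move, rng)
                       for _ in range(n_trials)]).ravel()
    bb = np.sqrt(1.0 - wflat) * x_rest + np.sqrt(wflat) * x_move
    if spec.notch_alpha_band:
        # leave the 8-13 Hz band to the oscillatory component
        sos = butter(4, [7.5, 13.5], "bandstop", fs=fs, output="sos")
        bb = sosfiltfilt(sos, bb.reshape(n_trials, tlen), axis=-1,
                         padlen=min(tlen - 1, 3 * int(fs))).ravel()

    # alpha envelope modulator: session-continuous, opposite modulation
    m_rest = _smooth_modulator(gen_fgn(n, spec.h_env_rest, rng), fs)
    m_move = _smooth_modulator(gen_fgn(n, spec.h_env_move, rng), fs)
    mod = np.sqrt(1.0 - wflat) * m_rest + np.sqrt(wflat) * m_move
    env = _softplus_envelope(mod)
    t = np.arange(n) / fs
    phase = rng.uniform(0.0, 2.0 * np.pi)
    alpha = spec.alpha_amp * env * np.cos(2.0 * np.pi * 10.0 * t + phase)

    sig = bb + alpha + spec.noise_sd * rng.standard_normal(n)

    h_bb = (1.0 - w) * spec.h_rest + w * spec.h_move
    h_env = (1.0 - w) * spec.h_env_rest + w * spec.h_env_move
    return sig.reshape(n_trials, tlen), onsets, h_bb, h_env


def gen_trial(spec: SyntheticSpec, condition: str, seed=None):
    """Generate a single 3-channel trial plus its ground truth."""
    ts, truth = _gen_condition(spec, condition, 1, seed)
    return ts.data[0], GroundTruth(truth.onsets, truth.h_bb, truth.h_env,
                                   truth.conditions)


def _gen_condition(spec: SyntheticSpec, condition: str, n_trials: int,
                   seed=None):
    if condition not in (TASK, REST):
        raise ParameterError(f"condition must be '{TASK}' or '{REST}'")
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    chans = []
    onsets = h_bb = h_env = None
    for _ in spec.channels:  # channels are generated i.i.d.
        sig, onsets, h_bb, h_env = _session(spec, condition, n_trials, rng)
        chans.append(sig)
    data = np.stack(chans, axis=1)  # (trials, channels, samples)
    conds = np.full(n_trials, condition)
    ts = TrialSet(data, spec.fs, spec.time0_index, conds, spec.channels)
    return ts, GroundTruth(onsets, h_bb, h_env, conds)


def gen_dataset(spec: SyntheticSpec, conditions=(TASK, REST)):
    """Generate a labelled TrialSet with ``n_trials_per_condition`` trials
    per requested condition, fully reproducible from ``spec.seed``."""
    root = np.random.default_rng(spec.seed)
    sub = root.spawn(len(conditions))
    parts = [
        _gen_condition(spec, cond, spec.n_trials_per_condition, sub[i])
        for i, cond in enumerate(conditions)
    ]
    data = np.concatenate([ts.data for ts, _ in parts])
    conds = np.concatenate([ts.conditions for ts, _ in parts])
    trialset = TrialSet(data, spec.fs, spec.time0_index, conds, spec.channels)
    truth = parts[0][1]
    for _, gt in parts[1:]:
        truth = truth.concat(gt)
    return trialset, truth
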