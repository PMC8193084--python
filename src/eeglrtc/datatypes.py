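"""Shared data containers.

Time convention: seconds relative to the trial event (movement onset or
task cue) at 0. Sliding windows are labelled by their causal *end* time,
i.e. the window reported at time ``t`` spans ``[t - window_length, t]``.
Sample indexing is 0-based with half-open intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import AlignmentError, ParameterError

DEFAULT_CHANNELS = ("C3", "Cz", "C4")


@dataclass
class TrialSet:
    """Epoched multichannel trials with a common event-relative time axis.

    Attributes
    ----------
    data : ndarray, shape (n_trials, n_channels, n_samples)
    fs : float
        Sampling rate in Hz.
    time0_index : int
        Sample index of the event (onset/cue) within each trial.
    conditions : ndarray of str, shape (n_trials,)
    channels : tuple of str
    """

    data: np.ndarray
    fs: float
    time0_index: int
    conditions: np.ndarray
    channels: tuple = DEFAULT_CHANNELS

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        self.conditions = np.asarray(self.conditions)
        if self.data.ndim != 3:
            raise ParameterError("data must be (trials, channels, samples)")
        if self.fs <= 0:
            raise ParameterError("fs must be positive")
        if not (0 <= self.time0_index < self.data.shape[2]):
            raise ParameterError("time0_index out of bounds")
        if len(self.conditions) != self.data.shape[0]:
            raise ParameterError("one condition label per trial required")
        if len(self.channels) != self.data.shape[1]:
            raise ParameterError("one channel label per channel required")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def times(self) -> np.ndarray:
        """Event-relative time of every sample (s)."""
        return (np.arange(self.n_samples) - self.time0_index) / self.fs

    def select(self, condition: str) -> "TrialSet":
        mask = self.conditions == condition
        return TrialSet(self.data[mask], self.fs, self.time0_index,
                        self.conditions[mask], self.channels)

    def copy_with(self, data: np.ndarray) -> "TrialSet":
        return TrialSet(data, self.fs, self.time0_index,
                        self.conditions.copy(), self.channels)


@dataclass
class WindowSeries:
    """Causal sliding windows cut from every trial and channel.

    ``windows`` has shape (n_trials, n_channels, n_windows, window_samples);
    ``window_end_times`` are event-relative end times in seconds.
    """

    windows: np.ndarray
    window_end_times: np.ndarray
    window_length: float
    step: float
    fs: float
    taper: str = "hanning"
    channels: tuple = DEFAULT_CHANNELS
    conditions: np.ndarray | None = None

    @property
    def n_windows(self) -> int:
        return self.windows.shape[2]

    @property
    def window_samples(self) -> int:
        return self.windows.shape[3]

    def time_index(self, window_end_time: float) -> int:
        idx = np.flatnonzero(np.isclose(self.window_end_times,
                                        window_end_time, atol=1e-6))
        if idx.size == 0:
            raise LookupError(
                f"window end time {window_end_time} s is not on the grid "
                f"[{self.window_end_times[0]:.2f}, "
                f"{self.window_end_times[-1]:.2f}] step {self.step}")
        return int(idx[0])


@dataclass
class StitchedSegment:
    """Concatenation of the same window across all trials."""

    series: np.ndarray
    fs: float
    window_end_time: float
    n_trials_stitched: int
    content: str = "broadband"  # or "alpha_envelope"

    @property
    def duration(self) -> float:
        return len(self.series) / self.fs


@dataclass
class FluctuationFunction:
    """DFA fluctuation magnitude per box size (forward/backward averaged)."""

    sizes: np.ndarray
    f: np.ndarray

    def __post_init__(self):
        self.sizes = np.asarray(self.sizes, dtype=int)
        self.f = np.asarray(self.f, dtype=float)


@dataclass
class DFAResult:
    """Slope/intercept/R^2 of the log2-log2 fluctuation fit."""

    h: float
    intercept: float
    r_squared: float
    fluctuations: FluctuationFunction


@dataclass
class FeatureTimeCourse:
    """Per-trial, per-channel scalar feature at each window end time."""

    values: np.ndarray  # (n_trials, n_channels, n_windows)
    window_end_times: np.ndarray
    condition: str = ""
    channels: tuple = DEFAULT_CHANNELS

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.window_end_times = np.asarray(self.window_end_times, dtype=float)

    def check_aligned(self, other: "FeatureTimeCourse"):
        if (len(self.window_end_times) != len(other.window_end_times)
                or not np.allclose(self.window_end_times,
                                   other.window_end_times, atol=1e-9)):
            raise AlignmentError("window grids differ between time courses")


@dataclass
class ClassifierTimeCourse:
    """Per-window classification performance with chance threshold."""

    accuracy: np.ndarray        # percent, per window
    f1: np.ndarray              # per window, task class positive
    window_end_times: np.ndarray
    threshold: float            # percent
    peak_accuracy: float = field(init=False)
    peak_time: float = field(init=False)
    crossing_time: float | None = field(init=False)

    def __post_init__(self):
        self.accuracy = np.asarray(self.accuracy, dtype=float)
        self.f1 = np.asarray(self.f1, dtype=float)
        self.window_end_times = np.asarray(self.window_end_times, dtype=float)
        i_peak = int(np.argmax(self.accuracy))  # first index on ties
        self.peak_accuracy = float(self.accuracy[i_peak])
        self.peak_time = float(self.window_end_times[i_peak])
        above = np.flatnonzero(self.accuracy > self.threshold)
        self.crossing_time = (float(self.window_end_times[above[0]])
                              if above.size else None)
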