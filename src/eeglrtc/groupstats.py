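"""Group-level time-course statistics."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.stats import kstest, mannwhitneyu, pearsonr, ttest_ind

from .datatypes import FeatureTimeCourse
from .errors import SampleSizeError

logger = logging.getLogger(__name__)

__all__ = ["grand_average", "choose_test", "significance_timecourse",
           "hbb_halpha_correlation", "SignificanceTimeCourse"]


@dataclass
class SignificanceTimeCourse:
    p_values: np.ndarray          # (n_channels, n_windows)
    tests: np.ndarray             # test id per channel/window
    window_end_times: np.ndarray
    alpha: float
    significant_interval: list    # per channel: (start_s, end_s) or None


def grand_average(tc: FeatureTimeCourse):
    """Mean and SD over trials per channel/window, NaNs excluded.

    All-NaN windows yield NaN outputs (logged).
    """
    if tc.values.shape[0] < 2:
        raise SampleSizeError("need at least 2 trials")
    with np.errstate(invalid="ignore"):
        mean = np.nanmean(tc.values, axis=0)
        sd = np.nanstd(tc.values, axis=0, ddof=1)
    n_empty = int(np.sum(np.all(~np.isfinite(tc.values), axis=0)))
    if n_empty:
        logger.warning("%d channel/window cells had no finite values", n_empty)
    return mean, sd


def _normalish(x: np.ndarray, alpha: float = 0.05) -> bool:
    """One-sample KS normality check with parameters estimated from the
    sample (Lilliefors-style caveat accepted)."""
    sd = x.std(ddof=1)
    if sd == 0.0:
        return False
    return kstest(x, "norm", args=(x.mean(), sd)).pvalue >= alpha


def choose_test(samples_a: np.ndarray, samples_b: np.ndarray,
                norm_alpha: float = 0.05) -> str:
    """``"t_test"`` when both groups pass KS normality, else ``"mann_whitney"``."""
    a = np.asarray(samples_a, dtype=float)
    b = np.asarray(samples_b, dtype=float)
    if len(a) < 5 or len(b) < 5:
        raise SampleSizeError("need at least 5 samples per group")
    if _normalish(a, norm_alpha) and _normalish(b, norm_alpha):
        return "t_test"
    return "mann_whitney"


def _run_test(a: np.ndarray, b: np.ndarray, test: str) -> float:
    if test == "t_test":
        return float(ttest_ind(a, b).pvalue)
    return float(mannwhitneyu(a, b, alternative="two-sided").pvalue)


def _longest_run(sig: np.ndarray, times: np.ndarray):
    """Longest contiguous run of True; (start_s, end_s) or None."""
    best = None
    start = None
    for i, s in enumerate(np.append(sig, False)):
        if s and start is None:
            start = i
        elif not s and start is not None:
            if best is None or (i - start) > (best[1] - best[0]):
                best = (start, i)
            start = None
    if best is None:
        return None
    return float(times[best[0]]), float(times[best[1] - 1])


def significance_timecourse(task: FeatureTimeCourse, rest: FeatureTimeCourse,
                            alpha: float = 0.05, test: str | None = None
                            ) -> SignificanceTimeCourse:
    """Per-window two-sided test of task vs rest over trials, per channel.

    ``test`` forces ``"t_test"`` or ``"mann_whitney"``; by default the
    choice is normality-gated per window via :func:`choose_test`. The
    significant interval is the longest contiguous run of p < alpha (no
    multiple-comparison correction, matching per-window reporting).
    """
    task.check_aligned(rest)
    n_ch, n_win = task.values.shape[1], task.values.shape[2]
    p = np.ones((n_ch, n_win))
    used = np.empty((n_ch, n_win), dtype=object)
    for c in range(n_ch):
        for wdx in range(n_win):
            a = task.values[:, c, wdx]
            b = rest.values[:, c, wdx]
            a = a[np.isfinite(a)]
            b = b[np.isfinite(b)]
            if len(a) < 5 or len(b) < 5:
                p[c, wdx] = np.nan
                used[c, wdx] = "none"
                continue
            t_id = test or choose_test(a, b)
            used[c, wdx] = t_id
            p[c, wdx] = _run_test(a, b, t_id)
    intervals = [
        _longest_run(p[c] < alpha, task.window_end_times) for c in range(n_ch)
    ]
    return SignificanceTimeCourse(p, used, task.window_end_times.copy(),
                                  alpha, intervals)


def hbb_halpha_correlation(hbb: np.ndarray, halpha: np.ndarray) -> float:
    """Pearson correlation between aligned stitched-exponent time courses."""
    a = np.asarray(hbb, dtype=float)
    b = np.asarray(halpha, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise SampleSizeError("need equal-length 1-D sequences")
    ok = np.isfinite(a) & np.isfinite(b)
    a, b = a[ok], b[ok]
    if len(a) < 10:
        raise SampleSizeError("need at least 10 aligned windows")
    if np.ptp(a) == 0.0 or np.ptp(b) == 0.0:
        logger.warning("zero variance: correlation undefined")
        return np.nan
    return float(pearsonr(a, b).statistic)
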