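"""Per-window LDA classification of task vs rest from 3-channel H features."""

from __future__ import annotations

import logging

import numpy as np
from scipy.stats import binom
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.metrics import f1_score
from sklearn.model_selection import StratifiedKFold

from .datatypes import ClassifierTimeCourse, FeatureTimeCourse
from .errors import ParameterError, SampleSizeError

logger = logging.getLogger(__name__)

__all__ = ["lda_train", "within_subject_cv", "loso_cv",
           "binomial_threshold", "detect_times"]


def lda_train(features: np.ndarray, labels: np.ndarray
              ) -> LinearDiscriminantAnalysis:
    """Pooled-covariance linear discriminant; shrinkage fallback on
    singular covariance (logged)."""
    x = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise ParameterError("need exactly two classes")
    if counts.min() < 4:
        raise SampleSizeError("need at least 4 samples per class")
    clf = LinearDiscriminantAnalysis(solver="svd")
    try:
        clf.fit(x, y)
        if not np.all(np.isfinite(clf.coef_)):
            raise np.linalg.LinAlgError("non-finite coefficients")
    except np.linalg.LinAlgError:
        logger.warning("singular pooled covariance; refitting with shrinkage")
        clf = LinearDiscriminantAnalysis(solver="lsqr", shrinkage="auto")
        clf.fit(x, y)
    return clf


def binomial_threshold(n_trials: int, alpha: float = 0.05) -> float:
    """Chance-level accuracy bound (%) from the exact binomial tail:
    the smallest k with P(X >= k | Bin(n, 1/2)) <= alpha, as 100 k / n."""
    if n_trials < 10:
        raise ParameterError("n_trials must be >= 10")
    k = int(binom.isf(alpha, n_trials, 0.5)) + 1
    while k > 0 and binom.sf(k - 2, n_trials, 0.5) <= alpha:
        k -= 1  # guard against isf edge rounding
    return 100.0 * k / n_trials


def _clean_window(values: np.ndarray) -> np.ndarray:
    """(trials, channels) feature block with NaN rows dropped."""
    ok = np.all(np.isfinite(values), axis=1)
    return values[ok]


def within_subject_cv(tc_task: FeatureTimeCourse, tc_rest: FeatureTimeCourse,
                      folds: int = 10, reps: int = 10, seed=None,
                      alpha: float = 0.05) -> ClassifierTimeCourse:
    """Repeated stratified k-fold CV per window.

    Rest feature vectors are randomly subsampled (refreshed each
    repetition, seeded) to match the task trial count, so both classes
    are balanced as in a trial-matched design.
    """
    tc_task.check_aligned(tc_rest)
    rng = np.random.default_rng(seed) if not isinstance(
        seed, np.random.Generator) else seed
    n_win = tc_task.values.shape[2]
    acc = np.full(n_win, np.nan)
    f1 = np.full(n_win, np.nan)
    for wdx in range(n_win):
        xt = _clean_window(tc_task.values[:, :, wdx])
        xr = _clean_window(tc_rest.values[:, :, wdx])
        n = min(len(xt), len(xr))
        if n < folds:
            logger.warning("window %d: only %d trials, reducing folds", wdx, n)
        k = max(2, min(folds, n))
        if n < 4:
            continue
        correct = total = 0
        y_true_all, y_pred_all = [], []
        for rep in range(reps):
            sub_t = xt if len(xt) == n else xt[rng.choice(len(xt), n, False)]
            sub_r = xr if len(xr) == n else xr[rng.choice(len(xr), n, False)]
            x = np.vstack([sub_t, sub_r])
            y = np.r_[np.ones(n, dtype=int), np.zeros(n, dtype=int)]
            skf = StratifiedKFold(n_splits=k, shuffle=True,
                                  random_state=int(rng.integers(2 ** 31)))
            for tr_idx, te_idx in skf.split(x, y):
                clf = lda_train(x[tr_idx], y[tr_idx])
                pred = clf.predict(x[te_idx])
                correct += int((pred == y[te_idx]).sum())
                total += len(te_idx)
                y_true_all.append(y[te_idx])
                y_pred_all.append(pred)
        acc[wdx] = 100.0 * correct / total
        f1[wdx] = f1_score(np.concatenate(y_true_all),
                           np.concatenate(y_pred_all), pos_label=1)
    thr = binomial_threshold(max(10, min(tc_task.values.shape[0],
                                         tc_rest.values.shape[0])), alpha)
    return ClassifierTimeCourse(acc, f1, tc_task.window_end_times.copy(), thr)


def loso_cv(datasets, alpha: float = 0.05):
    """Leave-one-participant-out CV.

    ``datasets`` is a sequence of ``(task_tc, rest_tc)`` pairs, one per
    participant, on a common window grid. For each held-out participant
    a per-window LDA is trained on all remaining participants' feature
    vectors and evaluated on the held-out ones. Returns a list of
    per-participant :class:`ClassifierTimeCourse`.
    """
    if len(datasets) < 3:
        raise SampleSizeError("need at least 3 participants")
    ref = datasets[0][0]
    for task_tc, rest_tc in datasets:
        ref.check_aligned(task_tc)
        ref.check_aligned(rest_tc)
    n_win = ref.values.shape[2]
    results = []
    for hold in range(len(datasets)):
        task_h, rest_h = datasets[hold]
        n_eval = min(task_h.values.shape[0], rest_h.values.shape[0])
        acc = np.full(n_win, np.nan)
        f1 = np.full(n_win, np.nan)
        for wdx in range(n_win):
            xt = np.vstack([_clean_window(d[0].values[:, :, wdx])
                            for i, d in enumerate(datasets) if i != hold])
            xr = np.vstack([_clean_window(d[1].values[:, :, wdx])
                            for i, d in enumerate(datasets) if i != hold])
            et = _clean_window(task_h.values[:, :, wdx])
            er = _clean_window(rest_h.values[:, :, wdx])
            if min(len(xt), len(xr)) < 4 or (len(et) + len(er)) == 0:
                continue
            x = np.vstack([xt, xr])
            y = np.r_[np.ones(len(xt), int), np.zeros(len(xr), int)]
            clf = lda_train(x, y)
            xe = np.vstack([et, er])
            ye = np.r_[np.ones(len(et), int), np.zeros(len(er), int)]
            pred = clf.predict(xe)
            acc[wdx] = 100.0 * float((pred == ye).mean())
            f1[wdx] = f1_score(ye, pred, pos_label=1)
        thr = binomial_threshold(max(10, n_eval), alpha)
        results.append(ClassifierTimeCourse(
            acc, f1, ref.window_end_times.copy(), thr))
    return results


def detect_times(ctc: ClassifierTimeCourse, event_time: float = 0.0):
    """(crossing_time, peak_time, lead_time); lead = event - crossing.

    ``crossing_time`` is the first window whose accuracy exceeds the
    chance threshold; missing (None) when the course never crosses.
    """
    if len(ctc.accuracy) == 0:
        raise ParameterError("empty time course")
    crossing = ctc.crossing_time
    lead = None if crossing is None else float(event_time - crossing)
    return crossing, ctc.peak_time, lead
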