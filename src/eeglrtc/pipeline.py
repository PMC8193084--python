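"""End-to-end run: simulate, preprocess, DFA, validate, stats, classify.

Every stage persists its output under the run directory; a manifest
records the config hash, seed and package version so any results bundle
can be regenerated from the manifest alone.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .classify import detect_times, within_subject_cv
from .config import PipelineConfig
from .datatypes import FeatureTimeCourse
from .dfa import fluctuation, h_timecourse, stitched_dfa
from .groupstats import grand_average, significance_timecourse
from .io import write_trials_csv, write_truth_json
from .prep import alpha_envelope, bandpass, sliding_windows, stitch
from .synth import gen_dataset
from .validate import compare_arma_arfima, mldfa, surrogate_test

logger = logging.getLogger(__name__)

__all__ = ["run_pipeline"]


def _tc_to_frame(tc: FeatureTimeCourse) -> pd.DataFrame:
    n_tr, n_ch, n_w = tc.values.shape
    rows = {
        "trial": np.repeat(np.arange(n_tr), n_ch * n_w),
        "channel": np.tile(np.repeat(np.asarray(tc.channels), n_w), n_tr),
        "window_end_time": np.tile(tc.window_end_times, n_tr * n_ch),
        "h": tc.values.ravel(),
    }
    df = pd.DataFrame(rows)
    df["condition"] = tc.condition
    return df


def run_pipeline(config: PipelineConfig, out_dir, seed: int | None = None
                 ) -> dict:
    """Execute the full chain on a synthetic dataset; returns the summary."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if seed is not None:
        config.synth.seed = int(seed)
    rng = np.random.default_rng(config.synth.seed)

    def stage(name):
        logger.info("stage: %s", name)

    summary: dict = {}
    # ------------------------------------------------------------ simulate
    stage("simulate")
    ts, truth = gen_dataset(config.synth)
    write_trials_csv(out / "dataset.csv", ts)
    write_truth_json(out / "truth.json", truth)

    # ---------------------------------------------------------------- prep
    stage("prep")
    p = config.prep
    broadband = ts.copy_with(
        bandpass(ts.data, p.band_low, p.band_high, ts.fs, p.filter_order))
    task_bb = broadband.select("task")
    rest_bb = broadband.select("rest")
    win_task = sliding_windows(task_bb, p.window, p.step, p.taper)
    win_rest = sliding_windows(rest_bb, p.window, p.step, p.taper)

    # ---------------------------------------------------------------- lrtc
    stage("lrtc")
    tc_task = h_timecourse(win_task, config.dfa.smooth_alpha,
                           condition="task")
    tc_rest = h_timecourse(win_rest, config.dfa.smooth_alpha,
                           condition="rest")
    pd.concat([_tc_to_frame(tc_task), _tc_to_frame(tc_rest)]).to_csv(
        out / "hbb_timecourse.csv", index=False)

    # ------------------------------------------------------------ validate
    stage("validate")
    wins = win_task.windows.reshape(-1, win_task.window_samples)
    sel = rng.choice(len(wins), min(config.validate.max_windows, len(wins)),
                     replace=False)
    windows = wins[sel]
    sur = surrogate_test(windows, config.validate.n_shuffles_per_window,
                         seed=rng)
    cmp_res = compare_arma_arfima(
        windows, count_d_parameter=config.validate.count_d_parameter,
        method=config.validate.arma_method)
    ml = mldfa(fluctuation(windows[0]))
    validation = {
        "surrogate_p": sur.p_value,
        "mean_h_shuffled": float(np.nanmean(sur.h_shuffled)),
        "pct_arfima_preferred": cmp_res.pct_arfima_preferred,
        "mldfa_best_by_aic": ml.best_by_aic,
        "mldfa_best_by_bic": ml.best_by_bic,
        "mldfa_r_squared": ml.r_squared,
        "n_windows": int(len(windows)),
    }
    (out / "validation.json").write_text(json.dumps(validation, indent=2))
    summary["validation"] = validation

    # --------------------------------------------------------------- stats
    stage("stats")
    sig = significance_timecourse(tc_task, tc_rest, config.stats.alpha,
                                  config.stats.test)
    mean_t, sd_t = grand_average(tc_task)
    mean_r, sd_r = grand_average(tc_rest)
    frames = []
    for ci, ch in enumerate(ts.channels):
        frames.append(pd.DataFrame({
            "channel": ch, "window_end_time": tc_task.window_end_times,
            "mean_task": mean_t[ci], "sd_task": sd_t[ci],
            "mean_rest": mean_r[ci], "sd_rest": sd_r[ci],
            "p_value": sig.p_values[ci],
        }))
    pd.concat(frames).to_csv(out / "groupstats.csv", index=False)
    summary["significant_intervals"] = {
        ch: sig.significant_interval[ci]
        for ci, ch in enumerate(ts.channels)
    }

    # ------------------------------------------------- stitched alpha LRTC
    stage("stitched alpha")
    env = alpha_envelope(ts, (p.alpha_low, p.alpha_high), p.filter_order)
    win_env_task = sliding_windows(env.select("task"), p.window, p.step,
                                   taper="none")
    bounds = (config.dfa.stitched_lo_s, config.dfa.stitched_hi_s)
    rows = []
    for ci, ch in enumerate(ts.channels):
        for t_end in win_env_task.window_end_times:
            seg = stitch(win_env_task, float(t_end), ci)
            try:
                res = stitched_dfa(seg, bounds)
                rows.append((ch, float(t_end), res.h, res.r_squared))
            except Exception as exc:
                logger.warning("stitched DFA failed at %s/%ss: %s",
                               ch, t_end, exc)
    pd.DataFrame(rows, columns=["channel", "window_end_time", "h_alpha",
                                "r_squared"]).to_csv(
        out / "halpha_stitched.csv", index=False)

    # ------------------------------------------------------------ classify
    stage("classify")
    c = config.classify
    ctc = within_subject_cv(tc_task, tc_rest, c.folds, c.reps,
                            seed=rng, alpha=c.alpha)
    pd.DataFrame({
        "window_end_time": ctc.window_end_times,
        "accuracy": ctc.accuracy, "f1": ctc.f1,
    }).to_csv(out / "classification.csv", index=False)
    crossing, peak_t, lead = detect_times(ctc, event_time=0.0)
    summary["classification"] = {
        "threshold": ctc.threshold, "peak_accuracy": ctc.peak_accuracy,
        "peak_time": peak_t, "crossing_time": crossing, "lead_time": lead,
    }

    # ------------------------------------------------------------ manifest
    manifest = {
        "package": "eeglrtc", "version": __version__,
        "config": config.to_dict(), "config_sha256": config.digest(),
        "seed": config.synth.seed,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    (out / "summary.json").write_text(json.dumps(summary, indent=2))
    return summary
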