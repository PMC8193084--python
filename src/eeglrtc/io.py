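"""Readers and writers for datasets, ground truth and tidy results."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import TrialSet
from .errors import ChannelError, FormatError
from .synth import GroundTruth

__all__ = ["write_trials_csv", "read_trials_csv", "write_truth_json",
           "read_truth_json", "read_continuous_csv", "write_edf_dataset",
           "read_edf_dataset", "read_recording"]


def write_trials_csv(path, ts: TrialSet):
    """Long-format delimited table: trial, channel, sample_index, value
    (+ condition). Sampling metadata goes to ``<path>.meta.json``."""
    n_tr, n_ch, n_s = ts.data.shape
    trial = np.repeat(np.arange(n_tr), n_ch * n_s)
    chan = np.tile(np.repeat(np.asarray(ts.channels), n_s), n_tr)
    samp = np.tile(np.arange(n_s), n_tr * n_ch)
    cond = np.repeat(ts.conditions, n_ch * n_s)
    df = pd.DataFrame({"trial": trial, "channel": chan,
                       "sample_index": samp, "value": ts.data.ravel(),
                       "condition": cond})
    df.to_csv(path, index=False, float_format="%.10g")
    meta = {"fs": ts.fs, "time0_index": int(ts.time0_index),
            "channels": list(ts.channels)}
    Path(str(path) + ".meta.json").write_text(json.dumps(meta))


def read_trials_csv(path) -> TrialSet:
    meta_path = Path(str(path) + ".meta.json")
    if not meta_path.exists():
        raise FormatError(f"missing metadata sidecar {meta_path}")
    meta = json.loads(meta_path.read_text())
    df = pd.read_csv(path)
    required = {"trial", "channel", "sample_index", "value", "condition"}
    if not required.issubset(df.columns):
        raise FormatError(
            f"missing columns {sorted(required - set(df.columns))}")
    channels = meta["channels"]
    trials = np.sort(df["trial"].unique())
    n_s = int(df["sample_index"].max()) + 1
    data = np.empty((len(trials), len(channels), n_s))
    conds = np.empty(len(trials), dtype=object)
    for ti, tr in enumerate(trials):
        sub = df[df["trial"] == tr]
        conds[ti] = sub["condition"].iloc[0]
        for ci, ch in enumerate(channels):
            vals = sub[sub["channel"] == ch].sort_values("sample_index")
            if len(vals) != n_s:
                raise FormatError(
                    f"trial {tr} channel {ch}: {len(vals)} samples, "
                    f"expected {n_s}")
            data[ti, ci] = vals["value"].to_numpy()
    return TrialSet(data, meta["fs"], meta["time0_index"],
                    conds.astype(str), tuple(channels))


def write_truth_json(path, truth: GroundTruth):
    payload = {
        "onsets": [None if np.isnan(v) else float(v) for v in truth.onsets],
        "h_bb": truth.h_bb.tolist(),
        "h_env": truth.h_env.tolist(),
        "conditions": [str(c) for c in truth.conditions],
    }
    Path(path).write_text(json.dumps(payload))


def read_truth_json(path) -> GroundTruth:
    d = json.loads(Path(path).read_text())
    onsets = np.array([np.nan if v is None else v for v in d["onsets"]])
    return GroundTruth(onsets, np.asarray(d["h_bb"]), np.asarray(d["h_env"]),
                       np.asarray(d["conditions"]))


def read_continuous_csv(path, channels=("C3", "Cz", "C4")):
    """Wide-format continuous recording: header row with a ``time``
    column, one column per channel, and an optional ``event`` column.

    Returns ``(data, fs, events)`` with ``data`` (channels x samples)
    and ``events`` a list of ``(time_s, label)``.
    """
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise FormatError(f"cannot parse {path}: {exc}") from exc
    if "time" not in df.columns:
        raise FormatError("continuous file needs a 'time' column")
    for ch in channels:
        if ch not in df.columns:
            raise ChannelError(f"channel '{ch}' absent from {path}")
    t = df["time"].to_numpy(dtype=float)
    if len(t) < 2:
        raise FormatError("need at least 2 samples")
    dt = np.diff(t)
    if not np.allclose(dt, dt[0], rtol=1e-6):
        raise FormatError("non-uniform time axis")
    fs = 1.0 / dt[0]
    data = np.vstack([df[ch].to_numpy(dtype=float) for ch in channels])
    events = []
    if "event" in df.columns:
        ev = df["event"].fillna("").astype(str).to_numpy()
        for i in np.flatnonzero((ev != "") & (ev != "0") & (ev != "0.0")):
            events.append((float(t[i]), ev[i]))
    return data, fs, events


def write_edf_dataset(path, ts: TrialSet):
    """Serialise a TrialSet as one continuous EDF+ file with a trial-start
    annotation per trial (label = condition)."""
    from .edf import write_edf

    n_tr, n_ch, n_s = ts.data.shape
    flat = ts.data.transpose(1, 0, 2).reshape(n_ch, n_tr * n_s)
    events = [((i * n_s + ts.time0_index) / ts.fs, str(ts.conditions[i]))
              for i in range(n_tr)]
    write_edf(path, flat, ts.fs, list(ts.channels), events)


def read_edf_dataset(path, trial_samples: int, time0_index: int) -> TrialSet:
    from .edf import read_edf

    data, fs, labels, events = read_edf(path)
    n_tr = data.shape[1] // trial_samples
    trials = data[:, :n_tr * trial_samples].reshape(
        data.shape[0], n_tr, trial_samples).transpose(1, 0, 2)
    conds = np.array(["unknown"] * n_tr, dtype=object)
    for onset, label in events:
        idx = int(round((onset * fs - time0_index) / trial_samples))
        if 0 <= idx < n_tr:
            conds[idx] = label
    return TrialSet(trials, fs, time0_index, conds.astype(str),
                    tuple(labels))


def read_recording(path, format: str = "delimited",
                   channels=("C3", "Cz", "C4")):
    """Continuous recording + events from EDF or a delimited file."""
    if format == "edf":
        from .edf import read_edf

        data, fs, labels, events = read_edf(path)
        missing = [c for c in channels if c not in labels]
        if missing:
            raise ChannelError(f"channel(s) {missing} absent from {path}")
        sel = [labels.index(c) for c in channels]
        return data[sel], fs, events
    if format == "delimited":
        return read_continuous_csv(path, channels)
    raise FormatError(f"unknown format '{format}'")
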