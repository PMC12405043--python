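"""Delimited-text trial-bundle formats.

Every on-disk artefact is inspectable UTF-8 text:

* force:  ``time_s,force_n,target_n`` (one row per force sample);
* EMG:    one file per muscle, ``time_s,ch1..ch4``;
* spikes: ``unit_id,muscle,spike_time_s,accuracy`` (one row per spike);
* metadata: a small JSON sidecar (level, sampling rates, seed, MVC, hold
  boundaries).

Readers validate headers, monotone time columns and NaNs, and report the
offending line number.  Round-trips preserve force to 1e-6 N and times to
1e-6 s.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .firing import SpikeTrain
from .force import ForceTrace

__all__ = [
    "TrialBundle",
    "ParseError",
    "read_force", "write_force",
    "read_emg", "write_emg",
    "read_spikes", "write_spikes",
    "write_trial_bundle", "read_trial_bundle",
]


class ParseError(ValueError):
    """Malformed trial-bundle file; message names the file and line."""


@dataclass
class TrialBundle:
    """In-memory view of one trial's files."""

    force: ForceTrace
    emg: dict[str, np.ndarray]   # muscle -> (4, n)
    emg_fs: float
    spikes: list[SpikeTrain]
    meta: dict


def _read_table(path, required_cols):
    path = Path(path)
    try:
        df = pd.read_csv(path, comment="#")
    except Exception as exc:  # noqa: BLE001 - surface as parse error
        raise ParseError(f"{path}: unreadable ({exc})") from exc
    missing = [c for c in required_cols if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing} in header")
    bad = df[required_cols].isna().any(axis=1)
    if bad.any():
        # +2: header line plus 1-based indexing
        raise ParseError(f"{path}: NaN at line {int(bad.idxmax()) + 2}")
    return df


def _check_monotone_time(path, t: np.ndarray):
    d = np.diff(t)
    if np.any(d <= 0):
        line = int(np.argmax(d <= 0)) + 3  # second sample of the bad pair
        raise ParseError(f"{path}: time column not strictly increasing "
                         f"at line {line}")


def write_force(trace: ForceTrace, path) -> Path:
    path = Path(path)
    t = trace.times
    target = np.full_like(t, trace.target)
    df = pd.DataFrame({"time_s": np.round(t, 6),
                       "force_n": np.round(trace.samples, 6),
                       "target_n": np.round(target, 6)})
    df.to_csv(path, index=False)
    return path


def read_force(path, level: float = 0.0, hold_start: float = 0.0,
               hold_end: float = 0.0) -> ForceTrace:
    df = _read_table(path, ["time_s", "force_n", "target_n"])
    t = df["time_s"].to_numpy(float)
    _check_monotone_time(path, t)
    fs = 1.0 / np.median(np.diff(t))
    return ForceTrace(samples=df["force_n"].to_numpy(float), fs=float(round(fs, 6)),
                      target=float(df["target_n"].iloc[0]), level=level,
                      hold_start=hold_start, hold_end=hold_end)


def write_emg(samples: np.ndarray, fs: float, path) -> Path:
    """``samples`` is (4, n) for one muscle."""
    samples = np.atleast_2d(samples)
    path = Path(path)
    t = np.arange(samples.shape[1]) / fs
    data = {"time_s": np.round(t, 6)}
    for ch in range(samples.shape[0]):
        data[f"ch{ch + 1}"] = samples[ch]
    pd.DataFrame(data).to_csv(path, index=False, float_format="%.6e")
    return path


def read_emg(path) -> tuple[np.ndarray, float]:
    """Returns ((channels, n) array, fs)."""
    df = _read_table(path, ["time_s", "ch1"])
    t = df["time_s"].to_numpy(float)
    _check_monotone_time(path, t)
    chans = [c for c in df.columns if c.startswith("ch")]
    fs = 1.0 / np.median(np.diff(t))
    return df[chans].to_numpy(float).T, float(round(fs, 4))


def write_spikes(trains: list[SpikeTrain], path) -> Path:
    path = Path(path)
    rows = [{"unit_id": tr.unit_id, "muscle": tr.muscle,
             "spike_time_s": round(float(t), 6),
             "accuracy": round(float(tr.accuracy), 3)}
            for tr in trains for t in tr.spike_times]
    pd.DataFrame(rows, columns=["unit_id", "muscle", "spike_time_s",
                                "accuracy"]).to_csv(path, index=False)
    return path


def read_spikes(path) -> list[SpikeTrain]:
    df = _read_table(path, ["unit_id", "muscle", "spike_time_s", "accuracy"])
    trains = []
    for (uid, muscle), sub in df.groupby(["unit_id", "muscle"], sort=True):
        times = sub["spike_time_s"].to_numpy(float)
        acc = sub["accuracy"].to_numpy(float)
        if not np.all(acc == acc[0]) or not (0 <= acc[0] <= 100):
            raise ParseError(f"{path}: inconsistent or out-of-range accuracy "
                             f"for unit {uid}")
        try:
            trains.append(SpikeTrain(unit_id=str(uid), muscle=str(muscle),
                                     spike_times=np.sort(times),
                                     accuracy=float(acc[0])))
        except ValueError as exc:
            raise ParseError(f"{path}: {exc}") from exc
    return trains


def write_trial_bundle(trial, stem) -> dict[str, Path]:
    """Write one synthetic trial as force/EMG/spike/metadata files.

    ``stem`` is a path prefix; returns a mapping of artefact kind to path.
    """
    stem = Path(stem)
    files: dict[str, Path] = {}
    files["force"] = write_force(trial.force_trace(), stem.with_name(
        stem.name + "_force.csv"))
    for muscle, chans in trial.emg.items():
        files[f"emg_{muscle}"] = write_emg(
            chans, trial.protocol.emg_fs,
            stem.with_name(f"{stem.name}_emg_{muscle}.csv"))
    all_trains = [tr for trains in trial.spikes.values() for tr in trains]
    files["spikes"] = write_spikes(all_trains, stem.with_name(
        stem.name + "_spikes.csv"))
    meta = {"level": trial.level, "mvc": trial.mvc, "seed": trial.seed,
            "force_fs": trial.protocol.force_fs,
            "emg_fs": trial.protocol.emg_fs,
            "hold_start": trial.protocol.hold_start,
            "hold_end": trial.protocol.hold_end,
            "muscles": list(trial.emg),
            "true_thresholds": {m: list(map(float, v))
                                for m, v in trial.true_thresholds.items()}}
    mp = stem.with_name(stem.name + "_meta.json")
    mp.write_text(json.dumps(meta, indent=1, sort_keys=True))
    files["meta"] = mp
    return files


def read_trial_bundle(stem) -> TrialBundle:
    """Read the files written by :func:`write_trial_bundle`."""
    stem = Path(stem)
    meta = json.loads(stem.with_name(stem.name + "_meta.json").read_text())
    force = read_force(stem.with_name(stem.name + "_force.csv"),
                       level=meta["level"], hold_start=meta["hold_start"],
                       hold_end=meta["hold_end"])
    emg = {}
    emg_fs = meta["emg_fs"]
    for muscle in meta["muscles"]:
        chans, fs = read_emg(stem.with_name(f"{stem.name}_emg_{muscle}.csv"))
        if chans.shape[0] != 4:
            raise ParseError(f"{muscle} EMG must have 4 channels")
        emg[muscle] = chans
    spikes = read_spikes(stem.with_name(stem.name + "_spikes.csv"))
    return TrialBundle(force=force, emg=emg, emg_fs=emg_fs, spikes=spikes,
                       meta=meta)
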