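"""Reading, writing and trimming two-sensor trial recordings.

One trial lives in one CSV file: a few ``#``-prefixed header lines carry
metadata (sampling rate, optional class label, free-form key/values),
followed by a header row and 19 columns — ``time_s`` plus the 9 hand
channels and 9 forearm channels in the canonical order
``ax ay az gx gy gz mx my mz`` (accelerometer in g, gyroscope in deg/s,
magnetometer in microtesla).  Values are written with 6 decimal places,
which the round-trip tests treat as the lossless precision.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .errors import InvalidParameterError, TrialParseError
from .synth import CHANNELS

HAND_COLS = tuple(f"hand_{c}" for c in CHANNELS)
FOREARM_COLS = tuple(f"forearm_{c}" for c in CHANNELS)
DATA_COLS = ("time_s",) + HAND_COLS + FOREARM_COLS

_FLOAT_FMT = "%.6f"


@dataclass
class RawTrial:
    """One synchronized two-sensor recording.

    ``hand`` and ``forearm`` are ``(n, 9)`` float arrays in the canonical
    channel order; ``fs`` is the sampling rate in Hz; ``label`` is 0
    (typical) / 1 (impaired) or ``None``; ``meta`` holds free-form
    string key/values (participant id, task, trim history...).
    """

    fs: float
    hand: np.ndarray
    forearm: np.ndarray
    label: int | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.hand = np.asarray(self.hand, dtype=float)
        self.forearm = np.asarray(self.forearm, dtype=float)
        if self.fs <= 0:
            raise InvalidParameterError("fs must be > 0")
        for name, arr in (("hand", self.hand), ("forearm", self.forearm)):
            if arr.ndim != 2 or arr.shape[1] != len(CHANNELS):
                raise InvalidParameterError(f"{name} must have shape (n, 9)")
        if len(self.hand) != len(self.forearm):
            raise InvalidParameterError("hand and forearm streams differ in length")
        if not (np.isfinite(self.hand).all() and np.isfinite(self.forearm).all()):
            raise InvalidParameterError("sensor channels must be finite")
        if self.label is not None and self.label not in (0, 1):
            raise InvalidParameterError("label must be 0, 1 or None")

    def __len__(self) -> int:
        return len(self.hand)

    @property
    def duration(self) -> float:
        """Trial length in seconds."""
        return len(self) / self.fs

    @property
    def t(self) -> np.ndarray:
        """Time stamps in seconds, starting at zero."""
        return np.arange(len(self)) / self.fs

    def channel(self, sensor: str, name: str) -> np.ndarray:
        """One channel by sensor ('hand'/'forearm') and canonical name."""
        arr = {"hand": self.hand, "forearm": self.forearm}[sensor]
        return arr[:, CHANNELS.index(name)]


def write_trial(trial: RawTrial, path: str | os.PathLike) -> str:
    """Write a trial to the documented CSV dialect; returns the path."""
    if len(trial) == 0:
        raise InvalidParameterError("refusing to write an empty trial")
    lines = [f"# imuwrist-trial v1", f"# fs={trial.fs!r}"]
    if trial.label is not None:
        lines.append(f"# label={trial.label}")
    for k, v in trial.meta.items():
        lines.append(f"# meta.{k}={v}")
    frame = pd.DataFrame(
        np.column_stack([trial.t, trial.hand, trial.forearm]), columns=list(DATA_COLS)
    )
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\n".join(lines) + "\n")
        frame.to_csv(fh, index=False, float_format=_FLOAT_FMT)
    return os.fspath(path)


def _parse_header(path: str | os.PathLike):
    fs = None
    label = None
    meta: dict = {}
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line[1:].strip()
            if "=" not in body:
                continue
            key, _, value = body.partition("=")
            key = key.strip()
            if key == "fs":
                fs = float(value)
            elif key == "label":
                label = int(value)
            elif key.startswith("meta."):
                meta[key[5:]] = value
    return fs, label, meta


def read_trial(path: str | os.PathLike, fs_default: float = 100.0) -> RawTrial:
    """Parse a trial CSV, validating columns and every numeric cell.

    A missing column or a non-numeric cell raises :class:`TrialParseError`
    naming the offending column and (0-based) data row.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    fs, label, meta = _parse_header(path)
    frame = pd.read_csv(path, comment="#")
    missing = [c for c in DATA_COLS if c not in frame.columns]
    if missing:
        raise TrialParseError(f"{path}: missing columns {missing}")
    for col in DATA_COLS:
        values = pd.to_numeric(frame[col], errors="coerce")
        bad = values.index[values.isna() & frame[col].notna()]
        if len(bad):
            raise TrialParseError(
                f"{path}: non-numeric value in column '{col}', data row {bad[0]}"
            )
        if values.isna().any():
            row = int(values.index[values.isna()][0])
            raise TrialParseError(f"{path}: empty cell in column '{col}', data row {row}")
        frame[col] = values
    if len(frame) == 0:
        raise TrialParseError(f"{path}: no data rows")
    hand = frame[list(HAND_COLS)].to_numpy(dtype=float)
    forearm = frame[list(FOREARM_COLS)].to_numpy(dtype=float)
    return RawTrial(fs=fs if fs is not None else fs_default, hand=hand,
                    forearm=forearm, label=label, meta=meta)


def trim_startup(trial: RawTrial, trim_seconds: float = 1.0) -> RawTrial:
    """Drop the unstable start-up segment from both sensor streams.

    Removes the first ``round(trim_seconds * fs)`` samples from hand and
    forearm alike, keeping the two streams synchronized, and records the
    trim in the metadata.  ``trim_seconds=0`` is the identity.
    """
    if trim_seconds < 0:
        raise InvalidParameterError("trim_seconds must be >= 0")
    n_trim = int(round(trim_seconds * trial.fs))
    if n_trim >= len(trial):
        raise InvalidParameterError(
            f"trim of {trim_seconds:g}s >= trial duration {trial.duration:g}s"
        )
    if n_trim == 0:
        return trial
    meta = dict(trial.meta)
    meta["trim_seconds"] = f"{float(meta.get('trim_seconds', 0)) + trim_seconds:g}"
    return RawTrial(fs=trial.fs, hand=trial.hand[n_trim:], forearm=trial.forearm[n_trim:],
                    label=trial.label, meta=meta)


def write_manifest(trials_and_paths, path: str | os.PathLike) -> str:
    """Write a YAML dataset manifest listing (trial file, label) pairs."""
    entries = [
        {"path": os.fspath(p), "label": t.label} for t, p in trials_and_paths
    ]
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump({"trials": entries}, fh, sort_keys=False)
    return os.fspath(path)


def read_manifest(path: str | os.PathLike, fs_default: float = 100.0) -> list[RawTrial]:
    """Load every trial listed in a YAML manifest, applying its labels."""
    with open(path, "r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    base = os.path.dirname(os.fspath(path))
    trials = []
    for entry in doc.get("trials", []):
        trial_path = entry["path"]
        if not os.path.isabs(trial_path):
            trial_path = os.path.join(base, trial_path)
        trial = read_trial(trial_path, fs_default=fs_default)
        if entry.get("label") is not None:
            trial.label = int(entry["label"])
        trials.append(trial)
    return trials
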