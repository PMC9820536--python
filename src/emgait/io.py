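"""Reading and writing EMG recordings and result tables.

Canonical on-disk dialect: a ``<stem>.csv`` signal table (optional ``time_s``
column plus one column per channel, e.g. ``Sol-L``) with a ``<stem>.meta.json``
sidecar holding acquisition metadata.  Times are seconds, amplitudes are
unitless floats (no calibration is assumed; downstream statistics are
relative).  Result tables are written as tidy CSV plus a JSON summary.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from .errors import DataError, FormatError, UsageError

GROUPS = ("TTnoEB", "TTx1EB", "TTx2EB")
CONDITIONS = ("pre_drug", "post_drug", "none")
MUSCLES = ("Sol", "TA", "other")
SIDES = ("L", "R", "none")

#: Relative tolerance for deciding that a time column is uniformly sampled.
_TIME_UNIFORMITY_TOL_S = 1e-6


@dataclass(frozen=True)
class ChannelLabel:
    """A muscle/side channel identifier, e.g. soleus of the left hindlimb.

    Round-trips through the text form ``"Sol-L"`` (case-insensitive on parse).
    Channels that are not Sol or TA keep their raw name and muscle ``other``.
    """

    muscle: str
    side: str = "none"
    raw_name: str = ""

    def __post_init__(self) -> None:
        if self.muscle not in MUSCLES:
            raise FormatError(f"unknown muscle {self.muscle!r}; expected one of {MUSCLES}")
        if self.side not in SIDES:
            raise FormatError(f"unknown side {self.side!r}; expected one of {SIDES}")
        if not self.raw_name:
            object.__setattr__(self, "raw_name", str(self))

    def __str__(self) -> str:
        if self.muscle == "other":
            return self.raw_name or "other"
        if self.side == "none":
            return self.muscle
        return f"{self.muscle}-{self.side}"

    @classmethod
    def parse(cls, name: str) -> "ChannelLabel":
        text = name.strip()
        parts = text.split("-")
        muscle_map = {m.lower(): m for m in ("Sol", "TA")}
        muscle = muscle_map.get(parts[0].lower())
        if muscle is not None:
            side = "none"
            if len(parts) > 1:
                side_key = parts[1].strip().upper()
                if side_key in ("L", "R"):
                    side = side_key
                else:
                    return cls("other", "none", text)
            return cls(muscle, side, text)
        return cls("other", "none", text)


def _as_label(channel: "ChannelLabel | str") -> ChannelLabel:
    if isinstance(channel, ChannelLabel):
        return channel
    return ChannelLabel.parse(channel)


@dataclass
class EmgRecording:
    """A multi-channel EMG recording with acquisition metadata.

    ``signal`` has one column per channel and one row per sample; amplitudes
    are signed, unitless floats.  ``sampling_rate`` is Hz, ``t0`` the time of
    the first sample in seconds, ``belt_speed`` the treadmill speed in cm/s.
    """

    animal_id: str
    group: str
    sampling_rate: float
    channels: list[ChannelLabel]
    signal: np.ndarray
    condition: str = "none"
    belt_speed: float = 5.0
    t0: float = 0.0
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.animal_id:
            raise FormatError("animal_id must be non-empty")
        if self.group not in GROUPS:
            raise FormatError(f"group must be one of {GROUPS}, got {self.group!r}")
        if self.condition not in CONDITIONS:
            raise FormatError(f"condition must be one of {CONDITIONS}, got {self.condition!r}")
        if not (self.sampling_rate > 0):
            raise FormatError("sampling_rate must be > 0")
        self.channels = [_as_label(c) for c in self.channels]
        if len(self.channels) == 0:
            raise FormatError("channel list must be non-empty")
        names = [str(c) for c in self.channels]
        if len(set(names)) != len(names):
            raise FormatError(f"channel labels must be unique, got {names}")
        self.signal = np.asarray(self.signal, dtype=float)
        if self.signal.ndim == 1:
            self.signal = self.signal[:, None]
        if self.signal.ndim != 2 or self.signal.shape[1] != len(self.channels):
            raise FormatError(
                f"signal must be (n_samples, {len(self.channels)}), got {self.signal.shape}"
            )
        if self.signal.shape[0] < 1:
            raise FormatError("signal must contain at least one sample")
        if not np.all(np.isfinite(self.signal)):
            raise DataError("signal contains non-finite values")

    @property
    def n_samples(self) -> int:
        return self.signal.shape[0]

    @property
    def duration(self) -> float:
        """Recording duration in seconds (n_samples / sampling_rate)."""
        return self.n_samples / self.sampling_rate

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_samples) / self.sampling_rate

    def channel_index(self, channel: "ChannelLabel | str") -> int:
        label = _as_label(channel)
        for i, c in enumerate(self.channels):
            if str(c) == str(label):
                return i
        raise UsageError(f"channel {label} not present in recording (has {self.channel_names})")

    @property
    def channel_names(self) -> list[str]:
        return [str(c) for c in self.channels]

    def channel_signal(self, channel: "ChannelLabel | str") -> np.ndarray:
        return self.signal[:, self.channel_index(channel)]

    def with_signal(self, signal: np.ndarray) -> "EmgRecording":
        return dataclasses.replace(self, signal=signal)


_REQUIRED_META = ("animal_id", "group", "sampling_rate", "channels")


def load_recording(path: "str | Path") -> EmgRecording:
    """Load a recording from ``<stem>.csv`` + ``<stem>.meta.json``.

    The CSV may carry an optional ``time_s`` column; if present it must be
    uniform at the metadata sampling rate to within 1e-6 s.  Any non-finite
    sample is rejected.
    """
    path = Path(path)
    csv_path = path if path.suffix == ".csv" else path.with_suffix(".csv")
    meta_path = csv_path.with_suffix("").with_suffix(".meta.json")
    if not csv_path.exists():
        raise FormatError(f"signal file not found: {csv_path}")
    if not meta_path.exists():
        raise FormatError(f"metadata sidecar not found: {meta_path}")
    try:
        meta = json.loads(meta_path.read_text())
    except json.JSONDecodeError as exc:
        raise FormatError(f"invalid JSON metadata in {meta_path}: {exc}") from exc
    for key in _REQUIRED_META:
        if key not in meta or meta[key] in (None, "", []):
            raise FormatError(f"metadata field {key!r} missing or blank in {meta_path}")

    frame = pd.read_csv(csv_path)
    columns = list(frame.columns)
    if columns and columns[0].lower() in ("time_s", "time", "t"):
        time = frame[columns[0]].to_numpy(dtype=float)
        frame = frame.drop(columns=[columns[0]])
        if len(time) > 1:
            dt = np.diff(time)
            if np.any(np.abs(dt - 1.0 / meta["sampling_rate"]) > _TIME_UNIFORMITY_TOL_S):
                raise DataError(f"time column in {csv_path} is not uniform at the stated rate")
        t0 = float(time[0]) if len(time) else float(meta.get("t0", 0.0))
    else:
        t0 = float(meta.get("t0", 0.0))

    declared = [str(_as_label(c)) for c in meta["channels"]]
    present = [str(_as_label(c)) for c in frame.columns]
    if declared != present:
        raise FormatError(
            f"channel mismatch between metadata ({declared}) and CSV header ({present})"
        )
    signal = frame.to_numpy(dtype=float)
    if not np.all(np.isfinite(signal)):
        raise DataError(f"non-finite samples in {csv_path}")

    return EmgRecording(
        animal_id=str(meta["animal_id"]),
        group=str(meta["group"]),
        condition=str(meta.get("condition", "none")),
        belt_speed=float(meta.get("belt_speed", 5.0)),
        sampling_rate=float(meta["sampling_rate"]),
        channels=[_as_label(c) for c in meta["channels"]],
        signal=signal,
        t0=t0,
        meta={k: v for k, v in meta.items() if k not in _REQUIRED_META + ("condition", "belt_speed", "t0")},
    )


def write_recording(rec: EmgRecording, path: "str | Path") -> None:
    """Write ``<stem>.csv`` + ``<stem>.meta.json``; round-trips to 1e-9 rel. tol."""
    path = Path(path)
    csv_path = path if path.suffix == ".csv" else path.with_suffix(".csv")
    meta_path = csv_path.with_suffix("").with_suffix(".meta.json")
    meta = {
        "animal_id": rec.animal_id,
        "group": rec.group,
        "condition": rec.condition,
        "belt_speed": rec.belt_speed,
        "sampling_rate": rec.sampling_rate,
        "t0": rec.t0,
        "channels": rec.channel_names,
        **rec.meta,
    }
    frame = pd.DataFrame(rec.signal, columns=rec.channel_names)
    frame.insert(0, "time_s", rec.times)
    try:
        meta_path.write_text(json.dumps(meta, indent=1, sort_keys=True) + "\n")
        frame.to_csv(csv_path, index=False, float_format="%.12g")
    except OSError as exc:
        raise IOError(f"cannot write recording to {csv_path}: {exc}") from exc


def _result_rows(results: Any) -> list[dict[str, Any]]:
    if dataclasses.is_dataclass(results) and not isinstance(results, type):
        results = [results]
    rows = []
    for item in results:
        if not (dataclasses.is_dataclass(item) and not isinstance(item, type)):
            raise UsageError(f"unsupported result entry of type {type(item).__name__}")
        row = {}
        for f in dataclasses.fields(item):
            value = getattr(item, f.name)
            if isinstance(value, (list, tuple, np.ndarray)):
                value = json.dumps(np.asarray(value).tolist())
            elif isinstance(value, dict):
                value = json.dumps(value, sort_keys=True, default=str)
            elif isinstance(value, ChannelLabel):
                value = str(value)
            elif isinstance(value, (np.floating, np.integer)):
                value = value.item()
            row[f.name] = value
        rows.append(row)
    return rows


def write_results(results: Any, path: "str | Path") -> None:
    """Write a result table as tidy ``<stem>.results.csv`` + ``.results.json``.

    Accepts a pandas DataFrame, a result dataclass, or a sequence of result
    dataclasses (ParamSummary, CircStatResult, TestResult, ...); one row per
    measurement.  An empty sequence yields a header-only CSV with no columns.
    """
    path = Path(path)
    stem = path
    for _ in range(3):
        if stem.suffix:
            stem = stem.with_suffix("")
    csv_path = stem.with_suffix(".results.csv")
    json_path = stem.with_suffix(".results.json")

    if isinstance(results, pd.DataFrame):
        frame = results
    elif isinstance(results, (list, tuple)) or (
        dataclasses.is_dataclass(results) and not isinstance(results, type)
    ):
        frame = pd.DataFrame(_result_rows(results))
    else:
        raise UsageError(f"unsupported result type {type(results).__name__}")

    try:
        frame.to_csv(csv_path, index=False, float_format="%.12g")
        payload = json.loads(frame.to_json(orient="records"))
        json_path.write_text(json.dumps(payload, indent=1, default=str) + "\n")
    except OSError as exc:
        raise IOError(f"cannot write results to {csv_path}: {exc}") from exc
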