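"""Device export dialects and the common internal time-series representation.

Two CSV dialects are supported:

* the Empatica-E4-style export: one file per channel, header row 1 holds
  the start epoch (UNIX seconds, UTC), row 2 the sample rate in Hz, then
  one numeric column per axis (three for the accelerometer).  Inter-beat
  intervals come as ``offset_s,duration_s`` pairs after a start-epoch row.
* a generic watch dialect for devices that only export inter-beat
  intervals: ``epoch_ms,rr_ms`` rows, no header.

All streams are normalised onto an absolute UNIX-seconds time axis so that
channels recorded at 4, 32 or 64 Hz can be joined without ambiguity.
Window intervals are half-open ``[t0, t1)`` throughout the package.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "FormatError",
    "UniformSeries",
    "IBISeries",
    "SessionRecord",
    "ArtifactMask",
    "CHANNELS",
    "SESSION_TYPES",
    "DEVICE_FAMILIES",
    "read_e4_channel",
    "write_e4_channel",
    "read_e4_ibi",
    "write_e4_ibi",
    "read_generic_ibi",
    "write_generic_ibi",
    "read_sessions",
    "write_sessions",
]

CHANNELS = ("eda", "temp", "acc_x", "acc_y", "acc_z", "bvp")
SESSION_TYPES = ("free", "lecture", "contest")
DEVICE_FAMILIES = ("e4", "gear_s", "gear_s2")

#: inter-beat durations outside this window are physiologically implausible;
#: parsing only warns — rejection belongs to the artifact stage.
IBI_PLAUSIBLE = (0.2, 3.0)


class FormatError(ValueError):
    """A device export file violates its dialect."""


@dataclass(frozen=True)
class UniformSeries:
    """Evenly sampled channel on an absolute time axis.

    ``values[i]`` is the sample at time ``start_epoch + i / fs``.
    Units: uS for EDA, degrees C for temperature, g for acceleration.
    """

    channel: str
    start_epoch: float
    fs: float
    values: np.ndarray

    def __post_init__(self) -> None:
        if self.channel not in CHANNELS:
            raise ValueError(f"unknown channel {self.channel!r}")
        if not self.fs > 0:
            raise ValueError("fs must be positive")
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim != 1:
            raise ValueError("values must be one-dimensional")
        if vals.size and not np.all(np.isfinite(vals)):
            raise ValueError("values must be finite")
        object.__setattr__(self, "values", vals)

    def __len__(self) -> int:
        return self.values.size

    @property
    def times(self) -> np.ndarray:
        return self.start_epoch + np.arange(self.values.size) / self.fs

    @property
    def t_end(self) -> float:
        """End of the covered interval (exclusive): time of one-past-last sample."""
        return self.start_epoch + self.values.size / self.fs

    def slice(self, t0: float, t1: float) -> "UniformSeries":
        """Samples with timestamps in the half-open window ``[t0, t1)``."""
        if t1 < t0:
            raise ValueError("t1 must be >= t0")
        n = self.values.size
        # index range [i0, i1) with start + i/fs in [t0, t1)
        i0 = int(np.ceil((t0 - self.start_epoch) * self.fs - 1e-9))
        i1 = int(np.ceil((t1 - self.start_epoch) * self.fs - 1e-9))
        i0, i1 = max(i0, 0), min(max(i1, 0), n)
        if i1 <= i0:
            return replace(self, start_epoch=t0, values=np.empty(0))
        return replace(
            self,
            start_epoch=self.start_epoch + i0 / self.fs,
            values=self.values[i0:i1],
        )


@dataclass(frozen=True)
class IBISeries:
    """Irregular event series of heart beats.

    ``ibi[i]`` is the inter-beat duration (seconds) of the interval *ending*
    at ``beat_times[i]``.
    """

    beat_times: np.ndarray
    ibi: np.ndarray

    def __post_init__(self) -> None:
        bt = np.asarray(self.beat_times, dtype=float)
        rr = np.asarray(self.ibi, dtype=float)
        if bt.shape != rr.shape or bt.ndim != 1:
            raise ValueError("beat_times and ibi must be 1-d and equal length")
        if bt.size > 1 and not np.all(np.diff(bt) > 0):
            raise ValueError("beat_times must be strictly ascending")
        object.__setattr__(self, "beat_times", bt)
        object.__setattr__(self, "ibi", rr)
        lo, hi = IBI_PLAUSIBLE
        if rr.size and (np.any(rr <= lo) or np.any(rr >= hi)):
            warnings.warn(
                f"{int(np.sum((rr <= lo) | (rr >= hi)))} inter-beat interval(s) "
                f"outside the plausible ({lo}, {hi}) s window; kept for the "
                "artifact stage",
                stacklevel=2,
            )

    def __len__(self) -> int:
        return self.beat_times.size

    @property
    def t_start(self) -> float:
        return float(self.beat_times[0]) if len(self) else np.nan

    @property
    def t_end(self) -> float:
        return float(self.beat_times[-1]) if len(self) else np.nan

    @property
    def span(self) -> float:
        """Time covered by the recorded beats, seconds."""
        return self.t_end - self.t_start if len(self) else 0.0

    def slice(self, t0: float, t1: float) -> "IBISeries":
        """Beats whose times fall in the half-open window ``[t0, t1)``."""
        if t1 < t0:
            raise ValueError("t1 must be >= t0")
        keep = (self.beat_times >= t0) & (self.beat_times < t1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # plausibility already reported at parse
            return IBISeries(self.beat_times[keep], self.ibi[keep])


@dataclass(frozen=True)
class SessionRecord:
    """One labelled recording session of one subject on one device."""

    subject_id: str
    device_id: str
    device_family: str
    session_type: str
    t_start: float
    t_end: float
    frustration: Optional[int] = None

    def __post_init__(self) -> None:
        if self.device_family not in DEVICE_FAMILIES:
            raise FormatError(f"unknown device_family {self.device_family!r}")
        if self.session_type not in SESSION_TYPES:
            raise FormatError(f"unknown session_type {self.session_type!r}")
        if not self.t_end > self.t_start:
            raise FormatError("t_end must be greater than t_start")
        f = self.frustration
        if f is not None and (f < 0 or f > 100 or f % 5 != 0):
            raise FormatError(
                f"frustration must be 0-100 in five-point increments, got {f}"
            )

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start


@dataclass(frozen=True)
class ArtifactMask:
    """Per-sample, per-beat or per-epoch boolean artifact flags.

    ``flags[i]`` True means element ``i`` is an artifact.  For epoch-based
    detectors ``epoch_starts``/``epoch_len`` locate each flag on the time
    axis; for beat-based detectors the flags align with the beat series.
    """

    flags: np.ndarray
    detector: str
    epoch_starts: Optional[np.ndarray] = None
    epoch_len: Optional[float] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "flags", np.asarray(self.flags, dtype=bool))
        if self.epoch_starts is not None:
            es = np.asarray(self.epoch_starts, dtype=float)
            if es.shape != self.flags.shape:
                raise ValueError("epoch_starts must align with flags")
            object.__setattr__(self, "epoch_starts", es)

    def __len__(self) -> int:
        return self.flags.size

    @property
    def n_flagged(self) -> int:
        return int(self.flags.sum())


# ---------------------------------------------------------------------------
# Empatica-E4-style dialect
# ---------------------------------------------------------------------------

def _read_rows(path) -> list[list[str]]:
    with open(path, newline="") as fh:
        return [row for row in csv.reader(fh) if row and any(c.strip() for c in row)]


def _parse_float(cell: str, path, row_idx: int) -> float:
    try:
        return float(cell)
    except ValueError:
        raise FormatError(f"{path}: non-numeric value {cell!r} at row {row_idx + 1}") from None


def read_e4_channel(path, channel: str):
    """Read an E4-style per-channel CSV.

    ``channel`` is ``"eda"``, ``"temp"`` or ``"acc"``; the accelerometer
    file carries three columns and yields a ``(acc_x, acc_y, acc_z)`` tuple
    sharing start epoch and rate.
    """
    rows = _read_rows(path)
    if len(rows) < 2:
        raise FormatError(f"{path}: missing start-epoch / sample-rate header")
    start = _parse_float(rows[0][0], path, 0)
    fs = _parse_float(rows[1][0], path, 1)
    if fs <= 0:
        raise FormatError(f"{path}: sample rate must be positive, got {fs}")
    ncol = 3 if channel == "acc" else 1
    data = np.empty((len(rows) - 2, ncol))
    for i, row in enumerate(rows[2:]):
        if len(row) < ncol:
            raise FormatError(f"{path}: expected {ncol} columns at row {i + 3}")
        for j in range(ncol):
            data[i, j] = _parse_float(row[j], path, i + 2)
    if channel == "acc":
        return tuple(
            UniformSeries(f"acc_{ax}", start, fs, data[:, j])
            for j, ax in enumerate("xyz")
        )
    if channel not in ("eda", "temp", "bvp"):
        raise ValueError(f"unsupported E4 channel {channel!r}")
    return UniformSeries(channel, start, fs, data[:, 0])


def write_e4_channel(path, series) -> None:
    """Write one or three (ACC) UniformSeries in the E4 dialect."""
    many: Sequence[UniformSeries] = series if isinstance(series, (tuple, list)) else [series]
    start, fs = many[0].start_epoch, many[0].fs
    for s in many[1:]:
        if s.start_epoch != start or s.fs != fs:
            raise ValueError("ACC axes must share start epoch and rate")
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow([repr(float(start))] * len(many))
        w.writerow([repr(float(fs))] * len(many))
        for vals in zip(*(s.values for s in many)):
            w.writerow([repr(float(v)) for v in vals])


def read_e4_ibi(path) -> IBISeries:
    """Read an E4-style IBI file: start-epoch row, then offset,duration pairs."""
    rows = _read_rows(path)
    if not rows:
        raise FormatError(f"{path}: empty IBI file")
    start = _parse_float(rows[0][0], path, 0)
    offsets = np.empty(len(rows) - 1)
    durs = np.empty(len(rows) - 1)
    for i, row in enumerate(rows[1:]):
        if len(row) < 2:
            raise FormatError(f"{path}: expected offset,duration at row {i + 2}")
        offsets[i] = _parse_float(row[0], path, i + 1)
        durs[i] = _parse_float(row[1], path, i + 1)
    if offsets.size > 1 and np.any(np.diff(offsets) < 0):
        raise FormatError(f"{path}: beat offsets must be nondecreasing")
    return IBISeries(start + offsets, durs)


def write_e4_ibi(path, rr: IBISeries) -> None:
    start = rr.beat_times[0] if len(rr) else 0.0
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow([repr(float(start)), "IBI"])
        for t, d in zip(rr.beat_times, rr.ibi):
            w.writerow([repr(float(t - start)), repr(float(d))])


# ---------------------------------------------------------------------------
# Generic watch dialect (epoch_ms, rr_ms)
# ---------------------------------------------------------------------------

def read_generic_ibi(path) -> IBISeries:
    """Read the generic watch IBI dialect: ``epoch_ms,rr_ms`` per row.

    Rows out of time order are sorted with a warning — real exports
    interleave buffered uploads.
    """
    rows = _read_rows(path)
    t = np.empty(len(rows))
    rr = np.empty(len(rows))
    for i, row in enumerate(rows):
        if len(row) < 2:
            raise FormatError(f"{path}: expected epoch_ms,rr_ms at row {i + 1}")
        t[i] = _parse_float(row[0], path, i) / 1000.0
        rr[i] = _parse_float(row[1], path, i) / 1000.0
    if t.size > 1 and np.any(np.diff(t) < 0):
        warnings.warn(f"{path}: rows out of time order; sorting", stacklevel=2)
        order = np.argsort(t, kind="stable")
        t, rr = t[order], rr[order]
    return IBISeries(t, rr)


def write_generic_ibi(path, rr: IBISeries) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        for t, d in zip(rr.beat_times, rr.ibi):
            w.writerow([repr(float(t) * 1000.0), repr(float(d) * 1000.0)])


# ---------------------------------------------------------------------------
# Session metadata
# ---------------------------------------------------------------------------

_SESSION_FIELDS = (
    "subject_id",
    "device_id",
    "device_family",
    "session_type",
    "t_start",
    "t_end",
    "frustration",
)


def read_sessions(path) -> list[SessionRecord]:
    """Read the session metadata CSV (header required, frustration optional)."""
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise FormatError(f"{path}: empty sessions file")
        missing = set(_SESSION_FIELDS[:-1]) - set(reader.fieldnames)
        if missing:
            raise FormatError(f"{path}: missing columns {sorted(missing)}")
        out = []
        for i, row in enumerate(reader):
            frus = row.get("frustration", "")
            frus_val = int(float(frus)) if frus not in (None, "", "NA") else None
            try:
                out.append(
                    SessionRecord(
                        subject_id=row["subject_id"],
                        device_id=row["device_id"],
                        device_family=row["device_family"],
                        session_type=row["session_type"],
                        t_start=float(row["t_start"]),
                        t_end=float(row["t_end"]),
                        frustration=frus_val,
                    )
                )
            except (FormatError, ValueError) as exc:
                raise FormatError(f"{path}: row {i + 2}: {exc}") from None
    return out


def write_sessions(path, sessions: Sequence[SessionRecord]) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(_SESSION_FIELDS)
        for s in sessions:
            w.writerow(
                [
                    s.subject_id,
                    s.device_id,
                    s.device_family,
                    s.session_type,
                    repr(float(s.t_start)),
                    repr(float(s.t_end)),
                    "" if s.frustration is None else s.frustration,
                ]
            )
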