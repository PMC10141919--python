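"""Reading and writing Empatica-E4-style session directories.

An on-disk session is a directory holding one CSV per physiological channel
(``HR.csv``, ``TEMP.csv``, ``EDA.csv``, ``ACC.csv``) in the de-facto E4
export dialect -- line 1 is the UNIX start timestamp, line 2 the sampling
rate in Hz, then one sample per line (three comma-separated columns for the
accelerometer, in raw counts of 1/64 g) -- plus an ``annotations.csv``
sidecar giving segment boundaries (baseline/task) and the nine Flow State
Scale responses for each task.  The device does not record task boundaries
or survey answers itself, so the sidecar is this package's convention.

Likert responses are coded 0..4 (strongly disagree = 0 ... strongly
agree = 4) so that the bottom category of the rating-scale measurement
model is zero.
"""

from __future__ import annotations

import csv
import math
import warnings
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Optional

import numpy as np

__all__ = [
    "Channel",
    "ChannelSeries",
    "Segment",
    "SessionRecord",
    "E4Error",
    "MissingChannelError",
    "FormatError",
    "AnnotationError",
    "EXPECTED_RATES",
    "CHANNEL_UNITS",
    "DEFAULT_ACC_SCALE",
    "read_e4_session",
    "write_e4_session",
    "read_annotations",
    "write_annotations",
]

DEFAULT_ACC_SCALE = 1.0 / 64.0  # g per raw accelerometer count


class Channel(str, Enum):
    """Physiological channel recorded by the wristband."""

    HR = "HR"
    TEMP = "TEMP"
    EDA = "EDA"
    ACC = "ACC"


#: Sampling rates the device uses, in samples/second.
EXPECTED_RATES = {Channel.HR: 1.0, Channel.TEMP: 4.0, Channel.EDA: 4.0, Channel.ACC: 32.0}

#: Physical units per channel.
CHANNEL_UNITS = {
    Channel.HR: "bpm",
    Channel.TEMP: "degC",
    Channel.EDA: "microsiemens",
    Channel.ACC: "g",
}

N_FSS_ITEMS = 9
FSS_MIN, FSS_MAX = 0, 4


class E4Error(ValueError):
    """Base class for session I/O and validation errors."""


class MissingChannelError(E4Error):
    pass


class FormatError(E4Error):
    pass


class AnnotationError(E4Error):
    pass


@dataclass(frozen=True)
class ChannelSeries:
    """One channel's samples: start time, rate and values.

    ``values`` is a 1-d float array for scalar channels and an (n, 3)
    array of (x, y, z) triples in g for the accelerometer.
    """

    channel: Channel
    start_time: float  # UNIX seconds
    rate: float  # samples / second
    values: np.ndarray
    units: str = ""
    trimmed: bool = False

    def __post_init__(self):
        object.__setattr__(self, "channel", Channel(self.channel))
        vals = np.asarray(self.values, dtype=float)
        if self.channel is Channel.ACC:
            if vals.ndim != 2 or vals.shape[1] != 3:
                raise E4Error("ACC values must be (n, 3) triples")
        else:
            if vals.ndim != 1:
                raise E4Error(f"{self.channel.value} values must be one-dimensional")
        if vals.shape[0] == 0:
            raise E4Error(f"{self.channel.value} series has no samples")
        if not self.rate > 0:
            raise E4Error("sampling rate must be positive")
        expected = EXPECTED_RATES[self.channel]
        if self.rate != expected:
            raise FormatError(
                f"{self.channel.value} declares rate {self.rate} Hz, expected {expected} Hz"
            )
        if not self.units:
            object.__setattr__(self, "units", CHANNEL_UNITS[self.channel])
        elif self.units != CHANNEL_UNITS[self.channel]:
            raise E4Error(
                f"units {self.units!r} do not match channel {self.channel.value}"
            )
        if self.start_time != math.floor(self.start_time):
            warnings.warn("sub-second session start rounded down to whole seconds")
            object.__setattr__(self, "start_time", float(math.floor(self.start_time)))
        object.__setattr__(self, "values", vals)

    @property
    def n_samples(self) -> int:
        return int(self.values.shape[0])

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.rate


@dataclass(frozen=True)
class Segment:
    """A baseline or task interval, in seconds from the session start.

    Task segments carry the nine Flow State Scale item responses
    (integers 0..4); baseline segments never do.
    """

    kind: str  # "baseline" | "task"
    task_id: str
    start_offset: float
    end_offset: float
    fss_response: Optional[tuple] = None

    def __post_init__(self):
        if self.kind not in ("baseline", "task"):
            raise AnnotationError(f"unknown segment kind {self.kind!r}")
        if not (0 <= self.start_offset < self.end_offset):
            raise AnnotationError(
                f"segment offsets must satisfy 0 <= start < end, got "
                f"[{self.start_offset}, {self.end_offset})"
            )
        if self.kind == "baseline":
            if self.fss_response is not None:
                raise AnnotationError("baseline segments carry no FSS response")
        else:
            if self.fss_response is None:
                raise AnnotationError(f"task {self.task_id!r} is missing its FSS response")
            resp = tuple(int(r) for r in self.fss_response)
            if len(resp) != N_FSS_ITEMS:
                raise AnnotationError(
                    f"task {self.task_id!r}: expected {N_FSS_ITEMS} FSS ratings, got {len(resp)}"
                )
            if any(r < FSS_MIN or r > FSS_MAX for r in resp):
                raise AnnotationError(
                    f"task {self.task_id!r}: FSS ratings must lie in {FSS_MIN}..{FSS_MAX}"
                )
            object.__setattr__(self, "fss_response", resp)

    @property
    def duration_s(self) -> float:
        return self.end_offset - self.start_offset


@dataclass
class SessionRecord:
    """One wear session: all four channels plus the segment annotation."""

    participant_id: str
    activity_id: str
    channels: dict
    segments: list
    trimmed: bool = False

    def __post_init__(self):
        self.channels = {Channel(k): v for k, v in self.channels.items()}
        missing = [c.value for c in Channel if c not in self.channels]
        if missing:
            raise MissingChannelError(f"session is missing channels: {', '.join(missing)}")
        if not self.segments:
            raise AnnotationError("session must declare at least one segment")
        self.segments = sorted(self.segments, key=lambda s: s.start_offset)
        for a, b in zip(self.segments, self.segments[1:]):
            if b.start_offset < a.end_offset:
                raise AnnotationError(
                    f"segments overlap: [{a.start_offset},{a.end_offset}) and "
                    f"[{b.start_offset},{b.end_offset})"
                )
        # Segment times are relative to the *untrimmed* session start; on a
        # trimmed record the head of early segments is simply gone.
        if not self.trimmed:
            end = max(s.end_offset for s in self.segments)
            for ch, series in self.channels.items():
                if series.duration_s + 1e-9 < end:
                    raise E4Error(
                        f"{ch.value} covers only {series.duration_s:.1f}s but segments "
                        f"extend to {end:.1f}s"
                    )

    @property
    def task_segments(self) -> list:
        return [s for s in self.segments if s.kind == "task"]

    @property
    def baseline_segments(self) -> list:
        return [s for s in self.segments if s.kind == "baseline"]


# ---------------------------------------------------------------------------
# on-disk dialect


def _read_channel_csv(path: Path, channel: Channel, acc_scale: float) -> ChannelSeries:
    rows = []
    with open(path, newline="") as fh:
        lines = fh.read().splitlines()
    if len(lines) < 3:
        raise FormatError(f"{path.name}: needs timestamp, rate and at least one sample")
    try:
        start_time = float(lines[0].split(",")[0])
    except ValueError as exc:
        raise FormatError(f"{path.name} line 1: bad timestamp {lines[0]!r}") from exc
    try:
        rate = float(lines[1].split(",")[0])
    except ValueError as exc:
        raise FormatError(f"{path.name} line 2: bad rate {lines[1]!r}") from exc
    expected = EXPECTED_RATES[channel]
    if rate != expected:
        raise FormatError(
            f"{path.name}: declared rate {rate} Hz does not match the expected "
            f"{expected} Hz for {channel.value}"
        )
    for lineno, line in enumerate(lines[2:], start=3):
        if not line.strip():
            continue
        parts = line.split(",")
        try:
            if channel is Channel.ACC:
                if len(parts) != 3:
                    raise ValueError("expected 3 columns")
                rows.append([float(p) for p in parts])
            else:
                if len(parts) != 1:
                    raise ValueError("expected 1 column")
                rows.append(float(parts[0]))
        except ValueError as exc:
            raise FormatError(f"{path.name} line {lineno}: cannot parse {line!r}") from exc
    values = np.asarray(rows, dtype=float)
    if channel is Channel.ACC:
        values = values * acc_scale
    return ChannelSeries(channel=channel, start_time=start_time, rate=rate, values=values)


def read_e4_session(directory, acc_scale: float = DEFAULT_ACC_SCALE) -> SessionRecord:
    """Read an E4-style session directory into a :class:`SessionRecord`.

    Accelerometer counts are converted to g with ``acc_scale``
    (default 1/64 g per count).
    """
    directory = Path(directory)
    channels = {}
    for channel in Channel:
        path = directory / f"{channel.value}.csv"
        if not path.exists():
            raise MissingChannelError(f"{directory}: missing {channel.value}.csv")
        channels[channel] = _read_channel_csv(path, channel, acc_scale)
    ann_path = directory / "annotations.csv"
    if not ann_path.exists():
        raise MissingChannelError(f"{directory}: missing annotations.csv")
    participant_id, activity_id, segments = read_annotations(ann_path)
    return SessionRecord(
        participant_id=participant_id,
        activity_id=activity_id,
        channels=channels,
        segments=segments,
    )


def write_e4_session(session: SessionRecord, directory,
                     acc_scale: float = DEFAULT_ACC_SCALE) -> Path:
    """Write ``session`` so that :func:`read_e4_session` is an exact inverse.

    ACC samples are emitted as integer counts (value / ``acc_scale``); the
    generator quantises acceleration to that grid, as the device does, so
    the roundtrip is bit-identical.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for channel, series in session.channels.items():
        path = directory / f"{channel.value}.csv"
        with open(path, "w", newline="") as fh:
            fh.write(f"{series.start_time:.1f}\n")
            fh.write(f"{series.rate:.1f}\n")
            if channel is Channel.ACC:
                counts = np.rint(series.values / acc_scale).astype(int)
                for x, y, z in counts:
                    fh.write(f"{x},{y},{z}\n")
            else:
                for v in series.values:
                    fh.write(f"{float(v)!r}\n")
    write_annotations(session, directory / "annotations.csv")
    return directory


ANNOTATION_COLUMNS = (
    ["participant_id", "activity_id", "kind", "task_id", "start_s", "end_s"]
    + [f"fss_q{i}" for i in range(1, N_FSS_ITEMS + 1)]
)


def write_annotations(session: SessionRecord, path) -> Path:
    path = Path(path)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(ANNOTATION_COLUMNS)
        for seg in session.segments:
            fss = list(seg.fss_response) if seg.fss_response is not None else [""] * N_FSS_ITEMS
            writer.writerow(
                [session.participant_id, session.activity_id, seg.kind, seg.task_id,
                 seg.start_offset, seg.end_offset] + fss
            )
    return path


def read_annotations(path):
    """Parse the annotation sidecar.

    Returns ``(participant_id, activity_id, segments)`` with segments in
    start-offset order.  Ratings outside 0..4, FSS responses on baseline
    rows, or overlapping segments raise :class:`AnnotationError`.
    """
    path = Path(path)
    segments = []
    participant_id = activity_id = None
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        missing = set(ANNOTATION_COLUMNS) - set(reader.fieldnames or [])
        if missing:
            raise AnnotationError(f"{path.name}: missing columns {sorted(missing)}")
        for row in reader:
            participant_id = participant_id or row["participant_id"]
            activity_id = activity_id or row["activity_id"]
            fss_vals = [row[f"fss_q{i}"].strip() for i in range(1, N_FSS_ITEMS + 1)]
            has_fss = any(v != "" for v in fss_vals)
            if row["kind"] == "baseline" and has_fss:
                raise AnnotationError(
                    f"{path.name}: baseline row at {row['start_s']}s carries FSS ratings"
                )
            fss = tuple(int(v) for v in fss_vals) if has_fss else None
            segments.append(
                Segment(
                    kind=row["kind"],
                    task_id=row["task_id"],
                    start_offset=float(row["start_s"]),
                    end_offset=float(row["end_s"]),
                    fss_response=fss,
                )
            )
    if not segments:
        raise AnnotationError(f"{path.name}: no segments")
    segments.sort(key=lambda s: s.start_offset)
    for a, b in zip(segments, segments[1:]):
        if b.start_offset < a.end_offset:
            raise AnnotationError(f"{path.name}: overlapping segments at {b.start_offset}s")
    return participant_id, activity_id, segments
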