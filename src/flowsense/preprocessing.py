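"""Calibration trimming and task/baseline window assembly.

The wristband needs time to stabilise after it is put on, so the head of
every session is discarded: 20 s from the temperature, electrodermal and
accelerometer streams, and 10 s from the heart-rate stream (heart rate is
reported as a 10 s trailing moving average, so only its first 10 samples
are calibration artifacts).  At the device rates this removes 80 TEMP/EDA
samples, 640 ACC samples and 10 HR samples.

Trimming happens once, at the session start -- not per segment -- and a
``trimmed`` flag on the record guards against accidental double trimming.
Segments are then cut out as half-open intervals [start, end) using sample
indices floor(t * rate), and each task segment is paired with a baseline
segment (by default the nearest preceding baseline) to support
baseline-relative features.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .io import Channel, ChannelSeries, SessionRecord, Segment

__all__ = [
    "TrimPolicy",
    "TaskWindow",
    "PreprocessingError",
    "TooShortError",
    "PairingError",
    "SCALAR_CHANNELS",
    "trim_calibration",
    "trim_session",
    "build_task_windows",
    "window_audit_table",
]

#: The six scalar streams features are computed on (ACC split per axis).
SCALAR_CHANNELS = ("HR", "TEMP", "EDA", "ACC_X", "ACC_Y", "ACC_Z")


class PreprocessingError(ValueError):
    pass


class TooShortError(PreprocessingError):
    pass


class PairingError(PreprocessingError):
    pass


@dataclass(frozen=True)
class TrimPolicy:
    """Seconds of calibration data to drop per channel at session start."""

    trim_seconds_by_channel: dict = field(
        default_factory=lambda: {
            Channel.TEMP: 20.0,
            Channel.EDA: 20.0,
            Channel.ACC: 20.0,
            Channel.HR: 10.0,
        }
    )

    def __post_init__(self):
        policy = {Channel(k): float(v) for k, v in self.trim_seconds_by_channel.items()}
        if any(v < 0 for v in policy.values()):
            raise PreprocessingError("trim durations must be >= 0")
        object.__setattr__(self, "trim_seconds_by_channel", policy)

    def seconds_for(self, channel: Channel) -> float:
        return self.trim_seconds_by_channel.get(Channel(channel), 0.0)


@dataclass
class TaskWindow:
    """One task's trimmed samples paired with its baseline's samples.

    ``task`` and ``baseline`` map each of the six scalar channels
    (HR, TEMP, EDA, ACC_X, ACC_Y, ACC_Z) to a 1-d sample array.
    """

    participant_id: str
    activity_id: str
    task_id: str
    task: dict
    baseline: dict
    fss_response: Optional[tuple] = None
    flow: Optional[int] = None

    def __post_init__(self):
        for name, streams in (("task", self.task), ("baseline", self.baseline)):
            missing = [c for c in SCALAR_CHANNELS if c not in streams]
            if missing:
                raise PreprocessingError(f"{name} streams missing channels {missing}")
            for c in SCALAR_CHANNELS:
                arr = np.asarray(streams[c], dtype=float)
                if arr.size == 0:
                    raise TooShortError(
                        f"task {self.task_id!r}: empty {name} stream for {c}"
                    )
                streams[c] = arr


def trim_calibration(series: ChannelSeries, policy: TrimPolicy):
    """Drop the calibration head of one channel.

    Returns ``(trimmed_series, removed_count)`` where
    ``removed_count = round(rate * trim_seconds)``; the trimmed series
    keeps the original tail and its start time advances by the trim
    duration.
    """
    if series.trimmed:
        raise PreprocessingError(
            f"{series.channel.value} series is already trimmed; refusing to trim twice"
        )
    trim_s = policy.seconds_for(series.channel)
    removed = int(round(series.rate * trim_s))
    if removed >= series.n_samples:
        raise TooShortError(
            f"{series.channel.value}: {series.n_samples} samples is shorter than the "
            f"{trim_s:.0f}s calibration window ({removed} samples)"
        )
    trimmed = ChannelSeries(
        channel=series.channel,
        start_time=series.start_time + trim_s,
        rate=series.rate,
        values=series.values[removed:],
        trimmed=True,
    )
    return trimmed, removed


def trim_session(session: SessionRecord, policy: TrimPolicy) -> SessionRecord:
    """Apply :func:`trim_calibration` to every channel of a session."""
    if session.trimmed:
        raise PreprocessingError("session is already trimmed; refusing to trim twice")
    channels = {}
    for channel, series in session.channels.items():
        channels[channel], _ = trim_calibration(series, policy)
    return SessionRecord(
        participant_id=session.participant_id,
        activity_id=session.activity_id,
        channels=channels,
        segments=list(session.segments),
        trimmed=True,
    )


def _segment_slice(series: ChannelSeries, segment: Segment, removed: int) -> np.ndarray:
    """Samples of ``series`` falling in [start, end), index floor(t * rate).

    ``removed`` is the number of samples trimmed off the session head, so
    index 0 of the stored array corresponds to original index ``removed``.
    """
    i0 = int(np.floor(segment.start_offset * series.rate)) - removed
    i1 = int(np.floor(segment.end_offset * series.rate)) - removed
    i0 = max(i0, 0)
    if i1 <= i0:
        raise TooShortError(
            f"{series.channel.value}: segment [{segment.start_offset},"
            f"{segment.end_offset}) is empty after trimming"
        )
    return series.values[i0:i1]


def _split_streams(session: SessionRecord, segment: Segment, removed_by_channel: dict) -> dict:
    streams = {}
    for channel in (Channel.HR, Channel.TEMP, Channel.EDA):
        streams[channel.value] = _segment_slice(
            session.channels[channel], segment, removed_by_channel[channel]
        )
    acc = _segment_slice(session.channels[Channel.ACC], segment, removed_by_channel[Channel.ACC])
    streams["ACC_X"], streams["ACC_Y"], streams["ACC_Z"] = acc[:, 0], acc[:, 1], acc[:, 2]
    return streams


def build_task_windows(session: SessionRecord, policy: Optional[TrimPolicy] = None,
                       baseline_mode: str = "preceding") -> list:
    """Trim a session once and cut one :class:`TaskWindow` per task segment.

    ``baseline_mode`` selects the baseline samples paired with each task:
    ``"preceding"`` (default) uses the nearest baseline segment that starts
    before the task; ``"mean_of_pre_post"`` pools the nearest preceding and
    nearest following baselines.  A task with no eligible baseline raises
    :class:`PairingError`.
    """
    if baseline_mode not in ("preceding", "mean_of_pre_post"):
        raise PreprocessingError(f"unknown baseline_mode {baseline_mode!r}")
    policy = policy or TrimPolicy()
    if session.trimmed:
        trimmed = session
        removed = {c: int(round(s.rate * policy.seconds_for(c)))
                   for c, s in session.channels.items()}
    else:
        removed = {}
        channels = {}
        for channel, series in session.channels.items():
            channels[channel], removed[channel] = trim_calibration(series, policy)
        trimmed = SessionRecord(
            participant_id=session.participant_id,
            activity_id=session.activity_id,
            channels=channels,
            segments=list(session.segments),
            trimmed=True,
        )

    baselines = trimmed.baseline_segments
    tasks = trimmed.task_segments
    if not baselines or not tasks:
        raise PairingError("session needs at least one baseline and one task segment")

    baseline_streams = {id(b): _split_streams(trimmed, b, removed) for b in baselines}

    windows = []
    for task in tasks:
        preceding = [b for b in baselines if b.start_offset < task.start_offset]
        if not preceding:
            raise PairingError(f"task {task.task_id!r} has no preceding baseline")
        pre = max(preceding, key=lambda b: b.start_offset)
        chosen = baseline_streams[id(pre)]
        if baseline_mode == "mean_of_pre_post":
            following = [b for b in baselines if b.start_offset >= task.end_offset]
            if following:
                post = min(following, key=lambda b: b.start_offset)
                post_streams = baseline_streams[id(post)]
                chosen = {c: np.concatenate([chosen[c], post_streams[c]])
                          for c in SCALAR_CHANNELS}
        windows.append(
            TaskWindow(
                participant_id=trimmed.participant_id,
                activity_id=trimmed.activity_id,
                task_id=task.task_id,
                task=_split_streams(trimmed, task, removed),
                baseline={c: chosen[c] for c in SCALAR_CHANNELS},
                fss_response=task.fss_response,
            )
        )
    return windows


def window_audit_table(windows) -> pd.DataFrame:
    """Tidy per-window sample-count summary, for auditing trims and cuts."""
    rows = []
    for w in windows:
        row = {"participant_id": w.participant_id, "activity_id": w.activity_id,
               "task_id": w.task_id}
        for c in SCALAR_CHANNELS:
            row[f"n_task_{c}"] = len(w.task[c])
            row[f"n_baseline_{c}"] = len(w.baseline[c])
        rows.append(row)
    return pd.DataFrame(rows)
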