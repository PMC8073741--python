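"""Reading, trimming and labelling of accelerometer traces and annotations.

Dialects
--------
Signal CSV: header ``timestamp,x,y,z``; ISO-8601 timestamps (millisecond
precision), axis values as floats in g. Annotation CSV: header
``behaviour,start,end``; lowercase behaviour names, ISO-8601 timestamps.
Timestamps are naive local time (clock synchronisation between sensor and
annotator is assumed to have been applied upstream).
"""

from __future__ import annotations

import datetime as dt
from pathlib import Path

import numpy as np
import pandas as pd

from .core import (
    BEHAVIOURS,
    UNLABELLED,
    AccelTrace,
    AnnotationLog,
    BehaviourEvent,
    LabelledTrace,
)

__all__ = [
    "read_signal_csv",
    "read_annotation_csv",
    "trim_to_window",
    "filter_short_events",
    "label_trace",
]

SIGNAL_COLUMNS = ["timestamp", "x", "y", "z"]
ANNOTATION_COLUMNS = ["behaviour", "start", "end"]


def _parse_clock(value: str | dt.time) -> dt.time:
    if isinstance(value, dt.time):
        return value
    return dt.time.fromisoformat(value)


def read_signal_csv(
    path: str | Path,
    animal_id: str | None = None,
    deployment: str | None = None,
    sampling_rate_hz: float = 25.0,
) -> AccelTrace:
    """Read a signal CSV into an :class:`AccelTrace`.

    ``animal_id``/``deployment`` default to parsing the synthio file naming
    convention ``{animal}_{deployment}_day{d}.csv``; pass them explicitly for
    real exports. Raises ``ValueError`` with the offending line number for a
    malformed row, and for non-monotone timestamps naming the first offending
    pair.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str)
    if list(df.columns) != SIGNAL_COLUMNS:
        raise ValueError(
            f"{path}: expected header {','.join(SIGNAL_COLUMNS)}, "
            f"got {','.join(df.columns)}"
        )
    t = pd.to_datetime(df["timestamp"], errors="coerce", format="ISO8601")
    xyz = df[["x", "y", "z"]].apply(pd.to_numeric, errors="coerce")
    bad = t.isna() | xyz.isna().any(axis=1) | ~np.isfinite(xyz).all(axis=1)
    if bad.any():
        line = int(np.flatnonzero(bad.to_numpy())[0]) + 2  # 1-based + header
        raise ValueError(f"{path}: malformed row at line {line}")
    tv = t.to_numpy()
    if len(tv) > 1:
        nonmono = np.flatnonzero(np.diff(tv) <= np.timedelta64(0))
        if nonmono.size:
            i = int(nonmono[0])
            raise ValueError(
                f"{path}: timestamps not strictly increasing at rows "
                f"{i + 2}-{i + 3} ({t.iloc[i]} >= {t.iloc[i + 1]})"
            )
    if animal_id is None or deployment is None:
        parts = path.stem.split("_")
        if animal_id is None:
            animal_id = parts[0]
        if deployment is None and len(parts) >= 2:
            deployment = parts[1]
    data = pd.DataFrame(
        {"t": t, "x": xyz["x"], "y": xyz["y"], "z": xyz["z"]}
    ).reset_index(drop=True)
    return AccelTrace(
        animal_id=animal_id,
        deployment=deployment or "collar",
        sampling_rate_hz=sampling_rate_hz,
        data=data,
    )


def read_annotation_csv(path: str | Path, animal_id: str | None = None) -> AnnotationLog:
    """Read an annotation CSV into an :class:`AnnotationLog`."""
    path = Path(path)
    df = pd.read_csv(path, dtype=str)
    if list(df.columns) != ANNOTATION_COLUMNS:
        raise ValueError(
            f"{path}: expected header {','.join(ANNOTATION_COLUMNS)}, "
            f"got {','.join(df.columns)}"
        )
    if animal_id is None:
        animal_id = path.stem.split("_")[0]
    events = []
    for i, row in df.iterrows():
        behaviour = str(row["behaviour"]).strip().lower()
        if behaviour not in BEHAVIOURS:
            raise ValueError(f"{path}: unknown behaviour {behaviour!r} at line {i + 2}")
        start = pd.Timestamp(row["start"])
        end = pd.Timestamp(row["end"])
        events.append(BehaviourEvent(behaviour, start, end))
    date = events[0].start.date() if events else dt.date.min
    return AnnotationLog(animal_id=animal_id, date=date, events=events)


def trim_to_window(
    trace: AccelTrace,
    start_clock: str | dt.time,
    end_clock: str | dt.time,
) -> AccelTrace:
    """Retain samples whose clock time lies in the half-open window
    ``[start_clock, end_clock)``, on every day the trace covers."""
    start = _parse_clock(start_clock)
    end = _parse_clock(end_clock)
    if start >= end:
        raise ValueError(f"window start {start} must precede end {end}")
    t = trace.data["t"]
    secs = (t - t.dt.normalize()).dt.total_seconds().to_numpy()
    lo = start.hour * 3600 + start.minute * 60 + start.second + start.microsecond / 1e6
    hi = end.hour * 3600 + end.minute * 60 + end.second + end.microsecond / 1e6
    keep = (secs >= lo) & (secs < hi)
    data = trace.data.loc[keep].reset_index(drop=True)
    return AccelTrace(
        animal_id=trace.animal_id,
        deployment=trace.deployment,
        sampling_rate_hz=trace.sampling_rate_hz,
        data=data,
    )


def filter_short_events(log: AnnotationLog, min_duration_s: float = 10.0) -> AnnotationLog:
    """Drop events shorter than ``min_duration_s`` (boundary inclusive: an
    event of exactly the minimum duration yields exactly one epoch and is
    kept). Mirrors the annotation rule that avoids several behaviours being
    merged into one epoch."""
    events = [e for e in log.events if e.duration_s >= min_duration_s]
    return AnnotationLog(animal_id=log.animal_id, date=log.date, events=events)


def label_trace(trace: AccelTrace, log: AnnotationLog) -> LabelledTrace:
    """Assign each sample the behaviour of the event containing it.

    Event intervals are half-open ``[start, end)``, so abutting events never
    double-label a sample. Samples outside every event are tagged
    ``unlabelled`` and excluded downstream.
    """
    if (
        trace.animal_id
        and log.animal_id
        and trace.animal_id != log.animal_id
    ):
        raise ValueError(
            f"trace animal {trace.animal_id!r} != log animal {log.animal_id!r}"
        )
    # AnnotationLog validates non-overlap on construction; re-check in case
    # the event list was mutated since.
    for prev, cur in zip(log.events, log.events[1:]):
        if cur.start < prev.end:
            raise ValueError(
                f"overlapping events: {prev.behaviour} ends {prev.end} after "
                f"{cur.behaviour} starts {cur.start}"
            )
    t = trace.data["t"].to_numpy()
    labels = np.full(len(t), UNLABELLED, dtype=object)
    if log.events:
        starts = np.array([e.start.to_datetime64() for e in log.events])
        ends = np.array([e.end.to_datetime64() for e in log.events])
        idx = np.searchsorted(starts, t, side="right") - 1
        inside = (idx >= 0) & (t < ends[np.clip(idx, 0, None)])
        behaviours = np.array([e.behaviour for e in log.events], dtype=object)
        labels[inside] = behaviours[idx[inside]]
    return LabelledTrace(trace=trace, labels=labels)
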