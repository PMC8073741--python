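"""Shared domain types for accelerometer behaviour studies.

The sensor axis convention follows the common livestock deployment: X is
dorso-ventral (vertical when the head is raised), Y medio-lateral, Z
anterior-posterior (longitudinal). Values are in gravitational units (g).
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: The four mutually exclusive base behaviours of the ethogram.
BEHAVIOURS: tuple[str, ...] = ("licking", "eating", "standing", "lying")

#: Sensor attachment sites (deployment modes).
DEPLOYMENTS: tuple[str, ...] = ("collar", "ear")

#: Tag used for samples that fall outside every annotated event.
UNLABELLED = "unlabelled"


@dataclass(frozen=True)
class BehaviourEvent:
    """A single annotated behaviour bout, half-open interval [start, end)."""

    behaviour: str
    start: pd.Timestamp
    end: pd.Timestamp

    def __post_init__(self) -> None:
        if self.behaviour not in BEHAVIOURS:
            raise ValueError(f"unknown behaviour {self.behaviour!r}")
        if not self.end > self.start:
            raise ValueError(
                f"event end must follow start (got {self.start} .. {self.end})"
            )

    @property
    def duration_s(self) -> float:
        return (self.end - self.start).total_seconds()


@dataclass
class AnnotationLog:
    """Chronologically ordered, non-overlapping behaviour events for one
    animal on one observation day (emulates a video annotation log)."""

    animal_id: str
    date: dt.date
    events: list[BehaviourEvent] = field(default_factory=list)

    def __post_init__(self) -> None:
        for prev, cur in zip(self.events, self.events[1:]):
            if cur.start < prev.end:
                raise ValueError(
                    "events must be chronological and non-overlapping: "
                    f"{prev.behaviour}[..{prev.end}] overlaps "
                    f"{cur.behaviour}[{cur.start}..]"
                )

    def __len__(self) -> int:
        return len(self.events)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "behaviour": [e.behaviour for e in self.events],
                "start": [e.start for e in self.events],
                "end": [e.end for e in self.events],
            }
        )


@dataclass
class AccelTrace:
    """An ordered tri-axial acceleration trace for one animal x deployment.

    ``data`` holds columns ``t`` (datetime64[ns]), ``x``, ``y``, ``z`` (g).
    Timestamps are naive local time and strictly increasing.
    """

    animal_id: str
    deployment: str
    sampling_rate_hz: float
    data: pd.DataFrame

    def __post_init__(self) -> None:
        if self.deployment not in DEPLOYMENTS:
            raise ValueError(f"unknown deployment {self.deployment!r}")
        missing = {"t", "x", "y", "z"} - set(self.data.columns)
        if missing:
            raise ValueError(f"trace data missing columns {sorted(missing)}")

    @property
    def n_samples(self) -> int:
        return len(self.data)

    def xyz(self) -> np.ndarray:
        """Samples as an (n, 3) float array in axis order x, y, z."""
        return self.data[["x", "y", "z"]].to_numpy(dtype=float)


@dataclass
class LabelledTrace:
    """An AccelTrace paired with one behaviour-or-unlabelled tag per sample."""

    trace: AccelTrace
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=object)
        if len(self.labels) != self.trace.n_samples:
            raise ValueError(
                f"label count {len(self.labels)} != sample count "
                f"{self.trace.n_samples}"
            )

    @property
    def n_labelled(self) -> int:
        return int(np.sum(self.labels != UNLABELLED))
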