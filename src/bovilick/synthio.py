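"""Synthetic accelerometer studies: schedule sampling, signal synthesis, CSV export.

The generator emulates a penned-cattle supplementation trial: animals wear a
tri-axial accelerometer on a neck-collar and an ear-tag, and are observed for
six hours a day while four mutually exclusive behaviours (licking, eating,
standing, lying) alternate. Each behaviour x deployment has a regime: a static
gravity orientation, an oscillatory component (head/jaw movement) and Gaussian
sensor noise, i.e.

    a(t) = static_mean + osc_amplitude * sin(2*pi*f*t + phase) + noise

Eating alternates between two postures (head-down biting, head-up chewing)
within an event, which is what makes it confusable with licking. Default
regimes are calibrated so that per-epoch movement variation (MVA) orders as
eating > licking >> lying >= standing for both deployments, and head-down
classes (licking, eating) differ from head-up classes (standing, lying) in
their mean X (dorso-ventral) component.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .core import BEHAVIOURS, DEPLOYMENTS, AccelTrace, AnnotationLog, BehaviourEvent

__all__ = [
    "BehaviourRegime",
    "StudyConfig",
    "default_regimes",
    "sample_schedule",
    "synthesize_trace",
    "write_study",
]


@dataclass(frozen=True)
class BehaviourRegime:
    """Signal-generation parameters for one behaviour under one deployment.

    Parameters
    ----------
    static_mean
        Gravity orientation of the sensor for the posture, in g.
    osc_amplitude, osc_frequency_hz
        Amplitude (g, per axis) and frequency of the oscillatory movement
        component; one random phase per event.
    noise_sd
        Per-axis Gaussian noise SD in g.
    duration_range_s
        (min, max) of the uniform event-duration distribution.
    alt_static_mean, substate_period_s
        If set, the static orientation alternates between ``static_mean``
        and ``alt_static_mean`` every ``substate_period_s`` seconds within
        an event (two-posture behaviours such as eating).
    orient_jitter_sd, amp_jitter
        Per-event variability: each event draws one orientation offset
        (Gaussian, g) added to the static mean(s) and one relative
        amplitude factor (1 + Gaussian); animals do not hold a posture
        identically from bout to bout, which is what makes neighbouring
        behaviours genuinely confusable.
    """

    behaviour: str
    deployment: str
    static_mean: tuple[float, float, float]
    osc_amplitude: tuple[float, float, float]
    osc_frequency_hz: float
    noise_sd: tuple[float, float, float]
    duration_range_s: tuple[float, float]
    alt_static_mean: tuple[float, float, float] | None = None
    substate_period_s: float = 5.0
    orient_jitter_sd: float = 0.05
    amp_jitter: float = 0.15

    def __post_init__(self) -> None:
        if self.behaviour not in BEHAVIOURS:
            raise ValueError(f"unknown behaviour {self.behaviour!r}")
        if self.deployment not in DEPLOYMENTS:
            raise ValueError(f"unknown deployment {self.deployment!r}")
        if self.osc_frequency_hz <= 0:
            raise ValueError("osc_frequency_hz must be positive")
        if any(s < 0 for s in self.noise_sd):
            raise ValueError("noise_sd must be non-negative componentwise")
        lo, hi = self.duration_range_s
        if lo < 1.0 or hi < lo:
            raise ValueError("duration range must satisfy 1 <= min <= max")


def default_regimes() -> dict[tuple[str, str], BehaviourRegime]:
    """Default regimes for both deployments.

    Calibrated so mean per-epoch MVA approximates the field values seen in
    penned cattle (collar: eating 0.20, licking 0.18, lying 0.04, standing
    0.03 g; ear-tag: 0.30, 0.17, 0.09, 0.07 g) — the ordering, not the exact
    values, is the contract. The ear-tag is noisier (looser attachment, ear
    movement independent of the body).
    """
    r: dict[tuple[str, str], BehaviourRegime] = {}

    def add(regime: BehaviourRegime) -> None:
        r[(regime.behaviour, regime.deployment)] = regime

    # --- neck-collar ---
    add(BehaviourRegime("standing", "collar", (-0.98, 0.03, 0.12),
                        (0.004, 0.004, 0.004), 0.4, (0.008, 0.008, 0.008),
                        (30.0, 240.0)))
    add(BehaviourRegime("lying", "collar", (-0.80, 0.42, 0.30),
                        (0.005, 0.005, 0.006), 0.3, (0.010, 0.010, 0.010),
                        (30.0, 240.0)))
    add(BehaviourRegime("licking", "collar", (-0.32, 0.08, 0.88),
                        (0.08, 0.04, 0.22), 2.0, (0.020, 0.020, 0.020),
                        (20.0, 180.0)))
    add(BehaviourRegime("eating", "collar", (-0.40, 0.10, 0.84),
                        (0.12, 0.06, 0.20), 2.5, (0.015, 0.015, 0.015),
                        (30.0, 240.0),
                        alt_static_mean=(-0.88, 0.06, 0.34)))
    # --- ear-tag ---
    add(BehaviourRegime("standing", "ear", (-0.90, 0.15, 0.25),
                        (0.006, 0.006, 0.006), 0.5, (0.018, 0.018, 0.018),
                        (30.0, 240.0)))
    add(BehaviourRegime("lying", "ear", (-0.70, 0.45, 0.40),
                        (0.008, 0.008, 0.008), 0.4, (0.024, 0.024, 0.024),
                        (30.0, 240.0)))
    add(BehaviourRegime("licking", "ear", (-0.30, 0.20, 0.85),
                        (0.06, 0.05, 0.15), 2.0, (0.025, 0.025, 0.025),
                        (20.0, 180.0)))
    add(BehaviourRegime("eating", "ear", (-0.38, 0.22, 0.80),
                        (0.15, 0.10, 0.25), 2.5, (0.028, 0.028, 0.028),
                        (30.0, 240.0),
                        alt_static_mean=(-0.82, 0.18, 0.38)))
    return r


def _default_probs() -> dict[str, float]:
    return {b: 0.25 for b in BEHAVIOURS}


@dataclass
class StudyConfig:
    """Configuration of a synthetic study (animals x days x deployments)."""

    n_animals: int = 4
    n_days: int = 1
    sampling_rate_hz: float = 25.0
    observation_window: tuple[dt.time, dt.time] = (dt.time(10, 0), dt.time(16, 0))
    epoch_s: float = 10.0
    seed: int = 0
    regimes: dict[tuple[str, str], BehaviourRegime] = field(default_factory=default_regimes)
    behaviour_probs: dict[str, float] = field(default_factory=_default_probs)
    start_date: dt.date = dt.date(2021, 3, 1)

    def __post_init__(self) -> None:
        if self.n_animals < 0 or self.n_days < 1:
            raise ValueError("need n_animals >= 0 and n_days >= 1")
        if self.sampling_rate_hz <= 0 or self.epoch_s <= 0:
            raise ValueError("sampling rate and epoch length must be positive")
        start, end = self.observation_window
        if self.window_length_s <= 0:
            raise ValueError(f"observation window {start}-{end} has no length")
        n = self.epoch_s * self.sampling_rate_hz
        if abs(n - round(n)) > 1e-9:
            raise ValueError("epoch_s x sampling_rate_hz must be an integer sample count")
        for regime in self.regimes.values():
            if regime.osc_frequency_hz >= self.sampling_rate_hz / 2:
                raise ValueError(
                    f"{regime.behaviour}/{regime.deployment}: oscillation "
                    f"frequency {regime.osc_frequency_hz} Hz violates Nyquist "
                    f"at {self.sampling_rate_hz} Hz sampling"
                )
        total = sum(self.behaviour_probs.get(b, 0.0) for b in BEHAVIOURS)
        if total <= 0:
            raise ValueError("behaviour probabilities must sum to a positive value")

    @property
    def window_length_s(self) -> float:
        start, end = self.observation_window
        return (
            dt.datetime.combine(dt.date.min, end)
            - dt.datetime.combine(dt.date.min, start)
        ).total_seconds()

    def animal_ids(self) -> list[str]:
        return [f"a{i:02d}" for i in range(self.n_animals)]


def _rng_for(config: StudyConfig, *key: int) -> np.random.Generator:
    """Deterministic per-(animal, day, stream) generator."""
    return np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=key))


def sample_schedule(
    config: StudyConfig,
    day: int,
    animal_id: str = "a00",
    rng: np.random.Generator | None = None,
) -> AnnotationLog:
    """Draw a behaviour schedule tiling one observation window.

    Behaviours are drawn i.i.d. from ``config.behaviour_probs`` and durations
    uniformly from the regime's duration range; the last event is truncated
    at the window end so the events exactly tile the window.
    """
    if rng is None:
        animal_idx = config.animal_ids().index(animal_id) if animal_id in config.animal_ids() else 0
        rng = _rng_for(config, 0, animal_idx, day)
    probs = np.array([config.behaviour_probs.get(b, 0.0) for b in BEHAVIOURS])
    probs = probs / probs.sum()
    active = [b for b, p in zip(BEHAVIOURS, probs) if p > 0]
    min_dur = min(
        config.regimes[(b, "collar")].duration_range_s[0] for b in active
        if (b, "collar") in config.regimes
    )
    window_s = config.window_length_s
    if window_s < min_dur:
        raise ValueError(
            f"observation window ({window_s:.0f} s) shorter than the minimum "
            f"event duration ({min_dur:.0f} s): schedule infeasible"
        )
    date = config.start_date + dt.timedelta(days=day)
    t0 = pd.Timestamp(dt.datetime.combine(date, config.observation_window[0]))
    t_end = t0 + pd.Timedelta(seconds=window_s)

    events: list[BehaviourEvent] = []
    cursor = t0
    while cursor < t_end:
        behaviour = str(rng.choice(BEHAVIOURS, p=probs))
        lo, hi = config.regimes[(behaviour, "collar")].duration_range_s
        dur = float(rng.uniform(lo, hi))
        end = min(cursor + pd.Timedelta(seconds=dur), t_end)
        events.append(BehaviourEvent(behaviour, cursor, end))
        cursor = end
    return AnnotationLog(animal_id=animal_id, date=date, events=events)


def synthesize_trace(
    log: AnnotationLog,
    config: StudyConfig,
    deployment: str,
    rng: np.random.Generator | None = None,
) -> AccelTrace:
    """Render an annotation log into a tri-axial acceleration trace.

    Each event emits ``round(duration * rate)`` samples starting at the event
    start; event intervals are half-open, so abutting events never collide
    and timestamps are strictly increasing across the whole trace.
    """
    if rng is None:
        animal_idx = config.animal_ids().index(log.animal_id) if log.animal_id in config.animal_ids() else 0
        day = (log.date - config.start_date).days
        rng = _rng_for(config, 1, animal_idx, day, DEPLOYMENTS.index(deployment))
    rate = config.sampling_rate_hz
    times: list[np.ndarray] = []
    chunks: list[np.ndarray] = []
    for event in log.events:
        key = (event.behaviour, deployment)
        if key not in config.regimes:
            raise KeyError(
                f"no regime defined for behaviour {event.behaviour!r} under "
                f"deployment {deployment!r}"
            )
        regime = config.regimes[key]
        n = int(round(event.duration_s * rate))
        if n == 0:
            continue
        t_rel = np.arange(n) / rate
        # one posture offset and vigour factor per event
        offset = rng.normal(0.0, regime.orient_jitter_sd, size=3)
        vigour = max(0.0, 1.0 + rng.normal(0.0, regime.amp_jitter))
        static = np.tile(np.asarray(regime.static_mean) + offset, (n, 1))
        if regime.alt_static_mean is not None:
            # alternate postures within the event (e.g. bite vs chew)
            sub = (np.floor(t_rel / regime.substate_period_s).astype(int) % 2).astype(bool)
            static[sub] = np.asarray(regime.alt_static_mean) + offset
        phase = rng.uniform(0.0, 2.0 * np.pi, size=3)
        osc = (vigour * np.asarray(regime.osc_amplitude)) * np.sin(
            2.0 * np.pi * regime.osc_frequency_hz * t_rel[:, None] + phase
        )
        noise = rng.normal(0.0, np.asarray(regime.noise_sd), size=(n, 3))
        chunks.append(static + osc + noise)
        times.append(
            event.start.to_datetime64()
            + (t_rel * 1e9).astype("timedelta64[ns]")
        )
    if chunks:
        xyz = np.concatenate(chunks)
        t = pd.to_datetime(np.concatenate(times))
    else:
        xyz = np.empty((0, 3))
        t = pd.to_datetime(np.array([], dtype="datetime64[ns]"))
    data = pd.DataFrame({"t": t, "x": xyz[:, 0], "y": xyz[:, 1], "z": xyz[:, 2]})
    return AccelTrace(
        animal_id=log.animal_id,
        deployment=deployment,
        sampling_rate_hz=rate,
        data=data,
    )


def _timestamp_strings(t: pd.Series) -> np.ndarray:
    """ISO-8601 with millisecond precision, vectorised."""
    return np.datetime_as_string(t.to_numpy().astype("datetime64[ms]"), unit="ms")


def write_signal_csv(trace: AccelTrace, path: Path) -> None:
    """Write a trace in the signal dialect: ``timestamp,x,y,z``."""
    df = pd.DataFrame(
        {
            "timestamp": _timestamp_strings(trace.data["t"]),
            "x": trace.data["x"].to_numpy(),
            "y": trace.data["y"].to_numpy(),
            "z": trace.data["z"].to_numpy(),
        }
    )
    df.to_csv(path, index=False, float_format="%.6f")


def write_annotation_csv(log: AnnotationLog, path: Path) -> None:
    """Write an annotation log in the dialect: ``behaviour,start,end``."""
    df = log.to_frame()
    df["start"] = np.datetime_as_string(
        df["start"].to_numpy().astype("datetime64[ms]"), unit="ms"
    )
    df["end"] = np.datetime_as_string(
        df["end"].to_numpy().astype("datetime64[ms]"), unit="ms"
    )
    df.to_csv(path, index=False)


def write_study(config: StudyConfig, out_dir: str | Path) -> list[Path]:
    """Generate and write a full study.

    Emits one signal CSV per animal x deployment x day
    (``{animal}_{deployment}_day{d}.csv``) and one annotation CSV per
    animal x day (``{animal}_day{d}_annotations.csv``); both deployments of
    an animal-day share the same schedule, as a video annotator would see.
    Returns the list of created paths.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: list[Path] = []
    for animal_id in config.animal_ids():
        for day in range(config.n_days):
            log = sample_schedule(config, day, animal_id)
            ann_path = out / f"{animal_id}_day{day}_annotations.csv"
            try:
                write_annotation_csv(log, ann_path)
            except OSError as exc:
                raise OSError(f"failed writing {ann_path}: {exc}") from exc
            manifest.append(ann_path)
            for deployment in DEPLOYMENTS:
                trace = synthesize_trace(log, config, deployment)
                sig_path = out / f"{animal_id}_{deployment}_day{day}.csv"
                try:
                    write_signal_csv(trace, sig_path)
                except OSError as exc:
                    raise OSError(f"failed writing {sig_path}: {exc}") from exc
                manifest.append(sig_path)
    return manifest


def generate_study(
    config: StudyConfig,
) -> dict[str, list[tuple[AnnotationLog, dict[str, AccelTrace]]]]:
    """In-memory equivalent of :func:`write_study`.

    Returns ``{animal_id: [(log, {deployment: trace}), ...]}`` with one list
    entry per day. Identical seeds give identical data to the CSV path.
    """
    study: dict[str, list[tuple[AnnotationLog, dict[str, AccelTrace]]]] = {}
    for animal_id in config.animal_ids():
        days = []
        for day in range(config.n_days):
            log = sample_schedule(config, day, animal_id)
            traces = {
                dep: synthesize_trace(log, config, dep) for dep in DEPLOYMENTS
            }
            days.append((log, traces))
        study[animal_id] = days
    return study


def scaled_regimes(separation: float) -> dict[tuple[str, str], BehaviourRegime]:
    """Regimes with between-class separation shrunk toward a common centre.

    ``separation=1`` reproduces :func:`default_regimes`; ``separation=0``
    collapses every behaviour onto the deployment-mean static orientation,
    oscillation and noise level, making the classes indistinguishable. Used
    to probe how classifier accuracy responds to class separability; the
    per-event jitter is switched off so epochs carry no bout-level
    fingerprint that a pooled split could exploit instead of class signal.
    """
    base = default_regimes()
    out: dict[tuple[str, str], BehaviourRegime] = {}
    for dep in DEPLOYMENTS:
        regs = [base[(b, dep)] for b in BEHAVIOURS]
        centre_static = np.mean([r.static_mean for r in regs], axis=0)
        centre_amp = np.mean([r.osc_amplitude for r in regs], axis=0)
        centre_freq = float(np.mean([r.osc_frequency_hz for r in regs]))
        centre_noise = np.mean([r.noise_sd for r in regs], axis=0)
        for r in regs:
            shrink = lambda v, c: tuple(c + separation * (np.asarray(v) - c))
            alt = (
                shrink(r.alt_static_mean, centre_static)
                if r.alt_static_mean is not None
                else None
            )
            out[(r.behaviour, dep)] = replace(
                r,
                static_mean=shrink(r.static_mean, centre_static),
                osc_amplitude=shrink(r.osc_amplitude, centre_amp),
                osc_frequency_hz=centre_freq
                + separation * (r.osc_frequency_hz - centre_freq),
                noise_sd=shrink(r.noise_sd, centre_noise),
                alt_static_mean=alt,
                orient_jitter_sd=0.0,
                amp_jitter=0.0,
            )
    return out
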