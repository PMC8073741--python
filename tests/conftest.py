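import datetime as dt

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from bovilick.core import AccelTrace, AnnotationLog, BehaviourEvent
from bovilick.synthio import StudyConfig

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_config() -> StudyConfig:
    """A 2-animal, 30-minute study: small enough for unit tests, large
    enough for every behaviour to contribute several epochs."""
    return StudyConfig(
        n_animals=2,
        n_days=1,
        seed=42,
        observation_window=(dt.time(10, 0), dt.time(10, 30)),
    )


@pytest.fixture(scope="session")
def small_tables(small_config):
    """Pooled feature tables of the small study, per deployment."""
    from bovilick.pipeline import study_feature_table

    return {
        dep: study_feature_table(small_config, dep) for dep in ("collar", "ear")
    }


def make_trace(
    n: int,
    rate: float = 25.0,
    start: str = "2021-03-01 10:00:00",
    values=None,
    animal_id: str = "a00",
    deployment: str = "collar",
) -> AccelTrace:
    """A trace of n samples at the given rate; constant (0, 0, 1) g unless
    explicit values are passed."""
    t = pd.Timestamp(start) + pd.to_timedelta(np.arange(n) / rate, unit="s")
    if values is None:
        xyz = np.tile([0.0, 0.0, 1.0], (n, 1))
    else:
        xyz = np.asarray(values, dtype=float)
    data = pd.DataFrame({"t": t, "x": xyz[:, 0], "y": xyz[:, 1], "z": xyz[:, 2]})
    return AccelTrace(
        animal_id=animal_id,
        deployment=deployment,
        sampling_rate_hz=rate,
        data=data,
    )


def make_log(events, animal_id: str = "a00") -> AnnotationLog:
    """events: list of (behaviour, start str/Timestamp, end str/Timestamp)."""
    evs = [
        BehaviourEvent(b, pd.Timestamp(s), pd.Timestamp(e)) for b, s, e in events
    ]
    date = evs[0].start.date() if evs else dt.date(2021, 3, 1)
    return AnnotationLog(animal_id=animal_id, date=date, events=evs)
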