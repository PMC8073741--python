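"""Epoch segmentation and the twenty per-epoch movement features.

A labelled trace is discretised into fixed-length epochs (default 10 s, i.e.
250 samples at 25 Hz) that never span a behaviour boundary: windows restart
at the first sample of every maximal single-label run, and trailing partial
windows are discarded. Each epoch is summarised into twenty features:

* per-axis minimum, maximum, mean and sample SD (n-1 divisor):
  MIN/MAX/AVG/SD x {X, Y, Z};
* MAG  — mean Euclidean norm, mean_i sqrt(x_i^2 + y_i^2 + z_i^2);
* MVA  — movement variation, the summed mean absolute first difference
  across axes, (sum |dx| + sum |dy| + sum |dz|) / (n - 1);
* SMA  — signal magnitude area, mean_i (|x_i| + |y_i| + |z_i|);
* ENT  — mean_i (1 + s_i)^2 ln (1 + s_i)^2 with s_i = x_i + y_i + z_i
  (a term with s_i = -1 contributes 0, the t ln t limit);
* ENG  — energy, mean squared norm by default (see ``energy_mode``);
* PIT/ROL/INC — pitch atan2(-x, sqrt(y^2+z^2)), roll atan2(y, z) and
  inclination atan2(sqrt(x^2+y^2), z) in degrees, averaged per sample.

MVA proxies movement intensity and SMA separates static from dynamic
activity; AVG_X captures head position (dorso-ventral static component).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import UNLABELLED, LabelledTrace

__all__ = [
    "FEATURE_COLUMNS",
    "KEY_COLUMNS",
    "Epoch",
    "segment_epochs",
    "axis_stats",
    "movement_variation",
    "signal_magnitude_area",
    "magnitude",
    "energy",
    "entropy",
    "orientation_angles",
    "compute_features",
    "build_feature_table",
    "extract_features",
]

log = logging.getLogger(__name__)

#: Canonical feature order, also the CSV column order.
FEATURE_COLUMNS = [
    "MIN_X", "MIN_Y", "MIN_Z",
    "MAX_X", "MAX_Y", "MAX_Z",
    "AVG_X", "AVG_Y", "AVG_Z",
    "SD_X", "SD_Y", "SD_Z",
    "MAG", "MVA", "SMA", "ENT", "ENG",
    "PIT", "ROL", "INC",
]

KEY_COLUMNS = ["animal_id", "deployment", "epoch_start"]


@dataclass
class Epoch:
    """A fixed-length single-behaviour window of raw samples."""

    animal_id: str
    deployment: str
    start_t: pd.Timestamp
    samples: np.ndarray  # (n, 3) float, axis order x, y, z
    label: str

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2 or self.samples.shape[1] != 3:
            raise ValueError("epoch samples must have shape (n, 3)")

    @property
    def n(self) -> int:
        return self.samples.shape[0]


def segment_epochs(lt: LabelledTrace, epoch_s: float = 10.0) -> list[Epoch]:
    """Cut a labelled trace into non-overlapping single-label epochs.

    Runs are maximal stretches with one behaviour label and no sampling gap
    larger than 1.5 sample periods (sensor dropouts split a run). Within
    each run, consecutive windows of exactly ``round(epoch_s * rate)``
    samples start at the run's first sample; the trailing remainder is
    discarded; unlabelled samples never enter an epoch.
    """
    rate = lt.trace.sampling_rate_hz
    n_epoch = int(round(epoch_s * rate))
    if abs(epoch_s * rate - n_epoch) > 1e-9:
        raise ValueError("epoch_s x sampling rate must be an integer sample count")
    t = lt.trace.data["t"].to_numpy()
    xyz = lt.trace.xyz()
    labels = lt.labels
    n = len(labels)
    if n == 0:
        return []
    breaks = np.zeros(n, dtype=bool)
    breaks[0] = True
    if n > 1:
        breaks[1:] |= labels[1:] != labels[:-1]
        gap = np.diff(t) > np.timedelta64(int(1.5e9 / rate), "ns")
        breaks[1:] |= gap
    run_starts = np.flatnonzero(breaks)
    run_ends = np.append(run_starts[1:], n)
    epochs: list[Epoch] = []
    for a, b in zip(run_starts, run_ends):
        label = labels[a]
        if label == UNLABELLED:
            continue
        for s in range(a, b - n_epoch + 1, n_epoch):
            epochs.append(
                Epoch(
                    animal_id=lt.trace.animal_id,
                    deployment=lt.trace.deployment,
                    start_t=pd.Timestamp(t[s]),
                    samples=xyz[s : s + n_epoch],
                    label=str(label),
                )
            )
    return epochs


# ---------------------------------------------------------------------------
# Batch feature kernels: arr has shape (k, n, 3); each returns (k,) arrays.
# The public per-epoch operations wrap these with k = 1.
# ---------------------------------------------------------------------------

def _axis_stats_batch(arr: np.ndarray) -> dict[str, np.ndarray]:
    out: dict[str, np.ndarray] = {}
    mins = arr.min(axis=1)
    maxs = arr.max(axis=1)
    avgs = arr.mean(axis=1)
    sds = arr.std(axis=1, ddof=1)
    for j, ax in enumerate("XYZ"):
        out[f"MIN_{ax}"] = mins[:, j]
        out[f"MAX_{ax}"] = maxs[:, j]
        out[f"AVG_{ax}"] = avgs[:, j]
        out[f"SD_{ax}"] = sds[:, j]
    return out


def _mva_batch(arr: np.ndarray) -> np.ndarray:
    n = arr.shape[1]
    return np.abs(np.diff(arr, axis=1)).sum(axis=(1, 2)) / (n - 1)


def _sma_batch(arr: np.ndarray) -> np.ndarray:
    return np.abs(arr).sum(axis=2).mean(axis=1)


def _norm_batch(arr: np.ndarray) -> np.ndarray:
    return np.sqrt((arr**2).sum(axis=2))


def _mag_batch(arr: np.ndarray) -> np.ndarray:
    return _norm_batch(arr).mean(axis=1)


def _eng_batch(arr: np.ndarray, mode: str = "squared_norm") -> np.ndarray:
    sq = (arr**2).sum(axis=2)
    if mode == "squared_norm":
        return sq.mean(axis=1)
    if mode == "squared_norm_sq":
        return (sq**2).mean(axis=1)
    raise ValueError(f"unknown energy_mode {mode!r}")


def _ent_batch(arr: np.ndarray) -> np.ndarray:
    s = arr.sum(axis=2)
    u = (1.0 + s) ** 2
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(u > 0.0, u * np.log(np.where(u > 0.0, u, 1.0)), 0.0)
    return terms.mean(axis=1)


def _angles_batch(arr: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    x, y, z = arr[..., 0], arr[..., 1], arr[..., 2]
    horiz = np.sqrt(y**2 + z**2)
    # atan2(-x, horiz) equals atan(-x / horiz) on horiz > 0 and gives the
    # +-90 deg limit when horiz == 0; atan2(0, 0) = 0 covers all-zero samples.
    pit = np.degrees(np.arctan2(-x, horiz)).mean(axis=1)
    rol = np.degrees(np.arctan2(y, z)).mean(axis=1)
    inc = np.degrees(np.arctan2(np.sqrt(x**2 + y**2), z)).mean(axis=1)
    return pit, rol, inc


def _features_batch(arr: np.ndarray, energy_mode: str = "squared_norm") -> dict[str, np.ndarray]:
    out = _axis_stats_batch(arr)
    out["MAG"] = _mag_batch(arr)
    out["MVA"] = _mva_batch(arr)
    out["SMA"] = _sma_batch(arr)
    out["ENT"] = _ent_batch(arr)
    out["ENG"] = _eng_batch(arr, energy_mode)
    out["PIT"], out["ROL"], out["INC"] = _angles_batch(arr)
    return out


# ---------------------------------------------------------------------------
# Per-epoch operations
# ---------------------------------------------------------------------------

def _require(epoch: Epoch, n_min: int, what: str) -> None:
    if epoch.n < n_min:
        raise ValueError(f"{what} requires at least {n_min} samples, epoch has {epoch.n}")


def axis_stats(epoch: Epoch) -> dict[str, float]:
    """Per-axis MIN/MAX/AVG and sample SD (n-1 divisor)."""
    _require(epoch, 2, "axis_stats (sample SD)")
    return {k: float(v[0]) for k, v in _axis_stats_batch(epoch.samples[None]).items()}


def movement_variation(epoch: Epoch) -> float:
    """MVA: summed mean absolute first difference over the three axes."""
    _require(epoch, 2, "movement_variation")
    return float(_mva_batch(epoch.samples[None])[0])


def signal_magnitude_area(epoch: Epoch) -> float:
    """SMA: mean of |x| + |y| + |z|."""
    _require(epoch, 1, "signal_magnitude_area")
    return float(_sma_batch(epoch.samples[None])[0])


def magnitude(epoch: Epoch) -> float:
    """MAG: mean Euclidean norm of the samples."""
    _require(epoch, 1, "magnitude")
    return float(_mag_batch(epoch.samples[None])[0])


def energy(epoch: Epoch, mode: str = "squared_norm") -> float:
    """ENG: mean squared norm (``squared_norm``) or mean of the squared
    squared-norm (``squared_norm_sq``) — both readings of an ambiguously
    typeset definition in the accelerometer-feature literature."""
    _require(epoch, 1, "energy")
    return float(_eng_batch(epoch.samples[None], mode)[0])


def entropy(epoch: Epoch) -> float:
    """ENT: mean of (1 + s)^2 ln (1 + s)^2 with s = x + y + z per sample."""
    _require(epoch, 1, "entropy")
    s = epoch.samples.sum(axis=1)
    if np.any(1.0 + s == 0.0):
        log.debug("entropy: degenerate sample(s) with x+y+z = -1, term set to 0")
    return float(_ent_batch(epoch.samples[None])[0])


def orientation_angles(epoch: Epoch) -> tuple[float, float, float]:
    """(PIT, ROL, INC) in degrees, computed per sample then averaged."""
    _require(epoch, 1, "orientation_angles")
    if np.any(~epoch.samples.any(axis=1)):
        log.debug("orientation_angles: all-zero sample(s), angle terms set to 0")
    pit, rol, inc = _angles_batch(epoch.samples[None])
    return float(pit[0]), float(rol[0]), float(inc[0])


def compute_features(epoch: Epoch, energy_mode: str = "squared_norm") -> dict[str, float]:
    """All twenty features of one epoch, in canonical order."""
    _require(epoch, 2, "feature computation")
    vals = _features_batch(epoch.samples[None], energy_mode)
    return {k: float(vals[k][0]) for k in FEATURE_COLUMNS}


def build_feature_table(
    epochs: list[Epoch], energy_mode: str = "squared_norm"
) -> pd.DataFrame:
    """One row per epoch: key columns, the twenty features, and the label.

    Epochs containing non-finite samples or failing a feature precondition
    (n < 2) are skipped with a logged reason. Rows are ordered by
    (animal, deployment, epoch start), deterministically.
    """
    if not epochs:
        raise ValueError("no epochs to build a feature table from")
    usable: list[Epoch] = []
    for ep in epochs:
        if ep.n < 2:
            log.warning("skipping epoch at %s: fewer than 2 samples", ep.start_t)
            continue
        if not np.isfinite(ep.samples).all():
            log.warning("skipping epoch at %s: non-finite samples", ep.start_t)
            continue
        usable.append(ep)
    if not usable:
        raise ValueError("all epochs were skipped (non-finite or too short)")
    rows: list[pd.DataFrame] = []
    # batch epochs of equal length for vectorised feature computation
    by_n: dict[int, list[Epoch]] = {}
    for ep in usable:
        by_n.setdefault(ep.n, []).append(ep)
    for eps in by_n.values():
        arr = np.stack([ep.samples for ep in eps])
        feats = _features_batch(arr, energy_mode)
        df = pd.DataFrame(
            {
                "animal_id": [ep.animal_id for ep in eps],
                "deployment": [ep.deployment for ep in eps],
                "epoch_start": [ep.start_t for ep in eps],
                **{k: feats[k] for k in FEATURE_COLUMNS},
                "label": [ep.label for ep in eps],
            }
        )
        rows.append(df)
    table = pd.concat(rows, ignore_index=True)
    table = table.sort_values(KEY_COLUMNS, kind="mergesort").reset_index(drop=True)
    return table


def extract_features(
    lt: LabelledTrace, epoch_s: float = 10.0, energy_mode: str = "squared_norm"
) -> pd.DataFrame:
    """Segment a labelled trace and build its feature table in one step."""
    return build_feature_table(segment_epochs(lt, epoch_s), energy_mode)
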