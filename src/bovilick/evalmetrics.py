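"""Confusion matrices, classification metrics and qualitative bands.

Conventions: the confusion matrix stores predicted classes as rows and
observed classes as columns. Overall accuracy is trace/total (for two
classes this reduces to (TP + TN) / (TP + TN + FP + FN)); sensitivity is
the one-vs-rest recall TP / (TP + FN) (diagonal over column sum) and PPV
the one-vs-rest precision TP / (TP + FP) (diagonal over row sum), both
reported as percentages. Cohen's kappa is the standard unweighted
chance-corrected agreement computed from the matrix margins.

Qualitative bands: accuracy-like percentages are graded high [90, 100],
moderate [80, 90), low [70, 80), poor [0, 70); kappa follows the McHugh
six-level scale — none (<= 0.20), minimal (0.21-0.39), weak (0.40-0.59),
moderate (0.60-0.79), strong (0.80-0.90), almost perfect (> 0.90).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ConfusionMatrix",
    "MetricsReport",
    "confusion_matrix",
    "overall_accuracy",
    "sensitivity_per_class",
    "ppv_per_class",
    "cohens_kappa",
    "accuracy_band",
    "kappa_band",
    "metrics_report",
    "render_report",
    "read_matrix_csv",
    "round_half_away",
]


@dataclass
class ConfusionMatrix:
    """Square count matrix: rows = predicted class, columns = observed class."""

    classes: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        k = len(self.classes)
        if self.counts.shape != (k, k):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match {k} classes"
            )
        if np.any(self.counts < 0) or not np.issubdtype(self.counts.dtype, np.integer):
            if np.any(self.counts != np.round(self.counts)) or np.any(self.counts < 0):
                raise ValueError("counts must be non-negative integers")
            self.counts = self.counts.astype(int)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.classes, columns=self.classes)


def confusion_matrix(
    predicted,
    observed,
    classes: list[str] | None = None,
) -> ConfusionMatrix:
    """Count matrix with counts[i, j] = #(predicted = class_i and observed = class_j)."""
    predicted = np.asarray(predicted, dtype=object)
    observed = np.asarray(observed, dtype=object)
    if len(predicted) != len(observed):
        raise ValueError(
            f"label lists differ in length: {len(predicted)} vs {len(observed)}"
        )
    if classes is None:
        classes = sorted(set(predicted) | set(observed))
    index = {c: i for i, c in enumerate(classes)}
    unknown = (set(predicted) | set(observed)) - set(index)
    if unknown:
        raise ValueError(f"labels outside the class list: {sorted(unknown)}")
    counts = np.zeros((len(classes), len(classes)), dtype=int)
    for p, o in zip(predicted, observed):
        counts[index[p], index[o]] += 1
    return ConfusionMatrix(classes=list(classes), counts=counts)


def overall_accuracy(cm: ConfusionMatrix) -> float:
    """Overall accuracy as a percentage: 100 * trace / total."""
    if cm.total == 0:
        raise ValueError("cannot compute accuracy of an empty confusion matrix")
    return 100.0 * float(np.trace(cm.counts)) / cm.total


def sensitivity_per_class(cm: ConfusionMatrix) -> dict[str, float | None]:
    """One-vs-rest recall per class (%): diagonal over column sum.

    A class never observed (empty column) is reported as None (undefined),
    not as zero.
    """
    col = cm.counts.sum(axis=0)
    diag = np.diag(cm.counts)
    return {
        c: (100.0 * diag[i] / col[i] if col[i] > 0 else None)
        for i, c in enumerate(cm.classes)
    }


def ppv_per_class(cm: ConfusionMatrix) -> dict[str, float | None]:
    """One-vs-rest precision per class (%): diagonal over row sum.

    A class never predicted (empty row) is reported as None (undefined).
    """
    row = cm.counts.sum(axis=1)
    diag = np.diag(cm.counts)
    return {
        c: (100.0 * diag[i] / row[i] if row[i] > 0 else None)
        for i, c in enumerate(cm.classes)
    }


def cohens_kappa(cm: ConfusionMatrix) -> float:
    """Unweighted Cohen's kappa from the matrix margins.

    kappa = (p_o - p_e) / (1 - p_e), with observed agreement p_o =
    trace/total and chance agreement p_e = sum_c row_c * col_c / total^2.
    A degenerate matrix with p_e = 1 has kappa 1 if agreement is perfect,
    otherwise kappa is undefined.
    """
    total = cm.total
    if total == 0:
        raise ValueError("cannot compute kappa of an empty confusion matrix")
    p_o = float(np.trace(cm.counts)) / total
    row = cm.counts.sum(axis=1).astype(float)
    col = cm.counts.sum(axis=0).astype(float)
    p_e = float(np.dot(row, col)) / total**2
    if p_e >= 1.0 - 1e-15:
        if p_o >= 1.0 - 1e-15:
            return 1.0
        raise ValueError("kappa undefined: chance agreement is 1 with imperfect agreement")
    return (p_o - p_e) / (1.0 - p_e)


def accuracy_band(percent: float) -> str:
    """Qualitative band for an accuracy-like percentage."""
    if not 0.0 <= percent <= 100.0:
        raise ValueError(f"percentage out of range: {percent}")
    if percent >= 90.0:
        return "high"
    if percent >= 80.0:
        return "moderate"
    if percent >= 70.0:
        return "low"
    return "poor"


def kappa_band(kappa: float) -> str:
    """McHugh six-level agreement band for a kappa value."""
    if not -1.0 <= kappa <= 1.0:
        raise ValueError(f"kappa out of range: {kappa}")
    if kappa <= 0.20:
        return "none"
    if kappa < 0.40:
        return "minimal"
    if kappa < 0.60:
        return "weak"
    if kappa < 0.80:
        return "moderate"
    if kappa <= 0.90:
        return "strong"
    return "almost perfect"


def round_half_away(value: float, decimals: int = 1) -> float:
    """Round half away from zero (the convention of printed report tables)."""
    factor = 10.0**decimals
    return float(np.sign(value) * np.floor(abs(value) * factor + 0.5) / factor)


@dataclass
class MetricsReport:
    """All headline metrics of one confusion matrix."""

    classes: list[str]
    overall_accuracy: float
    kappa: float
    sensitivity: dict[str, float | None]
    ppv: dict[str, float | None]
    accuracy_band: str
    kappa_band: str

    def to_dict(self) -> dict:
        return {
            "classes": self.classes,
            "overall_accuracy": self.overall_accuracy,
            "kappa": self.kappa,
            "sensitivity": self.sensitivity,
            "ppv": self.ppv,
            "accuracy_band": self.accuracy_band,
            "kappa_band": self.kappa_band,
        }


def metrics_report(cm: ConfusionMatrix) -> MetricsReport:
    """Compute accuracy, kappa, per-class sensitivity/PPV and both bands."""
    acc = overall_accuracy(cm)
    kap = cohens_kappa(cm)
    return MetricsReport(
        classes=list(cm.classes),
        overall_accuracy=acc,
        kappa=kap,
        sensitivity=sensitivity_per_class(cm),
        ppv=ppv_per_class(cm),
        accuracy_band=accuracy_band(acc),
        kappa_band=kappa_band(kap),
    )


def render_report(
    cm: ConfusionMatrix, report: MetricsReport, out_dir: str | Path
) -> list[Path]:
    """Write the confusion matrix (CSV, predicted rows x observed columns)
    and the metrics (JSON, raw unrounded values) to a directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cm_path = out / "confusion_matrix.csv"
    cm.to_frame().rename_axis("predicted").to_csv(cm_path)
    metrics_path = out / "metrics.json"
    metrics_path.write_text(json.dumps(report.to_dict(), indent=2) + "\n")
    return [cm_path, metrics_path]


def read_matrix_csv(path: str | Path) -> ConfusionMatrix:
    """Read a confusion matrix CSV written by :func:`render_report` (first
    column = predicted class names, header = observed class names)."""
    df = pd.read_csv(path, index_col=0)
    if list(df.index) != list(df.columns):
        raise ValueError(
            f"{path}: predicted and observed class sets differ "
            f"({list(df.index)} vs {list(df.columns)})"
        )
    return ConfusionMatrix(classes=list(df.columns), counts=df.to_numpy())
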