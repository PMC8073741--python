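"""Reference random-forest confusion matrices from the original penned-cattle
licking study this pipeline re-implements.

The study reported test-set confusion matrices of its best (random forest)
classifier for each ethogram x deployment, with predicted behaviour as rows
and observed behaviour as columns, together with the derived overall
accuracy, Cohen's kappa and per-class sensitivity/PPV. The count matrices
are embedded here as the validation surface for :mod:`bovilick.evalmetrics`:
every reported metric must be recomputable from the counts.

Display convention of the source tables: proportions were first rounded to
four decimal places (the print precision of the R tooling that produced
them) and then converted to a one-decimal percentage, half away from zero.
Four reported values (96.7, 91.9, 95.2 and 98.5) differ from directly
rounding the exact fraction by this double rounding; :func:`printed_percent`
reproduces the convention, under which all reported values match exactly.
"""

from __future__ import annotations

from .evalmetrics import ConfusionMatrix, round_half_away

__all__ = [
    "REFERENCE_MATRICES",
    "REPORTED",
    "reference_matrix",
    "printed_percent",
    "printed_kappa",
]

_E1 = ["licking", "eating", "standing", "lying"]
_E2 = ["licking", "eating", "inactive"]
_E3 = ["licking", "non-licking"]

#: (deployment, ethogram id) -> (class order, predicted-x-observed counts)
REFERENCE_MATRICES: dict[tuple[str, int], tuple[list[str], list[list[int]]]] = {
    ("collar", 1): (_E1, [[183, 8, 2, 0],
                          [2, 175, 12, 4],
                          [1, 0, 154, 14],
                          [0, 1, 10, 144]]),
    ("ear", 1): (_E1, [[166, 3, 13, 1],
                       [7, 173, 8, 1],
                       [4, 2, 137, 29],
                       [1, 1, 15, 119]]),
    ("collar", 2): (_E2, [[185, 10, 3],
                          [1, 169, 18],
                          [0, 5, 317]]),
    ("ear", 2): (_E2, [[165, 5, 4],
                       [1, 170, 7],
                       [12, 4, 312]]),
    ("collar", 3): (_E3, [[175, 7],
                          [9, 515]]),
    ("ear", 3): (_E3, [[160, 11],
                       [18, 491]]),
}

#: Reported random-forest metrics per (deployment, ethogram), exactly as
#: printed: overall accuracy (%), kappa, per-class sensitivity/PPV (%) in
#: class order.
REPORTED: dict[tuple[str, int], dict] = {
    ("collar", 1): {
        "accuracy": 92.4, "kappa": 0.90,
        "sensitivity": [98.4, 95.1, 86.5, 88.9],
        "ppv": [94.8, 90.7, 91.1, 92.9],
    },
    ("ear", 1): {
        "accuracy": 87.5, "kappa": 0.83,
        "sensitivity": [93.3, 96.7, 79.2, 79.3],
        "ppv": [90.7, 91.5, 79.7, 87.5],
    },
    ("collar", 2): {
        "accuracy": 94.8, "kappa": 0.92,
        "sensitivity": [99.5, 91.9, 93.8],
        "ppv": [93.4, 89.9, 98.5],
    },
    ("ear", 2): {
        "accuracy": 95.2, "kappa": 0.92,
        "sensitivity": [92.7, 95.0, 96.6],
        "ppv": [94.8, 95.5, 95.1],
    },
    ("collar", 3): {
        "accuracy": 97.7, "kappa": 0.94,
        "sensitivity": [95.1, 98.7],
        "ppv": [96.2, 98.3],
    },
    ("ear", 3): {
        "accuracy": 95.7, "kappa": 0.89,
        "sensitivity": [89.9, 97.8],
        "ppv": [93.6, 96.5],
    },
}


def reference_matrix(deployment: str, ethogram: int) -> ConfusionMatrix:
    """The reference confusion matrix for one deployment x ethogram."""
    classes, counts = REFERENCE_MATRICES[(deployment, ethogram)]
    return ConfusionMatrix(classes=list(classes), counts=counts)


def printed_percent(percent: float) -> float:
    """Render a raw percentage the way the reference tables print it:
    the proportion rounded to 4 decimals, then the percent to 1 decimal."""
    return round_half_away(round_half_away(percent / 100.0, 4) * 100.0, 1)


def printed_kappa(kappa: float) -> float:
    """Kappa as printed: two decimals, half away from zero."""
    return round_half_away(kappa, 2)
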