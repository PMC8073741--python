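"""Compute all evaluation metrics directly from a confusion matrix.

Works from any predicted x observed count matrix — here the embedded
reference random-forest matrix of the neck-collar four-behaviour ethogram.
Sensitivity is one-vs-rest recall (column-wise), PPV one-vs-rest precision
(row-wise), and kappa the chance-corrected overall agreement.
"""

from bovilick.evalmetrics import metrics_report
from bovilick.reference import reference_matrix

cm = reference_matrix("collar", 1)
print("confusion matrix (rows = predicted, columns = observed):")
print(cm.to_frame().to_string(), "\n")

rep = metrics_report(cm)
print(f"overall accuracy {rep.overall_accuracy:.1f}%  ({rep.accuracy_band})")
print(f"Cohen's kappa    {rep.kappa:.2f}   ({rep.kappa_band})")
for cls in cm.classes:
    print(f"  {cls:9s} sensitivity {rep.sensitivity[cls]:5.1f}%  PPV {rep.ppv[cls]:5.1f}%")
# 656 of 710 epochs on the diagonal: 92.4% accuracy, kappa 0.90 — the
# licking class is recovered with 98.4% sensitivity and 94.8% precision.
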