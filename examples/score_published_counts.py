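"""Score a published per-class count table with the metrics module.

Feeds class-wise TP/FP/FN/TN counts of a five-grade retinopathy classifier
into the report builder and prints per-class precision/recall/F1 plus the
macro and weighted aggregates and the overall accuracy.
"""

from hirdnet.metrics import report_from_class_counts

counts = {  # TP, FP, FN, TN per severity grade
    "Normal": (1961, 1, 12, 2217),
    "Mild": (350, 48, 45, 3828),
    "Moderate": (1105, 59, 62, 3073),
    "Severe": (222, 108, 64, 3956),
    "Proliferative": (267, 57, 90, 3911),
}

report = report_from_class_counts(list(counts.values()), tuple(counts))
print(f"{'class':>14}  {'prec%':>6} {'rec%':>6} {'F1%':>7} {'support':>8}")
for name, m in zip(counts, report.per_class):
    print(f"{name:>14}  {m.precision:6.1f} {m.recall:6.1f} {m.f1:7.2f} {m.support:8d}")
print(f"\nmacro    prec/rec/F1 : {report.macro_precision:.2f} / "
      f"{report.macro_recall:.2f} / {report.macro_f1:.2f}")
print(f"weighted prec/rec/F1 : {report.weighted_precision:.2f} / "
      f"{report.weighted_recall:.2f} / {report.weighted_f1:.2f}")
print(f"overall accuracy     : {report.accuracy:.2f}%")
# weighted recall always equals the overall accuracy (algebraic identity)
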