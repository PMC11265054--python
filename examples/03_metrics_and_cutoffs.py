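"""Confusion-matrix metrics, ROC/AUC, and Youden cutoff calibration.

Recomputes the full metric family from a printed validation confusion
matrix, then calibrates an operating threshold on a small score set and
applies the three-way record decision rule.
"""

from lorenzaf import (ConfusionMatrix, RecordClass, ThresholdSet, auc,
                      classification_metrics, classify_record, record_score,
                      roc_curve, youden_cutoff)

# metrics from raw 2x2 counts (AF = positive class)
cm = ConfusionMatrix(tp=66509, fn=514, fp=1791, tn=65771)
rep = classification_metrics(cm).rounded(3)
print("internal-validation-style matrix:", cm)
print("  " + "  ".join(f"{k}={v}" for k, v in rep.items() if v is not None))

# Youden-calibrated cutoff on a toy score set
scores = [0.05, 0.1, 0.2, 0.55, 0.6, 0.75, 0.9, 0.95]
labels = [0, 0, 0, 0, 1, 1, 1, 1]
curve = roc_curve(scores, labels)
cut = youden_cutoff(curve)
print(f"\ntoy ROC: AUC={auc(curve):.3f}, Youden-optimal cutoff={cut}")
print("  (J is maximized where the classes split; ties pick the higher,"
      " more specific threshold)")

# record-level three-way decision on AF burden fractions
ts = ThresholdSet(ls_cutoff=cut, record_af_cutoff=0.007, persistent_cutoff=0.948)
for window_scores in ([0.1, 0.2, 0.1, 0.15], [0.9, 0.1, 0.8, 0.2], [0.9] * 20):
    burden = record_score(window_scores, ts.ls_cutoff)
    decision = classify_record(burden, ts)
    print(f"  window scores {str(window_scores[:4]):28s}... "
          f"burden={burden:.2f} -> {decision.value}")

assert classify_record(0.007, ts) is RecordClass.PAROXYSMAL_AF  # inclusive bound
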