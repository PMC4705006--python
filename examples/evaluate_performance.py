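"""Diagnostic-test evaluation of a surveillance run.

Feeds a month-long patient-level confusion matrix (160 true positives, 3
missed cases, 7 false alarms, 17,824 true negatives over 17,994 evaluated
patients) to the metrics engine and prints sensitivity, specificity, PPV,
NPV with exact Clopper-Pearson 95% CIs, and Cohen's kappa.
"""

from habsi import ConfusionMatrix, compute_metrics

cm = ConfusionMatrix(tp=160, fn=3, fp=7, tn=17_824)
metrics = compute_metrics(cm)

print(f"evaluated patients: {cm.total}")
for name in ("sensitivity", "specificity", "ppv", "npv"):
    m = getattr(metrics, name)
    print(f"{name:12s} {m.pct:6.2f}%   (95% CI {100 * m.ci_low:.2f}-{100 * m.ci_high:.2f})")
k = metrics.kappa
print(f"kappa        {k.rounded:6.2f}    (95% CI {k.ci_low:.2f}-{k.ci_high:.2f})")
# Sensitivity and NPV say how little the system misses; PPV says how much
# human review effort each alert costs; kappa near 1 means the automated
# calls agree with the reference standard almost perfectly.
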