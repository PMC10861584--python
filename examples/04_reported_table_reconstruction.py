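"""Worked example: diagnostic metrics from printed rates alone.

A published 64-subject urine-VOC study reports, for the rule
gap1S2 >= 30, sensitivity 40.6% and specificity 87.5% at 32 cancer / 32
control subjects.  Reconstructing the integer 2x2 table from those rates
recovers every other printed metric: PPV, NPV, accuracy, the odds ratio
with its Woolf 95% CI, and the logistic-regression Wald p.
"""

import numpy as np

from urovoc import confusion_from_rates, diagnostic_metrics, fit_logistic_univariable

for name, sens, spec in [("gap1S2 >= 30", 0.406, 0.875),
                         ("gap4S2 >= 862", 0.750, 0.594)]:
    tab = confusion_from_rates(sens, spec, 32, 32)
    m = diagnostic_metrics(tab)
    x = np.r_[np.ones(tab.tp), np.zeros(tab.fn), np.ones(tab.fp), np.zeros(tab.tn)]
    y = np.r_[np.ones(32), np.zeros(32)]
    orr, lo, hi, p = fit_logistic_univariable(x, y)
    print(f"{name}: TP={tab.tp} FP={tab.fp} FN={tab.fn} TN={tab.tn}")
    print(
        f"  PPV {100 * m.ppv:.1f}%  NPV {100 * m.npv:.1f}%  "
        f"accuracy {100 * m.accuracy:.1f}%"
    )
    print(
        f"  OR {m.odds_ratio:.2f} (Woolf 95% CI {m.or_ci_low:.2f}-"
        f"{m.or_ci_high:.2f}); logistic OR {orr:.2f}, Wald p {p:.3f}"
    )
print(
    "\nFor a binary rule the ML logistic OR equals the 2x2 cross-product"
    "\nOR and the Wald CI equals the Woolf CI - a useful internal check."
)
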