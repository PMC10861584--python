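"""Simulate a small labelled cohort and extract the per-cycle features.

Each subject gets one resistance trace per sensor under the 5-step heater
protocol (2000/2500/3500/4500/5000 mV, 80 s each).  Feature columns are
named {param}{cycle}S{sensor}: e.g. gap1S2 is the resistance drop of
sensor 2 in cycle 1.
"""

from urovoc import build_feature_table, default_config, generate_cohort

cfg = default_config(n_cancer=4, n_noncancer=4, seed=0)
traces, labels = generate_cohort(cfg)
table = build_feature_table(traces)

print(f"{len(traces)} traces -> feature table {table.shape[0]} x {table.shape[1]}")
print(table[["min1S2", "gap1S2", "t1S2", "SL1S2", "gap4S2"]].round(2))
print("\nClass labels:", labels.classes)
print(
    "\ngap1S2 and gap4S2 are the class-separated features (cancer drops are"
    "\nlarger on sensor 2, cycles 1 and 4); min is in ohms, t in seconds,"
    "\nSL in ohm/s."
)
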