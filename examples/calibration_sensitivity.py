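"""How structural modelling choices move the lifetime results.

The published analysis under-specifies three mechanics: whether the
constant recurrence hazard continues past year 10, whether rewards use a
half-cycle correction, and the size of the fatal chemotherapy toxicity
risk.  This script evaluates the base case under each combination so the
sensitivity of the ICER, QALY gain and downstream cost changes to those
choices is explicit.
"""

import dataclasses

import pandas as pd

from ceassay import default_inputs, evaluate_both

base = default_inputs("japan")
rows = []
for hazard_mode in ("lifetime", "first_10_years"):
    for half_cycle in (True, False):
        for toxicity in (0.002, 0.0):
            b = base.replace_value("settings.fatal_toxicity_risk", toxicity)
            settings = dataclasses.replace(
                b.settings,
                recurrence_hazard_mode=hazard_mode,
                half_cycle_correction=half_cycle,
            )
            b = dataclasses.replace(b, settings=settings)
            wo, wi, inc = evaluate_both(b)
            rows.append(
                {
                    "hazard_mode": hazard_mode,
                    "half_cycle": half_cycle,
                    "fatal_toxicity": toxicity,
                    "icer": round(inc.icer),
                    "delta_qaly": round(inc.delta_qaly, 4),
                    "delta_monitoring": round(wi.cost_monitoring - wo.cost_monitoring),
                    "delta_recurrence": round(wi.cost_recurrence - wo.cost_recurrence),
                }
            )

print(pd.DataFrame(rows).to_string(index=False))
print(
    "\nThe lifetime hazard and half-cycle defaults reproduce the published\n"
    "numbers most closely; truncating the recurrence hazard at 10 years\n"
    "shrinks the recurrence-cost offset, and removing fatal toxicity\n"
    "slightly lowers the QALY gain of avoiding chemotherapy."
)
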