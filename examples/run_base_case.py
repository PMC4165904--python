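"""Base-case analysis: usual care vs 21-gene-assay-guided chemotherapy.

Loads the bundled inputs (the 104-patient decision-impact cohort, Japanese
recurrence-risk estimates, 2013 JPY costs), evaluates both strategy arms and
prints the incremental results.
"""

import pandas as pd

from ceassay import default_inputs, evaluate_both
from ceassay.report import results_frame

bundle = default_inputs("japan")
without, with_assay, inc = evaluate_both(bundle)

with pd.option_context("display.float_format", "{:,.4f}".format):
    print(results_frame(without, with_assay, inc, usd=True).to_string(index=False))
print()
print(f"QALYs gained per patient:   {inc.delta_qaly:8.3f}")
print(f"extra lifetime cost (JPY):  {inc.delta_cost:12,.0f}")
print(f"cost per QALY gained (JPY): {inc.icer:12,.0f}")
print()
print(
    "The assay arm treats 19.2% fewer patients with chemotherapy, saving\n"
    "about Y154,000 in acute costs per patient; after the Y350,000 assay\n"
    "cost and the downstream recurrence effects, each QALY gained costs\n"
    "roughly Y0.6M - far below conventional willingness-to-pay thresholds."
)
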