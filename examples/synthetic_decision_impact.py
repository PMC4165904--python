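"""Generate a synthetic decision-impact study and refit the model to it.

Samples patient-level risk groups and paired pre/post-assay chemotherapy
recommendations at the observed cohort's rates, aggregates them back into
risk-group inputs, and shows that a large synthetic cohort recovers the
base-case ICER.
"""

import dataclasses

from ceassay import (
    SyntheticCohortSpec,
    default_inputs,
    evaluate_both,
    generate_decision_impact_table,
)

base = default_inputs("japan")

# a study-sized replicate (n = 104)
spec = SyntheticCohortSpec.from_bundle(base, n_patients=104, seed=7)
table, groups = generate_decision_impact_table(spec, base)
print("one synthetic 104-patient study:")
for g in groups:
    print(
        f"  {g.label:12s} n={g.n_patients:3d}  chemo pre={g.n_chemo_pre:2d}"
        f"  post={g.n_chemo_post:2d}"
    )

# a large replicate: rates converge, the refitted ICER matches the base case
big = SyntheticCohortSpec.from_bundle(base, n_patients=200_000, seed=7)
_, big_groups = generate_decision_impact_table(big, base)
refit = dataclasses.replace(base, groups=big_groups)
print(f"\nbase-case ICER:   JPY {evaluate_both(base)[2].icer:,.0f}/QALY")
print(f"refit at n=200k:  JPY {evaluate_both(refit)[2].icer:,.0f}/QALY")
print(
    "\nSampling noise in the recommendation rates moves the ICER by only a\n"
    "few percent at large n - the pipeline recovers its own parameters."
)
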