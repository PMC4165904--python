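"""Break-even chemotherapy drug cost.

Searches for the drug cost at which the assay arm's total lifetime cost
equals usual care's: above it, testing is cost-saving outright.
"""

from ceassay import default_inputs, threshold_chemo_cost

for source in ("japan", "us_uk"):
    bundle = default_inputs(source)
    threshold = threshold_chemo_cost(bundle)
    print(f"{source:6s}: break-even chemotherapy drug cost JPY {threshold:,.0f}")

print(
    "\nAt the 2013 base price (JPY 561,813) the assay adds net cost; once a\n"
    "regimen costs more than ~JPY 1.4M (Japan risks) or ~JPY 1.5M (US/UK\n"
    "risks) - e.g. third-generation regimens with prophylactic G-CSF - the\n"
    "chemotherapy avoided by testing pays for the assay."
)
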