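"""Compare candidate human regimens by steady-state brain exposure and effect.

30 mg three-times-daily vs 60 mg twice-daily over 7 days: the b.i.d. arm
roughly doubles peak brain exposure but buys almost no additional effect,
because both regimens already sit on the plateau of the sigmoid Emax curve.
"""

from pbpkpd import scenarios
from pbpkpd.regimens import parse_regimen, regimen_compare

model = scenarios.reference_model("human")
table = regimen_compare(
    model,
    [parse_regimen("30mg t.i.d. x7d"), parse_regimen("60mg b.i.d. x7d")],
    scenarios.reference_pd_params(),
)
print(table.to_string(index=False, float_format="%.2f"))

# fraction_above_threshold is the share of the dosing interval the brain
# level exceeds EC50 (10.6 ng/mL): 30 mg t.i.d. covers the full day with a
# third less drug, which is the rationale for selecting it.
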