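"""Balance sheets of the three growth conditions, plus the Fdh-Ech sensitivity.

Builds the built-in high-H2, low-H2 and CO scenarios, validates that every
electron carrier closes exactly, and prints each net reaction with its
proton and ATP totals. The high-H2 ledger gives 2 H+ -> 0.5 ATP and the CO
ledger 6 H+ -> 1.5 ATP at 4 H+/ATP; low H2 shares the high-H2 net reaction
but loses (and reverses) the Fdh-Ech coupling site, which the final sweep
over x makes visible.
"""

from fractions import Fraction

from acetoledger.ledger import atp_yield, validate_scenario
from acetoledger.scenarios import ScenarioOptions, apply_formate_cycle, build_scenario

for name in ("high_h2", "low_h2", "co"):
    scenario = build_scenario(name)
    assert validate_scenario(scenario) == []
    print(atp_yield(scenario).to_table())
    print()

print("ATP per acetate as a function of the unknown Fdh-Ech proton number x:")
print("x    high_h2  low_h2   co")
for x in range(0, 3):
    options = ScenarioOptions(ech_protons=Fraction(x))
    row = [float(atp_yield(build_scenario(n, options)).atp_chemiosmotic) for n in ("high_h2", "low_h2", "co")]
    print(f"{x}    {row[0]:<8g} {row[1]:<8g} {row[2]:g}")

cycled = apply_formate_cycle(build_scenario("high_h2"), loop_protons_per_formate=2)
print(f"\nhigh_h2 with formate cycle (+2 H+ per formate cycled): "
      f"{float(atp_yield(cycled).atp_chemiosmotic):g} ATP")
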