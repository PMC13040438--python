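"""Free energies of the key electron transfers and the H2-pressure feasibility window.

Builds nothing external: couples come from the shipped registry. Prints the
standard free energy of formate oxidation to H2 + CO2 (slightly exergonic,
~-3 kJ/mol, the Fdh-Ech coupling site), the endergonic menaquinol ->
methylene-THF transfer the confurcating MTHFR must drive (+24.3 kJ/mol),
and the H2 pressure below which hydrogen can no longer hold the NADPH pool
at its cellular poise of -370 mV (~0.03 atm), which is where NADPH-dependent
CO2 reduction loses its driver.
"""

import numpy as np

from acetoledger.thermo import (
    delta_g_prime,
    delta_g_standard,
    feasibility_sweep,
    get_couple,
    h2_potential,
)

dg_formate = delta_g_standard(get_couple("co2_formate"), get_couple("h2"), 2)
print(f"formate -> H2 + CO2 (2 e-):       dG0' = {dg_formate:+.2f} kJ/mol (rounds to {round(dg_formate):+d})")

dg_mq = delta_g_standard(get_couple("mq_mqh2"), get_couple("methylene_methyl_thf"), 2)
print(f"MQH2 -> methylene-THF (2 e-):     dG0' = {dg_mq:+.1f} kJ/mol (endergonic, needs confurcation)")

shifted = delta_g_prime(dg_formate, 100.0)
print(f"formate oxidation, 100x quotient: dG'  = {shifted:+.2f} kJ/mol (now endergonic)")

for p in (1.0, 1e-2, 1e-4):
    print(f"E(H+/H2) at {p:g} atm H2: {h2_potential(p):+.1f} mV")

sweep = feasibility_sweep(get_couple("h2"), np.logspace(-6, 1, 100), target=get_couple("nadp"))
print(f"H2 can reduce NADP+ (pool at -370 mV) down to ~{sweep.crossover_atm:.3f} atm H2")
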