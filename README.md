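# acetoledger

Bioenergetic ledgers and transcriptome arithmetic for acetogenic bacteria.

Acetogens fix CO₂ through the Wood–Ljungdahl pathway (WLP), and in
*Moorella thermoacetica* — the one acetogen with both cytochromes and
menaquinone — the chemiosmotic side of autotrophic growth runs through an
unusual chain: a NADP⁺-reducing hydrogenase, a putative formate-dehydrogenase–
Ech respiratory complex (Fdh–Ech), an Fd²⁻-oxidising, menaquinone-reducing
NADH dehydrogenase, the electron-confurcating EtfABCX and Type IV MTHFR, and
a menaquinone redox loop. `acetoledger` turns that model into checkable
arithmetic:

* **thermo** — redox-couple registry and free-energy calculator.
  ΔG₀′ = −nF(E₀′_acc − E₀′_don), ΔG′ = ΔG₀′ + RT ln Q, and the Nernst
  correction E(H⁺/H₂) = E₀′ − (RT/2F) ln pH₂, plus feasibility sweeps over
  H₂ partial pressure with a bisection crossover.
* **ledger / scenarios** — exact-rational stoichiometric balance sheets for
  three growth conditions (high H₂, low H₂, CO), normalized to one acetate.
  Every electron-pair carrier (Fd²⁻, NADH, NADPH, MQH₂ — one pair each)
  must net to exactly zero; per-step electron-pair audits are recomputed;
  vectorial protons and substrate-level ATP are totalled, with
  ATP = H⁺ translocated / (H⁺/ATP quotient, default 4).
* **deg** — two-condition differential expression: median-of-ratios size
  factors, a negative-binomial Wald test (method-of-moments dispersion,
  small-sample t reference), Benjamini–Hochberg adjustment and the DEG rule
  |log2FC| ≥ 2 and adjusted p < 0.05, with category summaries.
* **assays** — specific enzyme activities from absorbance traces through
  Beer–Lambert (1 U = 2 μmol electrons · min⁻¹), activity fold changes, and
  log-linear growth fits (μ, doubling time ln 2/μ).
* **synth** — seeded generators for all of the above: NB count matrices
  with planted fold changes, exponential OD₆₀₀ curves, linear assay traces.

## Worked example

```python
from fractions import Fraction
from acetoledger.thermo import delta_g_standard, get_couple
from acetoledger.scenarios import build_scenario, ScenarioOptions
from acetoledger.ledger import atp_yield

dg = delta_g_standard(get_couple("co2_formate"), get_couple("h2"), 2)
print(round(dg, 2))                       # -3.47  (kJ/mol; formate -> H2 + CO2 is near equilibrium)

report = atp_yield(build_scenario("co"))
print(report.protons_translocated)        # 6      (5 H+ at the NADH dehydrogenase + 1 redox-loop H+)
print(float(report.atp_chemiosmotic))     # 1.5    (ATP per acetate at 4 H+/ATP)

low = build_scenario("low_h2", ScenarioOptions(ech_protons=Fraction(2)))
print(float(atp_yield(low).atp_chemiosmotic))  # 0.0  (reversed Fdh-Ech consumes the gradient)
```

The first number says formate oxidation to H₂ is almost thermoneutral —
which is why the Fdh–Ech site can run in either direction depending on H₂
pressure. The CO ledger closes all four carrier balances exactly and
converts its six vectorial protons into 1.5 ATP per acetate; at low H₂ the
same net chemistry yields less, and the unknown Fdh–Ech proton number `x`
is an explicit parameter.

Each capability has a narrative script under `examples/`
(`redox_thermodynamics.py`, `scenario_ledgers.py`,
`differential_expression.py`, `assays_and_growth.py`); run them with
`python examples/<name>.py`. A thin CLI mirrors the library:
`acetoledger scenario run --name co`, `acetoledger thermo dg --donor
co2_formate --acceptor h2`, `acetoledger deg ...`, `acetoledger simulate ...`.

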