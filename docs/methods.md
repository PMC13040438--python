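# Methods

## Redox thermodynamics

Electron-transfer free energies use ΔG₀′ = −n·F·(E₀′_acceptor − E₀′_donor)
with potentials in mV, F = 96.485 kJ·V⁻¹·mol⁻¹, and energies in kJ/mol;
negative means exergonic transfer in the stated direction. Concentration
corrections use ΔG′ = ΔG₀′ + RT ln Q with R = 8.314×10⁻³ kJ·mol⁻¹·K⁻¹.
The default temperature is 298.15 K because standard-condition values
(e.g. the near-equilibrium −3 kJ/mol for formate → H₂ + CO₂ and the
+24.3 kJ/mol menaquinol → methylene-THF transfer) presuppose 25 °C
constants; the 55 °C growth temperature (328.15 K) is available through
`ThermoParams`/`at_growth_temperature`.

The couples registry (`data/redox_couples.tsv`) carries a `source` tag:
CO₂/formate (−432 mV), NAD (−320/−270 mV), NADP (−320 mV standard,
−370 mV cellular), ferredoxin (−450 and −500 mV endpoints) and MQ/MQH₂
(−74 mV) are model constants; H⁺/H₂ (−414 mV) and
CH₂=THF/CH₃-THF (−200 mV) are literature constants, fixed by requiring
consistency with the −3 and +24.3 kJ/mol values above.

The H₂ Nernst correction is E = E₀′ − (RT/2F) ln pH₂, i.e.
29.58 mV per decade at 298.15 K, with lower pressure giving a weaker
reductant. `feasibility_sweep` evaluates ΔG′ = −nF(E_target − E_reductant)
across a pressure list: the reductant potential follows the H₂ Nernst
curve when the reductant is the H⁺/H₂ couple (the pool is assumed
equilibrated with gas-phase H₂), and otherwise stays at the couple's
cellular-else-standard potential. The ΔG′ = 0 crossover is located by
bisection on log₁₀ p to 10⁻⁶ decades; with the NADP pool as target the
crossover lands at ≈0.033 atm, the pressure below which H₂ can no longer
hold NADPH at its −370 mV poise and NADPH-dependent CO₂ reduction loses
its driver.

Concentration-shift convention: "a tenfold shift of educts and products"
is interpreted as a 100-fold reaction quotient at 298.15 K, giving
+7.9 kJ/mol for formate oxidation (conventions ranging over which species
shift and at which temperature give 7.9–9.1 kJ/mol); the convention is a
function argument, not a buried constant.

## Scenario ledgers

A scenario is an ordered list of enzyme-level steps with rational flux
multipliers normalized to one acetate. All balances use
`fractions.Fraction`, so closure means exactly zero, not within
tolerance. Conventions:

* **Carriers.** Fd²⁻, NADH, NADPH and MQH₂ each carry one electron pair.
  Counting reduced ferredoxin as a one-pair carrier is forced by the CO
  ledger's coefficients (0.75 MQH₂ + 0.75 Fd²⁻ → 1.5 NADH balances only
  then).
* **Pair audit.** Every metabolite has a fixed reduction level in pairs
  (H₂ = CO = formate = formyl-THF = methenyl-THF = 1, methylene-THF = 2,
  methyl-THF = 3, acetate = 4, relative to CO₂/2H⁺/THF). Per step, pairs
  entering (oxidised carriers + consumed reduced metabolites) must equal
  pairs leaving, and the declared `pairs_transferred` must equal the
  recomputed flow; the validator rejects mismatches.
* **Protons.** Vectorial protons only: the NADH dehydrogenase translocates
  4 H⁺ per MQ reduced (forced by "1.25 MQ ↔ five protons"); the
  menaquinone redox loop yields 2 H⁺ per MQH₂ oxidised, credited at the
  MTHFR step (1 H⁺ per 0.5 MQH₂); the Fdh–Ech site translocates `x` H⁺
  per formate with sign reversal when run in reverse. `x` is unknown in
  vivo and defaults to 0 — it is an explicit option, never silently
  nonzero. Chemiosmotic ATP = net vectorial H⁺ / (H⁺/ATP quotient),
  default 4. Substrate-level ATP: −1 at the formyl-THF synthetase, +1 at
  acetate kinase.
* **Water and scalar protons.** Scalar (non-vectorial) H⁺ is not
  balanced, matching the source figures. Water appears where chemistry
  demands it: +1 at the cyclohydrolase, +1 at CODH (CO₂ → CO), −1 per CO
  oxidised — which makes the nets close as 4 H₂ + 2 CO₂ → acetate + 2 H₂O
  and 4 CO + 2 H₂O → acetate + 2 CO₂.
* **Reversible steps.** Nfn, EtfABCX and Fdh–Ech are encoded once and
  reversed with `ReactionStep.reversed()` (coefficients negate;
  `protons_out`/`protons_in` swap).

The formate cycle (FocA export, periplasmic cytochrome-b Fdh feeding MQ,
cytoplasmic re-reduction) is modelled as a carbon- and carrier-closed loop
whose only net effect is its configurable vectorial proton yield — the
yield is not quantified in vivo, so the default (0) makes the toggle
neutral. It refuses the low-H₂ scenario, where the cycle is inactive.

CO oxidation is one pooled step: the monofunctional-CODH vs CODH/ACS
distinction is regulatory, not stoichiometric, and out of scope here.

## Differential expression

Size factors are DESeq-style median-of-ratios over genes with positive
counts in all samples, rescaled to geometric mean 1. The test models
counts as negative binomial with Var = μ + αμ². Per gene, α is the mean
of the two per-condition method-of-moments estimates (s² − m)/m² (Bessel
variances), floored at 10⁻⁸ with no shrinkage. log2FC =
log₂((m_trt + 0.5)/(m_ref + 0.5)) on normalized counts; the delta-method
variance of each log₂ group mean is (m + αm²)/(n·(m + 0.5)²·ln²2). The
Wald statistic is referred to a **t distribution with n₁ + n₂ − 2 df**
rather than a normal: with 3 + 3 replicates the normal reference is badly
anticonservative (null raw-p fraction ≈ 0.12 at the 0.05 level in seeded
NB simulations), while the t reference calibrates to ≈ 0.045 without
costing the required power. Degenerate-variance genes get p = 1 and a
flag; all-zero genes get log2FC = 0, p = 1, stay in the gene universe but
are excluded from the BH denominator.

BH adjustment delegates to `statsmodels.stats.multitest.multipletests`
(`fdr_bh`); hand-worked examples serve as the independent check. Note the
step-up adjustment is not idempotent on re-application in general — the
tested invariants are monotonicity in rank, adjusted ≥ raw, and
order-preserving inflation under re-application.

A gene is a DEG iff |log2FC| ≥ 2 and adjusted p < 0.05 (both thresholds
configurable). The summary percentage is 100·n_DEG/n_universe rounded to
two decimals, the universe being the annotated gene total (2594 by
default), and category counts let one gene count in several categories.

## Assays and growth

One enzyme unit is the transfer of 2 μmol electrons·min⁻¹. The activity
chain: least-squares absorbance slope (A/min) → /(ε·path) (mM/min) →
×volume (μmol/min) → ×electrons-per-chromophore (μmol e⁻/min) → /2 (U) →
/protein (U/mg). Defaults carry the assay constants ε = 6.3 mM⁻¹cm⁻¹
(NAD(P)H, 340 nm) and 13.1 mM⁻¹cm⁻¹ (ferredoxin, 430 nm); electrons per
chromophore is 2 for NAD(P)H and configurable for ferredoxin (default 2,
matching the ledger's one-pair convention). Negative slopes report signed
activity with a `consumption` flag.

Growth: μ is the OLS slope of ln OD₆₀₀ vs time over a user window
(default: the whole curve; `auto_window` finds the longest window with
log-linear R² ≥ 0.99 and positive slope); t_d = ln 2/μ exactly as
computed. `growth_consistency` cross-derives μ and t_d from each other and
flags inconsistent reported pairs (e.g. μ = 0.055 h⁻¹ with t_d = 12.4 h:
ln 2/0.055 = 12.6 h) instead of silently preferring one.

## Synthetic data

`generate_counts` emulates a two-condition prokaryotic RNA-seq experiment:
baseline means log-normal (ln-mean 5.0, ln-sd 1.5 — median ≈ 150 counts,
a realistic mRNA-seq depth for a 2594-gene genome at typical library
sizes), per-gene dispersion α = 1/μ + 0.05 (Poisson-like at high
expression, overdispersed at low), library-size factors log-normal with
ln-sd 0.1, gamma–Poisson NB draws. Defaults are the study shape: 2594
genes, 3 replicates per condition, 19% planted DEGs (round(0.19·2594) =
493) with |log2FC| uniform in [2, 8], random sign, placed stratified
across the expression range so power summaries are interpretable. Growth
curves are od₀·e^{μt} with multiplicative Gaussian noise; assay traces
invert the Beer–Lambert chain so the round trip is exact at zero noise.
Every generator takes an explicit seed, owns its RNG stream, and is
byte-deterministic.

What the generators do **not** emulate: gene-length and GC biases,
correlated genes/operons, batch effects, the real study's library sizes
or its actual DEG identities. Passing tests therefore demonstrate the
arithmetic and statistical machinery under the stated model, not recovery
of the real deposit's 489/517 DEG calls — reproducing those from raw
reads is explicitly out of scope.

## Problem sizes and numerical choices

Simulation-based tests use 1500–2594 genes with 3 + 3 replicates and
10 seeds for the null series — ample for the binomial Monte-Carlo bounds
they assert, and the full suite runs in seconds. Ledger arithmetic is
exact-rational end to end; floating point enters only at reporting.
Bisection tolerance for pressure crossovers is 10⁻⁶ decades. Report
rounding: energies to one decimal; integer comparisons round half away
from zero.

## Known limitations

* No activity-coefficient, ionic-strength or pH corrections beyond the
  fixed pH-7 convention; feasibility statements use midpoint potentials.
* Scenarios are fixed ledgers — no kinetics, no flux optimisation, no
  growth-yield-from-ATP model, no membrane-potential magnitude.
* The NB test uses unshrunk per-gene dispersions; with two or three
  replicates its per-gene dispersion estimates are noisy, and the t
  reference is a calibration device, not an exact sampling distribution.
* The Fdh–Ech proton number and the formate-cycle proton yield are free
  parameters; every ATP total should be read as a function of them.
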