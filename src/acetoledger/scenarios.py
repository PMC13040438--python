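"""The three growth-condition ledgers of acetogenesis in *Moorella thermoacetica*.

Each builder returns a :class:`~acetoledger.ledger.Scenario` normalized to
one acetate produced:

* ``high_h2`` — H2 + CO2 at high H2 pressure: the NADP+-reducing
  hydrogenase supplies five NADPH, one formate is re-oxidised by the
  putative Fdh–Ech complex (the H2 is recaptured), and the NADH
  dehydrogenase plus the menaquinone redox loop translocate 1 + 1 protons,
  i.e. 0.5 ATP at 4 H+/ATP.
* ``low_h2`` — the same net chemistry, but Fdh–Ech runs in reverse
  (H2 + CO2 -> formate, driven by the proton gradient), so its coupling
  site consumes rather than contributes protons.
* ``co`` — acetogenesis from CO: three of four CO are oxidised to reduced
  ferredoxin; the NADH dehydrogenase reduces 1.25 MQ and translocates five
  protons; with the loop proton the total is 6 H+, i.e. 1.5 ATP.

The Fdh–Ech vectorial proton number ``x`` is unknown in vivo and defaults
to zero; it is a parameter, never silently nonzero.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from fractions import Fraction

from .ledger import ReactionStep, Scenario, validate_scenario
from .thermo import DEFAULT_PARAMS, ThermoParams

__all__ = [
    "ScenarioOptions",
    "FormateCycleInactiveError",
    "build_high_h2",
    "build_low_h2",
    "build_co",
    "apply_formate_cycle",
    "build_scenario",
    "SCENARIO_NAMES",
]


@dataclass(frozen=True)
class ScenarioOptions:
    """Tunable knobs shared by all builders.

    ``ech_protons``: vectorial H+ per formate at the Fdh–Ech coupling site
    (unknown in vivo; default 0). ``proton_per_atp``: H+/ATP quotient of
    the ATP synthase (default 4).
    """

    ech_protons: Fraction = Fraction(0)
    proton_per_atp: float = 4.0
    temperature: float = DEFAULT_PARAMS.temperature

    def thermo_params(self) -> ThermoParams:
        return replace(
            DEFAULT_PARAMS, proton_per_atp=self.proton_per_atp, temperature=self.temperature
        )


class FormateCycleInactiveError(ValueError):
    """The formate cycle cannot be applied to this scenario (inactive at low H2)."""


# ---------------------------------------------------------------------------
# Unit reaction steps (coefficients per unit flux)
# ---------------------------------------------------------------------------

def _hyd_nadp() -> ReactionStep:
    """NADP+-reducing hydrogenase: H2 + NADP+ -> NADPH."""
    return ReactionStep(
        id="hyd_nadp", enzyme="NADP+-reducing hydrogenase",
        metabolites={"H2": -1}, carriers={"NADPH": 1}, pairs_transferred=1,
    )


def _fdh_nadph() -> ReactionStep:
    """Cytosolic NADPH-dependent formate dehydrogenase: CO2 + NADPH -> formate."""
    return ReactionStep(
        id="fdh_nadph", enzyme="NADPH-dependent Fdh",
        metabolites={"CO2": -1, "formate": 1}, carriers={"NADPH": -1}, pairs_transferred=1,
    )


def _fdh_ech(ech_protons: Fraction) -> ReactionStep:
    """Putative Fdh–Ech complex, forward: formate -> CO2 + H2, x H+ out."""
    return ReactionStep(
        id="fdh_ech", enzyme="Fdh-Ech",
        metabolites={"formate": -1, "CO2": 1, "H2": 1},
        protons_out=ech_protons, pairs_transferred=1,
    )


def _fthfs() -> ReactionStep:
    """Formyl-THF synthetase: formate + THF + ATP -> formyl-THF."""
    return ReactionStep(
        id="fthfs", enzyme="formyl-THF synthetase",
        metabolites={"formate": -1, "THF": -1, "formyl_THF": 1},
        atp_substrate=-1, pairs_transferred=1,
    )


def _cyclohydrolase() -> ReactionStep:
    """Methenyl-THF cyclohydrolase: formyl-THF -> methenyl-THF + H2O."""
    return ReactionStep(
        id="cyclohydrolase", enzyme="methenyl-THF cyclohydrolase",
        metabolites={"formyl_THF": -1, "methenyl_THF": 1, "H2O": 1}, pairs_transferred=1,
    )


def _mthfd() -> ReactionStep:
    """Methylene-THF dehydrogenase: methenyl-THF + NADPH -> methylene-THF."""
    return ReactionStep(
        id="mthfd", enzyme="methylene-THF dehydrogenase",
        metabolites={"methenyl_THF": -1, "methylene_THF": 1},
        carriers={"NADPH": -1}, pairs_transferred=2,
    )


def _nfn() -> ReactionStep:
    """Nfn transhydrogenase, forward: 2 NADPH + NAD+ + Fd -> NADH + Fd2-."""
    return ReactionStep(
        id="nfn", enzyme="Nfn",
        carriers={"NADPH": -2, "NADH": 1, "Fd2-": 1}, pairs_transferred=2,
    )


def _etf_bifurcation() -> ReactionStep:
    """EtfABCX, bifurcating direction (per NADH): NADH -> 1/2 MQH2 + 1/2 Fd2-."""
    return ReactionStep(
        id="etf", enzyme="EtfABCX",
        carriers={"NADH": -1, "MQH2": Fraction(1, 2), "Fd2-": Fraction(1, 2)},
        pairs_transferred=1,
    )


def _ndh() -> ReactionStep:
    """Fd2--oxidising, MQ-reducing NADH dehydrogenase (per MQ reduced): 4 H+ out."""
    return ReactionStep(
        id="ndh", enzyme="NADH dehydrogenase",
        carriers={"Fd2-": -1, "MQH2": 1}, protons_out=4, pairs_transferred=1,
    )


def _mthfr() -> ReactionStep:
    """Type IV confurcating MTHFR: methylene-THF + 1/2 NADH + 1/2 MQH2 -> methyl-THF.

    Oxidation of 0.5 MQH2 drives the menaquinone redox loop: one vectorial
    proton to the periplasm (2 H+ per MQH2 oxidised).
    """
    return ReactionStep(
        id="mthfr", enzyme="MTHFR (Type IV)",
        metabolites={"methylene_THF": -1, "methyl_THF": 1},
        carriers={"NADH": Fraction(-1, 2), "MQH2": Fraction(-1, 2)},
        protons_out=1, pairs_transferred=3,
    )


def _codh() -> ReactionStep:
    """CODH/ACS carbonyl branch: CO2 + Fd2- -> CO + H2O."""
    return ReactionStep(
        id="codh", enzyme="CODH/ACS (CO2 -> CO)",
        metabolites={"CO2": -1, "CO": 1, "H2O": 1}, carriers={"Fd2-": -1}, pairs_transferred=1,
    )


def _co_oxidation() -> ReactionStep:
    """CO oxidation (pooled CODH activity): CO + H2O -> CO2 + Fd2-."""
    return ReactionStep(
        id="co_ox", enzyme="CODH (CO oxidation)",
        metabolites={"CO": -1, "H2O": -1, "CO2": 1}, carriers={"Fd2-": 1}, pairs_transferred=1,
    )


def _acs_ack() -> ReactionStep:
    """ACS condensation + Pta/Ack: methyl-THF + CO -> acetate + THF, +1 ATP."""
    return ReactionStep(
        id="acs_ack", enzyme="ACS + Pta/Ack",
        metabolites={"methyl_THF": -1, "CO": -1, "acetate": 1, "THF": 1},
        atp_substrate=1, pairs_transferred=4,
    )


def _methyl_branch() -> list[tuple[ReactionStep, Fraction]]:
    """Formate -> methyl-THF at unit flux (synthetase, cyclohydrolase, dehydrogenase, MTHFR)."""
    one = Fraction(1)
    return [
        (_fthfs(), one),
        (_cyclohydrolase(), one),
        (_mthfd(), one),
        (_mthfr(), one),
    ]


# ---------------------------------------------------------------------------
# Scenario builders
# ---------------------------------------------------------------------------

_EXTERNAL = frozenset({"H2", "CO", "CO2", "acetate", "H2O"})


def build_high_h2(options: ScenarioOptions | None = None) -> Scenario:
    """Acetogenesis from H2 + CO2 at high H2 pressure: 4 H2 + 2 CO2 -> acetate + 2 H2O."""
    opt = options or ScenarioOptions()
    steps = [
        (_hyd_nadp(), Fraction(5)),
        (_fdh_nadph(), Fraction(2)),
        (_fdh_ech(opt.ech_protons), Fraction(1)),
        *_methyl_branch(),
        (_nfn(), Fraction(1)),
        (_etf_bifurcation(), Fraction(1, 2)),
        (_ndh(), Fraction(1, 4)),
        (_codh(), Fraction(1)),
        (_acs_ack(), Fraction(1)),
    ]
    return Scenario(
        name="high_h2", steps=steps, external_species=_EXTERNAL, params=opt.thermo_params()
    )


def build_low_h2(options: ScenarioOptions | None = None) -> Scenario:
    """Acetogenesis at low H2 pressure: same net chemistry, Fdh–Ech reversed.

    The formate cycle is not active under these conditions, so
    ``apply_formate_cycle`` refuses this scenario.
    """
    opt = options or ScenarioOptions()
    steps = [
        (_hyd_nadp(), Fraction(3)),
        (_fdh_ech(opt.ech_protons).reversed(), Fraction(1)),
        *_methyl_branch(),
        (_nfn(), Fraction(1)),
        (_etf_bifurcation(), Fraction(1, 2)),
        (_ndh(), Fraction(1, 4)),
        (_codh(), Fraction(1)),
        (_acs_ack(), Fraction(1)),
    ]
    return Scenario(
        name="low_h2",
        steps=steps,
        external_species=_EXTERNAL,
        params=opt.thermo_params(),
        formate_cycle_allowed=False,
    )


def build_co(options: ScenarioOptions | None = None) -> Scenario:
    """Acetogenesis from CO: 4 CO + 2 H2O -> acetate + 2 CO2, 6 H+ -> 1.5 ATP at x=0."""
    opt = options or ScenarioOptions()
    steps = [
        (_co_oxidation(), Fraction(3)),
        (_ndh(), Fraction(5, 4)),
        (_etf_bifurcation().reversed(), Fraction(3, 2)),  # confurcation: MQH2 + Fd2- -> NADH
        (_nfn().reversed(), Fraction(1)),  # NADH + Fd2- -> 2 NADPH
        (_fdh_nadph(), Fraction(2)),
        (_fdh_ech(opt.ech_protons), Fraction(1)),
        (_hyd_nadp(), Fraction(1)),  # recaptures the Fdh-Ech H2
        *_methyl_branch(),
        (_acs_ack(), Fraction(1)),  # the fourth CO enters here directly
    ]
    return Scenario(name="co", steps=steps, external_species=_EXTERNAL, params=opt.thermo_params())


def apply_formate_cycle(
    scenario: Scenario,
    loop_protons_per_formate: Fraction | int = Fraction(0),
    cycle_flux: Fraction | int = Fraction(1),
) -> Scenario:
    """Add the FocA / periplasmic cytochrome-b Fdh formate cycle to a scenario.

    Intracellular formate is exported by FocA, oxidised by the periplasmic
    cytochrome-b-dependent Fdh (electrons return on menaquinone), and the
    CO2 is re-reduced in the cytoplasm, closing both the carbon and the
    carrier balance. The vectorial proton yield of the cycle is not
    quantified in vivo; it is the explicit ``loop_protons_per_formate``
    parameter (default 0, a neutral toggle).
    """
    if not scenario.formate_cycle_allowed:
        raise FormateCycleInactiveError(
            f"the formate cycle is not active in scenario {scenario.name!r}"
        )
    if not any(step.id == "mthfr" for step, _ in scenario.steps):
        raise ValueError(
            f"scenario {scenario.name!r} has no MTHFR step; the formate cycle feeds it"
        )
    protons = Fraction(loop_protons_per_formate)
    foca = ReactionStep(
        id="foca", enzyme="FocA formate transporter",
        metabolites={"formate": -1, "formate_periplasm": 1}, pairs_transferred=1,
    )
    fdh_peri = ReactionStep(
        id="fdh_cytb", enzyme="periplasmic cytochrome-b Fdh",
        metabolites={"formate_periplasm": -1, "CO2": 1}, carriers={"MQH2": 1},
        protons_out=protons, pairs_transferred=1,
    )
    fdh_back = ReactionStep(
        id="fdh_mq_cyto", enzyme="cytoplasmic MQH2-dependent CO2 re-reduction",
        metabolites={"CO2": -1, "formate": 1}, carriers={"MQH2": -1}, pairs_transferred=1,
    )
    flux = Fraction(cycle_flux)
    steps = list(scenario.steps) + [(foca, flux), (fdh_peri, flux), (fdh_back, flux)]
    return replace(scenario, name=f"{scenario.name}+formate_cycle", steps=tuple(steps))


SCENARIO_NAMES = ("high_h2", "low_h2", "co")

_BUILDERS = {"high_h2": build_high_h2, "low_h2": build_low_h2, "co": build_co}


def build_scenario(
    name: str,
    options: ScenarioOptions | None = None,
    formate_cycle: bool = False,
    loop_protons_per_formate: Fraction | int = 0,
) -> Scenario:
    """Build a named scenario; every built-in validates with zero violations."""
    try:
        builder = _BUILDERS[name]
    except KeyError:
        raise KeyError(
            f"unknown scenario {name!r}; available: {', '.join(SCENARIO_NAMES)}"
        ) from None
    scenario = builder(options)
    if formate_cycle:
        scenario = apply_formate_cycle(scenario, loop_protons_per_formate)
    violations = validate_scenario(scenario)
    assert not violations, violations
    return scenario
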