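"""Stoichiometric bookkeeping for fixed metabolic scenarios.

A :class:`Scenario` is an ordered list of enzyme-level
:class:`ReactionStep` objects with rational flux multipliers, normalized
to one acetate produced. The engine validates closure (every internal
electron carrier and every non-external species must net to exactly
zero), recomputes each step's electron-pair audit, derives the net
reaction, and totals vectorial protons and ATP.

All arithmetic uses :class:`fractions.Fraction`, so balances close to
exactly zero rather than to within a tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from fractions import Fraction
from numbers import Rational
from typing import Iterable, Mapping, Sequence

from .thermo import DEFAULT_PARAMS, ThermoParams

__all__ = [
    "CARRIERS",
    "PAIR_CONTENT",
    "KNOWN_SPECIES",
    "ReactionStep",
    "Scenario",
    "LedgerReport",
    "ScenarioValidationError",
    "validate_scenario",
    "net_reaction",
    "atp_yield",
]

#: Electron-pair carriers. Each unit carries one pair (two electrons);
#: reduced ferredoxin is counted as a one-pair carrier, which is the only
#: convention under which 0.75 MQH2 + 0.75 Fd2- -> 1.5 NADH balances.
CARRIERS = frozenset({"Fd2-", "NADH", "NADPH", "MQH2"})

#: Reduction level of each metabolite in electron pairs, relative to the
#: CO2 / 2H+ / THF reference states. Species absent from the map carry no
#: transferable pairs (water, THF, CO2, periplasmic protons...).
PAIR_CONTENT: dict[str, Fraction] = {
    "H2": Fraction(1),
    "CO": Fraction(1),
    "formate": Fraction(1),
    "formate_periplasm": Fraction(1),
    "formyl_THF": Fraction(1),
    "methenyl_THF": Fraction(1),
    "methylene_THF": Fraction(2),
    "methyl_THF": Fraction(3),
    "acetate": Fraction(4),
}

#: All species names the validator accepts.
KNOWN_SPECIES = frozenset(PAIR_CONTENT) | {"CO2", "H2O", "THF"}


def _frac(value: object) -> Fraction:
    """Coerce int/str/float/Fraction to an exact Fraction."""
    if isinstance(value, Rational):
        return Fraction(value)
    if isinstance(value, str):
        return Fraction(value)
    if isinstance(value, float):
        return Fraction(value)  # exact binary expansion; fluxes are dyadic
    raise TypeError(f"cannot interpret {value!r} as a rational coefficient")


def _frac_map(mapping: Mapping[str, object]) -> dict[str, Fraction]:
    return {k: _frac(v) for k, v in mapping.items() if _frac(v) != 0}


@dataclass(frozen=True)
class ReactionStep:
    """One enzyme-level reaction.

    ``metabolites`` maps species to signed stoichiometric coefficients
    (negative = consumed); ``carriers`` maps carrier names to signed
    electron-PAIR coefficients (positive = reduced form produced);
    ``protons_out``/``protons_in`` are vectorial protons translocated to /
    taken from the periplasmic side per unit flux; ``atp_substrate`` is
    signed substrate-level ATP; ``pairs_transferred`` is the declared
    electron-pair audit the validator recomputes.
    """

    id: str
    enzyme: str
    metabolites: Mapping[str, object] = field(default_factory=dict)
    carriers: Mapping[str, object] = field(default_factory=dict)
    protons_out: object = 0
    protons_in: object = 0
    atp_substrate: object = 0
    pairs_transferred: object = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "metabolites", _frac_map(self.metabolites))
        object.__setattr__(self, "carriers", _frac_map(self.carriers))
        for fname in ("protons_out", "protons_in", "atp_substrate", "pairs_transferred"):
            object.__setattr__(self, fname, _frac(getattr(self, fname)))
        if self.protons_out < 0 or self.protons_in < 0:
            raise ValueError(f"step {self.id!r}: vectorial proton counts must be >= 0")

    # -- electron-pair audit ------------------------------------------------
    def pairs_in(self) -> Fraction:
        """Pairs entering the step: oxidised carriers plus consumed reduced metabolites."""
        carriers_in = -sum((c for c in self.carriers.values() if c < 0), Fraction(0))
        metabolites_in = -sum(
            (
                coeff * PAIR_CONTENT.get(species, Fraction(0))
                for species, coeff in self.metabolites.items()
                if coeff < 0
            ),
            Fraction(0),
        )
        return carriers_in + metabolites_in

    def pairs_out(self) -> Fraction:
        """Pairs leaving the step: reduced carriers plus produced reduced metabolites."""
        carriers_out = sum((c for c in self.carriers.values() if c > 0), Fraction(0))
        metabolites_out = sum(
            (
                coeff * PAIR_CONTENT.get(species, Fraction(0))
                for species, coeff in self.metabolites.items()
                if coeff > 0
            ),
            Fraction(0),
        )
        return carriers_out + metabolites_out

    def recomputed_pairs_transferred(self) -> Fraction:
        """Pairs flowing through the step, recomputed from the reduction-level table."""
        return self.pairs_in()

    def pair_conservation_residual(self) -> Fraction:
        """Zero iff pairs entering equal pairs leaving."""
        return self.pairs_out() - self.pairs_in()

    def reversed(self) -> "ReactionStep":
        """The same chemistry run backwards (protons_out and protons_in swap)."""
        return replace(
            self,
            id=f"{self.id}_rev",
            metabolites={k: -v for k, v in self.metabolites.items()},
            carriers={k: -v for k, v in self.carriers.items()},
            protons_out=self.protons_in,
            protons_in=self.protons_out,
            atp_substrate=-self.atp_substrate,
        )


@dataclass(frozen=True)
class Scenario:
    """An ordered set of steps with rational flux multipliers, one growth condition."""

    name: str
    steps: Sequence[tuple[ReactionStep, object]]
    external_species: frozenset[str]
    params: ThermoParams = DEFAULT_PARAMS
    formate_cycle_allowed: bool = True

    def __post_init__(self) -> None:
        coerced = tuple((step, _frac(flux)) for step, flux in self.steps)
        for step, flux in coerced:
            if flux < 0:
                raise ValueError(f"step {step.id!r}: flux multiplier must be >= 0")
        object.__setattr__(self, "steps", coerced)
        object.__setattr__(self, "external_species", frozenset(self.external_species))

    def scaled(self, k: object) -> "Scenario":
        kf = _frac(k)
        return replace(self, steps=tuple((s, f * kf) for s, f in self.steps))


class ScenarioValidationError(ValueError):
    """Raised when an operation needs a valid scenario but violations exist."""

    def __init__(self, scenario_name: str, violations: list[str]):
        self.violations = violations
        lines = "\n  - ".join(violations)
        super().__init__(f"scenario {scenario_name!r} is not balanced:\n  - {lines}")


def _accumulate(scenario: Scenario) -> tuple[dict[str, Fraction], dict[str, Fraction]]:
    """Flux-weighted sums of metabolite and carrier coefficients."""
    species: dict[str, Fraction] = {}
    carriers: dict[str, Fraction] = {}
    for step, flux in scenario.steps:
        for name, coeff in step.metabolites.items():
            species[name] = species.get(name, Fraction(0)) + flux * coeff
        for name, coeff in step.carriers.items():
            carriers[name] = carriers.get(name, Fraction(0)) + flux * coeff
    return species, carriers


def validate_scenario(scenario: Scenario) -> list[str]:
    """Return all closure violations; an empty list means the ledger balances."""
    if len(scenario.steps) == 0:
        raise ValueError(f"scenario {scenario.name!r} has no steps")

    unknown_carriers = sorted(
        {name for step, _ in scenario.steps for name in step.carriers if name not in CARRIERS}
    )
    unknown_species = sorted(
        {name for step, _ in scenario.steps for name in step.metabolites if name not in KNOWN_SPECIES}
    )
    if unknown_carriers or unknown_species:
        parts = []
        if unknown_carriers:
            parts.append(f"unknown carriers: {', '.join(unknown_carriers)}")
        if unknown_species:
            parts.append(f"unknown species: {', '.join(unknown_species)}")
        raise KeyError("; ".join(parts))

    violations: list[str] = []
    for step, _ in scenario.steps:
        residual = step.pair_conservation_residual()
        if residual != 0:
            violations.append(
                f"step {step.id!r} ({step.enzyme}): electron pairs not conserved "
                f"(residual {residual})"
            )
        declared = step.pairs_transferred
        recomputed = step.recomputed_pairs_transferred()
        if declared != recomputed:
            violations.append(
                f"step {step.id!r} ({step.enzyme}): declared pairs_transferred {declared} "
                f"!= recomputed {recomputed}"
            )

    species, carriers = _accumulate(scenario)
    for name in sorted(carriers):
        if carriers[name] != 0:
            violations.append(f"carrier {name!r} does not close: net {carriers[name]}")
    for name in sorted(species):
        if name not in scenario.external_species and species[name] != 0:
            violations.append(f"internal species {name!r} does not close: net {species[name]}")
    return violations


def net_reaction(scenario: Scenario) -> dict[str, Fraction]:
    """Net chemistry over external species (exact rationals), e.g. 4 H2 + 2 CO2 -> acetate."""
    violations = validate_scenario(scenario)
    if violations:
        raise ScenarioValidationError(scenario.name, violations)
    species, _ = _accumulate(scenario)
    return {
        name: coeff
        for name, coeff in sorted(species.items())
        if name in scenario.external_species and coeff != 0
    }


@dataclass(frozen=True)
class LedgerReport:
    """Balance sheet of one scenario: net chemistry, protons and ATP per acetate."""

    scenario: str
    net_reaction: dict[str, Fraction]
    carrier_balance: dict[str, Fraction]
    protons_translocated: Fraction
    atp_chemiosmotic: Fraction
    atp_substrate_level: Fraction

    @property
    def atp_total(self) -> Fraction:
        return self.atp_chemiosmotic + self.atp_substrate_level

    def to_dict(self) -> dict:
        """JSON-ready report (fractions both exact and as floats)."""
        return {
            "scenario": self.scenario,
            "net_reaction": {k: str(v) for k, v in self.net_reaction.items()},
            "carrier_balance": {k: str(v) for k, v in self.carrier_balance.items()},
            "protons_translocated": str(self.protons_translocated),
            "atp_chemiosmotic": float(self.atp_chemiosmotic),
            "atp_substrate_level": float(self.atp_substrate_level),
            "atp_total": float(self.atp_total),
        }

    def to_table(self) -> str:
        """Human-readable balance sheet."""
        consumed = [(-v, k) for k, v in self.net_reaction.items() if v < 0]
        produced = [(v, k) for k, v in self.net_reaction.items() if v > 0]
        fmt = lambda side: " + ".join(f"{c} {name}" for c, name in side) or "(nothing)"
        lines = [
            f"Scenario: {self.scenario}",
            f"Net reaction: {fmt(consumed)} -> {fmt(produced)}",
            f"Protons translocated (vectorial, net): {self.protons_translocated}",
            f"ATP chemiosmotic: {self.atp_chemiosmotic} ({float(self.atp_chemiosmotic):g})",
            f"ATP substrate-level: {self.atp_substrate_level}",
            f"ATP total: {self.atp_total} ({float(self.atp_total):g})",
        ]
        return "\n".join(lines)


def atp_yield(scenario: Scenario) -> LedgerReport:
    """Proton translocation total and chemiosmotic + substrate-level ATP yield."""
    violations = validate_scenario(scenario)
    if violations:
        raise ScenarioValidationError(scenario.name, violations)
    species, carriers = _accumulate(scenario)
    protons = sum(
        (flux * (step.protons_out - step.protons_in) for step, flux in scenario.steps),
        Fraction(0),
    )
    substrate = sum((flux * step.atp_substrate for step, flux in scenario.steps), Fraction(0))
    quotient = _frac(scenario.params.proton_per_atp)
    if quotient <= 0:
        raise ValueError("proton_per_atp must be > 0")
    return LedgerReport(
        scenario=scenario.name,
        net_reaction={
            k: v for k, v in sorted(species.items()) if k in scenario.external_species and v != 0
        },
        carrier_balance={k: v for k, v in sorted(carriers.items())},
        protons_translocated=protons,
        atp_chemiosmotic=protons / quotient,
        atp_substrate_level=substrate,
    )


def incidence_matrix(scenario: Scenario) -> tuple[list[str], list[str], list[list[Fraction]]]:
    """Explicit species x step incidence matrix (flux-unweighted), for cross-checks."""
    step_ids = [step.id for step, _ in scenario.steps]
    names = sorted({n for step, _ in scenario.steps for n in step.metabolites})
    matrix = [
        [step.metabolites.get(name, Fraction(0)) for step, _ in scenario.steps] for name in names
    ]
    return names, step_ids, matrix
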