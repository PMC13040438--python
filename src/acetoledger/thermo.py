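"""Redox thermodynamics for acetogen bioenergetics.

Free-energy changes of two-electron transfers between redox couples
(ferredoxin, NAD(P)H, menaquinone, H2, CO2/formate), Nernst correction of
the H+/H2 couple for its partial pressure, and feasibility sweeps that ask
at which hydrogen pressure a reduction stops being exergonic.

Conventions: midpoint potentials are stored in mV at pH 7; free energies
are returned in kJ/mol; ``dG = -n F (E_acceptor - E_donor)`` so a negative
value means exergonic electron transfer from donor to acceptor.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from importlib import resources
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "RedoxCouple",
    "ThermoParams",
    "DEFAULT_PARAMS",
    "GROWTH_TEMPERATURE_K",
    "load_couples",
    "get_couple",
    "delta_g_standard",
    "delta_g_prime",
    "h2_potential",
    "nernst_slope_mv_per_decade",
    "FeasibilitySweep",
    "feasibility_sweep",
]

#: Growth temperature of Moorella thermoacetica cultures (55 degC); standard
#: 25 degC constants are the default because printed dG0' values assume them.
GROWTH_TEMPERATURE_K = 328.15


@dataclass(frozen=True)
class ThermoParams:
    """Physical constants and the chemiosmotic H+/ATP quotient.

    temperature in K, faraday in kJ V-1 mol-1, gas_constant in
    kJ mol-1 K-1, proton_per_atp dimensionless (4 protons through the ATP
    synthase per ATP).
    """

    temperature: float = 298.15
    faraday: float = 96.485
    gas_constant: float = 8.314e-3
    proton_per_atp: float = 4.0

    def __post_init__(self) -> None:
        for field in ("temperature", "faraday", "gas_constant", "proton_per_atp"):
            value = getattr(self, field)
            if not (value > 0 and math.isfinite(value)):
                raise ValueError(f"{field} must be positive and finite, got {value!r}")

    @property
    def rt(self) -> float:
        """R*T in kJ/mol."""
        return self.gas_constant * self.temperature


DEFAULT_PARAMS = ThermoParams()


@dataclass(frozen=True)
class RedoxCouple:
    """A named half-reaction with midpoint potential(s) in mV.

    ``e0_prime`` is the standard midpoint potential at pH 7;
    ``e_prime_cellular`` the physiological poise where known (e.g. the
    NADPH/NADP+ pool sits near -370 mV although E0' is -320 mV).
    """

    name: str
    e0_prime: float
    n_electrons: int = 2
    e_prime_cellular: float | None = None
    source: str = "MODEL"

    def __post_init__(self) -> None:
        if self.n_electrons < 1:
            raise ValueError(f"n_electrons must be >= 1, got {self.n_electrons}")
        if not math.isfinite(self.e0_prime):
            raise ValueError(f"couple {self.name!r}: e0_prime must be finite")
        if self.e_prime_cellular is not None and not math.isfinite(self.e_prime_cellular):
            raise ValueError(f"couple {self.name!r}: e_prime_cellular must be finite")

    @property
    def effective_potential(self) -> float:
        """Cellular potential where known, standard potential otherwise (mV)."""
        if self.e_prime_cellular is not None:
            return self.e_prime_cellular
        return self.e0_prime


def load_couples() -> dict[str, RedoxCouple]:
    """Load the shipped registry of redox couples (TSV, potentials in mV)."""
    with resources.files("acetoledger.data").joinpath("redox_couples.tsv").open() as fh:
        table = pd.read_csv(fh, sep="\t")
    couples: dict[str, RedoxCouple] = {}
    for row in table.itertuples(index=False):
        cellular = None if pd.isna(row.e_prime_mV) else float(row.e_prime_mV)
        couples[row.name] = RedoxCouple(
            name=row.name,
            e0_prime=float(row.e0_prime_mV),
            n_electrons=int(row.n_electrons),
            e_prime_cellular=cellular,
            source=row.source,
        )
    return couples


_REGISTRY: dict[str, RedoxCouple] | None = None


def get_couple(name: str) -> RedoxCouple:
    """Fetch a couple from the registry by name (cached)."""
    global _REGISTRY
    if _REGISTRY is None:
        _REGISTRY = load_couples()
    try:
        return _REGISTRY[name]
    except KeyError:
        known = ", ".join(sorted(_REGISTRY))
        raise KeyError(f"unknown redox couple {name!r}; registry has: {known}") from None


def delta_g_standard(
    donor: RedoxCouple,
    acceptor: RedoxCouple,
    n: int,
    params: ThermoParams = DEFAULT_PARAMS,
) -> float:
    """Standard free energy (kJ/mol) of transferring n electrons donor -> acceptor.

    dG0' = -n F (E0'_acceptor - E0'_donor), potentials in mV. Negative
    means the transfer is exergonic in the stated direction.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    for couple in (donor, acceptor):
        if couple.e0_prime is None or not math.isfinite(couple.e0_prime):
            raise ValueError(f"couple {couple.name!r} has no standard potential")
    delta_e_volt = (acceptor.e0_prime - donor.e0_prime) / 1000.0
    return -n * params.faraday * delta_e_volt


def delta_g_prime(
    dg0: float,
    reaction_quotient: float,
    params: ThermoParams = DEFAULT_PARAMS,
) -> float:
    """Concentration-corrected free energy: dG' = dG0' + R T ln(Q)."""
    if not reaction_quotient > 0:
        raise ValueError(f"reaction quotient must be > 0, got {reaction_quotient!r}")
    return dg0 + params.rt * math.log(reaction_quotient)


def nernst_slope_mv_per_decade(params: ThermoParams = DEFAULT_PARAMS, n: int = 2) -> float:
    """Magnitude of the Nernst slope, mV per tenfold pressure change (29.58 at 25 degC, n=2)."""
    return params.rt / (n * params.faraday) * math.log(10.0) * 1000.0


def h2_potential(
    partial_pressure_h2: float,
    params: ThermoParams = DEFAULT_PARAMS,
    e0_prime_mv: float | None = None,
) -> float:
    """Potential (mV) of the H+/H2 couple at pH 7 for a given H2 pressure (atm).

    E = E0' - (R T / 2F) ln(pH2): at 1 atm the standard -414 mV; a lower
    pressure makes H2 a weaker reductant (less negative potential).
    """
    if not partial_pressure_h2 > 0:
        raise ValueError(f"H2 partial pressure must be > 0, got {partial_pressure_h2!r}")
    if e0_prime_mv is None:
        e0_prime_mv = get_couple("h2").e0_prime
    correction_volt = params.rt / (2.0 * params.faraday) * math.log(partial_pressure_h2)
    return e0_prime_mv - correction_volt * 1000.0


@dataclass(frozen=True)
class FeasibilitySweep:
    """Result of a pressure sweep: per-pressure table plus the dG' = 0 crossover."""

    table: pd.DataFrame
    crossover_atm: float | None
    reductant: str
    target: str


def _reductant_potential(
    reductant: RedoxCouple | None,
    pressure: float,
    params: ThermoParams,
    h2_equilibrated: bool,
) -> float:
    if h2_equilibrated:
        return h2_potential(pressure, params)
    assert reductant is not None
    return reductant.effective_potential


def feasibility_sweep(
    reductant: RedoxCouple | None,
    pressures: Sequence[float] | Iterable[float],
    params: ThermoParams = DEFAULT_PARAMS,
    target: RedoxCouple | None = None,
    h2_equilibrated: bool | None = None,
    crossover_tol_decades: float = 1e-6,
) -> FeasibilitySweep:
    """Sweep H2 partial pressure and report dG' of reducing ``target`` with ``reductant``.

    If the reductant is the H+/H2 couple (or ``reductant is None``, or
    ``h2_equilibrated=True``) its potential follows the Nernst curve of the
    pressure; otherwise it is held at its cellular-else-standard potential.
    The target couple (default: CO2/formate) contributes its
    cellular-else-standard potential. The crossover pressure where dG' = 0
    is located by bisection on log10 pressure when a sign change exists
    over the swept range.
    """
    pressures = [float(p) for p in pressures]
    if not pressures:
        raise ValueError("pressure list must be non-empty")
    if any(p <= 0 for p in pressures):
        raise ValueError("all pressures must be > 0")
    if target is None:
        target = get_couple("co2_formate")
    if h2_equilibrated is None:
        h2_equilibrated = reductant is None or reductant.name == "h2"
    if reductant is None and not h2_equilibrated:
        raise ValueError("a fixed-potential sweep needs an explicit reductant couple")

    n = target.n_electrons
    e_target = target.effective_potential

    def dg_at(pressure: float) -> tuple[float, float]:
        e_red = _reductant_potential(reductant, pressure, params, h2_equilibrated)
        dg = -n * params.faraday * (e_target - e_red) / 1000.0
        return e_red, dg

    rows = []
    for p in sorted(pressures, reverse=True):
        e_red, dg = dg_at(p)
        rows.append({"p_h2_atm": p, "e_reductant_mV": e_red, "delta_g_prime_kJ_mol": dg})
    table = pd.DataFrame(rows)

    crossover = None
    lo, hi = math.log10(min(pressures)), math.log10(max(pressures))
    f_lo, f_hi = dg_at(10.0**lo)[1], dg_at(10.0**hi)[1]
    if f_lo == 0.0:
        crossover = 10.0**lo
    elif f_hi == 0.0:
        crossover = 10.0**hi
    elif f_lo * f_hi < 0:
        while hi - lo > crossover_tol_decades:
            mid = 0.5 * (lo + hi)
            f_mid = dg_at(10.0**mid)[1]
            if f_mid == 0.0:
                lo = hi = mid
                break
            if f_lo * f_mid < 0:
                hi = mid
            else:
                lo, f_lo = mid, f_mid
        crossover = 10.0 ** (0.5 * (lo + hi))

    name = reductant.name if reductant is not None else "h2"
    return FeasibilitySweep(table=table, crossover_atm=crossover, reductant=name, target=target.name)


def at_growth_temperature(params: ThermoParams = DEFAULT_PARAMS) -> ThermoParams:
    """The same constants evaluated at the 55 degC growth temperature."""
    return replace(params, temperature=GROWTH_TEMPERATURE_K)
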