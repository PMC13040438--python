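"""Redox thermodynamics: free energies, Nernst behaviour, feasibility sweeps."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from acetoledger import thermo
from acetoledger.thermo import (
    DEFAULT_PARAMS,
    RedoxCouple,
    ThermoParams,
    delta_g_prime,
    delta_g_standard,
    feasibility_sweep,
    get_couple,
    h2_potential,
    nernst_slope_mv_per_decade,
)

potentials = st.floats(min_value=-600.0, max_value=200.0)


class TestRegistry:
    def test_registry_holds_the_printed_and_literature_potentials(self):
        assert get_couple("co2_formate").e0_prime == -432.0
        assert get_couple("mq_mqh2").e0_prime == -74.0
        assert get_couple("nadp").e_prime_cellular == -370.0
        assert get_couple("nad").e_prime_cellular == -270.0
        assert get_couple("h2").e0_prime == -414.0
        assert get_couple("h2").source == "LITERATURE"
        assert get_couple("methylene_methyl_thf").source == "LITERATURE"

    def test_unknown_couple_error_lists_names(self):
        with pytest.raises(KeyError, match="co2_formate"):
            get_couple("nonexistent")

    def test_couple_invariants_enforced(self):
        with pytest.raises(ValueError):
            RedoxCouple("bad", e0_prime=-100.0, n_electrons=0)
        with pytest.raises(ValueError):
            RedoxCouple("bad", e0_prime=float("nan"))


class TestDeltaGStandard:
    def test_formate_to_h2_is_minus_three_and_a_half(self):
        dg = delta_g_standard(get_couple("co2_formate"), get_couple("h2"), 2)
        assert dg == pytest.approx(-3.47, abs=0.01)
        assert round(dg) == -3

    def test_menaquinol_to_methylene_thf_is_endergonic(self):
        dg = delta_g_standard(get_couple("mq_mqh2"), get_couple("methylene_methyl_thf"), 2)
        assert dg == pytest.approx(24.3, abs=0.05)

    def test_identical_couples_give_zero(self):
        fd = get_couple("ferredoxin")
        for n in (1, 2, 4):
            assert delta_g_standard(fd, fd, n) == 0.0

    def test_invalid_electron_count(self):
        with pytest.raises(ValueError):
            delta_g_standard(get_couple("h2"), get_couple("nad"), 0)

    @given(e_don=potentials, e_acc=potentials, n=st.integers(1, 6))
    def test_antisymmetry(self, e_don, e_acc, n):
        a = RedoxCouple("a", e0_prime=e_don)
        b = RedoxCouple("b", e0_prime=e_acc)
        assert delta_g_standard(a, b, n) == pytest.approx(-delta_g_standard(b, a, n))

    @given(e_don=potentials, e_acc=potentials, n=st.integers(1, 6))
    def test_linearity_in_electron_count(self, e_don, e_acc, n):
        a = RedoxCouple("a", e0_prime=e_don)
        b = RedoxCouple("b", e0_prime=e_acc)
        assert delta_g_standard(a, b, n) == pytest.approx(n * delta_g_standard(a, b, 1))


class TestDeltaGPrime:
    def test_unit_quotient_is_identity(self):
        assert delta_g_prime(-3.47, 1.0) == -3.47

    def test_hundredfold_quotient(self):
        assert delta_g_prime(-3.47, 100.0) == pytest.approx(7.95, abs=0.01)

    def test_tenfold_quotient_from_zero(self):
        assert delta_g_prime(0.0, 10.0) == pytest.approx(5.71, abs=0.01)

    def test_nonpositive_quotient_rejected(self):
        for q in (0.0, -1.0):
            with pytest.raises(ValueError):
                delta_g_prime(0.0, q)

    @given(
        dg0=st.floats(-50, 50),
        q1=st.floats(1e-6, 1e6),
        q2=st.floats(1e-6, 1e6),
    )
    def test_additivity_over_quotient_factors(self, dg0, q1, q2):
        lhs = delta_g_prime(dg0, q1 * q2)
        rhs = delta_g_prime(dg0, q1) + DEFAULT_PARAMS.rt * math.log(q2)
        assert lhs == pytest.approx(rhs, rel=1e-9, abs=1e-9)


class TestH2Potential:
    def test_standard_state(self):
        assert h2_potential(1.0) == pytest.approx(-414.0)

    def test_four_decades_below_standard(self):
        assert h2_potential(1e-4) == pytest.approx(-414 + 4 * 29.58, abs=0.05)

    def test_one_decade_above_standard(self):
        assert h2_potential(10.0) == pytest.approx(-443.6, abs=0.05)

    def test_nonpositive_pressure_rejected(self):
        with pytest.raises(ValueError):
            h2_potential(0.0)

    def test_nernst_slope_at_25C(self):
        assert nernst_slope_mv_per_decade() == pytest.approx(29.58, abs=0.005)

    @given(
        log_p1=st.floats(-6, 1),
        log_p2=st.floats(-6, 1),
    )
    def test_strict_monotonicity_with_constant_slope(self, log_p1, log_p2):
        e1, e2 = h2_potential(10.0**log_p1), h2_potential(10.0**log_p2)
        expected = -(log_p2 - log_p1) * nernst_slope_mv_per_decade()
        assert e2 - e1 == pytest.approx(expected, rel=1e-9, abs=1e-9)


class TestFeasibilitySweep:
    def test_h2_equilibrated_nadph_crossover_near_0p03_atm(self):
        # below ~0.032 atm H2 can no longer hold the NADPH pool at -370 mV,
        # so NADPH-dependent CO2 reduction loses its driver
        sweep = feasibility_sweep(get_couple("h2"), [1e-6, 10.0], target=get_couple("nadp"))
        assert sweep.crossover_atm == pytest.approx(0.0325, abs=0.0005)

    def test_crossover_agrees_with_dense_grid_sign_change(self):
        pressures = np.logspace(-6, 1, 2000)
        sweep = feasibility_sweep(get_couple("h2"), pressures, target=get_couple("nadp"))
        dg = sweep.table.sort_values("p_h2_atm")["delta_g_prime_kJ_mol"].to_numpy()
        p_sorted = np.sort(pressures)
        flips = np.nonzero(np.diff(np.sign(dg)))[0]
        assert len(flips) == 1
        lo, hi = p_sorted[flips[0]], p_sorted[flips[0] + 1]
        assert lo <= sweep.crossover_atm <= hi

    def test_low_potential_ferredoxin_always_drives_formate_synthesis(self):
        sweep = feasibility_sweep(
            get_couple("ferredoxin_low"), np.logspace(-6, 1, 50), target=get_couple("co2_formate")
        )
        assert (sweep.table["delta_g_prime_kJ_mol"] < 0).all()
        assert sweep.crossover_atm is None

    def test_equal_potentials_give_exactly_zero(self):
        reductant = RedoxCouple("matched", e0_prime=-432.0)
        sweep = feasibility_sweep(reductant, [1.0], target=get_couple("co2_formate"))
        assert sweep.table["delta_g_prime_kJ_mol"].iloc[0] == 0.0

    def test_dg_monotone_increasing_as_pressure_decreases(self):
        sweep = feasibility_sweep(get_couple("h2"), np.logspace(-6, 1, 30))
        table = sweep.table.sort_values("p_h2_atm", ascending=False)
        assert table["delta_g_prime_kJ_mol"].is_monotonic_increasing

    def test_empty_pressure_list_rejected(self):
        with pytest.raises(ValueError):
            feasibility_sweep(get_couple("h2"), [])

    def test_nonpositive_pressures_rejected(self):
        with pytest.raises(ValueError):
            feasibility_sweep(get_couple("h2"), [1.0, -0.5])


def test_concentration_shift_convention_flips_the_formate_reaction_endergonic():
    """A 100-fold quotient shift turns formate oxidation to H2 endergonic, near +8.7 kJ/mol."""
    dg0 = delta_g_standard(get_couple("co2_formate"), get_couple("h2"), 2)
    shifted = delta_g_prime(dg0, 100.0)
    assert dg0 < 0 < shifted
    assert shifted == pytest.approx(8.7, abs=1.0)


def test_growth_temperature_params():
    params = thermo.at_growth_temperature()
    assert params.temperature == pytest.approx(328.15)
    assert nernst_slope_mv_per_decade(params) > nernst_slope_mv_per_decade()


def test_params_validation():
    with pytest.raises(ValueError):
        ThermoParams(temperature=-1.0)
    with pytest.raises(ValueError):
        ThermoParams(proton_per_atp=0.0)
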