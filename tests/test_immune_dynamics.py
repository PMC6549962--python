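"""Checkpoint binding algebra, priming chain, suppressor levels, and tumour
growth/kill terms."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.integrate import solve_ivp

from icbsim.immune_dynamics import (
    apc_antigen_dynamics,
    bind_checkpoints,
    equilibrium_occupancy,
    inhibition_factor,
    priming_transition,
    receptor_occupancy,
    suppressor_levels,
    tumour_growth_and_kill,
)
from icbsim.model_core import ParameterSet


class TestReceptorOccupancy:
    @pytest.mark.parametrize("bound, total, expected", [
        (0.0, 5000.0, 0.0), (5000.0, 5000.0, 1.0), (2500.0, 5000.0, 0.5),
        (0.0, 0.0, 0.0),  # empty pool convention
    ])
    def test_values(self, bound, total, expected):
        assert receptor_occupancy(bound, total) == pytest.approx(expected)

    def test_bound_exceeding_total_rejected(self):
        with pytest.raises(ValueError):
            receptor_occupancy(11.0, 10.0)


class TestInhibitionFactor:
    def test_no_inhibition_cases(self):
        assert inhibition_factor(0.7, emax=0.0) == 1.0
        assert inhibition_factor(0.0, emax=0.9) == 1.0

    def test_half_maximal_point(self):
        assert inhibition_factor(0.3, emax=1.0, ro50=0.3, hill=1.0) == \
            pytest.approx(0.5)

    @given(occ=st.lists(st.floats(0, 1), min_size=2, max_size=2),
           emax=st.floats(0, 1), hill=st.floats(1, 4))
    def test_monotone_nonincreasing_and_bounded(self, occ, emax, hill):
        lo, hi = sorted(occ)
        f_lo = inhibition_factor(lo, emax, 0.3, hill)
        f_hi = inhibition_factor(hi, emax, 0.3, hill)
        assert f_hi <= f_lo + 1e-12
        assert 1.0 - emax - 1e-12 <= f_hi <= 1.0

    def test_emax_out_of_range(self):
        with pytest.raises(ValueError):
            inhibition_factor(0.5, emax=1.2)


class TestBindCheckpoints:
    def test_no_antibody_reduces_to_natural_mass_action(self):
        fx = bind_checkpoints(10.0, 20.0, 5.0, kon=2.0, koff=0.5)
        assert fx.lig_complex == pytest.approx(2.0 * 10 * 20 - 0.5 * 5)
        assert fx.mab_complex == 0.0

    def test_kon_zero_gives_zero_formation(self):
        fx = bind_checkpoints(10.0, 20.0, 0.0, kon=0.0, koff=0.0,
                              mab_conc=5.0, kon_mab=0.0, koff_mab=0.0)
        assert fx.lig_complex == 0.0 and fx.mab_complex == 0.0

    def test_receptor_conservation_in_flux_set(self):
        fx = bind_checkpoints(3.0, 7.0, 2.0, 1.0, 0.3, 4.0, 1.0, 2.0, 0.1)
        assert fx.free_receptor + fx.lig_complex + fx.mab_complex == \
            pytest.approx(0.0)

    def test_equilibrium_matches_quadratic_closed_form(self):
        # integrate L + R <=> C to equilibrium, compare with the quadratic root
        kon, koff = 3.0, 2.0
        L0, R0 = 5.0, 8.0

        def rhs(t, y):
            L, R, C = y
            f = bind_checkpoints(L, R, C, kon, koff)
            return [-f.lig_complex, -f.lig_complex, f.lig_complex]

        sol = solve_ivp(rhs, (0, 200), [L0, R0, 0.0], rtol=1e-11, atol=1e-12)
        c_eq = sol.y[2, -1]
        kd = koff / kon
        b = R0 + L0 + kd
        c_exact = 0.5 * (b - math.sqrt(b * b - 4 * R0 * L0))
        assert c_eq == pytest.approx(c_exact, rel=1e-6)
        assert equilibrium_occupancy(R0, L0, kd) == pytest.approx(
            c_exact / R0, rel=1e-12)

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            bind_checkpoints(-1.0, 1.0, 0.0, 1.0, 1.0)


class TestPrimingTransition:
    RATES = (0.5, 3.0, 2.0)

    def test_zero_antigen_or_zero_mapc_stops_chain(self):
        pops = (1e5, 1e4, 1e3)
        assert priming_transition(pops, 1e4, 0.0, 0.9, 0.9, self.RATES, 2e4) \
            == (0.0, 0.0, 0.0)
        assert priming_transition(pops, 0.0, 0.7, 0.9, 0.9, self.RATES, 2e4) \
            == (0.0, 0.0, 0.0)

    def test_linear_in_antigen_intensity(self):
        pops = (1e5, 1e4, 1e3)
        r_02 = priming_transition(pops, 1e4, 0.2, 1.0, 1.0, self.RATES, 2e4)
        r_04 = priming_transition(pops, 1e4, 0.4, 1.0, 1.0, self.RATES, 2e4)
        for a, b in zip(r_02, r_04):
            assert b == pytest.approx(2 * a)

    def test_rates_scale_with_population_and_inhibition(self):
        r = priming_transition((100.0, 0.0, 0.0), 1e9, 1.0, 0.5, 0.5,
                               self.RATES, 1.0)
        # availability ~1, antigen 1, factors 0.25 -> k1 * 100 * 0.25
        assert r[0] == pytest.approx(0.5 * 100 * 0.25, rel=1e-6)
        assert r[1] == r[2] == 0.0


class TestSuppressorLevels:
    def test_zero_drivers(self):
        mdsc, treg_ln, treg_t = suppressor_levels(0.0, 0.0, 0.02, 0.3, 1e9, 5e7)
        assert (mdsc, treg_ln, treg_t) == (0.0, 0.0, 0.0)

    def test_mdsc_linear_in_cancer(self):
        m1, *_ = suppressor_levels(1e9, 0.0, 0.02, 0.3, 1e9, 5e7)
        m2, *_ = suppressor_levels(2e9, 0.0, 0.02, 0.3, 1e9, 5e7)
        assert m2 == pytest.approx(2 * m1)

    def test_treg_tumour_saturating_monotone(self):
        levels = [suppressor_levels(c, 0.0, 0.02, 0.3, 1e9, 5e7)[2]
                  for c in (1e8, 1e9, 1e10, 1e12)]
        assert all(a < b for a, b in zip(levels, levels[1:]))
        assert levels[-1] < 1e9  # bounded by treg_tum_max


class TestTumourGrowthAndKill:
    def test_pure_growth_recovers_doubling_time(self):
        # no effectors: exponential growth at ln2/Td, fitted from trajectory
        td = 50.0
        g = math.log(2) / td

        def rhs(t, y):
            r = tumour_growth_and_kill((y[0], 0, 0, 0), 0.0, (1, 1, 1, 1),
                                       g, kill_rate=40.0)
            return [r.derivatives[0]]

        sol = solve_ivp(rhs, (0, 100), [1e6], rtol=1e-10, atol=1e-3,
                        t_eval=[0, 100])
        fitted_td = 100 * math.log(2) / math.log(sol.y[0, -1] / sol.y[0, 0])
        assert fitted_td == pytest.approx(td, rel=1e-6)

    def test_empty_tumour_is_absorbing(self):
        r = tumour_growth_and_kill((0, 0, 0, 0), 1e7, (1, 1, 1, 1), 0.01, 40.0)
        assert r.derivatives == (0, 0, 0, 0)
        assert r.killed_cell_flux == 0.0

    def test_blockade_raises_kill_of_pdl1_positive_subtype(self):
        # same subtype size; engaged PD-1 (no antibody) vs blocked (factor 1)
        subtypes = (0.0, 1e9, 0.0, 0.0)
        inhibited = tumour_growth_and_kill(subtypes, 1e6, (1, 0.1, 1, 1),
                                           0.007, 40.0)
        blocked = tumour_growth_and_kill(subtypes, 1e6, (1, 1.0, 1, 1),
                                         0.007, 40.0)
        assert blocked.kill_fluxes[1] > inhibited.kill_fluxes[1]
        assert blocked.kill_fluxes[1] == pytest.approx(
            10 * inhibited.kill_fluxes[1])

    def test_kill_flux_nonnegative_and_logistic_cap(self):
        r = tumour_growth_and_kill((1e13, 0, 0, 0), 0.0, (1, 1, 1, 1),
                                   0.01, 40.0, carrying_capacity=1e13)
        assert r.derivatives[0] <= 0.0  # at capacity growth stops


class TestApcAntigenDynamics:
    def test_antigen_decays_to_zero_without_sources(self):
        # no killing, no baseline shedding: both antigen pools empty out
        p = ParameterSet({"k_ag_shed": 0.0})

        def rhs(t, y):
            d = apc_antigen_dynamics(y[0], y[1], 0, 0, 0, 0.0, 1e9,
                                     1.0, 1.0, p)
            return [d.d_antigen_tum, d.d_antigen_ln]

        sol = solve_ivp(rhs, (0, 30.0), [1e6, 1e5], rtol=1e-10, atol=1e-6)
        assert sol.y[0, -1] < 1e-3 and sol.y[1, -1] < 1e-3

    def test_migration_only_conserves_total_mapc(self):
        # zero maturation, death and uptake: migration just moves mAPCs
        p = ParameterSet({"k_mat": 0.0, "k_mat_ln": 0.0, "d_mapc_tum": 0.0,
                          "d_mapc_ln": 0.0, "s_apc_tum": 0.0, "d_apc_tum": 0.0})

        def rhs(t, y):
            d = apc_antigen_dynamics(0, 0, 0, y[0], y[1], 0.0, 0.0, 1.0, 1.0, p)
            return [d.d_mapc_tum, d.d_mapc_ln]

        sol = solve_ivp(rhs, (0, 20), [1e4, 1e3], rtol=1e-10, atol=1e-6)
        total = sol.y.sum(axis=0)
        assert np.allclose(total, total[0], rtol=1e-8)

    def test_zero_migration_isolates_tumour_pool(self):
        p = ParameterSet({"k_mig_mapc": 0.0})
        d = apc_antigen_dynamics(0, 1e6, 0, 5e3, 0, 0.0, 0.0, 1.0, 1.0, p)
        # TDLN gains only from resident maturation, not from tumour mAPCs
        assert d.d_mapc_ln == pytest.approx(
            p["k_mat_ln"] * p["apc_ln_resident"]
            * (1e6 / (1e6 + p["k_ag_half_ln"])))
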