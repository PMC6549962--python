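"""Antibody PK: dose conversion, compartmental fluxes against closed forms,
mass balance, linearity, and dosing-regimen resolution."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp
from scipy.linalg import expm

from icbsim.model_core import ParameterSet, PatientParameters, geometry_from
from icbsim.pkpd import (
    AntibodyConcentrations,
    AntibodyPKParameters,
    DoseEvent,
    Regimen,
    anti_pdl1_dose_regimen,
    mg_to_molar,
    pk_rhs,
    resolve_regimen,
)


@pytest.fixture(scope="module")
def geometry():
    return geometry_from(PatientParameters(), ParameterSet())


def pk_params(**kw):
    base = dict(MW=149e3, Cl=0.278, k_perm_BP=0.05, k_perm_BT=0.05,
                k_perm_BLN=0.05, kon=0.0, koff=0.0, target_list=("ctla4",))
    base.update(kw)
    return AntibodyPKParameters(**base)


class TestMgToMolar:
    def test_zero_dose(self):
        assert mg_to_molar(0.0, 149e3, 5.0) == 0.0

    def test_hand_arithmetic(self):
        # 1500 mg / 149 kg/mol / 5 L = 2.013e-6 M
        assert mg_to_molar(1500.0, 149e3, 5.0) == pytest.approx(2.013e-6,
                                                                rel=1e-3)

    def test_per_kg_resolution_against_trial_dose(self):
        # 1 mg/kg at the 75 kg reference weight equals the 75 mg trial dose
        reg = resolve_regimen("anti_ctla4_mono", body_weight=75.0)
        assert reg.events[0].amount_mg == pytest.approx(75.0)

    def test_invalid(self):
        with pytest.raises(ValueError):
            mg_to_molar(10.0, 0.0, 5.0)
        with pytest.raises(ValueError):
            mg_to_molar(10.0, 149e3, 0.0)


class TestPkRhs:
    def test_isolated_central_clearance_closed_form(self, geometry):
        pk = pk_params(k_perm_BP=0.0, k_perm_BT=0.0, k_perm_BLN=0.0)
        g0 = geometry
        # k_Lt > 0 only moves drug already in tumour/LN; start all in central
        c0 = 2e-6

        def rhs(t, y):
            d = pk_rhs(AntibodyConcentrations(*np.maximum(y, 0.0)), g0, pk)
            return list(d)

        sol = solve_ivp(rhs, (0, 30), [c0, 0, 0, 0], rtol=1e-11, atol=1e-16,
                        t_eval=[30.0])
        expected = c0 * np.exp(-pk.Cl * 30.0 / g0.V_blood)
        assert sol.y[0, -1] == pytest.approx(expected, rel=1e-8)
        assert np.all(sol.y[1:, -1] == 0.0)

    def test_mass_conservation_without_clearance_or_binding(self, geometry):
        pk = pk_params(Cl=0.0)
        g = geometry
        vols = np.array([g.V_blood, g.V_peripheral, g.V_tumour_pk,
                         g.V_tdln * g.n_tdln])

        def rhs(t, y):
            return list(pk_rhs(AntibodyConcentrations(*np.maximum(y, 0.0)),
                               g, pk))

        y0 = [2e-6, 0, 0, 0]
        sol = solve_ivp(rhs, (0, 100.0), y0, method="BDF",
                        rtol=1e-10, atol=1e-18)
        amount0 = float(vols @ y0)
        amount_end = float(vols @ sol.y[:, -1])
        assert abs(amount_end - amount0) / amount0 < 1e-6

    def test_linear_system_matches_matrix_exponential(self, geometry):
        """With binding off, the four-compartment system is linear: the
        trajectory must equal expm(A t) @ c0 with A assembled from the
        flux coefficients."""
        pk = pk_params()
        g = geometry
        vols = np.array([g.V_blood, g.V_peripheral, g.V_tumour_pk,
                         g.V_tdln * g.n_tdln])
        # build A column by column from the (linear) rhs
        A = np.zeros((4, 4))
        for j in range(4):
            e = np.zeros(4)
            e[j] = 1.0
            A[:, j] = pk_rhs(AntibodyConcentrations(*e), g, pk)
        c0 = np.array([2e-6, 0, 0, 0])

        def rhs(t, y):
            return list(pk_rhs(AntibodyConcentrations(*np.maximum(y, 0.0)),
                               g, pk))

        for t_end in (1.0, 10.0, 60.0):
            sol = solve_ivp(rhs, (0, t_end), c0, method="BDF",
                            rtol=1e-11, atol=1e-18, t_eval=[t_end])
            exact = expm(A * t_end) @ c0
            np.testing.assert_allclose(sol.y[:, -1], exact, rtol=1e-5,
                                       atol=1e-16)

    def test_dose_doubling_doubles_concentrations(self, geometry):
        pk = pk_params()

        def final(c0):
            sol = solve_ivp(
                lambda t, y: list(pk_rhs(AntibodyConcentrations(
                    *np.maximum(y, 0.0)), geometry, pk)),
                (0, 50.0), [c0, 0, 0, 0], method="BDF",
                rtol=1e-10, atol=1e-18)
            return sol.y[:, -1]

        np.testing.assert_allclose(final(4e-6), 2 * final(2e-6), rtol=1e-6)

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError):
            AntibodyConcentrations(-1e-9, 0, 0, 0)


class TestRegimens:
    def test_trial_combo_schedule(self):
        reg = resolve_regimen("trial_combo", body_weight=75.0, horizon=456.0)
        ctla4 = [e for e in reg.events if e.drug == "antictla4"]
        pdl1 = [e for e in reg.events if e.drug == "antipdl1"]
        assert [e.time for e in ctla4] == [0.0, 28.0, 56.0, 84.0]
        assert all(e.amount_mg == 75.0 for e in ctla4)
        induction = [e for e in pdl1 if e.amount_mg == 1500.0]
        maintenance = [e for e in pdl1 if e.amount_mg == 750.0]
        assert [e.time for e in induction] == [0.0, 28.0, 56.0, 84.0]
        assert maintenance[0].time == 112.0
        assert np.allclose(np.diff([e.time for e in maintenance]), 14.0)

    def test_q2w_maintenance_event_count(self):
        # floor((456 - 112) / 14) + 1 = 25 maintenance doses
        reg = resolve_regimen("anti_pdl1_mono", horizon=456.0)
        maintenance = [e for e in reg.events
                       if e.drug == "antipdl1" and e.time >= 112.0]
        assert len(maintenance) == 25

    def test_zero_dose_scale_drops_drug(self):
        reg = resolve_regimen("trial_combo", dose_scale={"antictla4": 0.0})
        assert reg.drugs() == ["antipdl1"]

    def test_dose_response_regimen_maintenance_map(self):
        assert len(anti_pdl1_dose_regimen(0.0).events) == 0
        r1 = anti_pdl1_dose_regimen(1.0)
        assert len(r1.events) == 4  # no maintenance below 3 mg/kg
        r20 = anti_pdl1_dose_regimen(20.0, body_weight=75.0)
        maint = [e for e in r20.events if e.time >= 112.0]
        assert maint[0].amount_mg == pytest.approx(750.0)  # 10 mg/kg * 75 kg

    def test_duplicate_events_merge_with_warning(self):
        with pytest.warns(UserWarning, match="duplicate"):
            reg = Regimen(events=[DoseEvent("antipdl1", 0.0, 100.0),
                                  DoseEvent("antipdl1", 0.0, 50.0)])
        assert len(reg.events) == 1
        assert reg.events[0].amount_mg == 150.0

    def test_invalid_events(self):
        with pytest.raises(ValueError):
            DoseEvent("antipdl1", 0.0, 0.0)
        with pytest.raises(ValueError):
            DoseEvent("antipdl1", -1.0, 10.0)
        with pytest.raises(KeyError):
            resolve_regimen("no_such_template")
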