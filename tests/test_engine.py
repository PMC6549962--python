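"""Steady-state initialization and event-segmented stiff integration."""

import numpy as np
import pytest

from icbsim import (
    CheckpointBlockadeModel,
    PatientParameters,
    Regimen,
    SimulationSettings,
    resolve_regimen,
)
from icbsim.engine import find_pretreatment_steady_state
from icbsim.model_core import STATE_INDEX


class TestSteadyState:
    def test_baseline_reaches_quasi_steady_state(self, baseline_model,
                                                 baseline_steady_state):
        """Immune equilibration completes within a few months and the
        returned state is a fixed point: another 30 days of drug-free
        integration changes the effector count by far less than 0.01%."""
        ss = baseline_steady_state
        assert ss.teff_total > 0
        from scipy.integrate import solve_ivp

        from icbsim.engine import _atol_vector
        sol = solve_ivp(
            lambda t, y: baseline_model.rhs(t, y, freeze_cancer=True),
            (0.0, 30.0), ss.vector, method="BDF", rtol=1e-8,
            atol=_atol_vector(1e-10))
        teff2 = float(np.maximum(sol.y[:, -1], 0.0)[
            [STATE_INDEX[n] for n in ("teff_ln", "teff_blood", "tp_free",
                                      "tp_bound", "tp_arr", "teff_peri",
                                      "tt_free", "tt_bound", "tt_arr",
                                      "teff_tum")]].sum())
        assert abs(teff2 - ss.teff_total) / ss.teff_total < 1e-4

    def test_small_tumour_supports_fewer_effectors(self, baseline_steady_state,
                                                   batch_settings):
        """A near-undetectable tumour sheds little antigen, so the immune
        system settles far below the 30 mm baseline."""
        small = CheckpointBlockadeModel(
            PatientParameters(initial_tumour_diameter=2.0))
        ss_small = small.steady_state(batch_settings)
        assert ss_small.teff_total < 0.2 * baseline_steady_state.teff_total

    def test_nonconvergence_raises(self, baseline_model):
        from icbsim.engine import SteadyStateError
        tight = SimulationSettings(ss_tol=1e-16, ss_max_days=60.0)
        with pytest.raises(SteadyStateError):
            find_pretreatment_steady_state(baseline_model, tight)


class TestSimulate:
    def test_untreated_tumour_grows_monotonically(self, baseline_model,
                                                  baseline_steady_state):
        traj = baseline_model.simulate(Regimen(events=[], horizon=456.0),
                                       state0=baseline_steady_state)
        assert np.all(np.diff(traj.diameter) >= -1e-9)
        assert traj.final_diameter > traj.baseline_diameter

    def test_bit_identical_repeat_runs(self, baseline_model,
                                       baseline_steady_state, batch_settings):
        reg = resolve_regimen("anti_ctla4_mono", horizon=120.0)
        settings = batch_settings.replace(horizon=120.0)
        a = baseline_model.simulate(reg, state0=baseline_steady_state,
                                    settings=settings)
        b = baseline_model.simulate(reg, state0=baseline_steady_state,
                                    settings=settings)
        np.testing.assert_array_equal(a.states, b.states)
        np.testing.assert_array_equal(a.t, b.t)

    def test_trial_combo_serum_shows_dose_peaks(self, baseline_model,
                                                baseline_steady_state,
                                                batch_settings):
        """Four induction peaks for the anti-CTLA-4 drug, maintenance peaks
        for the anti-PD-L1 drug through the horizon."""
        reg = resolve_regimen("trial_combo", horizon=456.0)
        traj = baseline_model.simulate(reg, state0=baseline_steady_state,
                                       settings=batch_settings)
        trem = traj.serum["antictla4"]
        peaks = list(np.flatnonzero((trem[1:-1] > trem[:-2])
                                    & (trem[1:-1] >= trem[2:])) + 1)
        if trem[0] > trem[1]:   # day-0 bolus peak sits on the grid boundary
            peaks.insert(0, 0)
        assert len(peaks) == 4
        assert trem[-1] < 0.1 * trem.max()  # decays after last dose
        durv = traj.serum["antipdl1"]
        d_peaks = np.flatnonzero((durv[1:-1] > durv[:-2])
                                 & (durv[1:-1] >= durv[2:])) + 1
        assert len(d_peaks) >= 20  # 4 induction + q2w maintenance
        assert traj.t[d_peaks[-1]] > 440.0

    def test_no_negative_species_on_output_grid(self, baseline_model,
                                                baseline_steady_state,
                                                batch_settings):
        reg = resolve_regimen("trial_combo", horizon=200.0)
        traj = baseline_model.simulate(
            reg, state0=baseline_steady_state,
            settings=batch_settings.replace(horizon=200.0))
        assert np.all(traj.states >= 0.0)
        assert np.all(np.diff(traj.t) > 0)

    def test_tolerance_convergence(self, baseline_model, baseline_steady_state):
        """Tightening rel_tol from 1e-6 to 5e-7 moves the final diameter by
        far less than 0.1% (the solution is tolerance-converged)."""
        reg = resolve_regimen("anti_ctla4_mono", horizon=200.0)
        finals = []
        for rtol in (1e-6, 5e-7):
            s = SimulationSettings(rel_tol=rtol, abs_tol=1e-8, horizon=200.0)
            traj = baseline_model.simulate(reg, state0=baseline_steady_state,
                                           settings=s)
            finals.append(traj.final_diameter)
        assert abs(finals[1] - finals[0]) / finals[0] < 1e-3

    def test_serum_jump_only_at_dose_events(self, baseline_model,
                                            baseline_steady_state,
                                            batch_settings):
        reg = resolve_regimen("anti_ctla4_mono", horizon=60.0)
        traj = baseline_model.simulate(
            reg, state0=baseline_steady_state,
            settings=batch_settings.replace(horizon=60.0))
        trem = traj.serum["antictla4"]
        jumps = np.flatnonzero(np.diff(trem) > 0.3 * trem.max())
        jump_days = set(np.round(traj.t[jumps + 1]))
        assert jump_days <= {0.0, 28.0, 56.0}

    def test_trajectory_frame_has_fixed_columns(self, baseline_model,
                                                baseline_steady_state,
                                                batch_settings):
        reg = resolve_regimen("anti_pdl1_mono", horizon=30.0)
        traj = baseline_model.simulate(
            reg, state0=baseline_steady_state,
            settings=batch_settings.replace(horizon=30.0))
        df = traj.to_frame()
        assert list(df.columns) == [
            "time_day", "tumour_diameter_mm", "teff_total", "mapc_ln",
            "serum_antictla4_mol_per_l", "serum_antipdl1_mol_per_l"]
        sf = traj.state_frame()
        assert sf.shape[1] == 1 + 42
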