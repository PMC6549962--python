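"""Stiff ODE integration of the full checkpoint-blockade model.

:class:`CheckpointBlockadeModel` wires the immune-dynamics, trafficking and
PK/PD terms into one autonomous right-hand side over the fixed named state
vector, finds the drug-free pre-treatment quasi-steady state, and runs
event-segmented stiff integration (BDF) across bolus dose events.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from . import immune_dynamics as imm
from .model_core import (
    AVOGADRO,
    CompartmentGeometry,
    ModelState,
    N_STATES,
    STATE_INDEX,
    STATE_NAMES,
    ParameterSet,
    PatientParameters,
    assemble_state,
    diameter_from_cell_count,
    geometry_from,
)
from .pkpd import (
    AntibodyConcentrations,
    AntibodyPKParameters,
    Regimen,
    mg_to_molar,
    pk_rhs,
)
from .trafficking import TraffickingParameters, TraffickingDerivs, VascularTcellState, trafficking_rhs

__all__ = [
    "SimulationSettings",
    "Trajectory",
    "SteadyStateError",
    "CheckpointBlockadeModel",
    "find_pretreatment_steady_state",
    "simulate",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SimulationSettings:
    """Integrator and output settings.

    The package default tolerances (rel 1e-8 with species-scaled abs) keep
    batch runs fast; :meth:`high_accuracy` returns very tight day-scaled
    tolerances (abs 1e-14, rel 1e-13) for single reference runs.
    """

    abs_tol: float = 1e-10       # scaled per species class, see _atol_vector
    rel_tol: float = 1e-8
    horizon: float = 456.0       # day; 15 months after therapy begins
    output_step: float = 1.0     # day
    max_step: float = np.inf     # day
    seed: int = 0                # reserved for stochastic extensions
    ss_window: float = 30.0      # day, steady-state comparison window
    ss_tol: float = 1e-4         # relative effector-T change per window
    ss_max_days: float = 1000.0

    def __post_init__(self) -> None:
        if not (0 < self.abs_tol < 1e-3 and 0 < self.rel_tol < 1e-3):
            raise ValueError("tolerances must lie in (0, 1e-3)")
        if self.horizon <= 0 or self.output_step <= 0:
            raise ValueError("horizon and output_step must be positive")

    @classmethod
    def high_accuracy(cls, **kwargs) -> "SimulationSettings":
        """Tight reference tolerances (abs 1e-14 day-scaled, rel 1e-13)."""
        kwargs.setdefault("abs_tol", 1e-14)
        kwargs.setdefault("rel_tol", 1e-13)
        return cls(**kwargs)

    def replace(self, **kwargs) -> "SimulationSettings":
        return replace(self, **kwargs)


def _atol_vector(abs_tol: float) -> np.ndarray:
    """Species-scaled absolute tolerances: molar species are ~1e-6 to 1e-12
    while cell counts reach 1e10, so a scalar atol cannot serve both."""
    atol = np.full(N_STATES, abs_tol * 1e7)  # counts (cells, antigen)
    for name, i in STATE_INDEX.items():
        if name.startswith(("antictla4", "antipdl1", "sctla4", "ab_sctla4")):
            atol[i] = abs_tol * 1e-8          # mol/L
        elif name.startswith("ab_"):
            atol[i] = abs_tol * 1e2           # molecules/cell
    return atol


@dataclass
class Trajectory:
    """Time series of the main model outputs on the output grid."""

    t: np.ndarray                       # day, strictly increasing
    diameter: np.ndarray                # mm
    teff_total: np.ndarray              # total effector T cells in the system
    mapc_ln: np.ndarray                 # mature APCs in TDLN
    serum: Dict[str, np.ndarray]        # drug -> central-compartment mol/L
    states: Optional[np.ndarray] = None  # (n_states, n_times) full state matrix

    def __post_init__(self) -> None:
        if len(self.t) == 0:
            raise ValueError("empty trajectory")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("time grid must be strictly increasing")

    @property
    def baseline_diameter(self) -> float:
        return float(self.diameter[0])

    @property
    def final_diameter(self) -> float:
        return float(self.diameter[-1])

    def to_frame(self) -> pd.DataFrame:
        """Tidy table, one row per time point; fixed column names."""
        data = {
            "time_day": self.t,
            "tumour_diameter_mm": self.diameter,
            "teff_total": self.teff_total,
            "mapc_ln": self.mapc_ln,
        }
        for drug, conc in self.serum.items():
            data[f"serum_{drug}_mol_per_l"] = conc
        return pd.DataFrame(data)

    def state_frame(self) -> pd.DataFrame:
        if self.states is None:
            raise ValueError("full state matrix was not recorded")
        df = pd.DataFrame(self.states.T, columns=list(STATE_NAMES))
        df.insert(0, "time_day", self.t)
        return df


class SteadyStateError(RuntimeError):
    """Pre-treatment immune steady state not reached within the time limit."""


_TEFF_IDX = np.array([STATE_INDEX[n] for n in
                      ("teff_ln", "teff_blood", "tp_free", "tp_bound", "tp_arr",
                       "teff_peri", "tt_free", "tt_bound", "tt_arr", "teff_tum")])


class CheckpointBlockadeModel:
    """Mechanistic tumour-immune-antibody model for one virtual patient.

    Parameters
    ----------
    patient : PatientParameters
    params : ParameterSet, optional
        Rate-constant registry; defaults are the calibrated baseline.

    The model instance is immutable once built; :meth:`steady_state` and
    :meth:`simulate` are deterministic functions of their inputs.
    """

    def __init__(self, patient: PatientParameters,
                 params: ParameterSet | None = None) -> None:
        self.patient = patient
        self.params = params if params is not None else ParameterSet()
        self.geometry: CompartmentGeometry = geometry_from(self.patient, self.params)
        self.pk = {
            "antictla4": AntibodyPKParameters(
                MW=self.params["mw_antictla4"], Cl=self.params["cl_antictla4"],
                k_perm_BP=self.params["k_perm_bp"], k_perm_BT=self.params["k_perm_bt"],
                k_perm_BLN=self.params["k_perm_bln"],
                kon=self.params["kon_antictla4"], koff=self.params["koff_antictla4"],
                target_list=("ctla4_treg_tumour", "sctla4_tumour", "ctla4_pnt_ln",
                             "ctla4_treg_ln", "sctla4_ln")),
            "antipdl1": AntibodyPKParameters(
                MW=self.params["mw_antipdl1"], Cl=self.params["cl_antipdl1"],
                k_perm_BP=self.params["k_perm_bp"], k_perm_BT=self.params["k_perm_bt"],
                k_perm_BLN=self.params["k_perm_bln"],
                kon=self.params["kon_antipdl1"], koff=self.params["koff_antipdl1"],
                target_list=("pdl1_cancer", "pdl1_apc_tumour", "pdl1_supp_tumour",
                             "pdl1_mapc_ln")),
        }
        g = self.geometry
        self._traffic_tum = TraffickingParameters(
            k_f=self.params["k_f_tum"], k_r=self.params["k_r_tum"],
            k_L=self.params["frac_lymph_tum"] * g.Q,
            AR=self.params["ar_tum"], J=self.params["j_tum"],
            B=self.params["b_sites_tum"], Vv=g.Vv, Q=g.Q,
            turnover=self.params["turnover_vasc"])
        self._traffic_peri = TraffickingParameters(
            k_f=self.params["k_f_peri"], k_r=self.params["k_r_peri"],
            k_L=self.params["frac_lymph_peri"] * self.params["q_peri"],
            AR=self.params["ar_peri"], J=self.params["j_peri"],
            B=self.params["b_sites_peri"], Vv=self.params["vv_peri"],
            Q=self.params["q_peri"], turnover=self.params["turnover_vasc"])

    # -- right-hand side -------------------------------------------------

    def rhs(self, t: float, y: np.ndarray, freeze_cancer: bool = False,
            dose_rates: Dict[str, float] | None = None) -> np.ndarray:
        """Full model derivative at state ``y`` (autonomous in ``t``)."""
        p = self.params
        g = self.geometry
        ix = STATE_INDEX
        y = np.maximum(y, 0.0)  # guard against integrator undershoot
        dy = np.zeros_like(y)

        c_nn, c_l1, c_l2, c_dp = y[0], y[1], y[2], y[3]
        ctot = c_nn + c_l1 + c_l2 + c_dp
        ag_t, ag_l = y[ix["antigen_tum"]], y[ix["antigen_ln"]]
        apc_t, mapc_t, mapc_l = y[ix["apc_tum"]], y[ix["mapc_tum"]], y[ix["mapc_ln"]]
        naive, primed, prolif, teff_ln = (y[ix["naive_ln"]], y[ix["primed_ln"]],
                                          y[ix["prolif_ln"]], y[ix["teff_ln"]])
        teff_b = y[ix["teff_blood"]]
        teff_tum, texh = y[ix["teff_tum"]], y[ix["texh_tum"]]

        # --- suppressor levels (algebraic) ---
        t_lymph_ln = naive + primed + prolif + teff_ln
        mdsc, treg_ln, treg_t = imm.suppressor_levels(
            ctot, t_lymph_ln, p["rho_mdsc"], p["phi_treg_ln"],
            p["treg_tum_max"], p["k_mdsc_treg_half"])

        # --- free receptor densities after antibody binding ---
        fr_pdl1_cancer = max(p["pdl1_per_cancer"] - y[ix["ab_pdl1_cancer"]], 0.0)
        fr_pdl1_apc = max(p["pdl1_per_apc"] - y[ix["ab_pdl1_apc"]], 0.0)
        fr_pdl1_supp = max(p["pdl1_per_supp"] - y[ix["ab_pdl1_supp"]], 0.0)
        fr_pdl1_mapc = max(p["pdl1_per_mapc_ln"] - y[ix["ab_pdl1_mapc_ln"]], 0.0)
        fr_ct_treg_t = max(p["ctla4_per_treg"] - y[ix["ab_ctla4_treg_t"]], 0.0)
        fr_ct_pnt = max(p["ctla4_per_pnt"] - y[ix["ab_ctla4_pnt"]], 0.0)
        fr_ct_treg_ln = max(p["ctla4_per_treg"] - y[ix["ab_ctla4_treg_ln"]], 0.0)

        # --- tumour killing inhibition per cancer subtype ---
        occ_l1 = imm.equilibrium_occupancy(p["pd1_per_teff"], fr_pdl1_cancer,
                                           p["kd_syn_pd1_pdl1"])
        occ_l2 = imm.equilibrium_occupancy(p["pd1_per_teff"], p["pdl2_per_cancer"],
                                           p["kd_syn_pd1_pdl2"])
        f_l1 = imm.inhibition_factor(occ_l1, p["emax_pd1_kill"], p["ro50_pd1"],
                                     p["hill_pd1"])
        f_l2 = imm.inhibition_factor(occ_l2, p["emax_pdl2_kill"], p["ro50_pd1"],
                                     p["hill_pd1"])
        f_nn = 1.0 - p["emax_baseline_kill"]
        supp = mdsc + treg_t
        s_ab = supp / (supp + p["k_supp_half"]) if supp > 0 else 0.0
        occ_supp = s_ab * imm.equilibrium_occupancy(
            p["pd1_per_teff"], fr_pdl1_supp, p["kd_syn_pd1_pdl1"])
        f_supp = imm.inhibition_factor(occ_supp, p["emax_supp_kill"],
                                       p["ro50_pd1"], p["hill_pd1"])
        multipliers = (f_nn * f_supp, f_l1 * f_supp, f_l2 * f_supp,
                       f_l1 * f_l2 * f_supp)

        growth_rate = math.log(2.0) / self.patient.tumour_doubling_time
        gk = imm.tumour_growth_and_kill(
            (c_nn, c_l1, c_l2, c_dp), teff_tum, multipliers, growth_rate,
            p["k_kill"], p["k_kill_half"], p["tumour_cap"])
        if not freeze_cancer:
            dy[0:4] = gk.derivatives
        kill_flux = gk.killed_cell_flux if not freeze_cancer else 0.0

        # --- exhaustion driver: aggregate engaged PD-1 on tumour effectors ---
        if ctot > 0:
            w_l1 = (c_l1 + c_dp) / ctot
            w_l2 = (c_l2 + c_dp) / ctot
        else:
            w_l1 = w_l2 = 0.0
        occ_pd1_agg = min(w_l1 * occ_l1 + w_l2 * occ_l2 + occ_supp, 1.0)

        # --- soluble CTLA-4 and APC maturation factors ---
        s_tum, s_ln = y[ix["sctla4_tum"]], y[ix["sctla4_ln"]]
        occ_cd80_t = s_tum / (s_tum + p["kd_cd80_sctla4"]) if s_tum > 0 else 0.0
        occ_cd80_l = s_ln / (s_ln + p["kd_cd80_sctla4"]) if s_ln > 0 else 0.0
        f_mat_t = imm.inhibition_factor(occ_cd80_t, p["emax_sctla4_mat"],
                                        p["ro50_sctla4"], p["hill_sctla4"])
        f_mat_l = imm.inhibition_factor(occ_cd80_l, p["emax_sctla4_mat"],
                                        p["ro50_sctla4"], p["hill_sctla4"])

        apcd = imm.apc_antigen_dynamics(ag_t, ag_l, apc_t, mapc_t, mapc_l,
                                        kill_flux, ctot, f_mat_t, f_mat_l, p)
        dy[ix["antigen_tum"]] = apcd.d_antigen_tum
        dy[ix["antigen_ln"]] = apcd.d_antigen_ln
        dy[ix["apc_tum"]] = apcd.d_apc_tum
        dy[ix["mapc_tum"]] = apcd.d_mapc_tum
        dy[ix["mapc_ln"]] = apcd.d_mapc_ln

        # --- T-cell priming in the TDLN ---
        occ_pd1_ln = imm.equilibrium_occupancy(p["pd1_per_teff"], fr_pdl1_mapc,
                                               p["kd_syn_pd1_pdl1"])
        f_pd1_ln = imm.inhibition_factor(occ_pd1_ln, p["emax_pd1_prime"],
                                         p["ro50_pd1"], p["hill_pd1"])
        occ_ct = (imm.equilibrium_occupancy(fr_ct_pnt, p["cd8086_per_mapc"],
                                            p["kd_syn_ctla4_cd80"])
                  * fr_ct_pnt / p["ctla4_per_pnt"])
        f_ct = imm.inhibition_factor(occ_ct, p["emax_ctla4_prime"],
                                     p["ro50_ctla4"], p["hill_ctla4"])
        tsat = treg_ln / (treg_ln + p["k_treg_ln_half"]) if treg_ln > 0 else 0.0
        occ_tr = (tsat * imm.equilibrium_occupancy(
            fr_ct_treg_ln, p["cd8086_per_mapc"], p["kd_syn_ctla4_cd80"])
            * fr_ct_treg_ln / p["ctla4_per_treg"])
        f_tr = 1.0 - p["emax_treg_prime"] * occ_tr

        r1, r2, r3 = imm.priming_transition(
            (naive, primed, prolif), mapc_l, self.patient.antigen_intensity,
            f_pd1_ln, f_ct,
            (p["k_prime1"], p["k_prime2"], p["k_prime3"]),
            p["k_mapc_half_prime"], treg_factor=f_tr)

        dy[ix["naive_ln"]] = p["s_naive"] - p["d_naive"] * naive - r1
        dy[ix["primed_ln"]] = r1 - p["d_pnt"] * primed - r2
        dy[ix["prolif_ln"]] = r2 - p["d_prol"] * prolif - r3
        dy[ix["teff_ln"]] = (p["expansion_fold"] * r3
                             - (p["d_teff_ln"] + p["k_exit_ln"]) * teff_ln)

        # --- vascular trafficking into tumour and peripheral tissue ---
        tr_t: TraffickingDerivs = trafficking_rhs(
            VascularTcellState(teff_b, y[ix["tt_free"]], y[ix["tt_bound"]],
                               y[ix["tt_arr"]]), self._traffic_tum)
        tr_p: TraffickingDerivs = trafficking_rhs(
            VascularTcellState(teff_b, y[ix["tp_free"]], y[ix["tp_bound"]],
                               y[ix["tp_arr"]]), self._traffic_peri)
        dy[ix["tt_free"]], dy[ix["tt_bound"]], dy[ix["tt_arr"]] = \
            tr_t.dT_f, tr_t.dT_b, tr_t.dT_a
        dy[ix["tp_free"]], dy[ix["tp_bound"]], dy[ix["tp_arr"]] = \
            tr_p.dT_f, tr_p.dT_b, tr_p.dT_a
        dy[ix["teff_blood"]] = (p["k_exit_ln"] * teff_ln
                                - p["d_teff_blood"] * teff_b
                                + tr_t.blood_exchange + tr_p.blood_exchange)
        dy[ix["teff_peri"]] = (tr_p.transmigration
                               - p["d_teff_peri"] * y[ix["teff_peri"]])
        exh = p["k_exhaust"] * occ_pd1_agg * teff_tum
        dy[ix["teff_tum"]] = (tr_t.transmigration - p["k_apo_teff"] * teff_tum - exh)
        dy[ix["texh_tum"]] = exh - p["d_texh"] * texh

        # --- antibody PK with binding sinks ---
        v_av_t = g.V_tumour_pk * g.K_T
        v_av_ln = g.V_tdln * g.n_tdln * g.K_LN
        dose_rates = dose_rates or {}

        # anti-PD-L1: binds PD-L1 pools in tumour and TDLN
        c_apdl1_t = y[ix["antipdl1_t"]] / g.K_T
        c_apdl1_ln = y[ix["antipdl1_ln"]] / g.K_LN
        kon_d, koff_d = p["kon_antipdl1"], p["koff_antipdl1"]
        sink_t = 0.0
        pools_t = (("ab_pdl1_cancer", fr_pdl1_cancer, c_l1 + c_dp),
                   ("ab_pdl1_apc", fr_pdl1_apc, apc_t + mapc_t),
                   ("ab_pdl1_supp", fr_pdl1_supp, supp))
        for name, free_pc, cells in pools_t:
            rate = kon_d * c_apdl1_t * free_pc - koff_d * y[ix[name]]
            dy[ix[name]] = rate
            sink_t += rate * cells / (AVOGADRO * g.V_tumour_pk)
        rate = kon_d * c_apdl1_ln * fr_pdl1_mapc - koff_d * y[ix["ab_pdl1_mapc_ln"]]
        dy[ix["ab_pdl1_mapc_ln"]] = rate
        sink_ln = rate * mapc_l / (AVOGADRO * g.V_tdln * g.n_tdln)
        pk_d = pk_rhs(AntibodyConcentrations(y[ix["antipdl1_b"]], y[ix["antipdl1_p"]],
                                             y[ix["antipdl1_t"]], y[ix["antipdl1_ln"]]),
                      g, self.pk["antipdl1"], sink_t, sink_ln,
                      dose_rates.get("antipdl1", 0.0))
        dy[ix["antipdl1_b"]], dy[ix["antipdl1_p"]] = pk_d.dC_B, pk_d.dC_P
        dy[ix["antipdl1_t"]], dy[ix["antipdl1_ln"]] = pk_d.dC_T, pk_d.dC_LN

        # anti-CTLA-4: binds surface + soluble CTLA-4 pools
        c_act_t = y[ix["antictla4_t"]] / g.K_T
        c_act_ln = y[ix["antictla4_ln"]] / g.K_LN
        kon_c, koff_c = p["kon_antictla4"], p["koff_antictla4"]
        rate = kon_c * c_act_t * fr_ct_treg_t - koff_c * y[ix["ab_ctla4_treg_t"]]
        dy[ix["ab_ctla4_treg_t"]] = rate
        sink_t = rate * treg_t / (AVOGADRO * g.V_tumour_pk)
        sink_ln = 0.0
        pools_ln = (("ab_ctla4_pnt", fr_ct_pnt, primed + prolif),
                    ("ab_ctla4_treg_ln", fr_ct_treg_ln, treg_ln))
        for name, free_pc, cells in pools_ln:
            rate = kon_c * c_act_ln * free_pc - koff_c * y[ix[name]]
            dy[ix[name]] = rate
            sink_ln += rate * cells / (AVOGADRO * g.V_tdln * g.n_tdln)

        # soluble CTLA-4 (interstitial mol/L) secreted by Tregs
        cplx_t, cplx_l = y[ix["ab_sctla4_tum"]], y[ix["ab_sctla4_ln"]]
        sec_t = p["k_sctla4_sec"] * treg_t / (AVOGADRO * v_av_t)
        sec_l = p["k_sctla4_sec"] * treg_ln / (AVOGADRO * v_av_ln)
        bind_s_t = kon_c * c_act_t * s_tum - koff_c * cplx_t
        bind_s_l = kon_c * c_act_ln * s_ln - koff_c * cplx_l
        dy[ix["sctla4_tum"]] = sec_t - p["k_sctla4_deg"] * s_tum - bind_s_t
        dy[ix["sctla4_ln"]] = sec_l - p["k_sctla4_deg"] * s_ln - bind_s_l
        dy[ix["ab_sctla4_tum"]] = bind_s_t - p["k_sctla4_deg"] * cplx_t
        dy[ix["ab_sctla4_ln"]] = bind_s_l - p["k_sctla4_deg"] * cplx_l
        sink_t += bind_s_t * g.K_T      # back to total-volume concentration scale
        sink_ln += bind_s_l * g.K_LN

        pk_c = pk_rhs(AntibodyConcentrations(y[ix["antictla4_b"]], y[ix["antictla4_p"]],
                                             y[ix["antictla4_t"]], y[ix["antictla4_ln"]]),
                      g, self.pk["antictla4"], sink_t, sink_ln,
                      dose_rates.get("antictla4", 0.0))
        dy[ix["antictla4_b"]], dy[ix["antictla4_p"]] = pk_c.dC_B, pk_c.dC_P
        dy[ix["antictla4_t"]], dy[ix["antictla4_ln"]] = pk_c.dC_T, pk_c.dC_LN

        return dy

    # -- convenience wrappers -------------------------------------------

    def initial_state(self) -> ModelState:
        return assemble_state(self.patient, self.params)

    def steady_state(self, settings: SimulationSettings | None = None) -> ModelState:
        return find_pretreatment_steady_state(self, settings)

    def simulate(self, regimen: Regimen, state0: ModelState | None = None,
                 settings: SimulationSettings | None = None) -> Trajectory:
        settings = settings or SimulationSettings()
        if state0 is None:
            state0 = self.steady_state(settings)
        return simulate(self, state0, regimen, settings)

    def diameter_of(self, y: np.ndarray) -> float:
        n = float(np.sum(np.maximum(y[0:4], 0.0)))
        return diameter_from_cell_count(n, self.patient.cancer_cell_diameter,
                                        self.params["packing_fraction"])


def find_pretreatment_steady_state(
        model: CheckpointBlockadeModel,
        settings: SimulationSettings | None = None) -> ModelState:
    """Drug-free immune quasi-steady state at the starting tumour size.

    The cancer-subtype derivatives are held frozen at the starting diameter
    while the immune species equilibrate; convergence is declared when the
    total effector T-cell count changes by less than ``ss_tol`` (relative)
    over one ``ss_window``. Raises :class:`SteadyStateError` after
    ``ss_max_days``.
    """
    settings = settings or SimulationSettings()
    y = model.initial_state().vector.copy()
    atol = _atol_vector(settings.abs_tol)
    t = 0.0
    teff_prev = float(y[_TEFF_IDX].sum())
    while t < settings.ss_max_days:
        sol = solve_ivp(lambda tt, yy: model.rhs(tt, yy, freeze_cancer=True),
                        (t, t + settings.ss_window), y, method="BDF",
                        rtol=settings.rel_tol, atol=atol,
                        max_step=settings.max_step)
        if not sol.success:
            raise SteadyStateError(
                f"integration failed during initialization at t={sol.t[-1]:.2f} d: "
                f"{sol.message}")
        y = sol.y[:, -1]
        t = sol.t[-1]
        teff = float(np.maximum(y[_TEFF_IDX], 0.0).sum())
        denom = max(teff_prev, 1.0)
        if abs(teff - teff_prev) / denom < settings.ss_tol:
            logger.info("pre-treatment steady state reached at t=%.0f d "
                        "(Teff total %.4g)", t, teff)
            return ModelState(np.maximum(y, 0.0))
        teff_prev = teff
    raise SteadyStateError(
        f"no immune steady state within {settings.ss_max_days:.0f} days "
        f"(last relative change {abs(teff - teff_prev) / max(teff_prev, 1.0):.2e})")


def _dose_jump(model: CheckpointBlockadeModel, y: np.ndarray,
               events) -> np.ndarray:
    y = y.copy()
    for ev in events:
        pk = model.pk[ev.drug]
        inc = mg_to_molar(ev.amount_mg, pk.MW, model.geometry.V_blood)
        y[STATE_INDEX[f"{ev.drug}_b"]] += inc
        logger.info("dose event: %s %.1f mg at day %.1f (+%.3e mol/L central)",
                    ev.drug, ev.amount_mg, ev.time, inc)
    return y


def simulate(model: CheckpointBlockadeModel, state0: ModelState,
             regimen: Regimen, settings: SimulationSettings | None = None
             ) -> Trajectory:
    """Event-segmented stiff integration over the therapy horizon.

    The state is continuous except for drug-concentration jumps at bolus
    dose events (the solver restarts at each event with an exact state
    handoff). Outputs are sampled on the regular output grid; the value
    recorded at a dose time is the post-dose state. Deterministic given its
    inputs.
    """
    settings = settings or SimulationSettings()
    horizon = settings.horizon
    grid = np.round(np.arange(0.0, horizon + settings.output_step / 2,
                              settings.output_step), 9)
    atol = _atol_vector(settings.abs_tol)

    infusion = model.params["infusion_duration"]
    boundaries = {0.0, horizon}
    bolus_times: Dict[float, list] = {}
    infusion_rates: List[tuple] = []   # (start, end, drug, mol/day)
    for ev in regimen.events:
        if ev.time >= horizon:
            continue
        if infusion > 0:
            start, end = ev.time, min(ev.time + infusion, horizon)
            pk = model.pk[ev.drug]
            rate = ev.amount_mg * 1e-3 / pk.MW / (end - start)
            infusion_rates.append((start, end, ev.drug, rate))
            boundaries.update((start, end))
        else:
            bolus_times.setdefault(ev.time, []).append(ev)
            boundaries.add(ev.time)
    seg_edges = sorted(boundaries)

    y = state0.vector.copy()
    ts: List[float] = []
    ys: List[np.ndarray] = []
    for seg_start, seg_end in zip(seg_edges[:-1], seg_edges[1:]):
        if seg_start in bolus_times:
            y = _dose_jump(model, y, bolus_times[seg_start])
        rates = {drug: r for (s, e, drug, r) in infusion_rates
                 if s <= seg_start < e}
        t_eval = grid[(grid >= seg_start) & (grid < seg_end)]
        t_req = np.append(t_eval, seg_end)  # seg_end always integrated to exactly
        sol = solve_ivp(lambda tt, yy: model.rhs(tt, yy, dose_rates=rates),
                        (seg_start, seg_end), y, method="BDF",
                        t_eval=t_req, rtol=settings.rel_tol, atol=atol,
                        max_step=settings.max_step)
        if not sol.success:
            raise RuntimeError(
                f"integration failed at t={sol.t[-1] if len(sol.t) else seg_start:.3f} d: "
                f"{sol.message}")
        y = sol.y[:, -1]
        # A dose time is recorded post-dose by the next segment's start; the
        # horizon endpoint is recorded here if it sits on the grid.
        if seg_end == seg_edges[-1] and np.any(np.isclose(grid, seg_end)):
            keep = np.ones(len(sol.t), dtype=bool)
        else:
            keep = sol.t < seg_end
        ts.extend(sol.t[keep])
        ys.extend(sol.y[:, keep].T)

    tarr = np.asarray(ts)
    order = np.argsort(tarr)
    tarr = tarr[order]
    states = np.maximum(np.asarray(ys)[order].T, 0.0)  # floor tiny undershoot at 0

    diam = np.array([model.diameter_of(states[:, i]) for i in range(states.shape[1])])
    teff = states[_TEFF_IDX, :].sum(axis=0)
    serum = {drug: states[STATE_INDEX[f"{drug}_b"], :].copy()
             for drug in ("antictla4", "antipdl1")}
    return Trajectory(t=tarr, diameter=diam, teff_total=teff,
                      mapc_ln=states[STATE_INDEX["mapc_ln"], :].copy(),
                      serum=serum, states=states)
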