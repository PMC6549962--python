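"""Core domain types for the checkpoint-blockade QSP model.

The simulator describes four physiological compartments — central blood,
peripheral tissue, tumour, and a lumped tumour-draining lymph node (TDLN) —
and tracks cancer cells, antigen, antigen-presenting cells, T-cell
populations, suppressor-cell checkpoints and two monoclonal antibodies
(an anti-CTLA-4 and an anti-PD-L1 drug).

This module holds the pieces every dynamics module shares:

* :class:`PatientParameters` — per-patient biomarkers and physiology,
* :class:`ParameterSet` — the registry of named rate constants with units,
  defaults and allowed ranges,
* :class:`CompartmentGeometry` — volumes, flows and exchange-surface terms,
* the fixed, documented state-vector layout (:data:`STATE_NAMES`) and
  :func:`assemble_state`,
* geometry/unit conversions between tumour diameter and cell count, and the
  partition of cancer cells into checkpoint-expression subtypes.

Units: time in days, volumes in litres, drug amounts in mol/L, cell
populations as dimensionless counts, diameters in mm for display (µm for the
single cell). Receptor numbers are molecules per cell.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields as dc_fields
from typing import Dict, Iterator, Mapping, Tuple

import numpy as np

__all__ = [
    "AVOGADRO",
    "PatientParameters",
    "Parameter",
    "ParameterSet",
    "CompartmentGeometry",
    "ModelState",
    "STATE_NAMES",
    "STATE_INDEX",
    "split_cancer_subtypes",
    "diameter_from_cell_count",
    "cell_count_from_diameter",
    "tumour_volume_l",
    "geometry_from",
    "assemble_state",
]

AVOGADRO = 6.02214076e23


# ---------------------------------------------------------------------------
# Patient
# ---------------------------------------------------------------------------

@dataclass
class PatientParameters:
    """Per-patient biomarker and physiology values.

    Defaults are the baseline virtual patient: 30 mm starting tumour,
    antigen intensity 0.7, 25% of cancer cells PD-L1 positive, 75 kg body
    weight. ``cd80_cancer`` and ``pd1_cancer`` exist for other cancer types
    and are zero in the breast-cancer configuration.
    """

    body_weight: float = 75.0              # kg
    initial_tumour_diameter: float = 30.0  # mm
    pdl1_fraction: float = 0.25            # fraction of cancer cells PD-L1+
    pdl2_fraction: float = 0.2             # fraction of cancer cells PD-L2+
    antigen_intensity: float = 0.7         # normalized TCR-antigen strength, 0..1
    tumour_doubling_time: float = 100.0    # day
    cancer_cell_diameter: float = 20.0     # um
    n_tdln: int = 10                       # lumped tumour-draining lymph nodes
    cd80_cancer: float = 0.0               # receptors/cell, 0 for breast cancer
    pd1_cancer: float = 0.0                # receptors/cell, 0 for breast cancer

    def __post_init__(self) -> None:
        for name in ("pdl1_fraction", "pdl2_fraction", "antigen_intensity"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        for name in ("body_weight", "initial_tumour_diameter",
                     "tumour_doubling_time", "cancer_cell_diameter"):
            v = getattr(self, name)
            if not v > 0:
                raise ValueError(f"{name} must be strictly positive, got {v}")
        if self.n_tdln < 1:
            raise ValueError("n_tdln must be at least 1")
        if self.cd80_cancer < 0 or self.pd1_cancer < 0:
            raise ValueError("receptor densities must be non-negative")

    def replace(self, **kwargs) -> "PatientParameters":
        data = {f.name: getattr(self, f.name) for f in dc_fields(self)}
        data.update(kwargs)
        return PatientParameters(**data)

    def to_dict(self) -> Dict[str, float]:
        return {f.name: getattr(self, f.name) for f in dc_fields(self)}

    @classmethod
    def from_dict(cls, data: Mapping[str, float]) -> "PatientParameters":
        known = {f.name for f in dc_fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise KeyError(f"unknown patient field(s): {sorted(unknown)}")
        return cls(**dict(data))


# ---------------------------------------------------------------------------
# Parameter registry
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Parameter:
    name: str
    value: float
    unit: str
    bounds: Tuple[float, float]   # plausible range (sampling/documentation)
    doc: str


def _p(name, value, unit, lo, hi, doc):
    if not lo <= value <= hi:
        raise ValueError(f"default of {name} ({value}) outside [{lo}, {hi}]")
    return Parameter(name, float(value), unit, (float(lo), float(hi)), doc)


#: Literature-informed defaults for the reduced model. Each entry carries a
#: unit, an allowed range and a one-line description; all are overridable.
_DEFAULT_PARAMETERS: Tuple[Parameter, ...] = (
    # -- compartment geometry / physiology -------------------------------
    _p("v_blood", 5.0, "L", 2, 8, "total blood volume"),
    _p("v_peripheral", 60.0, "L", 20, 80, "total peripheral tissue volume"),
    _p("v_tdln", 3e-4, "L", 1e-5, 2e-3, "volume of one tumour-draining lymph node"),
    _p("k_b", 0.8, "-", 0.01, 1, "available volume fraction, blood"),
    _p("k_p", 0.06, "-", 0.005, 1, "available volume fraction, peripheral"),
    _p("k_t", 0.3, "-", 0.01, 1, "available volume fraction, tumour"),
    _p("k_ln", 0.3, "-", 0.01, 1, "available volume fraction, TDLN"),
    _p("sa_bp", 0.4, "1/dm", 0.01, 10, "surface-area/volume ratio, blood-peripheral and blood-TDLN"),
    _p("sa_bt", 2.0, "1/dm", 0.01, 20, "surface-area/volume ratio, blood-tumour"),
    _p("k_perm_bp", 0.05, "dm/day", 1e-4, 1, "antibody permeability blood-peripheral"),
    _p("k_perm_bt", 0.05, "dm/day", 1e-4, 1, "antibody permeability blood-tumour"),
    _p("k_perm_bln", 0.05, "dm/day", 1e-4, 1, "antibody permeability blood-TDLN"),
    _p("k_lt", 0.02, "1/day", 1e-4, 1, "lymph flow rate constant (fraction of tumour volume per day)"),
    _p("packing_fraction", 0.74, "-", 0.1, 1, "tumour cell volume packing fraction (close sphere packing)"),
    _p("tumour_cap", 1e13, "cells", 1e10, 1e15, "logistic carrying capacity of the tumour"),
    # -- antibody PK -----------------------------------------------------
    _p("mw_antictla4", 149e3, "g/mol", 1e5, 2e5, "molar mass, anti-CTLA-4 IgG (tremelimumab)"),
    _p("mw_antipdl1", 148e3, "g/mol", 1e5, 2e5, "molar mass, anti-PD-L1 IgG (durvalumab)"),
    _p("cl_antictla4", 0.278, "L/day", 0.05, 1, "clearance, anti-CTLA-4 (published popPK)"),
    _p("cl_antipdl1", 0.232, "L/day", 0.05, 1, "clearance, anti-PD-L1 (published popPK)"),
    _p("kon_antictla4", 1.0e9, "1/(M*day)", 1e6, 1e12, "association rate, anti-CTLA-4 with CTLA-4"),
    _p("koff_antictla4", 5.6, "1/day", 1e-3, 1e3, "dissociation rate, anti-CTLA-4 with CTLA-4"),
    _p("kon_antipdl1", 2.5e9, "1/(M*day)", 1e6, 1e12, "association rate, anti-PD-L1 with PD-L1"),
    _p("koff_antipdl1", 0.055, "1/day", 1e-4, 1e3, "dissociation rate, anti-PD-L1 with PD-L1"),
    _p("infusion_duration", 0.0, "day", 0, 1, "IV infusion duration (0 = bolus)"),
    # -- receptor densities (molecules/cell) -----------------------------
    _p("pd1_per_teff", 3e3, "1/cell", 1e2, 1e5, "PD-1 on effector T cells"),
    _p("pdl1_per_cancer", 5e4, "1/cell", 1e3, 1e6, "PD-L1 on PD-L1+ cancer cells"),
    _p("pdl2_per_cancer", 1e4, "1/cell", 1e2, 1e6, "PD-L2 on PD-L2+ cancer cells"),
    _p("pdl1_per_apc", 1.6e4, "1/cell", 1e2, 1e6, "PD-L1 on tumour APCs"),
    _p("pdl1_per_supp", 3e4, "1/cell", 1e2, 1e6, "PD-L1 on Tregs/MDSCs in tumour"),
    _p("pdl1_per_mapc_ln", 1.6e4, "1/cell", 1e2, 1e6, "PD-L1 on mature APCs in TDLN"),
    _p("ctla4_per_treg", 5e3, "1/cell", 1e2, 1e5, "surface CTLA-4 on Tregs"),
    _p("ctla4_per_pnt", 3e3, "1/cell", 1e2, 1e5, "CTLA-4 on primed/proliferating T cells in TDLN"),
    _p("cd8086_per_mapc", 3e4, "1/cell", 1e2, 1e6, "CD80/86 on mature APCs"),
    _p("kd_syn_pd1_pdl1", 1e3, "1/cell", 1, 1e6, "synaptic PD-1:PD-L1 dissociation constant (per-cell units)"),
    _p("kd_syn_pd1_pdl2", 2e3, "1/cell", 1, 1e6, "synaptic PD-1:PD-L2 dissociation constant"),
    _p("kd_syn_ctla4_cd80", 6e2, "1/cell", 1, 1e6, "synaptic CTLA-4:CD80/86 dissociation constant"),
    _p("kd_cd80_sctla4", 2e-10, "M", 1e-12, 1e-6, "CD80/86 : soluble CTLA-4 dissociation constant"),
    # -- soluble CTLA-4 --------------------------------------------------
    _p("k_sctla4_sec", 1e2, "1/cell/day", 0, 1e5, "soluble CTLA-4 secretion per Treg"),
    _p("k_sctla4_deg", 1.0, "1/day", 1e-2, 1e2, "soluble CTLA-4 degradation"),
    # -- inhibition (Hill limiting factors) ------------------------------
    _p("emax_pd1_kill", 0.95, "-", 0, 1, "max inhibition of killing by PD-1:PD-L1 engagement"),
    _p("emax_pdl2_kill", 0.90, "-", 0, 1, "max inhibition of killing by PD-1:PD-L2 engagement"),
    _p("emax_baseline_kill", 0.95, "-", 0, 1, "baseline non-PD-1/PD-L1 suppression by checkpoint-negative cancer cells"),
    _p("emax_supp_kill", 0.6, "-", 0, 1, "max inhibition of killing by Treg/MDSC checkpoints"),
    _p("emax_pd1_prime", 0.8, "-", 0, 1, "max inhibition of priming by PD-L1 on TDLN mAPCs"),
    _p("emax_ctla4_prime", 0.85, "-", 0, 1, "max inhibition of priming by CTLA-4:CD80/86 engagement"),
    _p("emax_treg_prime", 0.5, "-", 0, 1, "max inhibition of priming by TDLN Tregs"),
    _p("emax_sctla4_mat", 0.6, "-", 0, 1, "max inhibition of APC maturation by soluble CTLA-4"),
    _p("ro50_pd1", 0.3, "-", 1e-3, 1, "half-maximal PD-1 receptor occupancy"),
    _p("hill_pd1", 2.0, "-", 1, 4, "Hill exponent, PD-1 inhibition"),
    _p("ro50_ctla4", 0.3, "-", 1e-3, 1, "half-maximal CTLA-4 receptor occupancy"),
    _p("hill_ctla4", 2.0, "-", 1, 4, "Hill exponent, CTLA-4 inhibition"),
    _p("ro50_sctla4", 0.3, "-", 1e-3, 1, "half-maximal CD80/86 occupancy by soluble CTLA-4"),
    _p("hill_sctla4", 1.0, "-", 1, 4, "Hill exponent, soluble CTLA-4 inhibition"),
    _p("k_supp_half", 5e8, "cells", 1e4, 1e12, "suppressor abundance giving half-maximal contact"),
    _p("k_treg_ln_half", 1e5, "cells", 1e2, 1e10, "TDLN Treg abundance giving half-maximal contact"),
    # -- T-cell priming chain (TDLN) -------------------------------------
    _p("s_naive", 1e4, "cells/day", 1, 1e8, "influx of tumour-specific naive T cells into TDLN"),
    _p("d_naive", 0.05, "1/day", 1e-4, 1, "naive T-cell turnover"),
    _p("k_prime1", 0.5, "1/day", 1e-3, 1e2, "contact rate, naive -> primed naive"),
    _p("k_prime2", 3.0, "1/day", 1e-3, 1e2, "contact rate, primed -> proliferating"),
    _p("k_prime3", 2.0, "1/day", 1e-3, 1e2, "contact rate, proliferating -> effector"),
    _p("expansion_fold", 1600.0, "-", 1, 1e4, "clonal burst size per proliferating T cell reaching effector stage"),
    _p("d_pnt", 0.05, "1/day", 1e-4, 1, "death rate, primed naive T cells"),
    _p("d_prol", 0.1, "1/day", 1e-4, 1, "death rate, proliferating T cells"),
    _p("d_teff_ln", 0.1, "1/day", 1e-4, 1, "death rate, TDLN effector T cells"),
    _p("k_exit_ln", 1.0, "1/day", 1e-3, 1e2, "effector T-cell egress TDLN -> blood"),
    _p("k_mapc_half_prime", 2e4, "cells", 1, 1e9, "mAPC abundance giving half-maximal priming"),
    # -- effector T-cell fate --------------------------------------------
    _p("d_teff_blood", 0.3, "1/day", 1e-3, 3, "death rate, blood effector T cells"),
    _p("d_teff_peri", 0.1, "1/day", 1e-3, 3, "death rate, peripheral effector T cells"),
    _p("k_apo_teff", 0.2, "1/day", 0.02, 2, "apoptosis rate of tumour-infiltrating effector T cells"),
    _p("k_exhaust", 0.1, "1/day", 0, 2, "PD-1-occupancy-driven exhaustion rate of tumour effector T cells"),
    _p("d_texh", 0.05, "1/day", 1e-4, 1, "death rate, exhausted T cells"),
    # -- APCs and antigen ------------------------------------------------
    _p("s_apc_tum", 5e4, "cells/day", 1, 1e8, "recruitment of immature APCs into the tumour"),
    _p("d_apc_tum", 0.1, "1/day", 1e-3, 3, "death rate, immature tumour APCs"),
    _p("k_mat", 2.0, "1/day", 1e-3, 1e2, "antigen-driven APC maturation rate, tumour"),
    _p("d_mapc_tum", 0.2, "1/day", 1e-3, 3, "death rate, mature APCs in tumour"),
    _p("k_mig_mapc", 1.0, "1/day", 1e-3, 1e2, "mature APC migration tumour -> TDLN"),
    _p("d_mapc_ln", 0.3, "1/day", 1e-3, 3, "death rate, mature APCs in TDLN"),
    _p("apc_ln_resident", 1e5, "cells", 1, 1e9, "resident immature APC pool in TDLN (constant)"),
    _p("k_mat_ln", 1.0, "1/day", 1e-3, 1e2, "antigen-driven APC maturation rate, TDLN"),
    _p("k_ag_half_tum", 1e9, "antigen", 1, 1e14, "antigen level giving half-maximal APC maturation, tumour"),
    _p("k_ag_half_ln", 1e8, "antigen", 1, 1e14, "antigen level giving half-maximal APC maturation, TDLN"),
    _p("k_ag_shed", 0.01, "antigen/cell/day", 0, 10, "baseline neoantigen shedding per cancer cell"),
    _p("k_ag_rel", 1.0, "antigen/cell", 0, 1e3, "neoantigen released per killed cancer cell"),
    _p("k_ag_deg", 2.0, "1/day", 1e-2, 1e2, "neoantigen degradation/consumption, tumour"),
    _p("k_ag_transport", 0.5, "1/day", 0, 1e2, "neoantigen lymphatic transport tumour -> TDLN"),
    _p("k_ag_deg_ln", 2.0, "1/day", 1e-2, 1e2, "neoantigen degradation/consumption, TDLN"),
    # -- suppressors -----------------------------------------------------
    _p("rho_mdsc", 0.02, "-", 1e-4, 0.5, "MDSCs per cancer cell in the tumour"),
    _p("phi_treg_ln", 0.3, "-", 0, 2, "Tregs per T lymphocyte in TDLN"),
    _p("treg_tum_max", 1e9, "cells", 1e3, 1e12, "saturating Treg level in the tumour"),
    _p("k_mdsc_treg_half", 5e7, "cells", 1e2, 1e12, "MDSC level giving half-maximal tumour Treg recruitment"),
    # -- tumour growth and killing ---------------------------------------
    _p("k_kill", 40.0, "1/day", 0.1, 100, "maximal cancer cells killed per effector T cell per day"),
    _p("k_kill_half", 1e7, "cells", 1e3, 1e12, "cancer-cell abundance giving half-maximal per-T-cell killing"),
    # -- effector T-cell vascular trafficking ----------------------------
    _p("f_vasc_tum", 0.02, "-", 1e-3, 0.2, "tumour vascular volume fraction"),
    _p("perfusion_tum", 30.0, "1/day", 0.1, 1e4, "tumour blood flow per unit tumour volume"),
    _p("b_sites_tum", 1e10, "sites/L", 1e6, 1e14, "adhesion site density, tumour vasculature"),
    _p("k_f_tum", 2e-9, "L/site/day", 1e-14, 1e-4, "T-cell attachment rate constant, tumour"),
    _p("k_r_tum", 1.0, "1/day", 1e-3, 1e3, "T-cell detachment rate, tumour"),
    _p("ar_tum", 1.0, "1/day", 1e-3, 1e3, "T-cell arrest (firm adhesion) rate, tumour"),
    _p("j_tum", 10.0, "1/day", 1e-3, 1e3, "T-cell transmigration rate, tumour"),
    _p("frac_lymph_tum", 0.1, "-", 0, 0.9, "lymph outflow as fraction of tumour blood flow"),
    _p("turnover_vasc", 0.1, "1/day", 1e-4, 3, "death rate of vascular-adherent T cells"),
    _p("vv_peri", 1.5, "L", 0.1, 5, "peripheral vascular space volume"),
    _p("q_peri", 100.0, "L/day", 1, 5e3, "peripheral blood flow"),
    _p("b_sites_peri", 1e8, "sites/L", 1e4, 1e14, "adhesion site density, peripheral vasculature"),
    _p("k_f_peri", 1e-9, "L/site/day", 1e-14, 1e-4, "T-cell attachment rate constant, peripheral"),
    _p("k_r_peri", 1.0, "1/day", 1e-3, 1e3, "T-cell detachment rate, peripheral"),
    _p("ar_peri", 0.1, "1/day", 1e-3, 1e3, "T-cell arrest rate, peripheral"),
    _p("j_peri", 0.5, "1/day", 1e-3, 1e3, "T-cell transmigration rate, peripheral"),
    _p("frac_lymph_peri", 0.0, "-", 0, 0.9, "lymph outflow as fraction of peripheral blood flow"),
)


class ParameterSet:
    """Registry of named model parameters.

    Lookup is total: an unknown name raises ``KeyError`` both on read and on
    override, so silent typos cannot detune the model. Values round-trip
    losslessly through :meth:`to_dict` / :meth:`from_dict`.
    """

    def __init__(self, overrides: Mapping[str, float] | None = None) -> None:
        self._params: Dict[str, Parameter] = {p.name: p for p in _DEFAULT_PARAMETERS}
        if overrides:
            self.update(overrides)

    def __getitem__(self, name: str) -> float:
        try:
            return self._params[name].value
        except KeyError:
            raise KeyError(f"unknown parameter {name!r}") from None

    def __contains__(self, name: str) -> bool:
        return name in self._params

    def __iter__(self) -> Iterator[str]:
        return iter(self._params)

    def __len__(self) -> int:
        return len(self._params)

    def __eq__(self, other) -> bool:
        if not isinstance(other, ParameterSet):
            return NotImplemented
        return self.to_dict() == other.to_dict()

    def meta(self, name: str) -> Parameter:
        """Full record (value, unit, bounds, doc) for one parameter."""
        try:
            return self._params[name]
        except KeyError:
            raise KeyError(f"unknown parameter {name!r}") from None

    def bounds(self, name: str) -> Tuple[float, float]:
        return self.meta(name).bounds

    def update(self, overrides: Mapping[str, float]) -> "ParameterSet":
        import warnings

        for name, value in overrides.items():
            old = self.meta(name)  # raises on unknown name
            lo, hi = old.bounds
            if not lo <= float(value) <= hi:
                warnings.warn(
                    f"{name} = {value} lies outside its documented range "
                    f"[{lo}, {hi}]", stacklevel=2)
            self._params[name] = Parameter(name, float(value), old.unit,
                                           old.bounds, old.doc)
        return self

    def replace(self, **overrides: float) -> "ParameterSet":
        new = ParameterSet()
        new._params = dict(self._params)
        new.update(overrides)
        return new

    def to_dict(self) -> Dict[str, float]:
        return {name: p.value for name, p in self._params.items()}

    def to_records(self) -> list[dict]:
        """Full table (for config files / documentation)."""
        return [
            {"name": p.name, "value": p.value, "unit": p.unit,
             "min": p.bounds[0], "max": p.bounds[1], "doc": p.doc}
            for p in self._params.values()
        ]

    @classmethod
    def from_dict(cls, values: Mapping[str, float]) -> "ParameterSet":
        return cls(overrides=values)


# ---------------------------------------------------------------------------
# Geometry and unit conversions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CompartmentGeometry:
    """Volumes, flows and exchange terms, fixed over a simulation.

    The tumour volume used for antibody PK and T-cell transport is constant
    (set from the starting diameter), even though the cell count evolves.
    """

    V_blood: float        # L
    V_peripheral: float   # L
    V_tumour_pk: float    # L, constant for PK/transport
    V_tdln: float         # L per node
    n_tdln: int
    Vv: float             # tumour vascular space volume, L
    Q: float              # tumour blood flow, L/day
    SA_BP: float          # 1/dm
    SA_BT: float          # 1/dm
    K_B: float
    K_P: float
    K_T: float
    K_LN: float
    k_Lt: float           # 1/day

    def __post_init__(self) -> None:
        for name in ("V_blood", "V_peripheral", "V_tumour_pk", "V_tdln",
                     "Vv", "Q", "SA_BP", "SA_BT", "k_Lt"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        for name in ("K_B", "K_P", "K_T", "K_LN"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must lie in (0, 1], got {v}")


def tumour_volume_l(diameter_mm: float) -> float:
    """Volume (L) of a spherical tumour of the given diameter (mm)."""
    d_dm = diameter_mm / 100.0  # mm -> dm; 1 L = 1 dm^3
    return math.pi / 6.0 * d_dm ** 3


def geometry_from(patient: PatientParameters, params: ParameterSet) -> CompartmentGeometry:
    """Build the compartment geometry for one patient."""
    v_t = tumour_volume_l(patient.initial_tumour_diameter)
    return CompartmentGeometry(
        V_blood=params["v_blood"],
        V_peripheral=params["v_peripheral"],
        V_tumour_pk=v_t,
        V_tdln=params["v_tdln"],
        n_tdln=patient.n_tdln,
        Vv=params["f_vasc_tum"] * v_t,
        Q=params["perfusion_tum"] * v_t,
        SA_BP=params["sa_bp"],
        SA_BT=params["sa_bt"],
        K_B=params["k_b"],
        K_P=params["k_p"],
        K_T=params["k_t"],
        K_LN=params["k_ln"],
        k_Lt=params["k_lt"],
    )


def split_cancer_subtypes(n_cells: float, pdl1_fraction: float,
                          pdl2_fraction: float) -> Tuple[float, float, float, float]:
    """Partition cancer cells into four checkpoint-expression subtypes.

    PD-L1 and PD-L2 expression are treated as independent probabilities, so
    the expected counts are products of the marginal fractions. Returns
    ``(PDL1-/PDL2-, PDL1+/PDL2-, PDL1-/PDL2+, PDL1+/PDL2+)``; the four
    values sum exactly to ``n_cells``.
    """
    if n_cells < 0:
        raise ValueError("n_cells must be non-negative")
    for name, f in (("pdl1_fraction", pdl1_fraction), ("pdl2_fraction", pdl2_fraction)):
        if not 0.0 <= f <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1], got {f}")
    p1, p2 = pdl1_fraction, pdl2_fraction
    return (
        n_cells * (1 - p1) * (1 - p2),
        n_cells * p1 * (1 - p2),
        n_cells * (1 - p1) * p2,
        n_cells * p1 * p2,
    )


def diameter_from_cell_count(n_cells: float, cell_diameter_um: float = 20.0,
                             packing_fraction: float = 0.74) -> float:
    """Tumour diameter (mm) of a sphere holding ``n_cells`` cells.

    The tumour volume is ``n_cells * v_cell / packing_fraction`` with
    spherical cells of the given diameter; the sphere factors cancel, so
    ``d_mm = (n / f)^(1/3) * d_cell_um / 1000``.
    """
    if n_cells < 0:
        raise ValueError("n_cells must be non-negative")
    if cell_diameter_um <= 0:
        raise ValueError("cell diameter must be positive")
    if not 0 < packing_fraction <= 1:
        raise ValueError("packing_fraction must lie in (0, 1]")
    return (n_cells / packing_fraction) ** (1.0 / 3.0) * cell_diameter_um / 1000.0


def cell_count_from_diameter(diameter_mm: float, cell_diameter_um: float = 20.0,
                             packing_fraction: float = 0.74) -> float:
    """Exact inverse of :func:`diameter_from_cell_count`."""
    if diameter_mm < 0:
        raise ValueError("diameter must be non-negative")
    if cell_diameter_um <= 0:
        raise ValueError("cell diameter must be positive")
    if not 0 < packing_fraction <= 1:
        raise ValueError("packing_fraction must lie in (0, 1]")
    return packing_fraction * (diameter_mm * 1000.0 / cell_diameter_um) ** 3


# ---------------------------------------------------------------------------
# State vector
# ---------------------------------------------------------------------------

#: Fixed, documented ordering of the named state vector. Trajectories are
#: column-stable across runs and versions of the same minor release.
STATE_NAMES: Tuple[str, ...] = (
    # cancer-cell subtypes (tumour, counts)
    "cancer_nn",        # PD-L1- / PD-L2-
    "cancer_l1",        # PD-L1+ / PD-L2-
    "cancer_l2",        # PD-L1- / PD-L2+
    "cancer_dp",        # PD-L1+ / PD-L2+
    # neoantigen pools (arbitrary antigen units)
    "antigen_tum",
    "antigen_ln",
    # antigen-presenting cells (counts)
    "apc_tum",          # immature APCs, tumour
    "mapc_tum",         # mature APCs, tumour
    "mapc_ln",          # mature APCs, TDLN
    # T-cell priming chain in TDLN (counts)
    "naive_ln",
    "primed_ln",
    "prolif_ln",
    "teff_ln",
    # circulating / peripheral effector T cells (counts)
    "teff_blood",
    "tp_free", "tp_bound", "tp_arr",   # peripheral vascular three-step pools
    "teff_peri",
    # tumour vascular three-step pools and interstitial effectors (counts)
    "tt_free", "tt_bound", "tt_arr",
    "teff_tum",
    "texh_tum",         # permanently exhausted effectors, tumour
    # antibody concentrations (mol/L) per compartment
    "antictla4_b", "antictla4_p", "antictla4_t", "antictla4_ln",
    "antipdl1_b", "antipdl1_p", "antipdl1_t", "antipdl1_ln",
    # antibody-bound receptors, molecules per cell
    "ab_pdl1_cancer",     # anti-PD-L1 : PD-L1 on PD-L1+ cancer cells (tumour)
    "ab_pdl1_apc",        # anti-PD-L1 : PD-L1 on tumour APCs
    "ab_pdl1_supp",       # anti-PD-L1 : PD-L1 on tumour Tregs/MDSCs
    "ab_pdl1_mapc_ln",    # anti-PD-L1 : PD-L1 on TDLN mAPCs
    "ab_ctla4_treg_t",    # anti-CTLA-4 : CTLA-4 on tumour Tregs
    "ab_ctla4_pnt",       # anti-CTLA-4 : CTLA-4 on primed/proliferating T cells (TDLN)
    "ab_ctla4_treg_ln",   # anti-CTLA-4 : CTLA-4 on TDLN Tregs
    # soluble CTLA-4 and its antibody complex (mol/L)
    "sctla4_tum", "sctla4_ln",
    "ab_sctla4_tum", "ab_sctla4_ln",
)

STATE_INDEX: Dict[str, int] = {name: i for i, name in enumerate(STATE_NAMES)}

N_STATES = len(STATE_NAMES)


@dataclass
class ModelState:
    """Named wrapper over the flat state vector."""

    vector: np.ndarray = field(default_factory=lambda: np.zeros(N_STATES))

    def __post_init__(self) -> None:
        self.vector = np.asarray(self.vector, dtype=float)
        if self.vector.shape != (N_STATES,):
            raise ValueError(
                f"state vector must have length {N_STATES}, got {self.vector.shape}")

    def __getitem__(self, name: str) -> float:
        return float(self.vector[STATE_INDEX[name]])

    def __setitem__(self, name: str, value: float) -> None:
        self.vector[STATE_INDEX[name]] = value

    def to_dict(self) -> Dict[str, float]:
        return {name: float(self.vector[i]) for name, i in STATE_INDEX.items()}

    def copy(self) -> "ModelState":
        return ModelState(self.vector.copy())

    @property
    def cancer_total(self) -> float:
        return float(self.vector[0] + self.vector[1] + self.vector[2] + self.vector[3])

    @property
    def teff_total(self) -> float:
        """Total effector T cells in the system (TDLN + blood + vascular +
        peripheral + tumour pools, excluding the exhausted sink)."""
        idx = [STATE_INDEX[n] for n in
               ("teff_ln", "teff_blood", "tp_free", "tp_bound", "tp_arr",
                "teff_peri", "tt_free", "tt_bound", "tt_arr", "teff_tum")]
        return float(self.vector[idx].sum())


def assemble_state(patient: PatientParameters,
                   params: ParameterSet | None = None) -> ModelState:
    """Initial named state vector for a drug-naive patient.

    Cancer subtype counts follow :func:`split_cancer_subtypes` applied to the
    cell count matching the starting diameter; immune pools start at modest
    seed values (the pre-treatment steady state is found by integration);
    antibody concentrations are zero.
    """
    if params is None:
        params = ParameterSet()
    if patient.initial_tumour_diameter <= 0:
        raise ValueError("initial_tumour_diameter must be positive")

    n_cells = cell_count_from_diameter(
        patient.initial_tumour_diameter,
        patient.cancer_cell_diameter,
        params["packing_fraction"],
    )
    c_nn, c_l1, c_l2, c_dp = split_cancer_subtypes(
        n_cells, patient.pdl1_fraction, patient.pdl2_fraction)

    s = ModelState()
    s["cancer_nn"] = c_nn
    s["cancer_l1"] = c_l1
    s["cancer_l2"] = c_l2
    s["cancer_dp"] = c_dp
    # Seed the immune system near its drug-free fixed point scale; the
    # steady-state finder refines these by integration.
    s["naive_ln"] = params["s_naive"] / params["d_naive"]
    s["apc_tum"] = params["s_apc_tum"] / params["d_apc_tum"]
    s["mapc_tum"] = 1.0
    s["mapc_ln"] = 1.0
    s["teff_ln"] = 1.0
    s["teff_blood"] = 1.0
    return s
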