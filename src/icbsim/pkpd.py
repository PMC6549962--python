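"""Four-compartment antibody pharmacokinetics and dosing regimens.

Each monoclonal antibody distributes between central blood, peripheral
tissue, tumour and the (lumped, per-node) tumour-draining lymph node.
Exchange across vascular walls is permeability-surface-area limited with
available-volume-fraction partitioning; lymph flow carries drug
tumour -> TDLN -> blood; elimination is linear clearance from the central
compartment. In the tumour and TDLN the antibody additionally binds its
checkpoint targets by mass action (the binding sinks are supplied by the
caller so this module stays independent of the immune state).

Doses are IV boluses into the central compartment by default (the limiting
case of a short infusion); mg/kg doses resolve against body weight.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, NamedTuple, Sequence, Tuple

from .model_core import CompartmentGeometry

__all__ = [
    "AntibodyPKParameters",
    "AntibodyConcentrations",
    "DoseEvent",
    "Regimen",
    "mg_to_molar",
    "pk_rhs",
    "resolve_regimen",
    "anti_pdl1_dose_regimen",
    "REGIMEN_TEMPLATES",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AntibodyPKParameters:
    """PK/PD constants for one antibody."""

    MW: float                 # g/mol
    Cl: float                 # L/day
    k_perm_BP: float          # dm/day
    k_perm_BT: float          # dm/day
    k_perm_BLN: float         # dm/day
    kon: float                # 1/(M*day)
    koff: float               # 1/day
    target_list: Tuple[str, ...]   # checkpoint pools this antibody binds

    def __post_init__(self) -> None:
        if not self.MW > 0:
            raise ValueError("MW must be positive")
        # zero clearance / permeability / binding are admissible limiting
        # cases (used by conservation and closed-form checks)
        for name in ("Cl", "k_perm_BP", "k_perm_BT", "k_perm_BLN",
                     "kon", "koff"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not self.target_list:
            raise ValueError("target_list must be non-empty")


@dataclass
class AntibodyConcentrations:
    """Molar concentration of one drug per compartment."""

    C_B: float = 0.0
    C_P: float = 0.0
    C_T: float = 0.0
    C_LN: float = 0.0

    def __post_init__(self) -> None:
        for name in ("C_B", "C_P", "C_T", "C_LN"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


class PKDerivs(NamedTuple):
    dC_B: float
    dC_P: float
    dC_T: float
    dC_LN: float


def mg_to_molar(dose_mg: float, mw: float, volume_l: float) -> float:
    """Concentration increment (mol/L) of a bolus ``dose_mg`` into ``volume_l``."""
    if mw <= 0:
        raise ValueError("molar mass must be positive")
    if volume_l <= 0:
        raise ValueError("volume must be positive")
    if dose_mg < 0:
        raise ValueError("dose must be non-negative")
    return dose_mg * 1e-3 / mw / volume_l


def pk_rhs(conc: AntibodyConcentrations, geometry: CompartmentGeometry,
           pk: AntibodyPKParameters,
           binding_sink_t: float = 0.0, binding_sink_ln: float = 0.0,
           dose_rate: float = 0.0) -> PKDerivs:
    """Compartmental derivatives (mol/L/day) for one antibody.

    Exchange fluxes use the mass-conservative form
    ``J = k_perm * SA * V_dst * (C_src/K_src - C_dst/K_dst)`` (amount/day);
    lymph flow ``k_Lt * V_T`` carries drug tumour -> TDLN and TDLN -> blood.
    ``binding_sink_*`` are net mass-action losses (mol/L/day, positive =
    consumption) to checkpoint targets in tumour and TDLN; ``dose_rate`` is
    an infusion rate in mol/day into the central compartment.
    """
    for name, v in (("C_B", conc.C_B), ("C_P", conc.C_P),
                    ("C_T", conc.C_T), ("C_LN", conc.C_LN)):
        if v < 0:
            raise ValueError(f"{name} must be non-negative")
    g = geometry
    v_ln_total = g.V_tdln * g.n_tdln

    flux_bp = pk.k_perm_BP * g.SA_BP * g.V_peripheral * (conc.C_B / g.K_B - conc.C_P / g.K_P)
    flux_bt = pk.k_perm_BT * g.SA_BT * g.V_tumour_pk * (conc.C_B / g.K_B - conc.C_T / g.K_T)
    flux_bln = pk.k_perm_BLN * g.SA_BP * v_ln_total * (conc.C_B / g.K_B - conc.C_LN / g.K_LN)
    lymph = g.k_Lt * g.V_tumour_pk                      # L/day
    lymph_t_ln = lymph * conc.C_T / g.K_T               # amount/day, tumour -> TDLN
    lymph_ln_b = lymph * conc.C_LN / g.K_LN             # amount/day, TDLN -> blood

    dC_B = (dose_rate - pk.Cl * conc.C_B - flux_bp - flux_bt - flux_bln
            + lymph_ln_b) / g.V_blood
    dC_P = flux_bp / g.V_peripheral
    dC_T = (flux_bt - lymph_t_ln) / g.V_tumour_pk - binding_sink_t
    dC_LN = (flux_bln + lymph_t_ln - lymph_ln_b) / v_ln_total - binding_sink_ln
    return PKDerivs(dC_B, dC_P, dC_T, dC_LN)


# ---------------------------------------------------------------------------
# Dosing regimens
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DoseEvent:
    drug: str
    time: float       # day
    amount_mg: float  # absolute mg (already weight-resolved)
    route: str = "IV"

    def __post_init__(self) -> None:
        if self.amount_mg <= 0:
            raise ValueError("dose amount must be positive")
        if self.time < 0:
            raise ValueError("dose time must be non-negative")


@dataclass
class Regimen:
    events: List[DoseEvent] = field(default_factory=list)
    horizon: float = 456.0   # day; 15 months after therapy begins

    def __post_init__(self) -> None:
        self.events = sorted(self.events, key=lambda e: (e.time, e.drug))
        merged: List[DoseEvent] = []
        for ev in self.events:
            if merged and merged[-1].drug == ev.drug and merged[-1].time == ev.time:
                warnings.warn(
                    f"duplicate {ev.drug} dose at day {ev.time}; summing amounts",
                    stacklevel=2)
                prev = merged.pop()
                ev = DoseEvent(ev.drug, ev.time, prev.amount_mg + ev.amount_mg,
                               ev.route)
            merged.append(ev)
        self.events = merged

    @property
    def dose_times(self) -> List[float]:
        return sorted({e.time for e in self.events})

    def events_at(self, time: float) -> List[DoseEvent]:
        return [e for e in self.events if e.time == time]

    def drugs(self) -> List[str]:
        return sorted({e.drug for e in self.events})


def _series(drug: str, amount_mg: float, start: float, interval: float,
            n: int | None, horizon: float) -> List[DoseEvent]:
    """Repeated doses from ``start`` every ``interval`` days, clipped at the
    horizon (inclusive); if ``n`` is None, repeat to the horizon."""
    events = []
    t = start
    i = 0
    while t <= horizon and (n is None or i < n):
        events.append(DoseEvent(drug, t, amount_mg))
        t += interval
        i += 1
    return events


#: Named regimen templates. ``mg_per_kg`` entries resolve against body
#: weight; the clinical trial arm uses fixed mg amounts.
REGIMEN_TEMPLATES: Dict[str, dict] = {
    # 75 mg anti-CTLA-4 + 1500 mg anti-PD-L1 monthly x4, then 750 mg
    # anti-PD-L1 every two weeks (the trial schedule).
    "trial_combo": {
        "doses": [
            {"drug": "antictla4", "mg": 75.0, "start": 0.0, "interval": 28.0, "n": 4},
            {"drug": "antipdl1", "mg": 1500.0, "start": 0.0, "interval": 28.0, "n": 4},
            {"drug": "antipdl1", "mg": 750.0, "start": 112.0, "interval": 14.0, "n": None},
        ],
    },
    # 20 mg/kg anti-PD-L1 monthly x4, then 10 mg/kg q2w.
    "anti_pdl1_mono": {
        "doses": [
            {"drug": "antipdl1", "mg_per_kg": 20.0, "start": 0.0, "interval": 28.0, "n": 4},
            {"drug": "antipdl1", "mg_per_kg": 10.0, "start": 112.0, "interval": 14.0, "n": None},
        ],
    },
    # 1 mg/kg anti-CTLA-4 monthly x4.
    "anti_ctla4_mono": {
        "doses": [
            {"drug": "antictla4", "mg_per_kg": 1.0, "start": 0.0, "interval": 28.0, "n": 4},
        ],
    },
    # Fixed 1 mg/kg anti-CTLA-4 with the 20/10 mg/kg anti-PD-L1 schedule.
    "combo": {
        "doses": [
            {"drug": "antictla4", "mg_per_kg": 1.0, "start": 0.0, "interval": 28.0, "n": 4},
            {"drug": "antipdl1", "mg_per_kg": 20.0, "start": 0.0, "interval": 28.0, "n": 4},
            {"drug": "antipdl1", "mg_per_kg": 10.0, "start": 112.0, "interval": 14.0, "n": None},
        ],
    },
}


#: Maintenance dose (mg/kg q2w) following four monthly anti-PD-L1 doses in
#: the dose-response design; induction doses of 1 mg/kg or less carry no
#: maintenance phase.
ANTI_PDL1_MAINTENANCE: Dict[float, float] = {3.0: 1.0, 10.0: 3.0,
                                             15.0: 5.0, 20.0: 10.0}


def anti_pdl1_dose_regimen(dose_mg_per_kg: float, body_weight: float = 75.0,
                           horizon: float = 456.0) -> Regimen:
    """Anti-PD-L1 dose-response schedule for one induction dose level.

    Four monthly doses at ``dose_mg_per_kg``; induction doses of 3, 10, 15
    and 20 mg/kg are followed by 1, 3, 5 and 10 mg/kg every two weeks up to
    the horizon. A dose of zero yields an empty regimen.
    """
    if dose_mg_per_kg < 0:
        raise ValueError("dose must be non-negative")
    if dose_mg_per_kg == 0:
        return Regimen(events=[], horizon=horizon)
    doses = [{"drug": "antipdl1", "mg_per_kg": dose_mg_per_kg,
              "start": 0.0, "interval": 28.0, "n": 4}]
    maint = ANTI_PDL1_MAINTENANCE.get(dose_mg_per_kg)
    if maint is not None:
        doses.append({"drug": "antipdl1", "mg_per_kg": maint,
                      "start": 112.0, "interval": 14.0, "n": None})
    return resolve_regimen({"doses": doses}, body_weight, horizon)


def resolve_regimen(spec: str | Mapping, body_weight: float = 75.0,
                    horizon: float = 456.0,
                    dose_scale: Mapping[str, float] | None = None) -> Regimen:
    """Resolve a regimen description to absolute-time, absolute-mg events.

    ``spec`` is a template name or a mapping with a ``doses`` list whose
    entries carry ``drug``, ``mg`` or ``mg_per_kg``, ``start``, ``interval``
    and ``n`` (``None`` = repeat to horizon). ``dose_scale`` multiplies the
    amounts of a drug (used for dose-response sweeps); a scale of zero drops
    that drug's events entirely.
    """
    if isinstance(spec, str):
        try:
            spec = REGIMEN_TEMPLATES[spec]
        except KeyError:
            raise KeyError(
                f"unknown regimen template {spec!r}; known: "
                f"{sorted(REGIMEN_TEMPLATES)}") from None
    if body_weight <= 0:
        raise ValueError("body_weight must be positive")
    scale = dict(dose_scale or {})
    events: List[DoseEvent] = []
    for entry in spec["doses"]:
        if "mg" in entry:
            amount = float(entry["mg"])
        elif "mg_per_kg" in entry:
            amount = float(entry["mg_per_kg"]) * body_weight
        else:
            raise KeyError("dose entry needs 'mg' or 'mg_per_kg'")
        amount *= scale.get(entry["drug"], 1.0)
        if amount == 0.0:
            continue
        events.extend(_series(entry["drug"], amount, float(entry["start"]),
                              float(entry["interval"]), entry.get("n"), horizon))
    return Regimen(events=events, horizon=horizon)
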