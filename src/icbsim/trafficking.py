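"""Three-step effector T-cell vascular transport.

Effector T cells leave the central blood pool with the blood flow into the
vascular space of a target tissue, where they reversibly attach to the
vessel wall, firmly arrest, and finally transmigrate into the
interstitium:

    dT_f/dt = -k_f (B - T_b/Vv - T_a/Vv) T_f + k_r T_b + (Q/Vv) T_B
              - ((Q - k_L)/Vv) T_f
    dT_b/dt = -turnover T_b + k_f (B - T_b/Vv - T_a/Vv) T_f - k_r T_b - AR T_b
    dT_a/dt = -J T_a - turnover T_a + AR T_b

with `T_B` the central-blood count, `T_f/T_b/T_a` free/captured/arrested
counts in the vascular space, `B` the (ad hoc) adhesion-site density,
`Vv` the vascular volume, `Q` the blood flow and `k_L` the lymph outflow
(which only reduces venous return — the printed scheme carries no explicit
lymphatic cell flux). The transmigration flux `J*T_a` feeds the tissue
interstitium. The same scheme is instantiated for the tumour and the
peripheral compartment with their own parameters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import NamedTuple

__all__ = ["TraffickingParameters", "VascularTcellState", "trafficking_rhs"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TraffickingParameters:
    k_f: float        # attachment rate constant, L/site/day
    k_r: float        # detachment rate, 1/day
    k_L: float        # lymphatic (outflow-reducing) flow, L/day
    AR: float         # arrest (firm adhesion) rate, 1/day
    J: float          # transmigration rate, 1/day
    B: float          # adhesion site density, sites/L
    Vv: float         # vascular space volume, L
    Q: float          # blood flow, L/day
    turnover: float   # vascular T-cell death rate, 1/day

    def __post_init__(self) -> None:
        for name in ("k_f", "k_r", "k_L", "AR", "J", "B", "turnover"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.Vv <= 0:
            raise ValueError("Vv must be positive")
        if not self.Q > self.k_L:
            raise ValueError("blood flow Q must exceed lymph flow k_L")


@dataclass
class VascularTcellState:
    T_B: float   # central blood count
    T_f: float   # free in vascular space
    T_b: float   # captured on vessel wall
    T_a: float   # arrested

    #: integrator undershoot below this magnitude is clamped to zero
    _NEG_TOL = 1e-6

    def __post_init__(self) -> None:
        for name in ("T_B", "T_f", "T_b", "T_a"):
            v = getattr(self, name)
            if v < 0:
                if v < -self._NEG_TOL:
                    raise ValueError(f"{name} must be non-negative, got {v}")
                setattr(self, name, 0.0)


class TraffickingDerivs(NamedTuple):
    dT_f: float
    dT_b: float
    dT_a: float
    transmigration: float   # J * T_a, flux into the interstitium
    blood_exchange: float   # net flux into the central pool (for dT_B/dt)


def trafficking_rhs(state: VascularTcellState,
                    params: TraffickingParameters) -> TraffickingDerivs:
    """Evaluate the three printed transport equations.

    If adhesion sites are over-saturated (numerical overshoot), the free
    capacity is clipped at zero and a warning is logged. ``blood_exchange``
    is the matching net term for the central pool so that, with
    ``turnover = J = k_L = 0``, total cells are conserved.
    """
    p = params
    free_sites = p.B - state.T_b / p.Vv - state.T_a / p.Vv
    if free_sites < 0:
        logger.warning("adhesion sites saturated (deficit %.3g sites/L); clipping",
                       -free_sites)
        free_sites = 0.0
    capture = p.k_f * free_sites * state.T_f
    inflow = (p.Q / p.Vv) * state.T_B
    outflow = ((p.Q - p.k_L) / p.Vv) * state.T_f

    dT_f = -capture + p.k_r * state.T_b + inflow - outflow
    dT_b = -p.turnover * state.T_b + capture - p.k_r * state.T_b - p.AR * state.T_b
    dT_a = -p.J * state.T_a - p.turnover * state.T_a + p.AR * state.T_b
    return TraffickingDerivs(dT_f, dT_b, dT_a,
                             transmigration=p.J * state.T_a,
                             blood_exchange=outflow - inflow)
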