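"""Immune-dynamics right-hand-side terms.

Tumour growth and T-cell killing, neoantigen release and transport, APC
maturation and migration, the three-stage T-cell priming chain in the
tumour-draining lymph node, Treg/MDSC suppressor levels, and the checkpoint
binding algebra (receptor occupancies, Hill-type limiting factors, and
mass-action antibody competition).

Cell-cell ligand-receptor engagement inside immunological synapses is
collapsed to effective rate laws: the engaged (bound) receptor fraction is
taken at the bimolecular equilibrium of the per-cell receptor and free
ligand densities, and feeds a limiting factor

    F(occ) = 1 - emax * occ^h / (occ^h + ro50^h)

which multiplies the affected rate. Antibody binding to its targets is
dynamic mass action and competes with the natural ligand by depleting the
free receptor pool.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple, Sequence, Tuple

__all__ = [
    "receptor_occupancy",
    "inhibition_factor",
    "equilibrium_occupancy",
    "BindingFluxes",
    "bind_checkpoints",
    "priming_transition",
    "suppressor_levels",
    "tumour_growth_and_kill",
    "apc_antigen_dynamics",
]


def receptor_occupancy(bound: float, total: float) -> float:
    """Fraction of a receptor pool that is ligand- or antibody-bound.

    By convention an empty pool (``total == 0``) has zero occupancy.
    """
    if bound < 0:
        raise ValueError("bound must be non-negative")
    if total == 0:
        return 0.0
    if bound > total * (1 + 1e-12):
        raise ValueError(f"bound ({bound}) exceeds total ({total})")
    return min(bound / total, 1.0)


def inhibition_factor(occupancy: float, emax: float, ro50: float = 0.3,
                      hill: float = 1.0) -> float:
    """Hill-type limiting factor in ``[1 - emax, 1]``.

    ``emax`` is the maximum inhibitory effect, ``ro50`` the half-maximal
    receptor occupancy, ``hill`` the steepness. Monotone non-increasing in
    occupancy; 1 when either occupancy or ``emax`` is zero.
    """
    if not 0.0 <= emax <= 1.0:
        raise ValueError(f"emax must lie in [0, 1], got {emax}")
    if ro50 <= 0:
        raise ValueError("ro50 must be positive")
    if occupancy <= 0.0:
        return 1.0
    on = occupancy ** hill
    return 1.0 - emax * on / (on + ro50 ** hill)


def equilibrium_occupancy(receptor_total: float, ligand_total: float,
                          kd: float) -> float:
    """Bound fraction of the receptor at bimolecular equilibrium.

    Solves ``L + R <=> C`` for the physical root of the quadratic
    ``C^2 - (R+L+Kd) C + R L = 0`` and returns ``C / R``. Used for synaptic
    engagement where per-cell densities play the role of concentrations.
    """
    if receptor_total <= 0 or ligand_total <= 0:
        return 0.0
    if kd < 0:
        raise ValueError("kd must be non-negative")
    b = receptor_total + ligand_total + kd
    disc = b * b - 4.0 * receptor_total * ligand_total
    c = 0.5 * (b - math.sqrt(max(disc, 0.0)))
    return min(c / receptor_total, 1.0)


class BindingFluxes(NamedTuple):
    """Mass-action fluxes for one receptor shared by a natural ligand and a
    competing antibody. Positive values form complexes."""

    lig_complex: float   # d[R:L]/dt from binding alone
    mab_complex: float   # d[R:mAb]/dt from binding alone

    @property
    def free_receptor(self) -> float:
        # Receptor conservation: free + both complexes is flux-neutral.
        return -(self.lig_complex + self.mab_complex)

    @property
    def free_ligand(self) -> float:
        return -self.lig_complex

    @property
    def free_mab(self) -> float:
        return -self.mab_complex


def bind_checkpoints(free_ligand: float, free_receptor: float,
                     lig_complex: float, kon: float, koff: float,
                     mab_conc: float = 0.0, mab_complex: float = 0.0,
                     kon_mab: float = 0.0, koff_mab: float = 0.0) -> BindingFluxes:
    """Mass-action binding fluxes for a ligand-receptor pair with an
    optional competing antibody on the same receptor pool.

    Returns the net complex-formation rates; the implied free-species fluxes
    (available as properties) conserve total receptor, ligand and antibody.
    """
    for name, v in (("free_ligand", free_ligand), ("free_receptor", free_receptor),
                    ("lig_complex", lig_complex), ("mab_conc", mab_conc),
                    ("mab_complex", mab_complex)):
        if v < 0:
            raise ValueError(f"{name} must be non-negative, got {v}")
    if kon < 0 or koff < 0 or kon_mab < 0 or koff_mab < 0:
        raise ValueError("rate constants must be non-negative")
    dlig = kon * free_ligand * free_receptor - koff * lig_complex
    dmab = kon_mab * mab_conc * free_receptor - koff_mab * mab_complex
    return BindingFluxes(dlig, dmab)


def priming_transition(stage_populations: Sequence[float], mapc_ln: float,
                       antigen_intensity: float,
                       pdl1_factor: float, ctla4_factor: float,
                       contact_rates: Sequence[float],
                       k_mapc_half: float,
                       treg_factor: float = 1.0) -> Tuple[float, ...]:
    """Per-stage transition rates of the three-stage TDLN priming chain.

    ``stage_populations`` are (naive, primed, proliferating) counts. Each
    transition rate is ``contact_rate * population * availability(mAPC) *
    antigen_intensity * F_PD-L1 * F_CTLA-4 * F_Treg`` with a saturating mAPC
    availability ``m/(m + K)``; zero mAPCs or zero antigen stop the chain.
    The limiting factors come from :func:`inhibition_factor`.
    """
    if mapc_ln < 0:
        raise ValueError("mapc_ln must be non-negative")
    if not 0.0 <= antigen_intensity <= 1.0:
        raise ValueError("antigen_intensity must lie in [0, 1]")
    if len(stage_populations) != len(contact_rates):
        raise ValueError("one contact rate per stage required")
    avail = mapc_ln / (mapc_ln + k_mapc_half) if mapc_ln > 0 else 0.0
    common = avail * antigen_intensity * pdl1_factor * ctla4_factor * treg_factor
    return tuple(k * max(pop, 0.0) * common
                 for k, pop in zip(contact_rates, stage_populations))


def suppressor_levels(cancer_count: float, t_lymphocytes_ln: float,
                      rho_mdsc: float, phi_treg_ln: float,
                      treg_tum_max: float, k_mdsc_half: float
                      ) -> Tuple[float, float, float]:
    """Algebraic suppressor-cell levels ``(MDSC_tumour, Treg_TDLN, Treg_tumour)``.

    MDSCs scale linearly with tumour burden; TDLN Tregs scale with the total
    T-lymphocyte count in the node; tumour Tregs are a saturating monotone
    function of the MDSC level.
    """
    if cancer_count < 0 or t_lymphocytes_ln < 0:
        raise ValueError("cell counts must be non-negative")
    mdsc = rho_mdsc * cancer_count
    treg_ln = phi_treg_ln * t_lymphocytes_ln
    treg_tum = treg_tum_max * mdsc / (mdsc + k_mdsc_half) if mdsc > 0 else 0.0
    return mdsc, treg_ln, treg_tum


@dataclass(frozen=True)
class GrowthKillResult:
    derivatives: Tuple[float, float, float, float]
    kill_fluxes: Tuple[float, float, float, float]

    @property
    def killed_cell_flux(self) -> float:
        return sum(self.kill_fluxes)


def tumour_growth_and_kill(cancer_subtypes: Sequence[float], teff_tumour: float,
                           inhibition_multipliers: Sequence[float],
                           growth_rate: float, kill_rate: float,
                           kill_half: float = 1e8,
                           carrying_capacity: float = 1e13) -> GrowthKillResult:
    """Per-subtype cancer-cell derivatives and the killed-cell flux.

    Growth is exponential at ``growth_rate = ln 2 / doubling_time`` with a
    logistic cap; killing distributes the effector cytotoxic capacity
    ``kill_rate * Teff`` over subtypes by abundance with saturation at low
    tumour burden, each subtype shielded by its own checkpoint limiting
    factor. An empty tumour is absorbing. The killed-cell flux feeds antigen
    release.
    """
    subtypes = [max(float(c), 0.0) for c in cancer_subtypes]
    if len(subtypes) != len(inhibition_multipliers):
        raise ValueError("one inhibition multiplier per subtype required")
    teff = max(float(teff_tumour), 0.0)
    total = sum(subtypes)
    growth = growth_rate * max(1.0 - total / carrying_capacity, 0.0)
    derivs, kills = [], []
    denom = total + kill_half
    for c, f in zip(subtypes, inhibition_multipliers):
        kill = kill_rate * teff * (c / denom) * f if total > 0 else 0.0
        kills.append(kill)
        derivs.append(growth * c - kill)
    return GrowthKillResult(tuple(derivs), tuple(kills))


class ApcAntigenDerivs(NamedTuple):
    d_antigen_tum: float
    d_antigen_ln: float
    d_apc_tum: float
    d_mapc_tum: float
    d_mapc_ln: float


def apc_antigen_dynamics(antigen_tum: float, antigen_ln: float,
                         apc_tum: float, mapc_tum: float, mapc_ln: float,
                         killed_cell_flux: float, cancer_total: float,
                         maturation_factor_tum: float,
                         maturation_factor_ln: float,
                         p) -> ApcAntigenDerivs:
    """Derivatives of the antigen pools and APC maturation/migration.

    Antigen is produced by baseline shedding (per cancer cell) plus release
    from killed cells, degrades first-order, and is transported to the TDLN
    by lymph. Maturation of tumour APCs is antigen-saturating and inhibited
    by soluble CTLA-4 through ``maturation_factor_tum`` (likewise in the
    node for the constant resident pool); mature APCs migrate to the TDLN at
    a first-order rate. ``p`` is the :class:`~icbsim.model_core.ParameterSet`.
    """
    ag_t = max(antigen_tum, 0.0)
    ag_l = max(antigen_ln, 0.0)
    apc = max(apc_tum, 0.0)
    mapc_t = max(mapc_tum, 0.0)
    mapc_l = max(mapc_ln, 0.0)

    d_ag_t = (p["k_ag_shed"] * max(cancer_total, 0.0)
              + p["k_ag_rel"] * max(killed_cell_flux, 0.0)
              - (p["k_ag_deg"] + p["k_ag_transport"]) * ag_t)
    d_ag_l = p["k_ag_transport"] * ag_t - p["k_ag_deg_ln"] * ag_l

    agsat_t = ag_t / (ag_t + p["k_ag_half_tum"]) if ag_t > 0 else 0.0
    agsat_l = ag_l / (ag_l + p["k_ag_half_ln"]) if ag_l > 0 else 0.0
    mat_t = p["k_mat"] * apc * agsat_t * maturation_factor_tum
    mat_l = p["k_mat_ln"] * p["apc_ln_resident"] * agsat_l * maturation_factor_ln

    d_apc = p["s_apc_tum"] - p["d_apc_tum"] * apc - mat_t
    d_mapc_t = mat_t - (p["k_mig_mapc"] + p["d_mapc_tum"]) * mapc_t
    d_mapc_l = p["k_mig_mapc"] * mapc_t + mat_l - p["d_mapc_ln"] * mapc_l
    return ApcAntigenDerivs(d_ag_t, d_ag_l, d_apc, d_mapc_t, d_mapc_l)
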