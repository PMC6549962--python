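"""Global sensitivity analysis: Latin hypercube sampling with partial rank
correlation coefficients (LHS/PRCC).

The output statistic is the percent tumour-size change at the 15-month
horizon; PRCC quantifies the monotone association between each sampled
parameter and that output with the other parameters' rank effects
regressed out. Suitable for monotone models; |PRCC| is bounded by 1 and the
sign matches the direction of the effect.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Callable, Dict, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.stats import rankdata, t as t_dist

__all__ = [
    "SensitivityResult",
    "lhs_sample",
    "prcc",
    "run_global_sensitivity",
    "DEFAULT_SENSITIVITY_RANGES",
]

logger = logging.getLogger(__name__)


@dataclass
class SensitivityResult:
    parameters: Tuple[str, ...]
    prcc: np.ndarray          # in [-1, 1] per parameter
    p_value: np.ndarray
    n_samples: int
    seed: int
    output_statistic: str = "percent_size_change_at_horizon"
    n_failed: int = 0

    def __post_init__(self) -> None:
        if np.any(np.abs(self.prcc) > 1 + 1e-12):
            raise ValueError("|PRCC| must not exceed 1")

    def to_frame(self) -> pd.DataFrame:
        """Tornado-ready table, ordered by |PRCC| descending."""
        df = pd.DataFrame({"parameter": self.parameters,
                           "prcc": self.prcc, "p_value": self.p_value})
        return df.reindex(df["prcc"].abs().sort_values(ascending=False).index
                          ).reset_index(drop=True)


def lhs_sample(n: int, ranges: Sequence[Tuple[float, float]],
               seed: int | np.random.Generator = 0) -> np.ndarray:
    """Latin hypercube sample: ``n`` points in ``len(ranges)`` dimensions.

    Every dimension is cut into ``n`` equal-probability strata; each stratum
    receives exactly one point, uniformly placed within it, with the strata
    independently permuted per dimension. Reproducible under a fixed seed.
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    ranges = list(ranges)
    if not ranges:
        raise ValueError("at least one parameter range is required")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    d = len(ranges)
    out = np.empty((n, d))
    for j, (a, b) in enumerate(ranges):
        if not a < b:
            raise ValueError(f"empty range [{a}, {b}] in dimension {j}")
        strata = (rng.permutation(n) + rng.uniform(size=n)) / n
        out[:, j] = a + strata * (b - a)
    return out


def _rank(x: np.ndarray) -> np.ndarray:
    return rankdata(x, method="average")


def prcc(X: np.ndarray, y: np.ndarray,
         parameters: Sequence[str] | None = None,
         n_samples: int | None = None, seed: int = 0) -> SensitivityResult:
    """Partial rank correlation coefficients of ``y`` against columns of ``X``.

    Both sides are rank-transformed (average ranks for ties); for each
    parameter the linear rank effects of all other parameters are regressed
    out of both the parameter and the output, and the Pearson correlation
    of the residuals is the PRCC. p-values come from the t distribution
    with ``n - 2 - (d - 1)`` degrees of freedom. A constant output yields
    all-zero coefficients with a warning.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, d = X.shape
    if len(y) != n:
        raise ValueError("X and y disagree on the number of samples")
    if n <= d + 2:
        raise ValueError(f"need n > d + 2 samples (n={n}, d={d})")
    if np.any(np.ptp(X, axis=0) == 0):
        raise ValueError("constant parameter column; drop it before PRCC")
    names = tuple(parameters) if parameters is not None else tuple(
        f"x{j}" for j in range(d))

    if np.ptp(y) == 0:
        warnings.warn("output is constant; PRCC set to 0 for all parameters",
                      stacklevel=2)
        return SensitivityResult(names, np.zeros(d), np.ones(d),
                                 n_samples or n, seed)

    R = np.column_stack([_rank(X[:, j]) for j in range(d)])
    ry = _rank(y)
    dof = n - 2 - (d - 1)
    coeffs = np.empty(d)
    pvals = np.empty(d)
    for j in range(d):
        others = np.delete(R, j, axis=1)
        design = np.column_stack([np.ones(n), others])
        beta_x, *_ = np.linalg.lstsq(design, R[:, j], rcond=None)
        beta_y, *_ = np.linalg.lstsq(design, ry, rcond=None)
        res_x = R[:, j] - design @ beta_x
        res_y = ry - design @ beta_y
        denom = np.sqrt(np.sum(res_x ** 2) * np.sum(res_y ** 2))
        if denom == 0:
            raise np.linalg.LinAlgError(
                f"rank-deficient design for parameter {names[j]!r}")
        r = float(np.clip(np.sum(res_x * res_y) / denom, -1.0, 1.0))
        coeffs[j] = r
        if abs(r) >= 1.0:
            pvals[j] = 0.0
        else:
            t_stat = r * np.sqrt(dof / (1.0 - r * r))
            pvals[j] = 2.0 * t_dist.sf(abs(t_stat), dof)
    return SensitivityResult(names, coeffs, pvals, n_samples or n, seed)


#: Ranges for the biomarkers and mechanism strengths screened by the global
#: sensitivity analysis. Patient-level entries map to PatientParameters
#: fields; the rest are ParameterSet overrides.
DEFAULT_SENSITIVITY_RANGES: Dict[str, Tuple[float, float]] = {
    "k_apo_teff": (0.05, 0.8),           # effector T-cell apoptosis rate
    "rho_mdsc": (0.005, 0.1),            # MDSC level per cancer cell
    "treg_tum_max": (1e8, 5e9),          # Treg level in the tumour
    "antigen_intensity": (0.2, 0.9),     # T-cell clonality / antigen strength
    "emax_supp_kill": (0.2, 0.9),        # checkpoint effect of Tregs/MDSCs
    "emax_ctla4_prime": (0.5, 0.95),     # CTLA-4 inhibition strength in TDLN
    "pdl1_fraction": (0.0, 0.6),
    "initial_tumour_diameter": (15.0, 45.0),
    "tumour_doubling_time": (60.0, 240.0),
}

_PATIENT_FIELDS = {"antigen_intensity", "pdl1_fraction",
                   "initial_tumour_diameter", "tumour_doubling_time",
                   "body_weight", "pdl2_fraction"}


def run_global_sensitivity(
        param_ranges: Mapping[str, Tuple[float, float]] | None = None,
        regimen: str = "combo",
        n: int = 1000, seed: int = 0,
        simulate_sample: Callable[[Dict[str, float], str], float] | None = None,
        max_failed_fraction: float = 0.05) -> SensitivityResult:
    """LHS/PRCC of percent tumour-size change over the parameter ranges.

    Each LHS sample is mapped onto a virtual patient (patient-level names)
    and parameter overrides (all others), simulated through pre-treatment
    steady state and therapy, and reduced to the percent diameter change at
    the 15-month horizon. Failed simulations are dropped (and counted);
    more than ``max_failed_fraction`` failures aborts.

    ``simulate_sample(overrides, regimen) -> percent_change`` may be
    injected for testing; the default builds and runs the full model.
    """
    ranges = dict(param_ranges or DEFAULT_SENSITIVITY_RANGES)
    names = list(ranges)
    X = lhs_sample(n, [ranges[k] for k in names], seed)

    if simulate_sample is None:
        simulate_sample = _simulate_sample_full

    y = np.empty(n)
    ok = np.ones(n, dtype=bool)
    for i in range(n):
        overrides = dict(zip(names, X[i]))
        try:
            y[i] = simulate_sample(overrides, regimen)
        except Exception:
            logger.exception("sensitivity sample %d failed", i)
            ok[i] = False
    n_failed = int((~ok).sum())
    if n_failed > max_failed_fraction * n:
        raise RuntimeError(
            f"{n_failed}/{n} sensitivity simulations failed "
            f"(> {max_failed_fraction:.0%}); check parameter ranges")
    result = prcc(X[ok], y[ok], parameters=names, n_samples=n, seed=seed)
    result.n_failed = n_failed
    return result


def _simulate_sample_full(overrides: Dict[str, float], regimen: str) -> float:
    from .engine import CheckpointBlockadeModel, SimulationSettings
    from .model_core import ParameterSet, PatientParameters
    from .pkpd import resolve_regimen
    from .response import percent_change

    patient_kw = {k: v for k, v in overrides.items() if k in _PATIENT_FIELDS}
    param_kw = {k: v for k, v in overrides.items() if k not in _PATIENT_FIELDS}
    patient = PatientParameters(**patient_kw)
    model = CheckpointBlockadeModel(patient, ParameterSet(param_kw))
    # batch settings: moderate tolerances, capped equilibration time
    settings = SimulationSettings(rel_tol=1e-6, abs_tol=1e-8,
                                  ss_tol=1e-3, ss_max_days=300.0)
    reg = resolve_regimen(regimen, body_weight=patient.body_weight,
                          horizon=settings.horizon)
    state0 = model.steady_state(settings)
    traj = model.simulate(reg, state0=state0, settings=settings)
    return percent_change(traj.baseline_diameter, traj.final_diameter)
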