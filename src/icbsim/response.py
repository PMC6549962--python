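"""RECIST-style response classification and parameter sweeps.

Tumour response is read off the simulated diameter trajectory: partial
response (PR) is at least a 30% diameter decrease from the start of
therapy; complete response (CR) is the diameter falling below a detection
floor; progressive disease (PD) is a +20% increase from the nadir with at
least 5 mm absolute growth (RECIST 1.1 conventions); anything else is
stable disease (SD). The module also locates the antigen-intensity
threshold for partial response by bisection and runs 1-D/2-D parameter
sweeps of percent tumour-size change.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Callable, Iterable, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .engine import Trajectory

__all__ = [
    "ResponseClassification",
    "percent_change",
    "classify_recist",
    "antigen_threshold_for_pr",
    "sweep",
    "SweepResult",
]

logger = logging.getLogger(__name__)

PR_THRESHOLD = -30.0        # percent; at least 30% diameter decrease
PD_THRESHOLD = 20.0         # percent increase from nadir
PD_ABSOLUTE_MM = 5.0        # minimum absolute increase from nadir
DETECTION_FLOOR_MM = 1.0    # diameter below which the lesion counts as CR


@dataclass(frozen=True)
class ResponseClassification:
    category: str                 # CR | PR | SD | PD
    percent_change: float         # best % change of diameter vs baseline
    end_percent_change: float     # % change at the end of the horizon
    time_of_classification: float  # day

    def __post_init__(self) -> None:
        if self.category not in ("CR", "PR", "SD", "PD"):
            raise ValueError(f"unknown category {self.category!r}")
        if self.category == "PR" and not self.percent_change <= PR_THRESHOLD:
            raise ValueError("PR requires a >= 30% diameter decrease")


def percent_change(d_start: float, d_end: float) -> float:
    """Percent change of tumour diameter relative to the start of therapy."""
    if d_start <= 0:
        raise ValueError("baseline diameter must be positive")
    return 100.0 * (d_end - d_start) / d_start


def classify_recist(trajectory: Trajectory,
                    detection_floor_mm: float = DETECTION_FLOOR_MM
                    ) -> ResponseClassification:
    """Best-overall-response classification of a diameter trajectory.

    Precedence CR > PR > PD > SD: a tumour that shrinks past the PR
    boundary and later regrows is reported by its best response. The PR
    boundary (-30%) is inclusive.
    """
    d = np.asarray(trajectory.diameter, dtype=float)
    t = np.asarray(trajectory.t, dtype=float)
    if d.size == 0:
        raise ValueError("empty trajectory")
    d0 = d[0]
    if d0 <= 0:
        raise ValueError("baseline diameter must be positive")
    best_idx = int(np.argmin(d))
    best_pct = percent_change(d0, d[best_idx])
    end_pct = percent_change(d0, d[-1])

    if d[best_idx] < detection_floor_mm:
        first_cr = int(np.argmax(d < detection_floor_mm))
        return ResponseClassification("CR", best_pct, end_pct, float(t[first_cr]))
    if best_pct <= PR_THRESHOLD:
        first_pr = int(np.argmax(percent_change(d0, d) <= PR_THRESHOLD))
        return ResponseClassification("PR", best_pct, end_pct, float(t[first_pr]))
    # progressive disease vs the running nadir
    nadir = np.minimum.accumulate(d)
    prog = (d >= 1.2 * nadir) & (d >= nadir + PD_ABSOLUTE_MM)
    prog[0] = d0 >= nadir[0] * 1.2  # degenerate single-point guard
    if np.any(prog):
        return ResponseClassification("PD", best_pct, end_pct,
                                      float(t[int(np.argmax(prog))]))
    return ResponseClassification("SD", best_pct, end_pct, float(t[-1]))


def antigen_threshold_for_pr(simulate_at: Callable[[float], Trajectory],
                             interval: Tuple[float, float] = (0.0, 1.0),
                             tol: float = 1e-3,
                             use_best_response: bool = False) -> float:
    """Lowest antigen intensity achieving partial response, by bisection.

    ``simulate_at(antigen)`` must return the therapy trajectory for that
    antigen intensity with everything else fixed. Response is required to be
    monotone non-decreasing in antigen intensity over the interval (checked
    at the endpoints). By default the end-of-horizon percent change decides
    PR ("PR or better at 15 months"); ``use_best_response`` switches to the
    best overall response. Returns NaN (with a diagnostic log entry) when
    even the upper endpoint fails to respond; returns the lower endpoint
    when it already responds.
    """

    def responds(antigen: float) -> bool:
        traj = simulate_at(antigen)
        cls = classify_recist(traj)
        pct = cls.percent_change if use_best_response else cls.end_percent_change
        return pct <= PR_THRESHOLD or cls.category == "CR"

    lo, hi = interval
    if not lo < hi:
        raise ValueError("interval must be non-degenerate")
    lo_ok, hi_ok = responds(lo), responds(hi)
    if lo_ok and not hi_ok:
        raise ValueError(
            "response is not monotone in antigen intensity over the interval; "
            "run a grid scan instead")
    if lo_ok:
        return lo
    if not hi_ok:
        logger.warning("no partial response anywhere in antigen interval "
                       "[%g, %g]", lo, hi)
        return math.nan
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if responds(mid):
            hi = mid
        else:
            lo = mid
    return hi


@dataclass
class SweepResult:
    """Grid of responses from a 1-D or 2-D parameter sweep."""

    axis1_name: str
    axis1_values: np.ndarray
    axis2_name: Optional[str]
    axis2_values: Optional[np.ndarray]
    end_percent_change: np.ndarray   # shape (n1,) or (n1, n2)
    best_percent_change: np.ndarray
    category: np.ndarray             # object array of RECIST categories

    def to_frame(self) -> pd.DataFrame:
        """Tidy long-format table (contour-ready after pivot)."""
        rows = []
        if self.axis2_name is None:
            for i, v1 in enumerate(self.axis1_values):
                rows.append({self.axis1_name: v1,
                             "end_percent_change": self.end_percent_change[i],
                             "best_percent_change": self.best_percent_change[i],
                             "category": self.category[i]})
        else:
            for i, v1 in enumerate(self.axis1_values):
                for j, v2 in enumerate(self.axis2_values):
                    rows.append({self.axis1_name: v1, self.axis2_name: v2,
                                 "end_percent_change": self.end_percent_change[i, j],
                                 "best_percent_change": self.best_percent_change[i, j],
                                 "category": self.category[i, j]})
        return pd.DataFrame(rows)


def sweep(simulate_at: Callable[..., Trajectory],
          axis1: Tuple[str, Sequence[float]],
          axis2: Tuple[str, Sequence[float]] | None = None) -> SweepResult:
    """Evaluate the model over a 1-D or 2-D parameter grid.

    ``simulate_at(**{axis_name: value, ...})`` runs one simulation per grid
    point. Results are independent of evaluation order; a failed cell is
    recorded as NaN (category ``"failed"``) and the sweep continues.
    """
    name1, vals1 = axis1
    vals1 = np.asarray(list(vals1), dtype=float)
    if axis2 is None:
        shape: tuple = (len(vals1),)
        points: Iterable = (((i,), {name1: v}) for i, v in enumerate(vals1))
        name2, vals2 = None, None
    else:
        name2, vals2 = axis2
        vals2 = np.asarray(list(vals2), dtype=float)
        shape = (len(vals1), len(vals2))
        points = (((i, j), {name1: v1, name2: v2})
                  for i, v1 in enumerate(vals1)
                  for j, v2 in enumerate(vals2))

    end_pct = np.full(shape, np.nan)
    best_pct = np.full(shape, np.nan)
    cat = np.full(shape, "failed", dtype=object)
    for idx, kwargs in points:
        try:
            traj = simulate_at(**kwargs)
            cls = classify_recist(traj)
        except Exception:  # record and continue — sweeps must survive bad cells
            logger.exception("sweep cell %s failed", kwargs)
            continue
        end_pct[idx] = cls.end_percent_change
        best_pct[idx] = cls.percent_change
        cat[idx] = cls.category
    return SweepResult(name1, vals1, name2, vals2, end_pct, best_pct, cat)
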