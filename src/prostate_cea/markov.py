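"""Monthly-cycle Markov cohort engine over five health states.

The cohort starts in INITIAL_TREATMENT, resolves the one-time PSA-control
split (90/10 at base case) on the transition into cycle 1, and thereafter
moves between PSA_CONTROLLED, the one-cycle PSA_FAILURE tunnel, ADT and DEAD.
In the RARP arm, men entering PSA_FAILURE receive salvage radiotherapy which
restores control in ``salvage_success`` of them; IMRT failures pass directly
to ADT.  All-cause mortality competes proportionally with clinical
transitions: each clinical probability is scaled by ``1 - q_m`` where ``q_m``
is the monthly death probability implied by the life-table annual ``qx`` at
the cohort's current whole-year age.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .parameters import Arm, ParameterSet, annual_to_monthly_prob

__all__ = [
    "HealthState",
    "LifeTable",
    "CohortTrace",
    "build_transition_matrix",
    "run_cohort",
    "validate_trace",
    "monthly_death_probs",
    "trace_to_frame",
]


class HealthState(enum.IntEnum):
    INITIAL_TREATMENT = 0
    PSA_CONTROLLED = 1
    PSA_FAILURE = 2
    ADT = 3
    DEAD = 4


N_STATES = len(HealthState)


@dataclass(frozen=True)
class LifeTable:
    """Age-indexed annual all-cause death probabilities (``qx``).

    Ages must be contiguous integers.  Synthetic tables are strictly
    increasing in ``qx``; user-supplied tables only get a warning when
    non-monotone, since published abridged tables occasionally dip.
    """

    ages: np.ndarray
    qx: np.ndarray

    def __post_init__(self) -> None:
        ages = np.asarray(self.ages, dtype=int)
        qx = np.asarray(self.qx, dtype=float)
        object.__setattr__(self, "ages", ages)
        object.__setattr__(self, "qx", qx)
        if ages.ndim != 1 or ages.shape != qx.shape or ages.size == 0:
            raise ValueError("life table needs matching 1-D age and qx arrays")
        if not np.all(np.diff(ages) == 1):
            raise ValueError("life-table ages must be contiguous integers")
        if np.any((qx < 0) | (qx > 1)):
            raise ValueError("life-table qx values must be in [0, 1]")
        if np.any(np.diff(qx) < 0):
            warnings.warn("life-table qx is not non-decreasing with age", stacklevel=2)

    def q_annual(self, age: int) -> float:
        """Annual death probability at integer ``age``."""
        idx = age - int(self.ages[0])
        if idx < 0 or idx >= self.ages.size:
            raise ValueError(f"age {age} outside life-table range "
                             f"[{self.ages[0]}, {self.ages[-1]}]")
        return float(self.qx[idx])

    def require_coverage(self, start_age: int, horizon_years: int) -> None:
        last_needed = start_age + horizon_years
        if int(self.ages[0]) > start_age or int(self.ages[-1]) < last_needed:
            raise ValueError(
                f"life table covers [{self.ages[0]}, {self.ages[-1]}] but "
                f"[{start_age}, {last_needed}] is required"
            )


def monthly_death_probs(params: ParameterSet, life_table: LifeTable) -> np.ndarray:
    """Per-cycle monthly death probability q_m for cycles 0..H-1.

    Age advances one whole year every 12 cycles; q_m is constant within a
    year of age.
    """
    H = params.settings.n_cycles
    start = params.settings.start_age
    qm = np.empty(H, dtype=float)
    for year in range((H + 11) // 12):
        q = annual_to_monthly_prob(life_table.q_annual(start + year))
        qm[12 * year : 12 * (year + 1)] = q
    return qm


def build_transition_matrix(
    arm: Arm, params: ParameterSet, cycle: int, life_table: LifeTable
) -> np.ndarray:
    """5x5 one-cycle transition matrix for ``arm`` at ``cycle``.

    Row convention: entry ``[i, j]`` is the probability of moving from state
    ``i`` at the start of the cycle to state ``j`` at its end.  Every row is
    stochastic; DEAD is absorbing.
    """
    if cycle < 0:
        raise ValueError("cycle must be >= 0")
    age = params.settings.start_age + cycle // 12
    qm = annual_to_monthly_prob(life_table.q_annual(age))
    return _transition_matrix(arm, params, qm)


def _transition_matrix(arm: Arm, params: ParameterSet, qm: float) -> np.ndarray:
    clin = params.clinical
    p_control = clin.psa_control(arm)
    late = clin.late_failure_monthly_hazard
    salvage = clin.salvage_success if arm is Arm.RARP else 0.0
    alive = 1.0 - qm

    m = np.zeros((N_STATES, N_STATES), dtype=float)
    s = HealthState
    m[s.INITIAL_TREATMENT, s.PSA_CONTROLLED] = p_control * alive
    m[s.INITIAL_TREATMENT, s.PSA_FAILURE] = (1.0 - p_control) * alive
    m[s.INITIAL_TREATMENT, s.DEAD] = qm

    m[s.PSA_CONTROLLED, s.PSA_CONTROLLED] = (1.0 - late) * alive
    m[s.PSA_CONTROLLED, s.PSA_FAILURE] = late * alive
    m[s.PSA_CONTROLLED, s.DEAD] = qm

    # PSA_FAILURE is a one-cycle tunnel: RARP salvage either restores control
    # or the patient moves to ADT; IMRT failures go straight to ADT.
    m[s.PSA_FAILURE, s.PSA_CONTROLLED] = salvage * alive
    m[s.PSA_FAILURE, s.ADT] = (1.0 - salvage) * alive
    m[s.PSA_FAILURE, s.DEAD] = qm

    m[s.ADT, s.ADT] = alive
    m[s.ADT, s.DEAD] = qm

    m[s.DEAD, s.DEAD] = 1.0
    return m


@dataclass(frozen=True)
class CohortTrace:
    """State-occupancy proportions per cycle plus entry flows.

    ``occupancy`` has H+1 rows (cycles 0..H) and five columns.  The flow
    vectors record the proportion of the cohort newly entering PSA_FAILURE
    and ADT at each cycle; one-time salvage costs attach to ``new_failure``.
    """

    arm: Arm
    occupancy: np.ndarray
    new_failure: np.ndarray
    new_adt: np.ndarray

    @property
    def n_cycles(self) -> int:
        return self.occupancy.shape[0] - 1


def run_cohort(arm: Arm, params: ParameterSet, life_table: LifeTable) -> CohortTrace:
    """Propagate the cohort through H monthly cycles.

    Row t+1 of the trace is row t right-multiplied by the cycle-t transition
    matrix; flows into PSA_FAILURE and ADT are recorded alongside.
    """
    settings = params.settings
    life_table.require_coverage(settings.start_age, settings.horizon_years)
    H = settings.n_cycles
    occ = np.zeros((H + 1, N_STATES), dtype=float)
    occ[0, HealthState.INITIAL_TREATMENT] = 1.0
    new_failure = np.zeros(H + 1, dtype=float)
    new_adt = np.zeros(H + 1, dtype=float)

    qm = monthly_death_probs(params, life_table)
    for t in range(H):
        m = _transition_matrix(arm, params, qm[t])
        row = occ[t]
        occ[t + 1] = row @ m
        inflow_f = row @ m[:, HealthState.PSA_FAILURE]
        inflow_f -= row[HealthState.PSA_FAILURE] * m[HealthState.PSA_FAILURE, HealthState.PSA_FAILURE]
        new_failure[t + 1] = inflow_f
        inflow_a = row @ m[:, HealthState.ADT]
        inflow_a -= row[HealthState.ADT] * m[HealthState.ADT, HealthState.ADT]
        new_adt[t + 1] = inflow_a
    return CohortTrace(arm=arm, occupancy=occ, new_failure=new_failure, new_adt=new_adt)


@dataclass(frozen=True)
class TraceValidation:
    conservation_ok: bool
    dead_monotone_ok: bool
    non_negative_ok: bool
    max_row_error: float
    messages: tuple[str, ...] = field(default_factory=tuple)

    @property
    def ok(self) -> bool:
        return self.conservation_ok and self.dead_monotone_ok and self.non_negative_ok


def validate_trace(trace: CohortTrace, tol: float = 1e-10) -> TraceValidation:
    """Check conservation, DEAD monotonicity and non-negativity (read-only)."""
    occ = trace.occupancy
    row_err = float(np.max(np.abs(occ.sum(axis=1) - 1.0)))
    conservation = row_err <= tol
    dead = occ[:, HealthState.DEAD]
    dead_monotone = bool(np.all(np.diff(dead) >= -tol))
    non_negative = bool(np.all(occ >= -tol))
    messages = []
    if not conservation:
        messages.append(f"row sums deviate from 1 by up to {row_err:.3e}")
    if not dead_monotone:
        messages.append("DEAD occupancy decreases at some cycle")
    if not non_negative:
        messages.append("negative occupancy encountered")
    return TraceValidation(conservation, dead_monotone, non_negative, row_err, tuple(messages))


def trace_to_frame(trace: CohortTrace) -> pd.DataFrame:
    """Tabular trace export with one row per cycle."""
    occ = trace.occupancy
    return pd.DataFrame(
        {
            "cycle": np.arange(occ.shape[0]),
            "initial": occ[:, HealthState.INITIAL_TREATMENT],
            "controlled": occ[:, HealthState.PSA_CONTROLLED],
            "failure": occ[:, HealthState.PSA_FAILURE],
            "adt": occ[:, HealthState.ADT],
            "dead": occ[:, HealthState.DEAD],
            "new_failure": trace.new_failure,
            "new_adt": trace.new_adt,
        }
    )
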