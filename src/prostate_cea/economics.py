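"""Reward layer: utilities, costs, discounting, ICER and INMB.

Rewards accrue for cycles 0..H-1 using the state occupancy at the start of
each cycle (the final trace row is the end state and accrues nothing), so a
1-year horizon at constant utility 0.90 with no discounting yields exactly
0.90 QALYs.  Discount factor d(t) = (1 + r)^(-t/12) with d(0) = 1.

Adverse-event burden enters as prevalence-weighted utility decrements applied
in every alive state (the model has no explicit AE substates).  The RARP
month-1 prevalence is reconstructed from the tabulated one-year value and the
one-year cure rate as ``p1 = p12 + cure * (1 - p12)`` — the cure rate is read
as the fraction of the initially affected complement that recovers within the
first postoperative year — and declines linearly to ``p12`` by month 12.
IMRT prevalences are flat at their reported value from month 1.  Events with
a finite duration (GI: 36 months) contribute nothing afterwards.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .markov import CohortTrace, HealthState
from .parameters import ARM_CLASS, EVENTS, Arm, ParameterSet, params_digest

__all__ = [
    "ae_prevalence",
    "ae_prevalence_schedule",
    "state_utility",
    "utility_matrix",
    "discount_factors",
    "cycle_cost",
    "cost_vector",
    "accumulate",
    "ArmResult",
    "Comparison",
    "compute_icer",
    "compute_inmb",
    "compare",
    "DOMINANT",
    "DOMINATED",
    "UNDEFINED",
]

DOMINANT = "dominant"
DOMINATED = "dominated"
UNDEFINED = "undefined"


def ae_prevalence(arm: Arm, event: str, cycle: int, params: ParameterSet) -> float:
    """Prevalence of ``event`` in ``arm`` at monthly ``cycle`` (0 at cycle 0)."""
    if event not in EVENTS:
        raise ValueError(f"unknown adverse event {event!r}")
    if cycle <= 0:
        return 0.0
    duration = params.settings.ae_duration_months.get(event)
    if duration is not None and cycle > duration:
        return 0.0
    p12 = params.clinical.ae_prevalence[(ARM_CLASS[arm], event)]
    if arm is Arm.RARP:
        cure = params.clinical.cure_rate(event)
        p1 = p12 + cure * (1.0 - p12)
        if cycle <= 12:
            return p1 + (p12 - p1) * (cycle - 1) / 11.0
    return p12


def ae_prevalence_schedule(
    arm: Arm, event: str, params: ParameterSet, n_cycles: int
) -> np.ndarray:
    """Vector of ``ae_prevalence`` over cycles 0..n_cycles-1."""
    return np.array([ae_prevalence(arm, event, t, params) for t in range(n_cycles)])


def _ae_utility_burden(arm: Arm, cycle: int, params: ParameterSet) -> float:
    return sum(
        ae_prevalence(arm, e, cycle, params) * params.utilities.decrement(e) for e in EVENTS
    )


def state_utility(arm: Arm, state: HealthState, cycle: int, params: ParameterSet) -> float:
    """Per-cycle utility for one state; DEAD is 0, alive states are the base
    utility minus the PSA-failure decrement (in PSA_FAILURE and ADT) and the
    prevalence-weighted AE decrements, floored at 0."""
    if state == HealthState.DEAD:
        return 0.0
    u = params.utilities
    dec_psa = u.dec_psa_failure if state in (HealthState.PSA_FAILURE, HealthState.ADT) else 0.0
    if params.settings.multiplicative_decrements:
        val = u.base_utility
        for d in (dec_psa, *(
            ae_prevalence(arm, e, cycle, params) * u.decrement(e) for e in EVENTS
        )):
            val *= max(0.0, (u.base_utility - d)) / u.base_utility
        return max(0.0, val)
    return max(0.0, u.base_utility - dec_psa - _ae_utility_burden(arm, cycle, params))


def utility_matrix(arm: Arm, params: ParameterSet, n_cycles: int) -> np.ndarray:
    """(n_cycles, 5) utilities per cycle and state."""
    out = np.zeros((n_cycles, len(HealthState)), dtype=float)
    for t in range(n_cycles):
        for s in HealthState:
            out[t, s] = state_utility(arm, s, t, params)
    return out


def discount_factors(params: ParameterSet, n: int) -> np.ndarray:
    """d(t) = (1 + r)^(-t/12) for t = 0..n-1."""
    r = params.settings.annual_discount
    return (1.0 + r) ** (-np.arange(n) / 12.0)


def cycle_cost(
    arm: Arm,
    occupancy: np.ndarray,
    new_failure: float,
    cycle: int,
    params: ParameterSet,
) -> float:
    """Undiscounted cohort cost accrued during one cycle.

    Cycle 0 carries the full upfront treatment cost; every cycle accrues the
    monthly ADT cost on ADT occupancy, salvage radiotherapy on new
    PSA_FAILURE entrants (RARP arm only), and any configured per-event AE
    management cost on alive occupancy.
    """
    occupancy = np.asarray(occupancy, dtype=float)
    if new_failure < 0 or np.any(occupancy < 0):
        raise ValueError("negative occupancy or entry flow")
    costs = params.costs
    total = 0.0
    if cycle == 0:
        total += costs.upfront(arm) * occupancy.sum()
    total += occupancy[HealthState.ADT] * costs.adt_annual / 12.0
    if arm is Arm.RARP:
        total += new_failure * costs.salvage_rt
    alive = occupancy.sum() - occupancy[HealthState.DEAD]
    for event, c in costs.ae_management.items():
        if c:
            total += alive * ae_prevalence(arm, event, cycle, params) * c
    return total


def cost_vector(trace: CohortTrace, arm: Arm, params: ParameterSet) -> np.ndarray:
    """Undiscounted per-cycle costs for cycles 0..H-1."""
    H = trace.n_cycles
    return np.array(
        [cycle_cost(arm, trace.occupancy[t], trace.new_failure[t], t, params) for t in range(H)]
    )


@dataclass(frozen=True)
class ArmResult:
    """Discounted and undiscounted totals for one strategy."""

    arm: Arm
    total_cost: float
    total_qalys: float
    undiscounted_cost: float
    undiscounted_qalys: float
    params_key: str | None = None


def accumulate(trace: CohortTrace, arm: Arm, params: ParameterSet) -> ArmResult:
    """Discounted total cost and QALYs for one arm's trace."""
    H = trace.n_cycles
    if H == 0:
        # Degenerate zero-length horizon: nothing accrues, not even upfront cost.
        return ArmResult(arm, 0.0, 0.0, 0.0, 0.0, params_key=params_digest(params))
    disc = discount_factors(params, H)
    weights = np.ones(H)
    if params.settings.half_cycle_correction:
        # Trapezoid weighting of the recurring streams; upfront cost is kept
        # at full weight below because it is a time-0 lump sum.
        weights[0] = 0.5

    U = utility_matrix(arm, params, H)
    qaly_per_cycle = (trace.occupancy[:H] * U).sum(axis=1) / 12.0
    cost_per_cycle = cost_vector(trace, arm, params)
    if params.settings.half_cycle_correction:
        upfront = cost_per_cycle[0] if H > 0 else 0.0
        recurring = cost_per_cycle.copy()
        recurring[0] = 0.0
        total_cost = float(upfront + (disc * weights * recurring).sum())
        undisc_cost = float(upfront + (weights * recurring).sum())
    else:
        total_cost = float((disc * cost_per_cycle).sum())
        undisc_cost = float(cost_per_cycle.sum())
    total_qalys = float((disc * weights * qaly_per_cycle).sum())
    undisc_qalys = float((weights * qaly_per_cycle).sum())
    return ArmResult(
        arm, total_cost, total_qalys, undisc_cost, undisc_qalys, params_key=params_digest(params)
    )


def compute_icer(delta_cost: float, delta_qalys: float) -> float | str:
    """ICER = ΔCost/ΔQALY, or a dominance label when the ratio is not
    meaningful: 'dominant' (more effective, no more costly), 'dominated'
    (less effective, no less costly), 'undefined' (ΔQALY = 0)."""
    if delta_qalys == 0.0:
        return UNDEFINED
    if delta_qalys > 0 and delta_cost <= 0:
        return DOMINANT
    if delta_qalys < 0 and delta_cost >= 0:
        return DOMINATED
    return delta_cost / delta_qalys


def compute_inmb(delta_qalys: float, delta_cost: float, wtp: float) -> float:
    """Incremental net monetary benefit: ΔQALY × WTP − ΔCost.

    Well-defined for every sign combination, which is why it anchors the
    dominance-prone sexual-disutility sweep.
    """
    if wtp < 0:
        raise ValueError("wtp must be >= 0")
    return delta_qalys * wtp - delta_cost


@dataclass(frozen=True)
class Comparison:
    """Incremental comparison of an alternative against a reference arm."""

    reference: Arm
    alternative: Arm
    delta_cost: float
    delta_qalys: float
    icer: float | str
    inmb: float
    wtp: float


def compare(reference: ArmResult, alternative: ArmResult, wtp: float) -> Comparison:
    """Incrementals of ``alternative`` minus ``reference`` (reference = RARP
    by convention in this analysis)."""
    if (
        reference.params_key is not None
        and alternative.params_key is not None
        and reference.params_key != alternative.params_key
    ):
        raise ValueError("arm results come from different parameter sets")
    dc = alternative.total_cost - reference.total_cost
    dq = alternative.total_qalys - reference.total_qalys
    return Comparison(
        reference=reference.arm,
        alternative=alternative.arm,
        delta_cost=dc,
        delta_qalys=dq,
        icer=compute_icer(dc, dq),
        inmb=compute_inmb(dq, dc, wtp),
        wtp=wtp,
    )
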