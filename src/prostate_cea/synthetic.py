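"""Synthetic inputs and the individual-level validation oracle.

The model needs an age-indexed all-cause mortality schedule for Japanese men
from age 65; no such table ships with the analysis, so this module generates
one from a Gompertz–Makeham hazard — the standard two-parameter adult
mortality law — optionally calibrated so that discrete life expectancy at 65
hits a target (defaults to 19.4 years, typical of contemporary Japanese men).
A real national life table can be substituted via the ``age,qx`` CSV format.

The micro-simulation oracle re-derives arm totals by simulating individuals
with categorical draws through the very same transition matrices and reward
functions used by the cohort engine, giving an independent route to the
cohort expectation.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import brentq

from . import economics
from .markov import HealthState, LifeTable, _transition_matrix, monthly_death_probs
from .parameters import Arm, ParameterSet, default_parameters, to_dict

__all__ = [
    "LifeTableSpec",
    "default_life_table_spec",
    "generate_life_table",
    "read_life_table",
    "write_life_table",
    "MicrosimEstimate",
    "microsim_oracle",
    "make_fixtures",
]

# Internal upper age used when integrating life expectancy, so that the
# calibration target does not depend on the stored table's span.
_MAX_AGE_FOR_EX = 130


@dataclass(frozen=True)
class LifeTableSpec:
    """Gompertz–Makeham specification: annual hazard a + b*exp(c*age).

    ``makeham_a`` is the age-independent hazard floor (accidents etc.),
    ``gompertz_b``/``gompertz_c`` the senescent scale and log-slope.  When
    ``target_ex65`` is set, ``gompertz_b`` is rescaled so the discrete life
    expectancy at 65 matches it to within 0.05 years.
    """

    model: str = "gompertz_makeham"
    makeham_a: float = 5e-4
    gompertz_b: float = 1.4e-5
    gompertz_c: float = 0.10
    age_range: tuple[int, int] = (65, 110)
    target_ex65: float | None = 19.4

    def __post_init__(self) -> None:
        if self.model != "gompertz_makeham":
            raise ValueError(f"unknown life-table model {self.model!r}")
        if self.makeham_a < 0 or self.gompertz_b <= 0 or self.gompertz_c <= 0:
            raise ValueError("require makeham_a >= 0, gompertz_b > 0, gompertz_c > 0")
        lo, hi = self.age_range
        if lo >= hi:
            raise ValueError("age_range must be increasing")


def default_life_table_spec() -> LifeTableSpec:
    return LifeTableSpec()


def _qx(spec: LifeTableSpec, ages: np.ndarray) -> np.ndarray:
    hazard = spec.makeham_a + spec.gompertz_b * np.exp(spec.gompertz_c * ages)
    return 1.0 - np.exp(-hazard)


def _ex65(spec: LifeTableSpec) -> float:
    """Discrete life expectancy at 65: curtate expectation + 1/2.

    Computed over ages 65..130 regardless of the stored range so the target
    is well defined even for short tables.
    """
    ages = np.arange(65, _MAX_AGE_FOR_EX + 1)
    qx = _qx(spec, ages)
    surv = np.cumprod(1.0 - qx)
    return float(surv.sum()) + 0.5


def generate_life_table(spec: LifeTableSpec) -> LifeTable:
    """Synthesize a life table; qx is strictly increasing by construction."""
    if spec.target_ex65 is not None:
        spec = _calibrate(spec)
    lo, hi = spec.age_range
    ages = np.arange(lo, hi + 1)
    return LifeTable(ages=ages, qx=_qx(spec, ages))


def _calibrate(spec: LifeTableSpec) -> LifeTableSpec:
    target = spec.target_ex65
    assert target is not None

    def gap(log_scale: float) -> float:
        return _ex65(replace(spec, gompertz_b=spec.gompertz_b * np.exp(log_scale),
                             target_ex65=None)) - target

    lo, hi = -20.0, 20.0
    g_lo, g_hi = gap(lo), gap(hi)
    if g_lo * g_hi > 0:
        raise ValueError(
            f"life-expectancy calibration cannot bracket target {target}: "
            f"ex65 range [{target + g_hi:.2f}, {target + g_lo:.2f}]"
        )
    root = brentq(gap, lo, hi, xtol=1e-13)
    return replace(spec, gompertz_b=spec.gompertz_b * float(np.exp(root)), target_ex65=None)


def write_life_table(table: LifeTable, path: str | os.PathLike) -> None:
    pd.DataFrame({"age": table.ages, "qx": table.qx}).to_csv(path, index=False, float_format="%.17g")


def read_life_table(path: str | os.PathLike, *, start_age: int | None = None,
                    horizon_years: int | None = None) -> LifeTable:
    """Read an ``age,qx`` CSV; optionally enforce horizon coverage."""
    df = pd.read_csv(path, float_precision="round_trip")
    if list(df.columns[:2]) != ["age", "qx"]:
        raise ValueError("life-table CSV must have header 'age,qx'")
    table = LifeTable(ages=df["age"].to_numpy(dtype=int), qx=df["qx"].to_numpy(dtype=float))
    if start_age is not None and horizon_years is not None:
        table.require_coverage(start_age, horizon_years)
    return table


@dataclass(frozen=True)
class MicrosimEstimate:
    arm: Arm
    n: int
    seed: int
    mean_cost: float
    mean_qalys: float
    se_cost: float
    se_qalys: float


def microsim_oracle(
    arm: Arm, params: ParameterSet, life_table: LifeTable, n: int, seed: int
) -> MicrosimEstimate:
    """Monte-Carlo estimate of discounted per-patient cost and QALYs.

    Simulates ``n`` independent patients through the monthly chain using the
    cohort engine's transition matrices and reward functions (shared code
    path), so agreement with :func:`prostate_cea.economics.accumulate`
    validates only the transition/expectation machinery.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    settings = params.settings
    life_table.require_coverage(settings.start_age, settings.horizon_years)
    H = settings.n_cycles
    rng = np.random.default_rng(seed)

    disc = economics.discount_factors(params, max(H, 1))
    U = economics.utility_matrix(arm, params, max(H, 1))
    adt_monthly = params.costs.adt_annual / 12.0
    ae_mgmt = {e: c for e, c in params.costs.ae_management.items() if c}

    qm = monthly_death_probs(params, life_table)
    state = np.full(n, int(HealthState.INITIAL_TREATMENT), dtype=np.int64)
    cost = np.zeros(n)
    qalys = np.zeros(n)
    if H > 0:
        cost += params.costs.upfront(arm)
    for t in range(H):
        # Accrue rewards on the state at cycle start (cohort convention).
        qalys += disc[t] * U[t, state] / 12.0
        on_adt = state == HealthState.ADT
        cost[on_adt] += disc[t] * adt_monthly
        if ae_mgmt:
            alive = state != HealthState.DEAD
            for event, c in ae_mgmt.items():
                cost[alive] += disc[t] * economics.ae_prevalence(arm, event, t, params) * c
        m = _transition_matrix(arm, params, qm[t])
        cum = np.cumsum(m, axis=1)
        u = rng.random(n)
        new_state = (u[:, None] > cum[state, :]).sum(axis=1)
        entered_failure = (new_state == HealthState.PSA_FAILURE) & (
            state != HealthState.PSA_FAILURE
        )
        if arm is Arm.RARP and t + 1 < H:
            # Salvage RT billed on entry into PSA failure, at the entry cycle
            # (entries at the final trace row fall outside the accrual window,
            # matching the cohort convention).
            cost[entered_failure] += disc[t + 1] * params.costs.salvage_rt
        state = new_state
    sd_cost = float(np.std(cost, ddof=1)) if n > 1 else 0.0
    sd_q = float(np.std(qalys, ddof=1)) if n > 1 else 0.0
    return MicrosimEstimate(
        arm=arm,
        n=n,
        seed=seed,
        mean_cost=float(cost.mean()),
        mean_qalys=float(qalys.mean()),
        se_cost=sd_cost / np.sqrt(n),
        se_qalys=sd_q / np.sqrt(n),
    )


def make_fixtures(out_dir: str | os.PathLike, *, seed: int = 0) -> dict[str, str]:
    """Write the default config, a calibrated synthetic life table and a
    default uncertainty spec into ``out_dir``; returns the file paths."""
    from .uncertainty import default_uncertainty_spec, write_uncertainty_spec

    os.makedirs(out_dir, exist_ok=True)
    paths = {
        "config": os.path.join(out_dir, "config.yaml"),
        "life_table": os.path.join(out_dir, "life_table.csv"),
        "uncertainty": os.path.join(out_dir, "uncertainty.yaml"),
    }
    params = default_parameters()
    with open(paths["config"], "w", encoding="utf-8") as fh:
        yaml.safe_dump(to_dict(params), fh, sort_keys=True)
    write_life_table(generate_life_table(default_life_table_spec()), paths["life_table"])
    write_uncertainty_spec(default_uncertainty_spec(params, seed=seed), paths["uncertainty"])
    return paths
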