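"""Scenario orchestration: base case, conventional fractionation, and the
sexual-dysfunction disutility-weight sweep, plus tabular report rendering.

RARP is always the reference strategy, so positive incrementals describe the
IMRT arm.  Every run report carries a provenance block (parameter digest,
life-table digest, timestamp) sufficient to re-run it bit-identically.
"""

from __future__ import annotations

import datetime as _dt
import hashlib
import json
import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import economics, uncertainty
from .economics import ArmResult, Comparison
from .markov import LifeTable, run_cohort
from .parameters import Arm, ParameterSet, jpy_to_usd, params_digest, set_params

__all__ = [
    "RunReport",
    "run_scenario",
    "run_base_case",
    "run_imrt38",
    "SweepRow",
    "sweep_sexual_disutility",
    "sweep_to_frame",
    "table_frame",
    "render_reports",
    "life_table_digest",
]


def life_table_digest(life_table: LifeTable) -> str:
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(life_table.ages).tobytes())
    h.update(np.ascontiguousarray(life_table.qx).tobytes())
    return h.hexdigest()


@dataclass(frozen=True)
class RunReport:
    label: str
    results: dict[Arm, ArmResult]
    comparison: Comparison
    provenance: dict


def run_scenario(
    label: str,
    alternative: Arm,
    params: ParameterSet,
    life_table: LifeTable,
) -> RunReport:
    """Run RARP and one IMRT arm under shared inputs and compare them."""
    results: dict[Arm, ArmResult] = {}
    for arm in (Arm.RARP, alternative):
        trace = run_cohort(arm, params, life_table)
        results[arm] = economics.accumulate(trace, arm, params)
    comparison = economics.compare(
        results[Arm.RARP], results[alternative], params.settings.wtp
    )
    provenance = {
        "label": label,
        "params_digest": params_digest(params),
        "life_table_digest": life_table_digest(life_table),
        "timestamp": _dt.datetime.now(_dt.timezone.utc).isoformat(),
    }
    return RunReport(label=label, results=results, comparison=comparison, provenance=provenance)


def run_base_case(params: ParameterSet, life_table: LifeTable) -> RunReport:
    """IMRT-20 (hypofractionated, 60 Gy/20 fx) versus RARP."""
    return run_scenario("base_case", Arm.IMRT20, params, life_table)


def run_imrt38(params: ParameterSet, life_table: LifeTable) -> RunReport:
    """IMRT-38 (conventional, 76 Gy/38 fx) versus RARP; differs from the base
    case only in the cycle-0 treatment cost."""
    return run_scenario("imrt38", Arm.IMRT38, params, life_table)


@dataclass(frozen=True)
class SweepRow:
    sexual_weight: float
    delta_cost: float
    delta_qalys: float
    icer: float | str
    inmb: float


def sweep_sexual_disutility(
    params: ParameterSet,
    weights: np.ndarray | list[float] | None = None,
    life_table: LifeTable | None = None,
) -> tuple[list[SweepRow], float | None]:
    """Rebuild the comparison at each sexual-dysfunction disutility weight.

    Returns the rows (ascending in weight) and the INMB zero-crossing weight,
    linearly interpolated at the first sign change (None when the INMB never
    changes sign on the grid).
    """
    if life_table is None:
        raise ValueError("life_table is required")
    if weights is None:
        # 0.0..1.0 in steps of 0.1, plus the reporting anchors 0.2 and 0.5
        # which the decade grid already contains.
        weights = np.round(np.arange(0.0, 1.0 + 1e-9, 0.1), 10)
    weights = np.asarray(weights, dtype=float)
    if np.any(weights < 0) or np.any(weights > 1) or np.any(np.diff(weights) <= 0):
        raise ValueError("weights must be an ascending grid within [0, 1]")
    rows: list[SweepRow] = []
    for w in weights:
        p_w = set_params(params, {"utilities.sexual_weight": float(w)})
        rep = run_scenario(f"sweep_w={w:g}", Arm.IMRT20, p_w, life_table)
        c = rep.comparison
        rows.append(SweepRow(float(w), c.delta_cost, c.delta_qalys, c.icer, c.inmb))
    crossing = None
    for lo, hi in zip(rows, rows[1:]):
        if lo.inmb == 0.0:
            crossing = lo.sexual_weight
            break
        if lo.inmb * hi.inmb < 0.0:
            frac = -lo.inmb / (hi.inmb - lo.inmb)
            crossing = lo.sexual_weight + frac * (hi.sexual_weight - lo.sexual_weight)
            break
    return rows, crossing


def sweep_to_frame(rows: list[SweepRow]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sexual_weight": [r.sexual_weight for r in rows],
            "delta_cost_jpy": [r.delta_cost for r in rows],
            "delta_qalys": [r.delta_qalys for r in rows],
            "icer": [r.icer for r in rows],
            "inmb_jpy": [r.inmb for r in rows],
        }
    )


def table_frame(reports: list[RunReport], jpy_per_usd: float = 152.0) -> pd.DataFrame:
    """Cost-effectiveness results table: one row per arm per scenario."""
    rows = []
    for rep in reports:
        ref = rep.comparison.reference
        for arm, res in rep.results.items():
            is_alt = arm is not ref
            rows.append(
                {
                    "scenario": rep.label,
                    "arm": arm.value,
                    "total_cost_jpy": res.total_cost,
                    "total_cost_usd": round(jpy_to_usd(res.total_cost, jpy_per_usd), 1),
                    "total_qalys": res.total_qalys,
                    "delta_cost_jpy": rep.comparison.delta_cost if is_alt else np.nan,
                    "delta_qalys": rep.comparison.delta_qalys if is_alt else np.nan,
                    "icer": rep.comparison.icer if is_alt else "",
                    "inmb_jpy": rep.comparison.inmb if is_alt else np.nan,
                }
            )
    return pd.DataFrame(rows)


def render_reports(
    out_dir: str | os.PathLike,
    *,
    reports: list[RunReport] | None = None,
    sweep_rows: list[SweepRow] | None = None,
    sweep_crossing: float | None = None,
    tornado: list[uncertainty.TornadoEntry] | None = None,
    prsa: uncertainty.PrSAResult | None = None,
    thresholds: np.ndarray | None = None,
    jpy_per_usd: float = 152.0,
) -> dict:
    """Write every supplied artifact as CSV plus a JSON run manifest.

    Emits (as applicable) ``table2.csv``, ``sweep.csv``, ``tornado.csv``,
    ``prsa_iterations.csv``, ``ceac.csv`` and ``manifest.json``; returns the
    manifest dict.
    """
    os.makedirs(out_dir, exist_ok=True)
    manifest: dict = {
        "written": [],
        "scenarios": [],
        "timestamp": _dt.datetime.now(_dt.timezone.utc).isoformat(),
    }

    def _write(name: str, frame: pd.DataFrame) -> None:
        path = os.path.join(out_dir, name)
        frame.to_csv(path, index=False)
        manifest["written"].append(name)

    if reports:
        _write("table2.csv", table_frame(reports, jpy_per_usd))
        manifest["scenarios"] = [rep.provenance for rep in reports]
    if sweep_rows:
        _write("sweep.csv", sweep_to_frame(sweep_rows))
        manifest["sweep_crossing_weight"] = sweep_crossing
    if tornado:
        _write("tornado.csv", uncertainty.tornado_to_frame(tornado))
    if prsa is not None:
        _write("prsa_iterations.csv", uncertainty.iterations_to_frame(prsa))
        _write("ceac.csv", uncertainty.ceac(prsa, thresholds))
        manifest["prsa"] = {
            "seed": prsa.seed,
            "n": prsa.n,
            "n_failed": prsa.n_failed,
            "wtp": prsa.wtp,
            "prob_cost_effective_at_wtp": prsa.prob_cost_effective_at_wtp,
        }
    with open(os.path.join(out_dir, "manifest.json"), "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, default=float)
    manifest["written"].append("manifest.json")
    return manifest
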