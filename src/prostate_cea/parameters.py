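"""Model inputs for the IMRT-vs-RARP cost-utility analysis.

All base-case inputs live here: clinical transition probabilities, adverse-event
(AE) prevalences and cure rates, unit costs in JPY from the 2024 Japanese fee
schedule, health-state utilities, and the model settings (discount rate, time
horizon, willingness-to-pay threshold, exchange rate).  The container is a
nested frozen dataclass that validates every field on construction, so any
`ParameterSet` reaching the engine is internally consistent.

Money is carried as floats in JPY at full precision; probabilities and
utilities are decimals in [0, 1].
"""

from __future__ import annotations

import copy
import dataclasses
import enum
import io
import os
from dataclasses import dataclass, field
from typing import Any, Mapping

import yaml

__all__ = [
    "Arm",
    "ARM_CLASS",
    "EVENTS",
    "ClinicalInputs",
    "CostInputs",
    "UtilityInputs",
    "ModelSettings",
    "ParameterSet",
    "default_parameters",
    "load_config",
    "to_dict",
    "from_dict",
    "get_param",
    "set_params",
    "annual_to_monthly_prob",
    "jpy_to_usd",
]


class Arm(str, enum.Enum):
    """Treatment strategy.

    The two IMRT arms differ only in the upfront treatment cost (20 vs 38
    fractions); RARP is robot-assisted radical prostatectomy.
    """

    IMRT20 = "IMRT20"
    IMRT38 = "IMRT38"
    RARP = "RARP"


#: Arm-class used to key AE prevalences: both IMRT fractionations share the
#: same toxicity profile.
ARM_CLASS: dict[Arm, str] = {Arm.IMRT20: "IMRT", Arm.IMRT38: "IMRT", Arm.RARP: "RARP"}

#: Adverse-event kinds tracked by the model.
EVENTS: tuple[str, ...] = ("urinary", "sexual", "gi")


def _check_prob(name: str, value: float) -> None:
    if not (0.0 <= value <= 1.0):
        raise ValueError(f"{name} must be in [0, 1], got {value!r}")


def _check_nonneg(name: str, value: float) -> None:
    if value < 0:
        raise ValueError(f"{name} must be non-negative, got {value!r}")


@dataclass(frozen=True)
class ClinicalInputs:
    """Transition probabilities and AE prevalences.

    ``ae_prevalence`` maps ``(arm_class, event)`` to the trial-reported
    prevalence at the stated follow-up (1 year for urinary/sexual, 3 years for
    gastrointestinal).  ``cure_*_rarp`` are the fractions of initially affected
    men recovering within the first postoperative year.
    """

    psa_control_imrt: float = 0.90
    psa_control_rarp: float = 0.90
    salvage_success: float = 0.50
    ae_prevalence: dict[tuple[str, str], float] = field(
        default_factory=lambda: {
            ("IMRT", "gi"): 0.098,
            ("IMRT", "urinary"): 0.031,
            ("IMRT", "sexual"): 0.389,
            ("RARP", "gi"): 0.0,
            ("RARP", "urinary"): 0.098,
            ("RARP", "sexual"): 0.540,
        }
    )
    cure_urinary_rarp: float = 0.645
    cure_sexual_rarp: float = 0.890
    late_failure_monthly_hazard: float = 0.0

    def __post_init__(self) -> None:
        for name in (
            "psa_control_imrt",
            "psa_control_rarp",
            "salvage_success",
            "cure_urinary_rarp",
            "cure_sexual_rarp",
            "late_failure_monthly_hazard",
        ):
            _check_prob(f"clinical.{name}", getattr(self, name))
        for (arm_class, event), p in self.ae_prevalence.items():
            if arm_class not in ("IMRT", "RARP") or event not in EVENTS:
                raise ValueError(f"unknown AE key ({arm_class!r}, {event!r})")
            _check_prob(f"clinical.ae_prevalence[{arm_class},{event}]", p)

    def psa_control(self, arm: Arm) -> float:
        return self.psa_control_rarp if arm is Arm.RARP else self.psa_control_imrt

    def cure_rate(self, event: str) -> float:
        """One-year RARP recovery fraction for an event (0 where unreported)."""
        return {"urinary": self.cure_urinary_rarp, "sexual": self.cure_sexual_rarp}.get(event, 0.0)


@dataclass(frozen=True)
class CostInputs:
    """Unit costs in JPY (2024 national fee schedule).

    ``ae_management`` is a per-event monthly management cost, zero by default
    because no AE-management tariff is tabulated.
    """

    imrt20_cost: float = 1_076_180.0
    imrt38_cost: float = 1_445_580.0
    rarp_surgery: float = 952_880.0
    rarp_hospitalization: float = 260_880.0
    rarp_anesthesia: float = 100_000.0
    salvage_rt: float = 1_265_110.0
    adt_annual: float = 224_690.0
    ae_management: dict[str, float] = field(
        default_factory=lambda: {"urinary": 0.0, "sexual": 0.0, "gi": 0.0}
    )

    def __post_init__(self) -> None:
        for f_ in dataclasses.fields(self):
            if f_.name == "ae_management":
                continue
            _check_nonneg(f"costs.{f_.name}", getattr(self, f_.name))
        for event, c in self.ae_management.items():
            if event not in EVENTS:
                raise ValueError(f"unknown AE management event {event!r}")
            _check_nonneg(f"costs.ae_management[{event}]", c)

    @property
    def rarp_upfront(self) -> float:
        """Total upfront RARP cost: surgery + hospitalization + anesthesia."""
        return self.rarp_surgery + self.rarp_hospitalization + self.rarp_anesthesia

    def upfront(self, arm: Arm) -> float:
        if arm is Arm.IMRT20:
            return self.imrt20_cost
        if arm is Arm.IMRT38:
            return self.imrt38_cost
        return self.rarp_upfront


@dataclass(frozen=True)
class UtilityInputs:
    """Health-state utility and additive decrements.

    ``sexual_weight`` scales the sexual-dysfunction decrement (the
    preference-sensitivity scenario sweeps it over [0, 1]).  ``dec_gi``
    defaults to 0: the gastrointestinal prevalence is tabulated but no matching
    decrement is, so a nonzero value must be supplied explicitly.
    """

    base_utility: float = 0.90
    dec_psa_failure: float = 0.17
    dec_urinary: float = 0.17
    dec_sexual: float = 0.11
    dec_gi: float = 0.0
    sexual_weight: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 < self.base_utility <= 1.0):
            raise ValueError(f"utilities.base_utility must be in (0, 1], got {self.base_utility!r}")
        for name in ("dec_psa_failure", "dec_urinary", "dec_sexual", "dec_gi"):
            v = getattr(self, name)
            if not (0.0 <= v <= self.base_utility):
                raise ValueError(f"utilities.{name} must be in [0, base_utility], got {v!r}")
        _check_prob("utilities.sexual_weight", self.sexual_weight)

    def decrement(self, event: str) -> float:
        if event == "urinary":
            return self.dec_urinary
        if event == "sexual":
            return self.dec_sexual * self.sexual_weight
        if event == "gi":
            return self.dec_gi
        raise ValueError(f"unknown event {event!r}")


@dataclass(frozen=True)
class ModelSettings:
    """Run settings: discounting, horizon, threshold, exchange rate.

    ``ae_duration_months`` gives the month after which an event stops
    contributing (``None`` = persists for the whole horizon; GI symptoms stop
    after month 36 to mirror the 3-year reporting window).
    """

    annual_discount: float = 0.02
    horizon_years: int = 20
    cycle_length_months: int = 1
    start_age: int = 65
    wtp: float = 5_000_000.0
    jpy_per_usd: float = 152.0
    ae_duration_months: dict[str, int | None] = field(
        default_factory=lambda: {"urinary": None, "sexual": None, "gi": 36}
    )
    half_cycle_correction: bool = False
    multiplicative_decrements: bool = False

    def __post_init__(self) -> None:
        if self.horizon_years < 0:
            raise ValueError(f"settings.horizon_years must be >= 0, got {self.horizon_years!r}")
        if self.annual_discount < 0:
            raise ValueError(f"settings.annual_discount must be >= 0, got {self.annual_discount!r}")
        if self.wtp <= 0:
            raise ValueError(f"settings.wtp must be > 0, got {self.wtp!r}")
        if self.cycle_length_months != 1:
            raise ValueError("settings.cycle_length_months is fixed at 1")
        if self.jpy_per_usd <= 0:
            raise ValueError(f"settings.jpy_per_usd must be > 0, got {self.jpy_per_usd!r}")
        for event in self.ae_duration_months:
            if event not in EVENTS:
                raise ValueError(f"unknown AE duration event {event!r}")

    @property
    def n_cycles(self) -> int:
        """Number of monthly cycles H; the trace has H + 1 rows."""
        return 12 * self.horizon_years


@dataclass(frozen=True)
class ParameterSet:
    clinical: ClinicalInputs = field(default_factory=ClinicalInputs)
    costs: CostInputs = field(default_factory=CostInputs)
    utilities: UtilityInputs = field(default_factory=UtilityInputs)
    settings: ModelSettings = field(default_factory=ModelSettings)


def default_parameters() -> ParameterSet:
    """The complete base case: every tabulated input at its printed value."""
    return ParameterSet()


# ---------------------------------------------------------------------------
# config serialization


def _ae_prev_to_nested(prev: Mapping[tuple[str, str], float]) -> dict[str, dict[str, float]]:
    out: dict[str, dict[str, float]] = {}
    for (arm_class, event), p in sorted(prev.items()):
        out.setdefault(arm_class, {})[event] = p
    return out


def _ae_prev_from_nested(nested: Mapping[str, Mapping[str, float]]) -> dict[tuple[str, str], float]:
    return {
        (arm_class, event): float(p)
        for arm_class, events in nested.items()
        for event, p in events.items()
    }


def to_dict(params: ParameterSet) -> dict[str, Any]:
    """Plain nested-dict form of a ParameterSet (YAML/JSON friendly)."""
    d = dataclasses.asdict(params)
    d["clinical"]["ae_prevalence"] = _ae_prev_to_nested(params.clinical.ae_prevalence)
    return d


def from_dict(doc: Mapping[str, Any]) -> ParameterSet:
    """Build a validated ParameterSet from a full nested dict (see to_dict)."""
    doc = copy.deepcopy(dict(doc))
    clin = dict(doc.get("clinical", {}))
    if "ae_prevalence" in clin:
        clin["ae_prevalence"] = _ae_prev_from_nested(clin["ae_prevalence"])
    sections = {
        "clinical": (ClinicalInputs, clin),
        "costs": (CostInputs, dict(doc.get("costs", {}))),
        "utilities": (UtilityInputs, dict(doc.get("utilities", {}))),
        "settings": (ModelSettings, dict(doc.get("settings", {}))),
    }
    unknown_sections = set(doc) - set(sections)
    if unknown_sections:
        raise ValueError(f"unknown config sections: {sorted(unknown_sections)}")
    built = {}
    for name, (cls, values) in sections.items():
        known = {f_.name for f_ in dataclasses.fields(cls)}
        unknown = set(values) - known
        if unknown:
            raise ValueError(f"unknown keys in section {name!r}: {sorted(unknown)}")
        built[name] = cls(**values)
    return ParameterSet(**built)


def _deep_merge(base: dict[str, Any], override: Mapping[str, Any]) -> dict[str, Any]:
    out = copy.deepcopy(base)
    for k, v in override.items():
        if isinstance(v, Mapping) and isinstance(out.get(k), dict):
            out[k] = _deep_merge(out[k], v)
        else:
            out[k] = copy.deepcopy(v)
    return out


def load_config(source: Any) -> ParameterSet:
    """Load a YAML/JSON config and overlay it on the defaults.

    ``source`` may be a path, an open text stream, a YAML string, or an
    already-parsed mapping.  Only keys present in the document override the
    base case; unknown keys raise ``ValueError``.
    """
    if isinstance(source, Mapping):
        doc = dict(source)
    else:
        if isinstance(source, (str, os.PathLike)) and os.path.exists(source):
            with open(source, "r", encoding="utf-8") as fh:
                doc = yaml.safe_load(fh)
        elif isinstance(source, io.IOBase) or hasattr(source, "read"):
            doc = yaml.safe_load(source)
        else:
            doc = yaml.safe_load(source)
    if doc is None:
        doc = {}
    if not isinstance(doc, Mapping):
        raise ValueError("config document must be a mapping at top level")
    merged = _deep_merge(to_dict(default_parameters()), doc)
    return from_dict(merged)


# ---------------------------------------------------------------------------
# dotted-path access (used by the sensitivity-analysis machinery)


def get_param(params: ParameterSet, path: str) -> float:
    """Read a scalar by dotted path, e.g. ``"costs.imrt20_cost"`` or
    ``"clinical.ae_prevalence.RARP.sexual"``."""
    d: Any = to_dict(params)
    for part in path.split("."):
        try:
            d = d[part]
        except (KeyError, TypeError) as exc:
            raise KeyError(f"no parameter at path {path!r}") from exc
    if not isinstance(d, (int, float)) or isinstance(d, bool):
        raise KeyError(f"path {path!r} does not address a scalar")
    return float(d)


def set_params(params: ParameterSet, updates: Mapping[str, float]) -> ParameterSet:
    """Return a new validated ParameterSet with dotted-path overrides applied.

    The pseudo-path ``"clinical.psa_control"`` sets both arms' PSA-control
    probabilities at once (they share a single evidence source).
    """
    doc = to_dict(params)
    for path, value in updates.items():
        if path == "clinical.psa_control":
            doc["clinical"]["psa_control_imrt"] = float(value)
            doc["clinical"]["psa_control_rarp"] = float(value)
            continue
        parts = path.split(".")
        d = doc
        for part in parts[:-1]:
            if not isinstance(d, dict) or part not in d:
                raise KeyError(f"no parameter at path {path!r}")
            d = d[part]
        if not isinstance(d, dict) or parts[-1] not in d:
            raise KeyError(f"no parameter at path {path!r}")
        d[parts[-1]] = float(value)
    return from_dict(doc)


def params_digest(params: ParameterSet) -> str:
    """Stable content hash of a ParameterSet (provenance for run manifests)."""
    import hashlib
    import json

    blob = json.dumps(to_dict(params), sort_keys=True, default=float).encode()
    return hashlib.sha256(blob).hexdigest()


# ---------------------------------------------------------------------------
# unit conversions


def annual_to_monthly_prob(q_annual: float) -> float:
    """Convert an annual probability to the per-month probability that
    compounds back to it over 12 cycles: ``1 - (1 - q)**(1/12)``."""
    if not (0.0 <= q_annual <= 1.0):
        raise ValueError(f"annual probability must be in [0, 1], got {q_annual!r}")
    return 1.0 - (1.0 - q_annual) ** (1.0 / 12.0)


def jpy_to_usd(amount_jpy: float, rate: float = 152.0) -> float:
    """Convert JPY to USD at the configured exchange rate (152 JPY/USD)."""
    return amount_jpy / rate
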