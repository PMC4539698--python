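"""Model inputs: domain types, configuration I/O, validation and derived
quantities.

The cohort model is parameterised by three-month transition matrices between
GOLD severity states (conditional on survival), three-month probabilities of
exacerbation events within each state, per-cycle direct costs and annual
utility weights for each state-event combination, drug acquisition costs, and
economic settings (discount rate, start age, treatment duration, initial GOLD
distribution).

All probabilities indexed by GOLD state use the fixed order
``[GOLD II, GOLD III, GOLD IV]``; event-indexed tables use
``[no exacerbation, non-severe exacerbation, severe exacerbation]``.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import yaml

from .mortality import BackgroundMortalityModel, CalibrationAnchors, ExcessMortalityConfig

__all__ = [
    "GoldState",
    "EventType",
    "TreatmentPhase",
    "ALIVE_STATES",
    "EVENTS",
    "ARMS",
    "TransitionMatrix",
    "ExacerbationRiskTable",
    "CostTable",
    "UtilityTable",
    "RelativeRisk",
    "EconomicSettings",
    "ModelParameters",
    "ValidationError",
    "load_parameters",
    "save_parameters",
    "parameters_to_dict",
    "normalize_event_row",
    "derive_comparator_events",
    "annual_to_cycle_probability",
    "cycle_to_annual_probability",
    "discount_factor",
    "drug_cost_per_cycle",
]


class GoldState(Enum):
    """Model health states: GOLD severity grades II-IV plus absorbing death."""

    GOLD_II = 0
    GOLD_III = 1
    GOLD_IV = 2
    DEAD = 3


class EventType(Enum):
    """Mutually exclusive within-cycle events."""

    NO_EXAC = 0
    NONSEV_EXAC = 1
    SEV_EXAC = 2


class TreatmentPhase(Enum):
    """Treatment phase of a cycle.

    The first cycle carries its own transition matrix (capturing the initial
    bronchodilator response); later cycles use the subsequent-treatment matrix
    until treatment stops, after which usual-care inputs apply.
    """

    FIRST_CYCLE = "first_cycle"
    ON_TREATMENT = "on_treatment"
    OFF_TREATMENT = "off_treatment"


ALIVE_STATES = (GoldState.GOLD_II, GoldState.GOLD_III, GoldState.GOLD_IV)
EVENTS = (EventType.NO_EXAC, EventType.NONSEV_EXAC, EventType.SEV_EXAC)
ARMS = ("UC", "TIO", "GLY")

_STATE_NAMES = ("GOLD II", "GOLD III", "GOLD IV")
_ROW_SUM_TOL = 0.02  # tolerance for rounded published rows before renormalising


class ValidationError(ValueError):
    """Raised when a parameter set violates its invariants.

    Collects *every* violation found so a malformed configuration can be fixed
    in one pass; ``violations`` is a list of human-readable messages.
    """

    def __init__(self, violations: list[str]):
        self.violations = list(violations)
        super().__init__(
            "parameter validation failed:\n  - " + "\n  - ".join(self.violations)
        )


def _as_matrix(values: Any, name: str, shape: tuple[int, int]) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.shape != shape:
        raise ValidationError([f"{name}: expected shape {shape}, got {arr.shape}"])
    return arr


@dataclass(frozen=True)
class TransitionMatrix:
    """3x3 three-month transition probabilities between alive GOLD states,
    conditional on surviving the cycle (death is handled separately)."""

    entries: np.ndarray

    def __post_init__(self) -> None:
        arr = _as_matrix(self.entries, "transition matrix", (3, 3))
        arr.flags.writeable = False
        object.__setattr__(self, "entries", arr)

    def validate(self, name: str = "transition matrix") -> list[str]:
        errs = []
        for i, row in enumerate(self.entries):
            if np.any(row < 0) or np.any(row > 1):
                errs.append(f"{name}, row {_STATE_NAMES[i]}: entries outside [0, 1]")
            if abs(row.sum() - 1.0) > _ROW_SUM_TOL:
                errs.append(
                    f"{name}, row {_STATE_NAMES[i]}: sums to {row.sum():.4f}, "
                    f"expected 1 within {_ROW_SUM_TOL}"
                )
        return errs

    def normalized(self) -> "TransitionMatrix":
        """Return a copy with rows rescaled to sum to exactly 1."""
        return TransitionMatrix(self.entries / self.entries.sum(axis=1, keepdims=True))


@dataclass(frozen=True)
class ExacerbationRiskTable:
    """Three-month event probabilities per alive state (state x event)."""

    probabilities: np.ndarray

    def __post_init__(self) -> None:
        arr = _as_matrix(self.probabilities, "exacerbation table", (3, 3))
        arr.flags.writeable = False
        object.__setattr__(self, "probabilities", arr)

    @classmethod
    def from_nonsev_sev(cls, nonsev, sev) -> "ExacerbationRiskTable":
        """Build from non-severe and severe probabilities per state; the
        no-exacerbation probability is the residual complement."""
        rows = [normalize_event_row(ns, s) for ns, s in zip(nonsev, sev, strict=True)]
        return cls(np.asarray(rows))

    def validate(self, name: str = "exacerbation table") -> list[str]:
        errs = []
        for i, row in enumerate(self.probabilities):
            if np.any(row < 0) or np.any(row > 1):
                errs.append(f"{name}, state {_STATE_NAMES[i]}: entries outside [0, 1]")
            if abs(row.sum() - 1.0) > 1e-9:
                errs.append(
                    f"{name}, state {_STATE_NAMES[i]}: event probabilities sum to "
                    f"{row.sum():.6f}, expected 1"
                )
        return errs


@dataclass(frozen=True)
class CostTable:
    """Direct cost (SEK 2014) per cycle for each state-event combination.

    Each cell is the three-month maintenance cost of the GOLD state plus the
    cost of the event experienced in the cycle (zero extra for no
    exacerbation); published as merged totals.
    """

    direct_cost: np.ndarray

    def __post_init__(self) -> None:
        arr = _as_matrix(self.direct_cost, "cost table", (3, 3))
        arr.flags.writeable = False
        object.__setattr__(self, "direct_cost", arr)

    def validate(self, name: str = "cost table") -> list[str]:
        errs = []
        if np.any(self.direct_cost < 0):
            errs.append(f"{name}: negative costs")
        c = self.direct_cost
        for i in range(3):
            if not (c[i, 2] >= c[i, 1] >= c[i, 0]):
                errs.append(
                    f"{name}, state {_STATE_NAMES[i]}: expected severe >= "
                    f"non-severe >= no-exacerbation cost"
                )
        return errs


@dataclass(frozen=True)
class UtilityTable:
    """Annual utility weight for each state-event combination (dimensionless,
    in [0, 1]); QALY accrual per cycle is weight x cycle length."""

    annual_weight: np.ndarray

    def __post_init__(self) -> None:
        arr = _as_matrix(self.annual_weight, "utility table", (3, 3))
        arr.flags.writeable = False
        object.__setattr__(self, "annual_weight", arr)

    def validate(self, name: str = "utility table") -> list[str]:
        errs = []
        if np.any(self.annual_weight < 0) or np.any(self.annual_weight > 1):
            errs.append(f"{name}: weights outside [0, 1]")
        u = self.annual_weight
        for i in range(3):
            if not (u[i, 0] >= u[i, 1] >= u[i, 2]):
                errs.append(
                    f"{name}, state {_STATE_NAMES[i]}: expected no-exacerbation >= "
                    f"non-severe >= severe weight"
                )
        return errs


@dataclass(frozen=True)
class RelativeRisk:
    """A relative risk with its 95% confidence interval."""

    point: float
    ci_low: float
    ci_high: float

    def validate(self, name: str = "relative risk") -> list[str]:
        if not (0 < self.ci_low <= self.point <= self.ci_high):
            return [f"{name}: requires 0 < ci_low <= point <= ci_high"]
        return []


@dataclass(frozen=True)
class EconomicSettings:
    """Run settings: discounting, ages, treatment duration, drug prices and
    the initial GOLD distribution of the cohort."""

    discount_rate_annual: float
    cycle_length_years: float
    start_age_years: float
    max_age_years: float
    treatment_duration_years: float
    drug_cost_per_day: Mapping[str, float]
    initial_distribution: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.initial_distribution, dtype=float)
        arr.flags.writeable = False
        object.__setattr__(self, "initial_distribution", arr)
        object.__setattr__(self, "drug_cost_per_day", dict(self.drug_cost_per_day))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, EconomicSettings):
            return NotImplemented
        return (
            self.discount_rate_annual == other.discount_rate_annual
            and self.cycle_length_years == other.cycle_length_years
            and self.start_age_years == other.start_age_years
            and self.max_age_years == other.max_age_years
            and self.treatment_duration_years == other.treatment_duration_years
            and self.drug_cost_per_day == other.drug_cost_per_day
            and np.array_equal(self.initial_distribution, other.initial_distribution)
        )

    @property
    def horizon_years(self) -> float:
        return self.max_age_years - self.start_age_years

    @property
    def n_cycles(self) -> int:
        return int(round(self.horizon_years / self.cycle_length_years))

    def validate(self) -> list[str]:
        errs = []
        if self.discount_rate_annual < 0:
            errs.append("settings: discount rate must be >= 0")
        if self.cycle_length_years <= 0:
            errs.append("settings: cycle length must be > 0")
        else:
            for what, years in (
                ("treatment duration", self.treatment_duration_years),
                ("horizon", self.horizon_years),
            ):
                n = years / self.cycle_length_years
                if abs(n - round(n)) > 1e-9:
                    errs.append(
                        f"settings: cycle length does not divide {what} "
                        f"({years} y) into whole cycles"
                    )
        if self.initial_distribution.shape != (3,):
            errs.append("settings: initial distribution must have three entries")
        elif abs(self.initial_distribution.sum() - 1.0) > 1e-9 or np.any(
            self.initial_distribution < 0
        ):
            errs.append(
                "settings: initial distribution must be non-negative and sum to 1"
            )
        if set(self.drug_cost_per_day) != set(ARMS):
            errs.append(f"settings: drug costs must be given for arms {ARMS}")
        elif any(v < 0 for v in self.drug_cost_per_day.values()):
            errs.append("settings: drug costs must be >= 0")
        if self.max_age_years <= self.start_age_years:
            errs.append("settings: max age must exceed start age")
        return errs


@dataclass(frozen=True)
class ModelParameters:
    """Complete, validated input set for one scenario.

    ``transitions[arm][phase]`` holds per-arm transition matrices with phase
    keys ``"first_cycle"`` and ``"subsequent"``; ``exacerbations[arm]`` holds
    the on-treatment event tables (usual care's table doubles as the
    off-treatment table for the active arms when
    ``revert_event_risks_off_treatment`` is set).
    """

    transitions: Mapping[str, Mapping[str, TransitionMatrix]]
    exacerbations: Mapping[str, ExacerbationRiskTable]
    costs: CostTable
    utilities: UtilityTable
    settings: EconomicSettings
    rr_severe_gly_vs_tio: RelativeRisk
    background_mortality: BackgroundMortalityModel
    excess_mortality: ExcessMortalityConfig
    revert_event_risks_off_treatment: bool = True
    anchors: CalibrationAnchors | None = None

    def validate(self) -> list[str]:
        errs: list[str] = []
        for arm in ARMS:
            if arm not in self.transitions:
                errs.append(f"transitions: missing arm {arm}")
                continue
            for phase in ("first_cycle", "subsequent"):
                if phase not in self.transitions[arm]:
                    errs.append(f"transitions[{arm}]: missing phase {phase}")
                else:
                    errs += self.transitions[arm][phase].validate(
                        f"transitions[{arm}][{phase}]"
                    )
        for arm in ARMS:
            if arm not in self.exacerbations:
                errs.append(f"exacerbations: missing arm {arm}")
            else:
                errs += self.exacerbations[arm].validate(f"exacerbations[{arm}]")
        errs += self.costs.validate("costs")
        errs += self.utilities.validate("utilities")
        errs += self.settings.validate()
        errs += self.rr_severe_gly_vs_tio.validate("rr_severe_gly_vs_tio")
        errs += self.background_mortality.validate()
        errs += self.excess_mortality.validate()
        if self.anchors is not None:
            errs += self.anchors.validate()
        return errs

    def replace(self, **changes: Any) -> "ModelParameters":
        return dataclasses.replace(self, **changes)


# ---------------------------------------------------------------------------
# derived-quantity helpers


def normalize_event_row(nonsev: float, sev: float) -> tuple[float, float, float]:
    """Complete an event-probability row from its non-severe and severe
    probabilities; no-exacerbation is the residual so the row sums to 1.

    Published rows are rounded to two decimals and may not sum to one; the
    residual convention keeps the cost- and mortality-bearing probabilities
    exactly as given.
    """
    if nonsev < 0 or sev < 0:
        raise ValueError("event probabilities must be >= 0")
    if nonsev + sev > 1 + 1e-12:
        raise ValueError(f"non-severe + severe probability exceeds 1 ({nonsev + sev})")
    return (1.0 - nonsev - sev, nonsev, sev)


def derive_comparator_events(
    tio_table: ExacerbationRiskTable, rr_sev: float, rr_nonsev: float = 1.0
) -> ExacerbationRiskTable:
    """Derive a comparator event table by scaling the tiotropium-arm baseline
    risks with relative risks (severe and, optionally, non-severe).

    Used to construct the glycopyrronium table from the head-to-head severe
    exacerbation RR, and to re-derive it when that RR is varied in
    sensitivity analyses.
    """
    if rr_sev < 0 or rr_nonsev < 0:
        raise ValueError("relative risks must be >= 0")
    p = tio_table.probabilities
    nonsev = p[:, 1] * rr_nonsev
    sev = np.minimum(1.0, p[:, 2] * rr_sev)
    if np.any(nonsev + sev > 1 + 1e-12):
        raise ValueError(
            "scaled event probabilities exceed 1; relative risk too large "
            f"(non-severe + severe = {(nonsev + sev).max():.4f})"
        )
    return ExacerbationRiskTable.from_nonsev_sev(nonsev, sev)


def annual_to_cycle_probability(p_annual: float, cycle_length_years: float) -> float:
    """Convert an annual probability to a per-cycle probability assuming a
    constant hazard within the year: 1 - (1 - p)^L."""
    if not 0 <= p_annual <= 1:
        raise ValueError(f"probability outside [0, 1]: {p_annual}")
    return 1.0 - (1.0 - p_annual) ** cycle_length_years


def cycle_to_annual_probability(p_cycle: float, cycle_length_years: float) -> float:
    """Inverse of :func:`annual_to_cycle_probability`."""
    if not 0 <= p_cycle <= 1:
        raise ValueError(f"probability outside [0, 1]: {p_cycle}")
    return 1.0 - (1.0 - p_cycle) ** (1.0 / cycle_length_years)


def discount_factor(
    annual_rate: float, cycle_index: int, cycle_length_years: float
) -> float:
    """Per-cycle discount factor, first cycle undiscounted:
    (1 + r)^(-(k - 1) * L)."""
    if annual_rate < 0:
        raise ValueError("discount rate must be >= 0")
    if cycle_index < 1:
        raise ValueError("cycle index starts at 1")
    return (1.0 + annual_rate) ** (-(cycle_index - 1) * cycle_length_years)


def drug_cost_per_cycle(settings: EconomicSettings, arm: str) -> float:
    """Drug acquisition cost per cycle: daily price x 365.25 x cycle length."""
    return settings.drug_cost_per_day[arm] * 365.25 * settings.cycle_length_years


# ---------------------------------------------------------------------------
# configuration I/O

_TOP_KEYS = {
    "settings",
    "drug_cost_per_day",
    "transitions",
    "exacerbations",
    "costs_sek_per_cycle",
    "utility_weights_annual",
    "relative_risk_severe_gly_vs_tio",
    "mortality",
    "options",
    "calibration_anchors",
}
_EVENT_KEYS = ("no_exacerbation", "nonsevere_exacerbation", "severe_exacerbation")


def _check_keys(mapping: Mapping, allowed: set[str], where: str, errs: list[str]):
    unknown = set(mapping) - allowed
    if unknown:
        errs.append(f"{where}: unknown keys {sorted(unknown)}")
    return errs


def _require(mapping: Mapping, key: str, where: str, errs: list[str]):
    if key not in mapping:
        errs.append(f"{where}: missing required key '{key}'")
        return None
    return mapping[key]


def load_parameters(config_source: str | Path | Mapping) -> ModelParameters:
    """Load and validate a complete parameter set.

    ``config_source`` may be a mapping, a YAML/JSON file path, or YAML/JSON
    text.  Unknown keys are rejected by name; all invariant violations are
    collected into a single :class:`ValidationError`.
    """
    raw = _read_config(config_source)
    errs: list[str] = []
    _check_keys(raw, _TOP_KEYS, "top level", errs)

    missing = [
        k for k in _TOP_KEYS - {"options", "calibration_anchors"} if k not in raw
    ]
    if missing:
        errs += [f"top level: missing required key '{k}'" for k in sorted(missing)]
        raise ValidationError(errs)

    try:
        s = raw["settings"]
        _check_keys(
            s,
            {
                "discount_rate_annual",
                "cycle_length_years",
                "start_age_years",
                "max_age_years",
                "treatment_duration_years",
                "initial_distribution",
            },
            "settings",
            errs,
        )
        settings = EconomicSettings(
            discount_rate_annual=float(s["discount_rate_annual"]),
            cycle_length_years=float(s["cycle_length_years"]),
            start_age_years=float(s["start_age_years"]),
            max_age_years=float(s["max_age_years"]),
            treatment_duration_years=float(s["treatment_duration_years"]),
            drug_cost_per_day={k: float(v) for k, v in raw["drug_cost_per_day"].items()},
            initial_distribution=np.asarray(s["initial_distribution"], dtype=float),
        )

        transitions: dict[str, dict[str, TransitionMatrix]] = {}
        for arm, phases in raw["transitions"].items():
            if arm not in ARMS:
                errs.append(f"transitions: unknown arm '{arm}'")
                continue
            _check_keys(phases, {"first_cycle", "subsequent"}, f"transitions[{arm}]", errs)
            transitions[arm] = {
                phase: TransitionMatrix(np.asarray(mat, dtype=float))
                for phase, mat in phases.items()
            }

        exacerbations: dict[str, ExacerbationRiskTable] = {}
        for arm, tab in raw["exacerbations"].items():
            if arm not in ARMS:
                errs.append(f"exacerbations: unknown arm '{arm}'")
                continue
            _check_keys(tab, {"nonsevere", "severe"}, f"exacerbations[{arm}]", errs)
            try:
                exacerbations[arm] = ExacerbationRiskTable.from_nonsev_sev(
                    tab["nonsevere"], tab["severe"]
                )
            except ValueError as e:
                errs.append(f"exacerbations[{arm}]: {e}")

        costs = CostTable(np.asarray(
            [raw["costs_sek_per_cycle"][k] for k in _EVENT_KEYS], dtype=float
        ).T)
        utilities = UtilityTable(np.asarray(
            [raw["utility_weights_annual"][k] for k in _EVENT_KEYS], dtype=float
        ).T)

        rr_raw = raw["relative_risk_severe_gly_vs_tio"]
        _check_keys(rr_raw, {"point", "ci_low", "ci_high"}, "relative_risk", errs)
        rr = RelativeRisk(
            float(rr_raw["point"]), float(rr_raw["ci_low"]), float(rr_raw["ci_high"])
        )

        mort = raw["mortality"]
        _check_keys(mort, {"background", "excess"}, "mortality", errs)
        bg_raw = dict(mort["background"])
        _check_keys(
            bg_raw,
            {"makeham_a", "gompertz_b", "gompertz_c", "copd_death_fraction"},
            "mortality.background",
            errs,
        )
        background = BackgroundMortalityModel(
            makeham_a=float(bg_raw["makeham_a"]),
            gompertz_b=float(bg_raw["gompertz_b"]),
            gompertz_c=float(bg_raw["gompertz_c"]),
            copd_death_fraction=float(bg_raw["copd_death_fraction"]),
        )
        ex_raw = dict(mort["excess"])
        _check_keys(
            ex_raw,
            {
                "state_rr",
                "state_age_gradient",
                "sevex_base_excess",
                "sevex_age_gradient",
                "reference_age",
                "state_scale",
                "sevex_scale",
            },
            "mortality.excess",
            errs,
        )
        excess = ExcessMortalityConfig(
            state_rr=tuple(float(v) for v in ex_raw["state_rr"]),
            state_age_gradient=float(ex_raw["state_age_gradient"]),
            sevex_base_excess=float(ex_raw["sevex_base_excess"]),
            sevex_age_gradient=float(ex_raw["sevex_age_gradient"]),
            reference_age=float(ex_raw.get("reference_age", 65.0)),
            state_scale=float(ex_raw.get("state_scale", 1.0)),
            sevex_scale=float(ex_raw.get("sevex_scale", 1.0)),
        )

        options = raw.get("options", {})
        _check_keys(options, {"revert_event_risks_off_treatment"}, "options", errs)

        anchors = None
        if "calibration_anchors" in raw:
            a = raw["calibration_anchors"]
            _check_keys(
                a,
                {"uc_discounted_ly", "gly_discounted_ly", "discount_rate_annual"},
                "calibration_anchors",
                errs,
            )
            anchors = CalibrationAnchors(
                uc_discounted_ly=float(a["uc_discounted_ly"]),
                gly_discounted_ly=float(a["gly_discounted_ly"]),
                discount_rate=float(a["discount_rate_annual"]),
            )
    except (KeyError, TypeError, ValueError) as e:
        if isinstance(e, ValidationError):
            raise
        errs.append(f"malformed configuration: {e!r}")
        raise ValidationError(errs) from e

    params = ModelParameters(
        transitions=transitions,
        exacerbations=exacerbations,
        costs=costs,
        utilities=utilities,
        settings=settings,
        rr_severe_gly_vs_tio=rr,
        background_mortality=background,
        excess_mortality=excess,
        revert_event_risks_off_treatment=bool(
            options.get("revert_event_risks_off_treatment", True)
        ),
        anchors=anchors,
    )
    errs += params.validate()
    if errs:
        raise ValidationError(errs)
    # renormalise transition rows exactly to 1 (rounded published inputs)
    transitions_n = {
        arm: {ph: m.normalized() for ph, m in phases.items()}
        for arm, phases in transitions.items()
    }
    return params.replace(transitions=transitions_n)


def _read_config(source: str | Path | Mapping) -> Mapping:
    if isinstance(source, Mapping):
        return source
    if isinstance(source, Path) or (
        isinstance(source, str) and "\n" not in source and Path(source).exists()
    ):
        text = Path(source).read_text()
    else:
        text = str(source)
    if text.lstrip().startswith("{"):
        return json.loads(text)
    return yaml.safe_load(text)


def parameters_to_dict(params: ModelParameters) -> dict:
    """Serialise a parameter set to the configuration schema (plain types,
    full float precision; round-trips through :func:`load_parameters`)."""
    s = params.settings
    out: dict[str, Any] = {
        "settings": {
            "discount_rate_annual": s.discount_rate_annual,
            "cycle_length_years": s.cycle_length_years,
            "start_age_years": s.start_age_years,
            "max_age_years": s.max_age_years,
            "treatment_duration_years": s.treatment_duration_years,
            "initial_distribution": [float(x) for x in s.initial_distribution],
        },
        "drug_cost_per_day": {k: float(v) for k, v in s.drug_cost_per_day.items()},
        "transitions": {
            arm: {ph: m.entries.tolist() for ph, m in phases.items()}
            for arm, phases in params.transitions.items()
        },
        "exacerbations": {
            arm: {
                "nonsevere": tab.probabilities[:, 1].tolist(),
                "severe": tab.probabilities[:, 2].tolist(),
            }
            for arm, tab in params.exacerbations.items()
        },
        "costs_sek_per_cycle": {
            k: params.costs.direct_cost[:, j].tolist()
            for j, k in enumerate(_EVENT_KEYS)
        },
        "utility_weights_annual": {
            k: params.utilities.annual_weight[:, j].tolist()
            for j, k in enumerate(_EVENT_KEYS)
        },
        "relative_risk_severe_gly_vs_tio": {
            "point": params.rr_severe_gly_vs_tio.point,
            "ci_low": params.rr_severe_gly_vs_tio.ci_low,
            "ci_high": params.rr_severe_gly_vs_tio.ci_high,
        },
        "mortality": {
            "background": {
                "makeham_a": params.background_mortality.makeham_a,
                "gompertz_b": params.background_mortality.gompertz_b,
                "gompertz_c": params.background_mortality.gompertz_c,
                "copd_death_fraction": params.background_mortality.copd_death_fraction,
            },
            "excess": {
                "state_rr": list(params.excess_mortality.state_rr),
                "state_age_gradient": params.excess_mortality.state_age_gradient,
                "sevex_base_excess": params.excess_mortality.sevex_base_excess,
                "sevex_age_gradient": params.excess_mortality.sevex_age_gradient,
                "reference_age": params.excess_mortality.reference_age,
                "state_scale": params.excess_mortality.state_scale,
                "sevex_scale": params.excess_mortality.sevex_scale,
            },
        },
        "options": {
            "revert_event_risks_off_treatment": params.revert_event_risks_off_treatment
        },
    }
    if params.anchors is not None:
        out["calibration_anchors"] = {
            "uc_discounted_ly": params.anchors.uc_discounted_ly,
            "gly_discounted_ly": params.anchors.gly_discounted_ly,
            "discount_rate_annual": params.anchors.discount_rate,
        }
    return out


def save_parameters(params: ModelParameters, path: str | Path) -> None:
    """Write a parameter set to YAML or JSON (chosen by file extension)."""
    path = Path(path)
    data = parameters_to_dict(params)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(data, indent=2))
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=False))
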