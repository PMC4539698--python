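"""Deterministic cohort simulation.

Propagates a probability mass over {GOLD II, III, IV, DEAD} in three-month
cycles.  Within each cycle, per alive state: (1) the mass splits across the
three exacerbation events; (2) the cycle's cost, utility and life-time are
accrued for the full cycle (patients dying within the cycle still accrue it,
including the hospitalisation cost of a fatal severe exacerbation); (3) the
state- and age-specific death probability is applied, with the additive
severe-exacerbation excess for the severe fraction; (4) survivors move
between GOLD states by the phase-appropriate transition matrix, which is
conditional on survival and therefore applied without renormalisation.

Active arms use their own transition matrices and event tables during the
first cycle and while on treatment; after treatment stops both revert to
usual-care inputs (event-risk reversion is configurable).  Costs and effects
are discounted per cycle with the first cycle undiscounted; event counts and
person-years accumulate undiscounted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .mortality import MortalitySchedule
from .parameters import (
    ARMS,
    EventType,
    ModelParameters,
    TreatmentPhase,
    discount_factor,
    drug_cost_per_cycle,
)

__all__ = [
    "CohortState",
    "CycleInputs",
    "CycleAccrual",
    "ArmResult",
    "treatment_phase",
    "resolve_cycle_inputs",
    "step_cycle",
    "run_cohort",
    "annualized_event_rate",
]

_MASS_TOL = 1e-12


@dataclass(frozen=True)
class CohortState:
    """Occupancy over [GOLD II, GOLD III, GOLD IV, DEAD] at a cycle start."""

    occupancy: np.ndarray
    age: float
    cycle_index: int
    phase: TreatmentPhase

    def __post_init__(self) -> None:
        arr = np.asarray(self.occupancy, dtype=float)
        if arr.shape != (4,):
            raise ValueError("occupancy must have four entries (three states + dead)")
        if abs(arr.sum() - 1.0) > 1e-9 or np.any(arr < -_MASS_TOL):
            raise ValueError("occupancy must be a probability vector")
        arr.flags.writeable = False
        object.__setattr__(self, "occupancy", arr)

    @property
    def alive(self) -> np.ndarray:
        return self.occupancy[:3]


@dataclass(frozen=True)
class CycleInputs:
    """Everything one cycle of one arm needs, already phase-resolved."""

    transition: np.ndarray  # (3, 3) conditional on survival
    events: np.ndarray  # (3, 3) state x event probabilities
    cost: np.ndarray  # (3, 3) SEK per cycle
    utility: np.ndarray  # (3, 3) annual weights
    drug_cost: float  # SEK per cycle, 0 when off treatment / usual care
    state_death: np.ndarray  # (3,) per-cycle death probabilities
    sevex_excess: float  # additive death probability for the severe fraction
    discount: float
    cycle_length: float


@dataclass(frozen=True)
class CycleAccrual:
    treatment_cost: float
    other_direct_cost: float
    qalys: float
    life_years: float
    person_years: float
    events: np.ndarray  # (3,) undiscounted expected counts
    deaths: float


@dataclass
class ArmResult:
    """Discounted accumulators and undiscounted event counts for one arm."""

    arm: str
    treatment_cost: float = 0.0
    other_direct_cost: float = 0.0
    qalys: float = 0.0
    life_years: float = 0.0
    person_years: float = 0.0
    events: np.ndarray = field(default_factory=lambda: np.zeros(3))
    n_cycles: int = 0
    discount_rate: float = 0.0
    horizon_years: float = 0.0
    final_occupancy: np.ndarray | None = None

    @property
    def total_cost(self) -> float:
        return self.treatment_cost + self.other_direct_cost


def treatment_phase(
    cycle_index: int, treatment_duration_years: float, cycle_length_years: float
) -> TreatmentPhase:
    """Phase of a given cycle (1-based): the first cycle is special, cycles
    up to the treatment duration are on treatment, later ones are off."""
    if cycle_index < 1:
        raise ValueError("cycle index starts at 1")
    if cycle_index == 1:
        return TreatmentPhase.FIRST_CYCLE
    if cycle_index <= round(treatment_duration_years / cycle_length_years):
        return TreatmentPhase.ON_TREATMENT
    return TreatmentPhase.OFF_TREATMENT


def resolve_cycle_inputs(
    arm: str,
    params: ModelParameters,
    schedule: MortalitySchedule,
    cycle_index: int,
) -> CycleInputs:
    """Select the matrices, tables and rates applying to one cycle of one arm."""
    if arm not in ARMS:
        raise ValueError(f"unknown arm {arm!r}; expected one of {ARMS}")
    s = params.settings
    phase = treatment_phase(cycle_index, s.treatment_duration_years, s.cycle_length_years)

    on = phase is not TreatmentPhase.OFF_TREATMENT
    if arm == "UC":
        matrix_arm, phase_key = "UC", ("first_cycle" if cycle_index == 1 else "subsequent")
        event_arm = "UC"
        drug = 0.0
    else:
        if on:
            matrix_arm = arm
            phase_key = "first_cycle" if phase is TreatmentPhase.FIRST_CYCLE else "subsequent"
            event_arm = arm
            drug = drug_cost_per_cycle(s, arm)
        else:
            matrix_arm, phase_key = "UC", "subsequent"
            event_arm = "UC" if params.revert_event_risks_off_treatment else arm
            drug = 0.0

    k = cycle_index - 1
    return CycleInputs(
        transition=params.transitions[matrix_arm][phase_key].entries,
        events=params.exacerbations[event_arm].probabilities,
        cost=params.costs.direct_cost,
        utility=params.utilities.annual_weight,
        drug_cost=drug,
        state_death=schedule.state_cycle_death[k],
        sevex_excess=float(schedule.sevex_cycle_excess[k]),
        discount=discount_factor(s.discount_rate_annual, cycle_index, s.cycle_length_years),
        cycle_length=s.cycle_length_years,
    )


def step_cycle(state: CohortState, inputs: CycleInputs) -> tuple[CohortState, CycleAccrual]:
    """Advance the cohort one cycle and return the cycle's accruals."""
    alive = state.alive
    frac = alive[:, None] * inputs.events  # (state, event) mass

    d = inputs.discount
    L = inputs.cycle_length
    alive_mass = float(alive.sum())
    other_cost = float((frac * inputs.cost).sum()) * d
    treat_cost = inputs.drug_cost * alive_mass * d
    qalys = float((frac * inputs.utility).sum()) * L * d
    life_years = alive_mass * L * d
    person_years = alive_mass * L
    event_counts = frac.sum(axis=0)

    # death: state-specific probability, plus per-event excess for the severe
    # fraction, capped at 1
    p_death = np.minimum(
        1.0,
        inputs.state_death[:, None]
        + np.array([0.0, 0.0, inputs.sevex_excess])[None, :],
    )
    survivors = (frac * (1.0 - p_death)).sum(axis=1)  # (3,)
    deaths = alive_mass - float(survivors.sum())
    if np.any(survivors < -_MASS_TOL):
        raise ValueError("negative occupancy mass produced in cycle step")

    next_alive = survivors @ inputs.transition
    next_occ = np.empty(4)
    next_occ[:3] = next_alive
    next_occ[3] = state.occupancy[3] + deaths

    next_state = CohortState(
        occupancy=next_occ,
        age=state.age + L,
        cycle_index=state.cycle_index + 1,
        phase=state.phase,
    )
    accrual = CycleAccrual(
        treatment_cost=treat_cost,
        other_direct_cost=other_cost,
        qalys=qalys,
        life_years=life_years,
        person_years=person_years,
        events=event_counts,
        deaths=deaths,
    )
    return next_state, accrual


def run_cohort(
    arm: str,
    params: ModelParameters,
    schedule: MortalitySchedule | None = None,
    horizon_years: float | None = None,
) -> ArmResult:
    """Run one arm of the cohort model over the horizon (default: start age
    to maximum age) and return its discounted accumulators."""
    from .mortality import build_schedule

    s = params.settings
    horizon = s.horizon_years if horizon_years is None else horizon_years
    n_float = horizon / s.cycle_length_years
    if abs(n_float - round(n_float)) > 1e-9:
        raise ValueError(
            f"horizon {horizon} y is not a whole number of cycles "
            f"of {s.cycle_length_years} y"
        )
    n_cycles = int(round(n_float))
    if schedule is None:
        schedule = build_schedule(
            params.background_mortality, params.excess_mortality, s, horizon
        )
    if schedule.n_cycles < n_cycles:
        raise ValueError("mortality schedule shorter than the run horizon")

    occ = np.zeros(4)
    occ[:3] = s.initial_distribution
    state = CohortState(
        occupancy=occ, age=s.start_age_years, cycle_index=1,
        phase=TreatmentPhase.FIRST_CYCLE,
    )
    result = ArmResult(
        arm=arm, discount_rate=s.discount_rate_annual, horizon_years=horizon
    )
    for k in range(1, n_cycles + 1):
        inputs = resolve_cycle_inputs(arm, params, schedule, k)
        state, acc = step_cycle(state, inputs)
        result.treatment_cost += acc.treatment_cost
        result.other_direct_cost += acc.other_direct_cost
        result.qalys += acc.qalys
        result.life_years += acc.life_years
        result.person_years += acc.person_years
        result.events = result.events + acc.events
        result.n_cycles += 1
        if abs(state.occupancy.sum() - 1.0) > _MASS_TOL * (k + 1):
            raise ValueError("mass conservation violated")
    result.final_occupancy = state.occupancy
    return result


def annualized_event_rate(result: ArmResult, event: EventType) -> float:
    """Expected events of one type per undiscounted person-year alive."""
    if result.person_years <= 0:
        raise ValueError("no person-years accumulated")
    return float(result.events[event.value]) / result.person_years
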