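"""Cohort engine: phase logic, single-cycle semantics, conservation laws and
oracle equivalence against an independent explicit-enumeration
re-implementation."""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pytest

from copdce import engine, fixtures
from copdce.engine import (
    CohortState,
    annualized_event_rate,
    resolve_cycle_inputs,
    run_cohort,
    step_cycle,
    treatment_phase,
)
from copdce.mortality import build_schedule
from copdce.parameters import (
    EventType,
    ExacerbationRiskTable,
    TreatmentPhase,
    drug_cost_per_cycle,
)


@pytest.mark.parametrize(
    "cycle, duration, expected",
    [
        (1, 4.0, TreatmentPhase.FIRST_CYCLE),
        (2, 4.0, TreatmentPhase.ON_TREATMENT),
        (16, 4.0, TreatmentPhase.ON_TREATMENT),
        (17, 4.0, TreatmentPhase.OFF_TREATMENT),
        (1, 0.25, TreatmentPhase.FIRST_CYCLE),
        (2, 0.25, TreatmentPhase.OFF_TREATMENT),
    ],
)
def test_treatment_phase_boundaries(cycle, duration, expected):
    assert treatment_phase(cycle, duration, 0.25) is expected


def brute_force_run(arm, params, schedule, n_cycles):
    """Independent spreadsheet-style re-implementation: explicit loops over
    states and events with scalar arithmetic, no shared engine code."""
    states = [0, 1, 2]
    occ = {s: float(params.settings.initial_distribution[s]) for s in states}
    dead = 0.0
    acc = {
        "treatment_cost": 0.0, "other_direct_cost": 0.0, "qalys": 0.0,
        "life_years": 0.0, "person_years": 0.0,
        "events": [0.0, 0.0, 0.0],
    }
    L = params.settings.cycle_length_years
    r = params.settings.discount_rate_annual
    dur = params.settings.treatment_duration_years
    n_treat_cycles = round(dur / L)
    for k in range(1, n_cycles + 1):
        disc = (1.0 + r) ** (-(k - 1) * L)
        on = k <= n_treat_cycles
        if arm == "UC":
            matrix = params.transitions["UC"][
                "first_cycle" if k == 1 else "subsequent"
            ].entries
            events = params.exacerbations["UC"].probabilities
            drug = 0.0
        elif on:
            matrix = params.transitions[arm][
                "first_cycle" if k == 1 else "subsequent"
            ].entries
            events = params.exacerbations[arm].probabilities
            drug = params.settings.drug_cost_per_day[arm] * 365.25 * L
        else:
            matrix = params.transitions["UC"]["subsequent"].entries
            events = (
                params.exacerbations["UC"].probabilities
                if params.revert_event_risks_off_treatment
                else params.exacerbations[arm].probabilities
            )
            drug = 0.0
        new_occ = {s: 0.0 for s in states}
        for s in states:
            mass = occ[s]
            acc["treatment_cost"] += mass * drug * disc
            acc["life_years"] += mass * L * disc
            acc["person_years"] += mass * L
            for e in range(3):
                f = mass * events[s][e]
                acc["other_direct_cost"] += f * params.costs.direct_cost[s][e] * disc
                acc["qalys"] += f * params.utilities.annual_weight[s][e] * L * disc
                acc["events"][e] += f
                p_die = schedule.state_cycle_death[k - 1][s]
                if e == 2:
                    p_die = min(1.0, p_die + schedule.sevex_cycle_excess[k - 1])
                surv = f * (1.0 - p_die)
                dead += f * p_die
                for t in states:
                    new_occ[t] += surv * matrix[s][t]
        occ = new_occ
    return acc, occ, dead


class TestStepCycle:
    def test_degenerate_fixed_point(self):
        """Zero mortality, identity transitions, certain no-exacerbation:
        occupancy is unchanged and accruals are the state-weighted
        no-exacerbation cost and utility."""
        p = fixtures.generate_random_parameters(0, corner="zero_mortality_identity")
        sched = build_schedule(p.background_mortality, p.excess_mortality, p.settings)
        inputs = resolve_cycle_inputs("UC", p, sched, cycle_index=1)
        occ = np.array([0.5, 0.3, 0.2, 0.0])
        state = CohortState(occ, p.settings.start_age_years, 1, TreatmentPhase.FIRST_CYCLE)
        nxt, acc = step_cycle(state, inputs)
        np.testing.assert_allclose(nxt.occupancy, occ, atol=1e-15)
        expected_cost = float(occ[:3] @ p.costs.direct_cost[:, 0])
        expected_qaly = float(occ[:3] @ p.utilities.annual_weight[:, 0]) * 0.25
        assert acc.other_direct_cost == pytest.approx(expected_cost)
        assert acc.qalys == pytest.approx(expected_qaly)
        assert acc.deaths == 0.0

    def test_all_dead_cohort_accrues_nothing(self, base_params, calibrated_schedule):
        inputs = resolve_cycle_inputs("TIO", base_params, calibrated_schedule, 5)
        state = CohortState(
            np.array([0.0, 0.0, 0.0, 1.0]), 66.0, 5, TreatmentPhase.ON_TREATMENT
        )
        nxt, acc = step_cycle(state, inputs)
        np.testing.assert_array_equal(nxt.occupancy, state.occupancy)
        assert acc.other_direct_cost == acc.treatment_cost == acc.qalys == 0.0
        assert acc.life_years == acc.person_years == 0.0

    def test_first_cycle_matches_hand_multiplied_product(self, base_params):
        """One usual-care first cycle with mortality switched off must equal
        the hand-multiplied vector-matrix product with the published
        first-cycle matrix."""
        p = base_params.replace(
            background_mortality=fixtures.generate_random_parameters(
                0, corner="zero_mortality_identity"
            ).background_mortality,
            excess_mortality=replace(
                base_params.excess_mortality,
                state_rr=(1.0, 1.0, 1.0), sevex_base_excess=0.0,
            ),
        )
        sched = build_schedule(p.background_mortality, p.excess_mortality, p.settings)
        inputs = resolve_cycle_inputs("UC", p, sched, 1)
        init = [0.48, 0.44, 0.08]
        m = [  # published usual-care first-cycle matrix
            [0.86, 0.13, 0.01],
            [0.13, 0.81, 0.06],
            [0.02, 0.22, 0.76],
        ]
        expected = [sum(init[j] * m[j][i] for j in range(3)) for i in range(3)]
        occ = np.array(init + [0.0])
        state = CohortState(occ, 65.0, 1, TreatmentPhase.FIRST_CYCLE)
        nxt, _ = step_cycle(state, inputs)
        np.testing.assert_allclose(nxt.occupancy[:3], expected, atol=1e-12)


class TestRunCohort:
    def test_mass_conservation_and_monotone_survival(
        self, calibrated_params, calibrated_schedule
    ):
        for arm in ("UC", "TIO", "GLY"):
            r = run_cohort(arm, calibrated_params, calibrated_schedule)
            assert r.final_occupancy.sum() == pytest.approx(1.0, abs=1e-10)
            assert np.all(r.final_occupancy >= -1e-12)

    def test_alive_fraction_non_increasing(self, calibrated_params, calibrated_schedule):
        p = calibrated_params
        occ = np.zeros(4)
        occ[:3] = p.settings.initial_distribution
        state = CohortState(occ, 65.0, 1, TreatmentPhase.FIRST_CYCLE)
        prev_alive = 1.0
        for k in range(1, p.settings.n_cycles + 1):
            state, _ = step_cycle(
                state, resolve_cycle_inputs("TIO", p, calibrated_schedule, k)
            )
            alive = state.occupancy[:3].sum()
            assert alive <= prev_alive + 1e-12
            prev_alive = alive

    def test_zero_mortality_zero_discount_conserves_time(self):
        p = fixtures.generate_random_parameters(0, corner="zero_mortality_identity")
        p = p.replace(settings=replace(p.settings, discount_rate_annual=0.0))
        sched = build_schedule(p.background_mortality, p.excess_mortality, p.settings)
        for arm in ("UC", "GLY"):
            r = run_cohort(arm, p, sched, horizon_years=12.0)
            assert r.life_years == pytest.approx(12.0, abs=1e-9)
            assert r.person_years == pytest.approx(12.0, abs=1e-9)

    @pytest.mark.parametrize("arm", ["UC", "TIO", "GLY"])
    def test_oracle_equivalence_eight_cycles(
        self, calibrated_params, calibrated_schedule, arm
    ):
        """Engine accumulators match the independent explicit-enumeration
        oracle to 1e-9 over 8 cycles, for every arm."""
        r = run_cohort(arm, calibrated_params, calibrated_schedule, horizon_years=2.0)
        acc, occ, dead = brute_force_run(
            arm, calibrated_params, calibrated_schedule, n_cycles=8
        )
        assert r.treatment_cost == pytest.approx(acc["treatment_cost"], abs=1e-9)
        assert r.other_direct_cost == pytest.approx(acc["other_direct_cost"], abs=1e-9)
        assert r.qalys == pytest.approx(acc["qalys"], abs=1e-9)
        assert r.life_years == pytest.approx(acc["life_years"], abs=1e-9)
        assert r.person_years == pytest.approx(acc["person_years"], abs=1e-9)
        np.testing.assert_allclose(r.events, acc["events"], atol=1e-9)
        np.testing.assert_allclose(
            r.final_occupancy, [occ[0], occ[1], occ[2], dead], atol=1e-9
        )

    def test_oracle_equivalence_random_parameters(self):
        """Oracle equivalence also holds on randomised valid inputs,
        including the off-treatment reversion boundary."""
        p = fixtures.generate_random_parameters(7)
        p = p.replace(settings=replace(p.settings, treatment_duration_years=1.0))
        sched = build_schedule(p.background_mortality, p.excess_mortality, p.settings)
        r = run_cohort("GLY", p, sched, horizon_years=2.0)
        acc, _, _ = brute_force_run("GLY", p, sched, n_cycles=8)
        for key in ("treatment_cost", "other_direct_cost", "qalys", "life_years"):
            assert getattr(r, key) == pytest.approx(acc[key], abs=1e-9)

    def test_higher_mortality_never_lengthens_life(self, base_params):
        from copdce.mortality import apply_scales

        lys = []
        for scale in (0.5, 1.5):
            p = apply_scales(base_params, scale, 1.0)
            sched = build_schedule(p.background_mortality, p.excess_mortality, p.settings)
            r = run_cohort("UC", p, sched)
            lys.append((r.life_years, r.qalys, r.other_direct_cost))
        assert lys[1][0] < lys[0][0]
        assert lys[1][1] < lys[0][1]
        assert lys[1][2] < lys[0][2]

    def test_discounting_never_increases_accumulators(self, base_params):
        undiscounted = base_params.replace(
            settings=replace(base_params.settings, discount_rate_annual=0.0)
        )
        sched = build_schedule(
            base_params.background_mortality,
            base_params.excess_mortality,
            base_params.settings,
        )
        r0 = run_cohort("TIO", undiscounted, sched)
        r3 = run_cohort("TIO", base_params, sched)
        for key in ("treatment_cost", "other_direct_cost", "qalys", "life_years"):
            assert getattr(r0, key) >= getattr(r3, key)
        np.testing.assert_allclose(r0.events, r3.events)  # counts undiscounted

    def test_non_integer_cycle_count_rejected(self, base_params, calibrated_schedule):
        with pytest.raises(ValueError, match="whole number of cycles"):
            run_cohort("UC", base_params, calibrated_schedule, horizon_years=1.1)


class TestAnnualizedEventRate:
    def test_single_cycle_closed_form(self):
        """A one-cycle, single-state cohort with severe probability p and no
        deaths has rate p / cycle length."""
        p = fixtures.generate_random_parameters(0, corner="zero_mortality_identity")
        exac = dict(p.exacerbations)
        exac["UC"] = ExacerbationRiskTable.from_nonsev_sev(
            [0.0, 0.0, 0.0], [0.1, 0.1, 0.1]
        )
        p = p.replace(exacerbations=exac)
        sched = build_schedule(p.background_mortality, p.excess_mortality, p.settings)
        r = run_cohort("UC", p, sched, horizon_years=0.25)
        assert annualized_event_rate(r, EventType.SEV_EXAC) == pytest.approx(
            0.1 / 0.25
        )

    def test_zero_person_years_rejected(self):
        from copdce.engine import ArmResult

        with pytest.raises(ValueError):
            annualized_event_rate(ArmResult(arm="UC"), EventType.SEV_EXAC)
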