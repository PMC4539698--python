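"""One-way deterministic sensitivity analysis and probabilistic sensitivity
analysis (Monte Carlo with cost-effectiveness acceptability curves).

DSA scenarios are declarative patches on the configuration mapping (plus a
few structural knobs: run horizon, background-hazard scaling for sex-specific
rows, re-derivation of the glycopyrronium event table from a varied relative
risk).  Mortality is *not* recalibrated per scenario — the calibrated scales
travel with the patched configuration — except where a scenario explicitly
changes them.

The PSA draws, per iteration, the severe-exacerbation relative risk
(lognormal, parameterised from its 95% CI), and every cost and utility cell
independently (uniform within a ±fraction band, utilities truncated at 1).
The glycopyrronium event table is re-derived from each drawn relative risk.
Draws producing an invalid probability table are redrawn and counted.  The
calibrated mortality schedule is held fixed across iterations.  All draws are
reproducible from the seed: iteration ``i`` uses an independent generator
keyed by ``(seed, i)``, so single iterations can be reconstructed exactly.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from . import engine
from .economics import incremental_analysis
from .mortality import MortalitySchedule, build_schedule
from .parameters import (
    ExacerbationRiskTable,
    CostTable,
    ModelParameters,
    UtilityTable,
    ValidationError,
    derive_comparator_events,
    drug_cost_per_cycle,
    load_parameters,
    parameters_to_dict,
)

__all__ = [
    "ScenarioOverride",
    "ParameterDistribution",
    "CEAC",
    "PSAResult",
    "run_one_way_dsa",
    "standard_scenarios",
    "lognormal_sigma_from_ci",
    "default_psa_distributions",
    "sample_psa_parameters",
    "run_psa",
]

_Z95 = 1.959964  # two-sided 95% normal quantile


# ---------------------------------------------------------------------------
# one-way deterministic sensitivity analysis


@dataclass(frozen=True)
class ScenarioOverride:
    """A named one-way scenario.

    ``patch`` maps dotted configuration paths to replacement values (applied
    to a copy of the base configuration, which is then re-validated).
    ``horizon_years`` overrides the run horizon; ``rederive_gly_events``
    rebuilds the glycopyrronium event table from the (possibly patched)
    severe-exacerbation relative risk; ``background_hazard_scale`` scales the
    background-mortality hazard (sex-specific rows); ``transform`` is an
    optional in-code hook applied to the loaded parameters last.
    """

    name: str
    patch: dict[str, object] = field(default_factory=dict)
    horizon_years: float | None = None
    rederive_gly_events: bool = False
    background_hazard_scale: float | None = None
    transform: Callable[[ModelParameters], ModelParameters] | None = None


def _set_path(mapping: dict, path: str, value: object) -> None:
    parts = path.split(".")
    node = mapping
    for p in parts[:-1]:
        node = node[int(p)] if isinstance(node, list) else node[p]
    last = parts[-1]
    if isinstance(node, list):
        node[int(last)] = value
    else:
        if last not in node:
            raise KeyError(f"unknown configuration path {path!r}")
        node[last] = value


def apply_scenario(base: ModelParameters, scenario: ScenarioOverride) -> ModelParameters:
    """Materialise a scenario into a validated parameter set."""
    cfg = copy.deepcopy(parameters_to_dict(base))
    for path, value in scenario.patch.items():
        _set_path(cfg, path, value)
    if scenario.background_hazard_scale is not None:
        f = scenario.background_hazard_scale
        cfg["mortality"]["background"]["makeham_a"] *= f
        cfg["mortality"]["background"]["gompertz_b"] *= f
    params = load_parameters(cfg)
    if scenario.rederive_gly_events:
        gly = derive_comparator_events(
            params.exacerbations["TIO"], params.rr_severe_gly_vs_tio.point
        )
        params = params.replace(
            exacerbations={**params.exacerbations, "GLY": gly}
        )
    if scenario.transform is not None:
        params = scenario.transform(params)
    return params


def run_one_way_dsa(
    base: ModelParameters,
    scenarios: Sequence[ScenarioOverride],
    comparisons: Sequence[tuple[str, str]] = (("UC", "TIO"), ("GLY", "TIO")),
) -> pd.DataFrame:
    """Run every scenario through the full model for every comparison.

    Returns one row per (scenario, comparison) with the deltas and the ICER
    (or dominance label).  A scenario whose patch fails validation yields an
    error row; remaining scenarios still run.
    """
    rows = []
    arms = sorted({a for pair in comparisons for a in pair})
    for sc in scenarios:
        try:
            params = apply_scenario(base, sc)
            horizon = sc.horizon_years
            schedule = build_schedule(
                params.background_mortality, params.excess_mortality, params.settings
            )
            results = {
                arm: engine.run_cohort(arm, params, schedule, horizon_years=horizon)
                for arm in arms
            }
            for ref, interv in comparisons:
                inc = incremental_analysis(results[ref], results[interv])
                rows.append(
                    {
                        "scenario": sc.name,
                        "comparison": f"{interv} vs {ref}",
                        "delta_cost": inc.delta_cost,
                        "delta_qalys": inc.delta_qalys,
                        "delta_ly": inc.delta_ly,
                        "icer": inc.icer_or_label,
                        "error": None,
                    }
                )
        except (ValidationError, ValueError) as e:
            for ref, interv in comparisons:
                rows.append(
                    {
                        "scenario": sc.name,
                        "comparison": f"{interv} vs {ref}",
                        "delta_cost": np.nan,
                        "delta_qalys": np.nan,
                        "delta_ly": np.nan,
                        "icer": None,
                        "error": str(e),
                    }
                )
    return pd.DataFrame(rows)


def standard_scenarios(base: ModelParameters) -> list[ScenarioOverride]:
    """The standard published one-way scenario set: discounting, horizon,
    treatment duration, sex (encoded as background-hazard scaling), start
    age (calibrated scales reused), initial GOLD distribution, mortality
    structure, the severe-exacerbation relative risk CI endpoints, severe-
    exacerbation costs and quality-of-life loss."""
    sev_costs = base.costs.direct_cost[:, 2]
    sevex_scale = base.excess_mortality.sevex_scale

    def qol_loss(loss: float):
        def t(p: ModelParameters) -> ModelParameters:
            u = p.utilities.annual_weight.copy()
            u[:, 2] = u[:, 0] * (1.0 - loss)
            return p.replace(utilities=UtilityTable(u))

        return t

    life_duration = base.settings.horizon_years
    return [
        ScenarioOverride("base_case"),
        ScenarioOverride("discount_rate_0pct", {"settings.discount_rate_annual": 0.0}),
        ScenarioOverride("discount_rate_5pct", {"settings.discount_rate_annual": 0.05}),
        ScenarioOverride("horizon_5y", horizon_years=5.0),
        ScenarioOverride("horizon_10y", horizon_years=10.0),
        ScenarioOverride("horizon_20y", horizon_years=20.0),
        ScenarioOverride("duration_1y", {"settings.treatment_duration_years": 1.0}),
        ScenarioOverride("duration_10y", {"settings.treatment_duration_years": 10.0}),
        ScenarioOverride(
            "duration_lifetime",
            {"settings.treatment_duration_years": life_duration},
        ),
        ScenarioOverride("males_only", background_hazard_scale=1.25),
        ScenarioOverride("females_only", background_hazard_scale=0.80),
        ScenarioOverride("start_age_40", {"settings.start_age_years": 40.0}),
        ScenarioOverride("start_age_80", {"settings.start_age_years": 80.0}),
        ScenarioOverride(
            "all_start_gold_ii", {"settings.initial_distribution": [1.0, 0.0, 0.0]}
        ),
        ScenarioOverride(
            "all_start_gold_iii", {"settings.initial_distribution": [0.0, 1.0, 0.0]}
        ),
        ScenarioOverride(
            "all_start_gold_iv", {"settings.initial_distribution": [0.0, 0.0, 1.0]}
        ),
        ScenarioOverride(
            "normal_mortality_all_states",
            {
                "mortality.background.copd_death_fraction": 0.0,
                "mortality.excess.state_scale": 0.0,
            },
        ),
        ScenarioOverride(
            "sevex_excess_mortality_+20pct",
            {"mortality.excess.sevex_scale": sevex_scale * 1.2},
        ),
        ScenarioOverride(
            "sevex_excess_mortality_-20pct",
            {"mortality.excess.sevex_scale": sevex_scale * 0.8},
        ),
        ScenarioOverride(
            "rr_sevex_gly_low_ci",
            {"relative_risk_severe_gly_vs_tio.point": base.rr_severe_gly_vs_tio.ci_low},
            rederive_gly_events=True,
        ),
        ScenarioOverride(
            "rr_sevex_gly_high_ci",
            {"relative_risk_severe_gly_vs_tio.point": base.rr_severe_gly_vs_tio.ci_high},
            rederive_gly_events=True,
        ),
        ScenarioOverride(
            "sevex_cost_+20pct",
            {"costs_sek_per_cycle.severe_exacerbation": (sev_costs * 1.2).tolist()},
        ),
        ScenarioOverride(
            "sevex_cost_-20pct",
            {"costs_sek_per_cycle.severe_exacerbation": (sev_costs * 0.8).tolist()},
        ),
        ScenarioOverride("sevex_qol_loss_0pct", transform=qol_loss(0.0)),
        ScenarioOverride("sevex_qol_loss_20pct", transform=qol_loss(0.20)),
    ]


# ---------------------------------------------------------------------------
# probabilistic sensitivity analysis


@dataclass(frozen=True)
class ParameterDistribution:
    """A sampling distribution for one PSA input.

    Families: ``lognormal-from-CI`` (targets
    ``rr_severe_gly_vs_tio`` / ``rr_severe_tio_vs_uc``; median at the point
    estimate, sigma from the 95% CI) and ``uniform-pm-fraction`` (targets
    ``costs`` / ``utilities``; each cell drawn independently within
    ±fraction of its point estimate).
    """

    target: str
    family: str
    point: float | None = None
    ci_low: float | None = None
    ci_high: float | None = None
    fraction: float | None = None

    def __post_init__(self) -> None:
        if self.family == "lognormal-from-CI":
            if not (self.point and self.ci_low and self.ci_high):
                raise ValueError("lognormal-from-CI needs point, ci_low, ci_high")
            if not (0 < self.ci_low <= self.point <= self.ci_high):
                raise ValueError("lognormal-from-CI: requires 0 < low <= point <= high")
        elif self.family == "uniform-pm-fraction":
            if self.fraction is None or not 0 <= self.fraction < 1:
                raise ValueError("uniform-pm-fraction needs fraction in [0, 1)")
        else:
            raise ValueError(f"unknown distribution family {self.family!r}")


def lognormal_sigma_from_ci(ci_low: float, ci_high: float) -> float:
    """Sigma of a lognormal whose 95% CI spans [low, high]:
    (ln high - ln low) / (2 * 1.959964)."""
    return (math.log(ci_high) - math.log(ci_low)) / (2.0 * _Z95)


@dataclass(frozen=True)
class CEAC:
    """Cost-effectiveness acceptability curve: probability the intervention
    has positive net monetary benefit at each willingness-to-pay."""

    wtp_grid: np.ndarray
    prob_cost_effective: np.ndarray
    n_iterations: int
    seed: int


@dataclass(frozen=True)
class PSAResult:
    comparison: tuple[str, str]
    ce_points: pd.DataFrame  # one row per iteration: delta_cost, delta_qalys
    ceac: CEAC
    n_iterations: int
    seed: int
    n_redraws: int

    def probability_cost_effective(self, wtp: float) -> float:
        dq = self.ce_points["delta_qalys"].to_numpy()
        dc = self.ce_points["delta_cost"].to_numpy()
        return float(np.mean(wtp * dq - dc > 0))


def default_psa_distributions(params: ModelParameters) -> list[ParameterDistribution]:
    """The published PSA specification: lognormal severe-exacerbation RR
    (glycopyrronium vs tiotropium) from its 95% CI; uniform ±20% on every
    cost and utility cell.

    The tiotropium-vs-usual-care exacerbation-effect CI is not published, so
    no default is fabricated for it; supply a ``rr_severe_tio_vs_uc``
    distribution explicitly to vary that comparison's treatment effect.
    """
    rr = params.rr_severe_gly_vs_tio
    return [
        ParameterDistribution(
            "rr_severe_gly_vs_tio", "lognormal-from-CI",
            point=rr.point, ci_low=rr.ci_low, ci_high=rr.ci_high,
        ),
        ParameterDistribution("costs", "uniform-pm-fraction", fraction=0.20),
        ParameterDistribution("utilities", "uniform-pm-fraction", fraction=0.20),
    ]


@dataclass(frozen=True)
class _IterationDraw:
    rr_gly: float | None
    rr_uc: float | None
    cost_factors: np.ndarray | None  # (3, 3)
    utility_factors: np.ndarray | None
    redraws: int


def _draw_iteration(
    rng: np.random.Generator,
    distributions: Sequence[ParameterDistribution],
    base: ModelParameters,
) -> _IterationDraw:
    """One iteration's draws, redrawn wholesale until every derived
    probability table is valid."""
    tio = base.exacerbations["TIO"].probabilities
    uc = base.exacerbations["UC"].probabilities
    redraws = 0
    while True:
        rr_gly = rr_uc = None
        costs = utils = None
        for d in distributions:
            if d.family == "lognormal-from-CI":
                sigma = lognormal_sigma_from_ci(d.ci_low, d.ci_high)
                val = float(rng.lognormal(math.log(d.point), sigma))
                if d.target == "rr_severe_gly_vs_tio":
                    rr_gly = val
                elif d.target == "rr_severe_tio_vs_uc":
                    rr_uc = val
                else:
                    raise ValueError(f"unknown lognormal target {d.target!r}")
            else:
                f = d.fraction
                if d.target == "costs":
                    costs = rng.uniform(1.0 - f, 1.0 + f, size=(3, 3))
                elif d.target == "utilities":
                    utils = rng.uniform(1.0 - f, 1.0 + f, size=(3, 3))
                else:
                    raise ValueError(f"unknown uniform target {d.target!r}")
        ok = True
        if rr_gly is not None:
            ok &= bool(np.all(tio[:, 1] + tio[:, 2] * rr_gly <= 1.0))
        if rr_uc is not None:
            ok &= bool(np.all(uc[:, 1] + uc[:, 2] * rr_uc <= 1.0))
        if ok:
            return _IterationDraw(rr_gly, rr_uc, costs, utils, redraws)
        redraws += 1


def _patched_parameters(base: ModelParameters, draw: _IterationDraw) -> ModelParameters:
    exac = dict(base.exacerbations)
    if draw.rr_uc is not None:
        exac["TIO"] = derive_comparator_events(base.exacerbations["UC"], draw.rr_uc)
    if draw.rr_gly is not None:
        exac["GLY"] = derive_comparator_events(exac["TIO"], draw.rr_gly)
    params = base.replace(exacerbations=exac)
    if draw.cost_factors is not None:
        params = params.replace(
            costs=CostTable(base.costs.direct_cost * draw.cost_factors)
        )
    if draw.utility_factors is not None:
        params = params.replace(
            utilities=UtilityTable(
                np.minimum(1.0, base.utilities.annual_weight * draw.utility_factors)
            )
        )
    return params


def sample_psa_parameters(
    base: ModelParameters,
    distributions: Sequence[ParameterDistribution],
    rng_seed: int,
    iteration: int,
) -> ModelParameters:
    """Reconstruct the exact patched parameter set of one PSA iteration.

    Iteration ``i`` of a PSA with seed ``s`` is drawn from
    ``default_rng([s, i])``, so any single iteration can be re-materialised
    without rerunning the others.  Cost and utility draws deliberately skip
    the cell-wise ordering invariants (they are sampled independently, per
    the stated PSA design), so the patched set is returned without
    re-validating those orderings.
    """
    rng = np.random.default_rng([rng_seed, iteration])
    draw = _draw_iteration(rng, distributions, base)
    return _patched_parameters(base, draw)


def _run_batch(
    arm: str,
    params: ModelParameters,
    schedule: MortalitySchedule,
    events: np.ndarray,  # (n, 3, 3) per-iteration event tables for this arm
    costs: np.ndarray,  # (n, 3, 3)
    utils: np.ndarray,  # (n, 3, 3)
) -> dict[str, np.ndarray]:
    """Vectorised cohort propagation across PSA iterations (semantics
    identical to engine.run_cohort; equivalence is covered by tests)."""
    from .parameters import TreatmentPhase

    s = params.settings
    n_iter = events.shape[0]
    n_cycles = s.n_cycles
    occ = np.broadcast_to(s.initial_distribution, (n_iter, 3)).copy()
    total_cost = np.zeros(n_iter)
    qalys = np.zeros(n_iter)
    life_years = np.zeros(n_iter)
    L = s.cycle_length_years
    for k in range(1, n_cycles + 1):
        inputs = engine.resolve_cycle_inputs(arm, params, schedule, k)
        phase = engine.treatment_phase(k, s.treatment_duration_years, L)
        # the per-iteration tables apply while the arm's own risks do; off
        # treatment the (fixed) resolved table — usual care's on reversion —
        # applies to every iteration
        own = (
            arm == "UC"
            or phase is not TreatmentPhase.OFF_TREATMENT
            or not params.revert_event_risks_off_treatment
        )
        E = events if own else np.broadcast_to(inputs.events, (n_iter, 3, 3))
        frac = occ[:, :, None] * E
        d = inputs.discount
        alive = occ.sum(axis=1)
        total_cost += ((frac * costs).sum(axis=(1, 2)) + inputs.drug_cost * alive) * d
        qalys += (frac * utils).sum(axis=(1, 2)) * L * d
        life_years += alive * L * d
        p_death = np.minimum(
            1.0,
            inputs.state_death[:, None] + np.array([0.0, 0.0, inputs.sevex_excess]),
        )
        survivors = (frac * (1.0 - p_death)).sum(axis=2)
        occ = survivors @ inputs.transition
    return {"total_cost": total_cost, "qalys": qalys, "life_years": life_years}


def run_psa(
    base: ModelParameters,
    distributions: Sequence[ParameterDistribution] | None = None,
    n_iterations: int = 10_000,
    seed: int = 0,
    comparison: tuple[str, str] = ("GLY", "TIO"),
    wtp_grid: np.ndarray | None = None,
    schedule: MortalitySchedule | None = None,
) -> PSAResult:
    """Monte Carlo PSA for one pairwise comparison.

    Returns the cost-effectiveness plane points (intervention minus
    reference) and the acceptability curve.  Two runs with the same seed
    produce bit-identical results.
    """
    if distributions is None:
        distributions = default_psa_distributions(base)
    if wtp_grid is None:
        wtp_grid = np.arange(0.0, 1_500_001.0, 25_000.0)
    if schedule is None:
        schedule = build_schedule(
            base.background_mortality, base.excess_mortality, base.settings
        )
    ref_arm, int_arm = comparison

    tio = base.exacerbations["TIO"].probabilities
    uc = base.exacerbations["UC"].probabilities
    n_redraws = 0
    cost_f = np.ones((n_iterations, 3, 3))
    util_f = np.ones((n_iterations, 3, 3))
    event_tables = {
        arm: np.broadcast_to(
            base.exacerbations[arm].probabilities, (n_iterations, 3, 3)
        ).copy()
        for arm in set(comparison)
    }
    for i in range(n_iterations):
        rng = np.random.default_rng([seed, i])
        draw = _draw_iteration(rng, distributions, base)
        n_redraws += draw.redraws
        if draw.cost_factors is not None:
            cost_f[i] = draw.cost_factors
        if draw.utility_factors is not None:
            util_f[i] = draw.utility_factors
        tio_i = tio
        if draw.rr_uc is not None and "TIO" in event_tables:
            nonsev, sev = uc[:, 1], np.minimum(1.0, uc[:, 2] * draw.rr_uc)
            tio_i = np.column_stack([1.0 - nonsev - sev, nonsev, sev])
            event_tables["TIO"][i] = tio_i
        if draw.rr_gly is not None and "GLY" in event_tables:
            nonsev, sev = tio_i[:, 1], np.minimum(1.0, tio_i[:, 2] * draw.rr_gly)
            event_tables["GLY"][i] = np.column_stack(
                [1.0 - nonsev - sev, nonsev, sev]
            )

    costs = base.costs.direct_cost * cost_f
    utils = np.minimum(1.0, base.utilities.annual_weight * util_f)
    out = {
        arm: _run_batch(arm, base, schedule, event_tables[arm], costs, utils)
        for arm in set(comparison)
    }
    dc = out[int_arm]["total_cost"] - out[ref_arm]["total_cost"]
    dq = out[int_arm]["qalys"] - out[ref_arm]["qalys"]
    ce_points = pd.DataFrame({"delta_cost": dc, "delta_qalys": dq})
    prob = np.array([(w * dq - dc > 0).mean() for w in wtp_grid])
    ceac = CEAC(
        wtp_grid=wtp_grid, prob_cost_effective=prob,
        n_iterations=n_iterations, seed=seed,
    )
    return PSAResult(
        comparison=comparison,
        ce_points=ce_points,
        ceac=ceac,
        n_iterations=n_iterations,
        seed=seed,
        n_redraws=n_redraws,
    )
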