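"""Packaged base-case configuration and synthetic input generators.

The packaged YAML bundle is the single source of truth for the base-case
analysis: loading it and running the three arms needs nothing outside this
package.  The random generators produce validator-passing parameter sets
(including degenerate corners) for property tests, and jittered background-
mortality laws for calibration robustness checks.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from importlib import resources
from pathlib import Path

import numpy as np

from .mortality import BackgroundMortalityModel, CalibrationAnchors
from .parameters import (
    ARMS,
    CostTable,
    EconomicSettings,
    ExacerbationRiskTable,
    ModelParameters,
    TransitionMatrix,
    UtilityTable,
    load_parameters,
)

__all__ = [
    "FixtureBundle",
    "base_case_config",
    "base_case_parameters",
    "generate_random_parameters",
    "generate_synthetic_mortality",
]

_DEFAULT_BACKGROUND = BackgroundMortalityModel(
    makeham_a=1.618574e-3,
    gompertz_b=1.581215e-6,
    gompertz_c=0.129355,
    copd_death_fraction=0.03,
)


@dataclass(frozen=True)
class FixtureBundle:
    """The packaged base case: configuration text, parsed parameters and the
    calibration anchors."""

    config_text: str
    parameters: ModelParameters
    anchors: CalibrationAnchors


def _config_path() -> Path:
    return Path(resources.files("copdce").joinpath("data/base_case.yaml"))  # type: ignore[arg-type]


def base_case_config() -> FixtureBundle:
    """Load the packaged base-case bundle (validated on load)."""
    text = _config_path().read_text()
    params = load_parameters(text)
    assert params.anchors is not None
    return FixtureBundle(config_text=text, parameters=params, anchors=params.anchors)


def base_case_parameters() -> ModelParameters:
    """Shorthand for the packaged, validated base-case parameter set."""
    return base_case_config().parameters


def generate_random_parameters(
    seed: int, corner: str | None = None
) -> ModelParameters:
    """Generate a random validator-passing parameter set (deterministic per
    seed).

    ``corner`` requests degenerate fixtures: ``"zero_mortality_identity"``
    (no deaths, identity transitions, certain no-exacerbation — the engine
    fixed point) or ``"point_mass_init"`` (whole cohort starts in GOLD II).
    """
    if corner not in (None, "zero_mortality_identity", "point_mass_init"):
        raise ValueError(f"unknown corner {corner!r}")
    rng = np.random.default_rng(seed)
    base = base_case_parameters()

    def random_stochastic_matrix() -> TransitionMatrix:
        m = rng.dirichlet(np.array([8.0, 1.5, 0.5]), size=3)
        # bias toward staying put, as disease progression matrices do
        m = 0.5 * m + 0.5 * np.eye(3)
        return TransitionMatrix(m / m.sum(axis=1, keepdims=True))

    def random_events() -> ExacerbationRiskTable:
        nonsev = rng.uniform(0.05, 0.25, size=3)
        sev = rng.uniform(0.0, 0.15, size=3)
        return ExacerbationRiskTable.from_nonsev_sev(nonsev, sev)

    if corner == "zero_mortality_identity":
        transitions = {
            arm: {ph: TransitionMatrix(np.eye(3)) for ph in ("first_cycle", "subsequent")}
            for arm in ARMS
        }
        exac = {
            arm: ExacerbationRiskTable.from_nonsev_sev([0, 0, 0], [0, 0, 0])
            for arm in ARMS
        }
        background = BackgroundMortalityModel(
            makeham_a=0.0, gompertz_b=1e-300, gompertz_c=1e-6, copd_death_fraction=0.0
        )
        excess = replace(
            base.excess_mortality, state_rr=(1.0, 1.0, 1.0), sevex_base_excess=0.0,
            state_scale=0.0, sevex_scale=0.0,
        )
        return base.replace(
            transitions=transitions,
            exacerbations=exac,
            background_mortality=background,
            excess_mortality=excess,
        )

    transitions = {
        arm: {
            "first_cycle": random_stochastic_matrix(),
            "subsequent": random_stochastic_matrix(),
        }
        for arm in ARMS
    }
    exacerbations = {arm: random_events() for arm in ARMS}
    cost_scale = rng.uniform(0.5, 2.0)
    base_costs = np.sort(rng.uniform(500, 5000, size=(3, 1)), axis=0)
    event_markup = np.array([[0.0, 3000.0, 25000.0]]) * cost_scale
    costs = CostTable(base_costs + event_markup)
    u0 = np.sort(rng.uniform(0.4, 0.9, size=3))[::-1]
    utilities = UtilityTable(
        np.column_stack([u0, u0 * (1 - 0.0166), u0 * (1 - 0.0482)])
    )
    if corner == "point_mass_init":
        init = np.array([1.0, 0.0, 0.0])
    else:
        init = rng.dirichlet(np.ones(3) * 3)
    settings = EconomicSettings(
        discount_rate_annual=float(rng.uniform(0.0, 0.05)),
        cycle_length_years=0.25,
        start_age_years=float(rng.integers(50, 75)),
        max_age_years=100.0,
        treatment_duration_years=float(rng.integers(1, 8)),
        drug_cost_per_day={"UC": 0.0, "TIO": float(rng.uniform(5, 20)),
                           "GLY": float(rng.uniform(5, 20))},
        initial_distribution=init,
    )
    params = base.replace(
        transitions=transitions,
        exacerbations=exacerbations,
        costs=costs,
        utilities=utilities,
        settings=settings,
        background_mortality=generate_synthetic_mortality(int(rng.integers(2**31))),
    )
    errs = params.validate()
    if errs:  # pragma: no cover - generator contract
        raise AssertionError(f"generator produced invalid parameters: {errs}")
    return params


def generate_synthetic_mortality(
    seed: int, roughness: float = 0.1
) -> BackgroundMortalityModel:
    """Jitter the default Gompertz–Makeham law (lognormal multiplicative
    noise of scale ``roughness`` on each parameter).  Always yields a valid,
    age-increasing annual death probability on ages 40-100; ``roughness`` 0
    returns the defaults exactly."""
    if roughness < 0:
        raise ValueError("roughness must be >= 0")
    if roughness == 0:
        return _DEFAULT_BACKGROUND
    rng = np.random.default_rng(seed)
    d = _DEFAULT_BACKGROUND
    model = BackgroundMortalityModel(
        makeham_a=d.makeham_a * float(rng.lognormal(0.0, roughness)),
        gompertz_b=d.gompertz_b * float(rng.lognormal(0.0, roughness)),
        gompertz_c=d.gompertz_c * float(rng.lognormal(0.0, roughness / 4)),
        copd_death_fraction=d.copd_death_fraction,
    )
    errs = model.validate()
    if errs:  # pragma: no cover - generator contract
        raise AssertionError(f"synthetic mortality invalid: {errs}")
    return model
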