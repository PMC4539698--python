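"""Mortality synthesis and calibration.

Per-cycle death probabilities are built from two parts:

1. **Background mortality** — a Gompertz–Makeham law for Swedish-type
   all-cause mortality, annual hazard ``h(x) = a + b·exp(c·x)``, with the
   share of deaths attributable to COPD (ICD-10 J44) factored out so the
   disease-specific excess is not double counted.
2. **Excess mortality** — a relative risk per GOLD state applied to the
   corrected background (the excess ``RR - 1`` decaying per decade of age,
   as relative risks do while absolute risks rise), plus an additive
   per-event death probability for severe exacerbations that grows with age.

The GOLD-state excess and the severe-exacerbation excess each carry a free
multiplicative scale.  The two scales are not taken from any life table;
they are calibrated so the cohort model reproduces two published discounted
life-expectancy anchors (usual care and glycopyrronium arms).  The third
arm's life expectancy is then a genuine model prediction.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import TYPE_CHECKING, Sequence

import numpy as np
from scipy.optimize import brentq

if TYPE_CHECKING:  # pragma: no cover
    from .parameters import EconomicSettings, ModelParameters

__all__ = [
    "BackgroundMortalityModel",
    "ExcessMortalityConfig",
    "MortalitySchedule",
    "CalibrationAnchors",
    "CalibrationResult",
    "MortalityError",
    "build_schedule",
    "calibrate",
    "apply_scales",
    "write_calibration_sidecar",
]


class MortalityError(ValueError):
    """Raised when a mortality configuration yields invalid probabilities."""


@dataclass(frozen=True)
class BackgroundMortalityModel:
    """Gompertz–Makeham background mortality with COPD deaths removed.

    Annual hazard at age ``x`` is ``makeham_a + gompertz_b * exp(gompertz_c * x)``;
    ``copd_death_fraction`` is the age-constant share of all-cause deaths
    attributed to COPD, subtracted from the baseline so excess mortality can
    be layered on top without double counting.
    """

    makeham_a: float
    gompertz_b: float
    gompertz_c: float
    copd_death_fraction: float

    def annual_hazard(self, age) -> np.ndarray:
        return self.makeham_a + self.gompertz_b * np.exp(self.gompertz_c * np.asarray(age, dtype=float))

    def annual_death_probability(self, age) -> np.ndarray:
        """All-cause annual death probability 1 - exp(-hazard)."""
        return -np.expm1(-self.annual_hazard(age))

    def corrected_annual_probability(self, age) -> np.ndarray:
        """Annual death probability with the COPD-attributed share removed."""
        return self.annual_death_probability(age) * (1.0 - self.copd_death_fraction)

    def validate(self) -> list[str]:
        errs = []
        if self.makeham_a < 0 or self.gompertz_b <= 0 or self.gompertz_c <= 0:
            errs.append("background mortality: requires a >= 0, b > 0, c > 0")
        if not 0 <= self.copd_death_fraction <= 0.2:
            errs.append("background mortality: copd_death_fraction outside [0, 0.2]")
        if not errs:
            q = self.annual_death_probability(np.array([40.0, 100.0]))
            if q[0] <= 0 or q[1] >= 1:
                errs.append(
                    "background mortality: implied annual death probability "
                    "outside (0, 1) on ages 40-100"
                )
        return errs


@dataclass(frozen=True)
class ExcessMortalityConfig:
    """COPD excess mortality: per-GOLD-state relative risks and a per-event
    severe-exacerbation death probability, each with a per-decade age
    gradient and a global calibration scale.

    ``state_rr`` are point estimates at ``reference_age`` ordered
    [GOLD II, III, IV]; ``state_age_gradient`` multiplies the excess
    ``RR - 1`` per decade of age (values < 1 let the relative excess decay
    with age); ``sevex_age_gradient`` multiplies the per-event excess per
    decade (> 1: severe exacerbations grow more lethal with age).
    ``state_scale`` scales ``RR - 1``; ``sevex_scale`` scales the per-event
    excess — these two are the calibration degrees of freedom.
    """

    state_rr: Sequence[float]
    state_age_gradient: float
    sevex_base_excess: float
    sevex_age_gradient: float
    reference_age: float = 65.0
    state_scale: float = 1.0
    sevex_scale: float = 1.0

    def validate(self) -> list[str]:
        errs = []
        if any(rr < 1 for rr in self.state_rr) or len(self.state_rr) != 3:
            errs.append("excess mortality: state_rr must be three values >= 1")
        if not (self.state_rr[0] <= self.state_rr[1] <= self.state_rr[2]):
            errs.append("excess mortality: state_rr must be non-decreasing II -> IV")
        if not 0 <= self.sevex_base_excess <= 1:
            errs.append("excess mortality: sevex_base_excess outside [0, 1]")
        if self.state_age_gradient <= 0 or self.sevex_age_gradient <= 0:
            errs.append("excess mortality: age gradients must be > 0")
        if self.state_scale < 0 or self.sevex_scale < 0:
            errs.append("excess mortality: scales must be >= 0")
        return errs


@dataclass(frozen=True)
class MortalitySchedule:
    """Per-cycle death probabilities on an age grid.

    ``state_cycle_death[k, s]`` is the probability of dying during cycle
    ``k+1`` (age ``ages[k]`` at cycle start) in alive state ``s``;
    ``sevex_cycle_excess[k]`` is the *additional* death probability applied
    to the fraction experiencing a severe exacerbation that cycle.
    """

    ages: np.ndarray
    state_cycle_death: np.ndarray
    sevex_cycle_excess: np.ndarray

    def __post_init__(self) -> None:
        for name in ("ages", "state_cycle_death", "sevex_cycle_excess"):
            arr = np.asarray(getattr(self, name), dtype=float)
            arr.flags.writeable = False
            object.__setattr__(self, name, arr)

    @property
    def n_cycles(self) -> int:
        return len(self.ages)


@dataclass(frozen=True)
class CalibrationAnchors:
    """Published discounted life-year anchors used to pin the two excess-
    mortality scales (usual care and glycopyrronium arms)."""

    uc_discounted_ly: float = 10.18
    gly_discounted_ly: float = 9.93
    discount_rate: float = 0.03

    def validate(self) -> list[str]:
        errs = []
        if not (0 < self.gly_discounted_ly <= self.uc_discounted_ly):
            errs.append("anchors: require 0 < GLY life years <= UC life years")
        if self.discount_rate < 0:
            errs.append("anchors: discount rate must be >= 0")
        return errs


@dataclass(frozen=True)
class CalibrationResult:
    state_scale: float
    sevex_scale: float
    uc_discounted_ly: float
    gly_discounted_ly: float
    tio_discounted_ly: float
    anchors: CalibrationAnchors
    tolerance_years: float
    engine_runs: int


def _decade_interp(
    ages: np.ndarray, base: np.ndarray | float, gradient: float, reference_age: float
) -> np.ndarray:
    """Evaluate ``base * gradient**((age - ref)/10)`` at whole-decade knots
    and interpolate linearly between them (piecewise-linear age profile)."""
    lo = reference_age + 10.0 * math.floor((ages.min() - reference_age) / 10.0)
    hi = reference_age + 10.0 * math.ceil((ages.max() - reference_age) / 10.0)
    knots = np.arange(lo, hi + 5.0, 10.0)
    base = np.atleast_1d(np.asarray(base, dtype=float))
    knot_vals = base[:, None] * gradient ** ((knots - reference_age) / 10.0)
    out = np.vstack([np.interp(ages, knots, kv) for kv in knot_vals])
    return out


def build_schedule(
    background: BackgroundMortalityModel,
    excess: ExcessMortalityConfig,
    settings: "EconomicSettings",
    horizon_years: float | None = None,
) -> MortalitySchedule:
    """Construct the per-cycle mortality schedule over the model horizon.

    For each cycle-start age the annual state-specific death probability is
    ``1 - (1 - q0(age))**(1 + state_scale * (RR_state(age) - 1))`` with
    ``q0`` the COPD-corrected background: the state relative risk acts on the
    hazard scale, which coincides with probability-scale multiplication for
    small risks but stays inside [0, 1] at the oldest ages where GOLD IV
    relative risks would otherwise push the product past certainty.  The
    annual probability is then converted to a per-cycle one under a constant
    hazard.  The severe-exacerbation excess is a per-event additive
    probability ``sevex_scale * base_excess * gradient^((age-ref)/10)``.
    """
    errs = background.validate() + excess.validate()
    if errs:
        raise MortalityError("; ".join(errs))
    L = settings.cycle_length_years
    horizon = settings.horizon_years if horizon_years is None else horizon_years
    n = int(round(horizon / L))
    ages = settings.start_age_years + L * np.arange(n)

    q0 = background.corrected_annual_probability(ages)
    rr_excess = _decade_interp(
        ages,
        np.asarray(excess.state_rr, dtype=float) - 1.0,
        excess.state_age_gradient,
        excess.reference_age,
    )  # (3, n)
    hazard_multiplier = 1.0 + excess.state_scale * rr_excess
    annual = 1.0 - (1.0 - q0[None, :]) ** hazard_multiplier
    if np.any(annual < 0) or np.any(annual > 1):
        k, s = _first_bad(annual.T)
        raise MortalityError(
            f"annual death probability outside [0, 1] at age {ages[k]:.2f}, "
            f"state index {s}"
        )
    state_cycle = (1.0 - (1.0 - annual) ** L).T  # (n, 3)

    sevex = excess.sevex_scale * _decade_interp(
        ages, excess.sevex_base_excess, excess.sevex_age_gradient, excess.reference_age
    )[0]
    if np.any(sevex < 0):
        k = int(np.argmax(sevex < 0))
        raise MortalityError(
            f"negative severe-exacerbation excess death probability "
            f"at age {ages[k]:.2f}"
        )
    # a per-event death probability saturates at certainty; the engine caps
    # the state-plus-event total at 1 as well
    sevex = np.minimum(sevex, 1.0)

    _check_monotone(ages, state_cycle)
    return MortalitySchedule(ages=ages, state_cycle_death=state_cycle, sevex_cycle_excess=sevex)


def _first_bad(arr: np.ndarray) -> tuple[int, int]:
    bad = np.argwhere((arr < 0) | (arr > 1))
    return int(bad[0][0]), int(bad[0][1])


def _check_monotone(ages: np.ndarray, state_cycle: np.ndarray) -> None:
    tol = 1e-12
    if np.any(np.diff(state_cycle, axis=0) < -tol):
        k = int(np.argmax(np.any(np.diff(state_cycle, axis=0) < -tol, axis=1)))
        raise MortalityError(
            f"death probability decreases with age near age {ages[k]:.2f}"
        )
    if np.any(np.diff(state_cycle, axis=1) < -tol):
        k = int(np.argmax(np.any(np.diff(state_cycle, axis=1) < -tol, axis=1)))
        raise MortalityError(
            f"death probability not ordered GOLD II <= III <= IV at age {ages[k]:.2f}"
        )


def apply_scales(
    params: "ModelParameters", state_scale: float, sevex_scale: float
) -> "ModelParameters":
    """Return a copy of ``params`` with the two calibration scales set."""
    return params.replace(
        excess_mortality=replace(
            params.excess_mortality, state_scale=state_scale, sevex_scale=sevex_scale
        )
    )


def calibrate(
    anchors: CalibrationAnchors,
    params: "ModelParameters",
    ly_tolerance: float = 1e-3,
    max_scale: float = 64.0,
) -> CalibrationResult:
    """Find the (state_scale, sevex_scale) pair reproducing both anchors.

    Nested deterministic one-dimensional root-finding: for each candidate
    GOLD-state scale the inner solve pins the severe-exacerbation scale on
    the glycopyrronium anchor, then the outer residual is evaluated on the
    usual-care arm.  Both discounted life-year residuals are driven below
    ``ly_tolerance``; brackets are grown by doubling and a diagnostic error
    reports the attainable range if an anchor lies outside it.
    """
    from . import engine  # deferred: engine depends on parameters

    errs = anchors.validate()
    if errs:
        raise MortalityError("; ".join(errs))
    base = params.replace(
        settings=replace(params.settings, discount_rate_annual=anchors.discount_rate)
    )
    runs = 0

    def arm_ly(arm: str, state_scale: float, sevex_scale: float) -> float:
        nonlocal runs
        runs += 1
        p = apply_scales(base, state_scale, sevex_scale)
        schedule = build_schedule(p.background_mortality, p.excess_mortality, p.settings)
        return engine.run_cohort(arm, p, schedule).life_years

    def solve_sevex(state_scale: float) -> float:
        f = lambda x: arm_ly("GLY", state_scale, x) - anchors.gly_discounted_ly
        f0 = f(0.0)
        if f0 < 0:
            raise MortalityError(
                f"GLY anchor {anchors.gly_discounted_ly} not attainable: even with "
                f"no severe-exacerbation excess the arm yields {f0 + anchors.gly_discounted_ly:.3f} y"
            )
        hi = 1.0
        while f(hi) > 0:
            hi *= 2.0
            if hi > max_scale:
                raise MortalityError(
                    f"GLY anchor {anchors.gly_discounted_ly} below attainable range "
                    f"(sevex_scale bracket [0, {max_scale}])"
                )
        return brentq(f, 0.0, hi, xtol=1e-8)

    def outer(state_scale: float) -> float:
        x = solve_sevex(state_scale)
        return arm_ly("UC", state_scale, x) - anchors.uc_discounted_ly

    g0 = outer(0.0)
    if g0 < 0:
        raise MortalityError(
            f"UC anchor {anchors.uc_discounted_ly} not attainable: zero GOLD-state "
            f"excess already yields {g0 + anchors.uc_discounted_ly:.3f} y"
        )
    hi = 1.0
    while outer(hi) > 0:
        hi *= 2.0
        if hi > max_scale:
            raise MortalityError(
                f"UC anchor {anchors.uc_discounted_ly} below attainable range "
                f"(state_scale bracket [0, {max_scale}])"
            )
    state_scale = brentq(outer, 0.0, hi, xtol=1e-7)
    sevex_scale = solve_sevex(state_scale)

    uc_ly = arm_ly("UC", state_scale, sevex_scale)
    gly_ly = arm_ly("GLY", state_scale, sevex_scale)
    tio_ly = arm_ly("TIO", state_scale, sevex_scale)
    if abs(uc_ly - anchors.uc_discounted_ly) > ly_tolerance or abs(
        gly_ly - anchors.gly_discounted_ly
    ) > ly_tolerance:
        raise MortalityError(
            f"calibration did not converge: UC {uc_ly:.4f} vs "
            f"{anchors.uc_discounted_ly}, GLY {gly_ly:.4f} vs "
            f"{anchors.gly_discounted_ly}"
        )
    return CalibrationResult(
        state_scale=state_scale,
        sevex_scale=sevex_scale,
        uc_discounted_ly=uc_ly,
        gly_discounted_ly=gly_ly,
        tio_discounted_ly=tio_ly,
        anchors=anchors,
        tolerance_years=ly_tolerance,
        engine_runs=runs,
    )


def write_calibration_sidecar(result: CalibrationResult, path: str | Path) -> None:
    """Write calibrated scales plus provenance (anchors, tolerance, number of
    cohort runs) to a JSON sidecar."""
    Path(path).write_text(
        json.dumps(
            {
                "state_scale": result.state_scale,
                "sevex_scale": result.sevex_scale,
                "uc_discounted_ly": result.uc_discounted_ly,
                "gly_discounted_ly": result.gly_discounted_ly,
                "tio_discounted_ly": result.tio_discounted_ly,
                "anchors": {
                    "uc_discounted_ly": result.anchors.uc_discounted_ly,
                    "gly_discounted_ly": result.anchors.gly_discounted_ly,
                    "discount_rate": result.anchors.discount_rate,
                },
                "tolerance_years": result.tolerance_years,
                "engine_runs": result.engine_runs,
            },
            indent=2,
        )
    )
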