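"""Pairwise incremental analysis and net-benefit computation.

The incremental cost-effectiveness ratio (ICER) is always computed on
unrounded accumulators; rounded deltas are a display concern.  Dominance is
labelled on the cost-effectiveness plane: an intervention that is no more
expensive and strictly more effective (or strictly cheaper and no less
effective) dominates; the mirror case is dominated; in the trade-off
quadrants the ICER is reported.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .engine import ArmResult

__all__ = [
    "DOMINATING",
    "DOMINATED",
    "EQUIVALENT",
    "IncrementalResult",
    "NetBenefit",
    "incremental_analysis",
    "net_monetary_benefit",
    "comparison_table",
]

DOMINATING = "DOMINATING"
DOMINATED = "DOMINATED"
EQUIVALENT = "EQUIVALENT"


@dataclass(frozen=True)
class IncrementalResult:
    """Intervention-minus-reference deltas and the resulting ICER or
    dominance label (exactly one of ``icer`` / ``label`` is set)."""

    reference: str
    intervention: str
    delta_cost: float
    delta_qalys: float
    delta_ly: float
    icer: float | None
    label: str | None

    @property
    def icer_or_label(self) -> float | str:
        return self.icer if self.icer is not None else self.label


@dataclass(frozen=True)
class NetBenefit:
    """Net monetary benefit at a willingness-to-pay: wtp * dQALY - dcost."""

    wtp: float
    nmb: float


def incremental_analysis(
    reference: ArmResult, intervention: ArmResult, tol: float = 1e-12
) -> IncrementalResult:
    """Compare two arm results run under identical settings."""
    if (
        abs(reference.discount_rate - intervention.discount_rate) > 1e-12
        or abs(reference.horizon_years - intervention.horizon_years) > 1e-9
    ):
        raise ValueError(
            "arm results were produced under different settings "
            f"(discount {reference.discount_rate} vs {intervention.discount_rate}, "
            f"horizon {reference.horizon_years} vs {intervention.horizon_years})"
        )
    dc = intervention.total_cost - reference.total_cost
    dq = intervention.qalys - reference.qalys
    dly = intervention.life_years - reference.life_years

    icer: float | None = None
    label: str | None = None
    if abs(dq) <= tol and abs(dc) <= tol:
        label = EQUIVALENT
    elif (dq > tol and dc <= tol) or (dq >= -tol and dc < -tol):
        label = DOMINATING
    elif (dq < -tol and dc >= -tol) or (dq <= tol and dc > tol):
        label = DOMINATED
    else:
        icer = dc / dq
    return IncrementalResult(
        reference=reference.arm,
        intervention=intervention.arm,
        delta_cost=dc,
        delta_qalys=dq,
        delta_ly=dly,
        icer=icer,
        label=label,
    )


def net_monetary_benefit(inc: IncrementalResult, wtp: float) -> NetBenefit:
    """Net monetary benefit of the intervention at a willingness-to-pay
    threshold (SEK per QALY)."""
    if wtp < 0:
        raise ValueError("willingness-to-pay must be >= 0")
    return NetBenefit(wtp=wtp, nmb=wtp * inc.delta_qalys - inc.delta_cost)


def comparison_table(
    results: dict[str, ArmResult], comparisons: list[tuple[str, str]]
) -> pd.DataFrame:
    """Arm-level accumulators plus pairwise comparisons in the standard
    result-table layout (treatment / direct / total costs, QALYs, life
    years, ICER)."""
    rows = []
    for arm, r in results.items():
        rows.append(
            {
                "arm": arm,
                "treatment_costs": r.treatment_cost,
                "direct_costs": r.other_direct_cost,
                "total_costs": r.total_cost,
                "qalys": r.qalys,
                "life_years": r.life_years,
                "severe_exacerbations": float(r.events[2]),
                "nonsevere_exacerbations": float(r.events[1]),
            }
        )
    for ref, interv in comparisons:
        inc = incremental_analysis(results[ref], results[interv])
        rows.append(
            {
                "arm": f"{interv} vs {ref}",
                "treatment_costs": results[interv].treatment_cost
                - results[ref].treatment_cost,
                "direct_costs": results[interv].other_direct_cost
                - results[ref].other_direct_cost,
                "total_costs": inc.delta_cost,
                "qalys": inc.delta_qalys,
                "life_years": inc.delta_ly,
                "icer": inc.icer_or_label,
            }
        )
    return pd.DataFrame(rows)
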