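"""Incremental cost-effectiveness computation and WTP classification."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Optional

from .engine import CohortTrace

Classification = Literal[
    "dominant", "cost_effective", "not_cost_effective", "dominated", "indifferent"
]


def icer(cost_a: float, qaly_a: float, cost_b: float, qaly_b: float
         ) -> Optional[float]:
    """(cost_a - cost_b) / (qaly_a - qaly_b), or None when QALYs are equal.

    The raw ratio is returned even when its sign makes it meaningless as a
    willingness-to-pay comparison (dominance); callers should report the
    classification, not the ratio, in that case.
    """
    dq = qaly_a - qaly_b
    if dq == 0:
        return None
    return (cost_a - cost_b) / dq


def nmb(delta_cost: float, delta_qaly: float, wtp: float) -> float:
    """Net monetary benefit ``wtp * dQALY - dCost``; positive iff acceptable."""
    if wtp < 0:
        raise ValueError("wtp must be >= 0")
    return wtp * delta_qaly - delta_cost


def classify(delta_cost: float, delta_qaly: float, wtp: float) -> Classification:
    """Dominance/WTP classification of the intervention vs its comparator.

    ``dominated`` corresponds to "inferior" in Monte Carlo reporting: more
    costly and less effective.  Ties at zero net monetary benefit resolve
    to ``cost_effective``.
    """
    if delta_cost == 0 and delta_qaly == 0:
        return "indifferent"
    if delta_cost < 0 and delta_qaly > 0:
        return "dominant"
    if delta_cost > 0 and delta_qaly < 0:
        return "dominated"
    return "cost_effective" if nmb(delta_cost, delta_qaly, wtp) >= 0 else "not_cost_effective"


@dataclass(frozen=True)
class CEAResult:
    """Pairwise comparison: intervention (index 0) vs comparator (index 1)."""

    strategy_names: tuple[str, str]
    cost: tuple[float, float]
    qaly: tuple[float, float]
    delta_cost: float
    delta_qaly: float
    icer: Optional[float]
    classification: Classification
    wtp: float

    def to_dict(self) -> dict:
        return {
            "strategies": list(self.strategy_names),
            "cost": list(self.cost),
            "qaly": list(self.qaly),
            "delta_cost": self.delta_cost,
            "delta_qaly": self.delta_qaly,
            "icer": self.icer,
            "classification": self.classification,
            "wtp": self.wtp,
        }


def compare(name_a: str, cost_a: float, qaly_a: float,
            name_b: str, cost_b: float, qaly_b: float,
            wtp: float = 100_000.0) -> CEAResult:
    """Build a :class:`CEAResult` for intervention ``a`` vs comparator ``b``."""
    dc = cost_a - cost_b
    dq = qaly_a - qaly_b
    return CEAResult(
        strategy_names=(name_a, name_b),
        cost=(cost_a, cost_b),
        qaly=(qaly_a, qaly_b),
        delta_cost=dc,
        delta_qaly=dq,
        icer=icer(cost_a, qaly_a, cost_b, qaly_b),
        classification=classify(dc, dq, wtp),
        wtp=wtp,
    )


def compare_traces(trace_a: CohortTrace, trace_b: CohortTrace,
                   wtp: float = 100_000.0) -> CEAResult:
    """Compare two cohort traces (intervention first)."""
    return compare(trace_a.model_name, trace_a.cumulative_cost, trace_a.cumulative_qaly,
                   trace_b.model_name, trace_b.cumulative_cost, trace_b.cumulative_qaly,
                   wtp=wtp)
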