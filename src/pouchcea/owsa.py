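"""One-way deterministic sensitivity analysis with threshold refinement.

A sweep evaluates the full cohort pipeline at equally spaced values of one
parameter (all others held at their current values), classifies each point
at the chosen willingness-to-pay, and refines every classification change
by bisection.  Sweeps may exceed the Monte Carlo ranges (the published
sweeps go to 0-99% and $1-$10,000) but never the role bounds.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np
import pandas as pd

from .cea import CEAResult, Classification, compare_traces
from .engine import DiscountBasis, StrategyModel, run_cohort
from .params import ParameterError, ParameterSet, override, registry, role_bounds

ModelBuilder = Callable[[ParameterSet], tuple[StrategyModel, StrategyModel]]


@dataclass(frozen=True)
class ThresholdResult:
    parameter: str
    sweep_range: tuple[float, float]
    wtp: float
    thresholds: tuple[tuple[float, Classification, Classification], ...]
    curve: pd.DataFrame  # columns: value, icer, classification

    def threshold_values(self) -> list[float]:
        return [t[0] for t in self.thresholds]


def evaluate_at(builder: ModelBuilder, ps: ParameterSet, parameter: str,
                value: float, *, wtp: float = 100_000.0,
                horizon_years: float = 2.0, discount_rate: float = 0.03,
                discount_basis: DiscountBasis = "cycle") -> CEAResult:
    """CEA of the built pair with one parameter overridden."""
    p = override(ps, parameter, value)
    intervention, comparator = builder(p)
    tr_a = run_cohort(intervention, p, horizon_years, discount_rate, discount_basis)
    tr_b = run_cohort(comparator, p, horizon_years, discount_rate, discount_basis)
    return compare_traces(tr_a, tr_b, wtp=wtp)


def _check_range(ps: ParameterSet, parameter: str, low: float, high: float) -> None:
    reg = registry(ps.scope)
    if parameter not in reg:
        raise ParameterError(f"unknown parameter {parameter!r}")
    lo, hi = role_bounds(reg[parameter].role)
    if low < lo or high > hi:
        raise ParameterError(
            f"sweep range [{low}, {high}] violates {reg[parameter].role} "
            f"bounds [{lo}, {hi}] for {parameter}")


def find_threshold(builder: ModelBuilder, ps: ParameterSet, parameter: str,
                   bracket: tuple[float, float], *, wtp: float = 100_000.0,
                   tol: Optional[float] = None, horizon_years: float = 2.0,
                   discount_rate: float = 0.03,
                   discount_basis: DiscountBasis = "cycle") -> float:
    """Bisect a classification change inside ``bracket``.

    The returned value is the crossing point of the classification
    indicator (a zero of net monetary benefit, or a dominance boundary).
    Raises if both endpoints classify identically.
    """
    low, high = bracket
    if not low < high:
        raise ValueError("bracket must satisfy low < high")
    _check_range(ps, parameter, low, high)
    if tol is None:
        tol = 1e-4 * (high - low)

    def cls(x: float) -> Classification:
        return evaluate_at(builder, ps, parameter, x, wtp=wtp,
                           horizon_years=horizon_years,
                           discount_rate=discount_rate,
                           discount_basis=discount_basis).classification

    c_lo, c_hi = cls(low), cls(high)
    if c_lo == c_hi:
        raise ValueError(
            f"no classification change in bracket [{low}, {high}] "
            f"(both {c_lo})")
    while high - low > tol:
        mid = 0.5 * (low + high)
        if cls(mid) == c_lo:
            low = mid
        else:
            high = mid
    return 0.5 * (low + high)


def sweep(builder: ModelBuilder, ps: ParameterSet, parameter: str,
          low: float, high: float, n_points: int = 199, *,
          wtp: float = 100_000.0, horizon_years: float = 2.0,
          discount_rate: float = 0.03,
          discount_basis: DiscountBasis = "cycle",
          refine: bool = True) -> ThresholdResult:
    """Sweep ``parameter`` over [low, high] and locate all thresholds."""
    if n_points < 2:
        raise ValueError("n_points must be >= 2")
    if not low < high:
        raise ValueError("low < high required")
    _check_range(ps, parameter, low, high)

    grid = np.linspace(low, high, n_points)
    rows = []
    classes: list[Classification] = []
    for x in grid:
        res = evaluate_at(builder, ps, parameter, float(x), wtp=wtp,
                          horizon_years=horizon_years,
                          discount_rate=discount_rate,
                          discount_basis=discount_basis)
        rows.append({"value": float(x), "icer": res.icer,
                     "classification": res.classification})
        classes.append(res.classification)

    thresholds = []
    for (x0, c0), (x1, c1) in zip(zip(grid, classes), zip(grid[1:], classes[1:])):
        if c0 == c1:
            continue
        x_star = float(x1)
        if refine:
            x_star = find_threshold(builder, ps, parameter, (float(x0), float(x1)),
                                    wtp=wtp, horizon_years=horizon_years,
                                    discount_rate=discount_rate,
                                    discount_basis=discount_basis)
        thresholds.append((x_star, c0, c1))

    return ThresholdResult(
        parameter=parameter, sweep_range=(low, high), wtp=wtp,
        thresholds=tuple(thresholds), curve=pd.DataFrame(rows))
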