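"""Patient-level microsimulation oracle and synthetic-data generator.

Simulates individual trajectories under the same transition matrices and
replays the cohort engine's reward conventions (shared code, not a
re-implementation), so comparing aggregated trajectories with the cohort
trace isolates the transition logic.  Also generates bounds-respecting
synthetic parameter sets for property-based tests.

Each patient gets an independent random stream derived from
``(master seed, patient index)``, so estimates are reproducible and
independent of execution order.
"""

from __future__ import annotations

from dataclasses import dataclass
import numpy as np
import pandas as pd

from .engine import (DiscountBasis, StrategyModel, discount_factors,
                     n_cycles_for, reward_arrays)
from .params import ParameterSet
from .psa import draw_parameter_set


@dataclass
class PatientHistory:
    strategy: str
    states: list[str]                 # one per cycle boundary, length n_cycles+1
    events: list[tuple[int, str]]     # (cycle, event tag) at first entry
    accrued_cost: float               # discounted
    accrued_qaly: float               # discounted


def _path_rewards(model: StrategyModel, path: np.ndarray,
                  utility: np.ndarray, cycle_cost: np.ndarray,
                  entry: np.ndarray, df: np.ndarray) -> tuple[float, float]:
    """Replay the engine's reward conventions over one state-index path."""
    cur, nxt = path[:-1], path[1:]
    cost = float((cycle_cost[cur] * df[:-1]).sum()
                 + (entry[cur, nxt] * df[1:]).sum())
    qaly = float((utility[cur] * df[:-1]).sum() * model.cycle_length_years)
    return cost, qaly


def _transition_cumsums(model: StrategyModel, ps: ParameterSet) -> np.ndarray:
    M = np.asarray(model.transition_rule(0, ps), dtype=float)
    cum = np.cumsum(M, axis=1)
    cum[:, -1] = 1.0  # guard against cumulative rounding below 1
    return cum


def simulate_patient(model: StrategyModel, ps: ParameterSet,
                     horizon_years: float, seed: int,
                     discount_rate: float = 0.03,
                     discount_basis: DiscountBasis = "cycle") -> PatientHistory:
    """Simulate one trajectory; deterministic for a fixed seed."""
    n_cycles = n_cycles_for(horizon_years, model.cycle_length_years)
    rng = np.random.default_rng(seed)
    cum = _transition_cumsums(model, ps)
    init_cum = np.cumsum(model.initial_occupancy)
    init_cum[-1] = 1.0

    path = np.empty(n_cycles + 1, dtype=np.int64)
    path[0] = int(np.searchsorted(init_cum, rng.random(), side="right"))
    us = rng.random(n_cycles)
    for k in range(n_cycles):
        path[k + 1] = int(np.searchsorted(cum[path[k]], us[k], side="right"))

    utility, cycle_cost, entry = reward_arrays(model, ps)
    df = discount_factors(n_cycles, model.cycle_length_years,
                          discount_rate, discount_basis)
    cost, qaly = _path_rewards(model, path, utility, cycle_cost, entry, df)

    tags = sorted({t for s in model.states for t in s.tags})
    events: list[tuple[int, str]] = []
    for tag in tags:
        member = np.array([tag in s.tags for s in model.states])
        hits = np.nonzero(member[path])[0]
        if hits.size:
            events.append((int(hits[0]), tag))
    return PatientHistory(strategy=model.name,
                          states=[model.state_ids[i] for i in path],
                          events=sorted(events),
                          accrued_cost=cost, accrued_qaly=qaly)


@dataclass
class SimulationEstimate:
    n_patients: int
    mean_cost: float
    se_cost: float
    mean_qaly: float
    se_qaly: float
    occupancy: np.ndarray             # empirical (n_cycles+1, n_states)
    occupancy_se: np.ndarray
    event_incidence: dict[str, float]
    event_incidence_se: dict[str, float]


def estimate_by_simulation(model: StrategyModel, ps: ParameterSet,
                           n: int, seed: int, *, horizon_years: float = 2.0,
                           discount_rate: float = 0.03,
                           discount_basis: DiscountBasis = "cycle"
                           ) -> SimulationEstimate:
    """Aggregate ``n`` simulated trajectories into a cohort-trace estimate.

    A consistent estimator of :func:`pouchcea.engine.run_cohort`; standard
    errors are empirical (normal for means, binomial for proportions).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    n_cycles = n_cycles_for(horizon_years, model.cycle_length_years)
    n_states = len(model.states)
    children = np.random.SeedSequence([int(seed)]).spawn(n)

    U = np.empty((n, n_cycles + 1))
    for i, child in enumerate(children):
        U[i] = np.random.default_rng(child).random(n_cycles + 1)

    cum = _transition_cumsums(model, ps)
    init_cum = np.cumsum(model.initial_occupancy)
    init_cum[-1] = 1.0
    paths = np.empty((n, n_cycles + 1), dtype=np.int64)
    paths[:, 0] = np.searchsorted(init_cum, U[:, 0], side="right")
    for k in range(n_cycles):
        rows = cum[paths[:, k]]                       # (n, n_states)
        paths[:, k + 1] = (U[:, k + 1][:, None] >= rows).sum(axis=1)

    utility, cycle_cost, entry = reward_arrays(model, ps)
    df = discount_factors(n_cycles, model.cycle_length_years,
                          discount_rate, discount_basis)
    cur, nxt = paths[:, :-1], paths[:, 1:]
    costs = (cycle_cost[cur] * df[:-1]).sum(axis=1) + (entry[cur, nxt] * df[1:]).sum(axis=1)
    qalys = (utility[cur] * df[:-1]).sum(axis=1) * model.cycle_length_years

    occ = np.stack([np.bincount(paths[:, k], minlength=n_states) / n
                    for k in range(n_cycles + 1)])
    occ_se = np.sqrt(occ * (1 - occ) / n)

    tags = sorted({t for s in model.states for t in s.tags})
    inc, inc_se = {}, {}
    for tag in tags:
        member = np.array([tag in s.tags for s in model.states])
        ever = member[paths].any(axis=1)
        p = float(ever.mean())
        inc[tag] = p
        inc_se[tag] = float(np.sqrt(p * (1 - p) / n))

    ddof = 1 if n > 1 else 0
    return SimulationEstimate(
        n_patients=n,
        mean_cost=float(costs.mean()),
        se_cost=float(costs.std(ddof=ddof) / np.sqrt(n)),
        mean_qaly=float(qalys.mean()),
        se_qaly=float(qalys.std(ddof=ddof) / np.sqrt(n)),
        occupancy=occ,
        occupancy_se=occ_se,
        event_incidence=inc,
        event_incidence_se=inc_se,
    )


def histories_to_frame(histories: list[PatientHistory]) -> pd.DataFrame:
    """Long-format (patient, cycle, state) table for inspection/export."""
    rows = []
    for i, h in enumerate(histories):
        for k, s in enumerate(h.states):
            rows.append({"patient": i, "cycle": k, "state": s,
                         "cost": h.accrued_cost, "qaly": h.accrued_qaly})
    return pd.DataFrame(rows)


def generate_test_parameters(scope: str, n: int, seed: int) -> list[ParameterSet]:
    """Synthetic, bounds-respecting parameter sets (triangular draws)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    return [draw_parameter_set(scope, rng) for _ in range(n)]
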