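"""Primary-prevention models: probiotic prophylaxis vs no prophylaxis.

A cohort of patients with an ileal pouch and no history of pouchitis is
followed on 2-week cycles.  The first pouchitis episode triggers a
diagnostic workup (base variant) and a ciprofloxacin course; ciprofloxacin
failures escalate to metronidazole and then to a 4-week dual
ciprofloxacin/tinidazole course.  Responders enter a line-specific
remission from which recurrences are retreated with the previously
effective antibiotic, and failure of that antibiotic escalates to the next
line.  Patients on the probiotic take it only while pouchitis-free and stop
at the first episode.

Variants
--------
``base``
    Workup charged at the first episode; dual-antibiotic response is
    structurally 100% (the model's terminal line).
``empirical_workup``
    First episode treated empirically; the workup cost is deferred to the
    first recurrence or first antibiotic failure, whichever comes first.
    Identical QALYs to ``base`` at equal parameters (cost-only change).
``extended_biologics``
    Dual-antibiotic nonresponders (response 0.69) escalate to vedolizumab
    and then to an absorbing infliximab remission, with dosing costs on the
    2-week grid.
"""

from __future__ import annotations

from typing import Literal

import numpy as np

from .biologics import ifx_schedule_2wk, vdz_schedule_2wk, BiologicSchedule
from .engine import HealthState, StrategyModel, to_cycle_probability
from .params import ParameterSet, validate

CYCLE_LENGTH_YEARS = 1.0 / 26.0

PrimaryVariant = Literal["base", "empirical_workup", "extended_biologics"]

_VARIANT_ALIASES = {
    "base": "base",
    "empirical": "empirical_workup",
    "empirical_workup": "empirical_workup",
    "extended": "extended_biologics",
    "extended_biologics": "extended_biologics",
}

_ACTIVE = "utility_active_pouchitis"
_WELL = "utility_no_pouchitis"


def resolve_variant(variant: str) -> PrimaryVariant:
    try:
        return _VARIANT_ALIASES[variant]
    except KeyError:
        raise ValueError(
            f"unknown primary variant {variant!r}; expected one of "
            f"{sorted(set(_VARIANT_ALIASES))}") from None


def _biologic_states(prefix: str, schedule: BiologicSchedule, *,
                     induction_utility: str, tags: frozenset
                     ) -> tuple[list[HealthState], list[str], list[str]]:
    """Induction chain + maintenance loop states for one biologic.

    Returns ``(states, induction_ids, maintenance_ids)``; dose costs are
    attached per state from the schedule's per-cycle dose counts.
    """
    states: list[HealthState] = []
    ind_ids: list[str] = []
    for c in range(schedule.induction_length_cycles):
        doses = schedule.doses_at(c)
        costs = ((schedule.dose_cost_ref, doses * schedule.dose_scale),) if doses else ()
        sid = f"{prefix}_ind{c + 1}"
        states.append(HealthState(sid, f"{schedule.drug} induction cycle {c + 1}",
                                  induction_utility, costs, tags=tags))
        ind_ids.append(sid)
    maint_ids: list[str] = []
    interval = schedule.maintenance_interval_cycles
    dose_phase = ((schedule.maintenance_start_cycle - schedule.induction_length_cycles)
                  % interval)
    for j in range(interval):
        doses = 1 if j == dose_phase else 0
        costs = ((schedule.dose_cost_ref, doses * schedule.dose_scale),) if doses else ()
        sid = f"{prefix}_m{j}"
        states.append(HealthState(sid, f"{schedule.drug} maintenance phase {j}",
                                  _WELL, costs, tags=tags))
        maint_ids.append(sid)
    return states, ind_ids, maint_ids


def _build_arm(ps: ParameterSet, arm: str, variant: PrimaryVariant,
               weight_kg: float) -> StrategyModel:
    probiotic = arm == "probiotic"
    p_first_ref = ("p_first_pouchitis_ppx_annual" if probiotic
                   else "p_first_pouchitis_no_ppx_annual")
    well_costs = (("cost_probiotic_2wk", 1.0),) if probiotic else ()
    well_tags = frozenset({"on_probiotic"}) if probiotic else frozenset()

    pouch = {"ever_pouchitis"}
    t_active = frozenset(pouch | {"active_episode"})
    t_metro = frozenset(pouch | {"ever_metro"})
    t_dual = frozenset(pouch | {"ever_metro", "ever_dual"})
    t_bio = frozenset(t_dual | {"ever_carp"})
    t_vdz = frozenset(t_bio | {"ever_vdz"})
    t_ifx = frozenset(t_bio | {"ever_vdz", "ever_ifx"})

    states: list[HealthState] = [
        HealthState("well", "pouchitis-free, never pouchitis", _WELL,
                    well_costs, tags=well_tags),
    ]
    if variant == "empirical_workup":
        states += [
            HealthState("cipro_rx_nw", "first episode, empirical cipro", _ACTIVE,
                        tags=t_active),
            HealthState("rem_cipro_nw", "remission after cipro, no workup yet",
                        _WELL, tags=frozenset(pouch)),
            HealthState("cipro_rx_w", "first recurrence, cipro + workup", _ACTIVE,
                        tags=t_active),
        ]
    states += [
        HealthState("cipro_rx", "cipro course", _ACTIVE, tags=t_active),
        HealthState("rem_cipro", "remission, cipro-responsive", _WELL,
                    tags=frozenset(pouch)),
        HealthState("metro_rx", "metronidazole course", _ACTIVE,
                    tags=t_active | t_metro),
        HealthState("rem_metro", "remission, metro-responsive", _WELL, tags=t_metro),
        HealthState("dual_rx1", "dual antibiotics, cycle 1 of 2", _ACTIVE,
                    tunnel_length_cycles=2, tags=t_active | t_dual),
        HealthState("dual_rx2", "dual antibiotics, cycle 2 of 2", _ACTIVE,
                    tunnel_length_cycles=2, tags=t_active | t_dual),
        HealthState("rem_dual", "remission, dual-responsive", _WELL, tags=t_dual),
    ]

    vdz = ifx = None
    if variant == "extended_biologics":
        vdz = vdz_schedule_2wk()
        ifx = ifx_schedule_2wk(weight_kg)
        vdz_states, vdz_ind, vdz_maint = _biologic_states(
            "vdz", vdz, induction_utility=_ACTIVE, tags=t_vdz | {"active_episode"})
        # maintenance states are responders in remission: strip the active marker
        vdz_states = [
            s if s.id in vdz_ind else
            HealthState(s.id, s.label, s.utility_ref, s.cycle_cost_refs, tags=t_vdz)
            for s in vdz_states
        ]
        ifx_states, ifx_ind, ifx_maint = _biologic_states(
            "ifx", ifx, induction_utility=_WELL, tags=t_ifx)
        states += vdz_states + ifx_states

    idx = {s.id: i for i, s in enumerate(states)}
    n = len(states)
    first_entry = "cipro_rx_nw" if variant == "empirical_workup" else "cipro_rx"

    entry_costs: dict[tuple[str, str], tuple[tuple[str, float], ...]] = {}
    if variant == "empirical_workup":
        entry_costs[("well", "cipro_rx_nw")] = (("cost_cipro_2wk", 1.0),)
        entry_costs[("cipro_rx_nw", "metro_rx")] = (
            ("cost_first_episode_workup", 1.0), ("cost_metro_2wk", 1.0))
        entry_costs[("rem_cipro_nw", "cipro_rx_w")] = (
            ("cost_first_episode_workup", 1.0), ("cost_cipro_2wk", 1.0))
        entry_costs[("cipro_rx_w", "metro_rx")] = (("cost_metro_2wk", 1.0),)
    else:
        entry_costs[("well", "cipro_rx")] = (
            ("cost_first_episode_workup", 1.0), ("cost_cipro_2wk", 1.0))
    entry_costs[("rem_cipro", "cipro_rx")] = (("cost_cipro_2wk", 1.0),)
    entry_costs[("cipro_rx", "metro_rx")] = (("cost_metro_2wk", 1.0),)
    entry_costs[("rem_metro", "metro_rx")] = (("cost_metro_2wk", 1.0),)
    entry_costs[("metro_rx", "dual_rx1")] = (("cost_dual_4wk", 1.0),)
    entry_costs[("rem_dual", "dual_rx1")] = (("cost_dual_4wk", 1.0),)

    def rule(cycle: int, p: ParameterSet) -> np.ndarray:
        q1 = to_cycle_probability(p[p_first_ref], CYCLE_LENGTH_YEARS)
        qr = to_cycle_probability(p["p_recurrent_pouchitis_annual"], CYCLE_LENGTH_YEARS)
        rc = p["p_resp_cipro_2wk"]
        rm = p["p_resp_metro_2wk"]
        rd = p["p_resp_dual_4wk"] if variant == "extended_biologics" else 1.0
        M = np.zeros((n, n))

        def t(src, dst, prob):
            M[idx[src], idx[dst]] += prob

        def stay(src):
            i = idx[src]
            M[i, i] += 1.0 - M[i].sum()

        t("well", first_entry, q1); stay("well")
        if variant == "empirical_workup":
            t("cipro_rx_nw", "rem_cipro_nw", rc)
            t("cipro_rx_nw", "metro_rx", 1 - rc)
            t("rem_cipro_nw", "cipro_rx_w", qr); stay("rem_cipro_nw")
            t("cipro_rx_w", "rem_cipro", rc)
            t("cipro_rx_w", "metro_rx", 1 - rc)
        t("cipro_rx", "rem_cipro", rc)
        t("cipro_rx", "metro_rx", 1 - rc)
        t("rem_cipro", "cipro_rx", qr); stay("rem_cipro")
        t("metro_rx", "rem_metro", rm)
        t("metro_rx", "dual_rx1", 1 - rm)
        t("rem_metro", "metro_rx", qr); stay("rem_metro")
        t("dual_rx1", "dual_rx2", 1.0)
        t("dual_rx2", "rem_dual", rd)
        t("rem_dual", "dual_rx1", qr); stay("rem_dual")
        if variant == "extended_biologics":
            qlor = to_cycle_probability(p["p_lor_vdz_annual"], CYCLE_LENGTH_YEARS)
            pv = p["p_resp_vdz"]
            t("dual_rx2", "vdz_ind1", 1 - rd)
            for a, b in zip(vdz_ind, vdz_ind[1:]):
                t(a, b, 1.0)
            t(vdz_ind[-1], vdz_maint[0], pv)
            t(vdz_ind[-1], ifx_ind[0], 1 - pv)
            for j, sid in enumerate(vdz_maint):
                t(sid, ifx_ind[0], qlor)
                t(sid, vdz_maint[(j + 1) % len(vdz_maint)], 1 - qlor)
            for a, b in zip(ifx_ind, ifx_ind[1:]):
                t(a, b, 1.0)
            t(ifx_ind[-1], ifx_maint[0], 1.0)
            for j, sid in enumerate(ifx_maint):
                t(sid, ifx_maint[(j + 1) % len(ifx_maint)], 1.0)
        return M

    init = tuple(1.0 if s.id == "well" else 0.0 for s in states)
    name = f"primary/{variant}/{'probiotic' if probiotic else 'no_prophylaxis'}"
    return StrategyModel(name=name, states=tuple(states), initial_occupancy=init,
                         cycle_length_years=CYCLE_LENGTH_YEARS,
                         transition_rule=rule, entry_costs=entry_costs)


def build_primary(ps: ParameterSet, variant: str = "base",
                  weight_kg: float = 70.0) -> tuple[StrategyModel, StrategyModel]:
    """Build the (probiotic, no-prophylaxis) pair of primary-prevention models."""
    var = resolve_variant(variant)
    violations = validate(ps, "primary")
    if violations:
        raise ValueError("invalid parameter set: " + "; ".join(violations))
    return (_build_arm(ps, "probiotic", var, weight_kg),
            _build_arm(ps, "no_prophylaxis", var, weight_kg))


def antibiotic_course_cost(line: str, model: str) -> tuple[str, int]:
    """(cost parameter name, tunnel length in cycles) for an antibiotic line."""
    table = {
        ("cipro", "primary"): ("cost_cipro_2wk", 1),
        ("metro", "primary"): ("cost_metro_2wk", 1),
        ("dual", "primary"): ("cost_dual_4wk", 2),
        ("cipro", "secondary"): ("cost_cipro_4wk", 1),
        ("metro", "secondary"): ("cost_metro_4wk", 1),
        ("dual", "secondary"): ("cost_dual_4wk", 1),
    }
    try:
        return table[(line, model)]
    except KeyError:
        raise ValueError(f"unknown line/model {(line, model)!r}") from None
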