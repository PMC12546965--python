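"""Secondary-prevention models: probiotic vs no prophylaxis of relapse.

A cohort with relapsing pouchitis starts in remission and is followed on
4-week cycles.  Relapses are treated empirically (no workup): a 4-week
ciprofloxacin course, then metronidazole, then dual ciprofloxacin/
tinidazole; later relapses are retreated with the previously effective
antibiotic, with failures escalating.  Dual-antibiotic failure defines
chronic antibiotic-refractory pouchitis (CARP): a one-time evaluation is
charged, the probiotic is discontinued, and vedolizumab is started
(response assessed after induction; responders face an annual loss of
response).  VDZ nonresponse or loss of response leads to infliximab, an
absorbing remission with continued dosing costs.

Patients on the probiotic continue it through antibiotic courses and
relapses, stopping only at CARP.
"""

from __future__ import annotations

import numpy as np

from .biologics import ifx_schedule_4wk, vdz_schedule_4wk
from .engine import HealthState, StrategyModel, to_cycle_probability
from .params import ParameterSet, validate
from .primary import _biologic_states

CYCLE_LENGTH_YEARS = 1.0 / 13.0

_ACTIVE = "utility_active_pouchitis"
_WELL = "utility_no_pouchitis"


def _build_arm(ps: ParameterSet, arm: str, weight_kg: float) -> StrategyModel:
    probiotic = arm == "probiotic"
    p_rel_ref = "p_relapse_ppx_annual" if probiotic else "p_relapse_no_ppx_annual"
    prob_cost = (("cost_probiotic_4wk", 1.0),) if probiotic else ()

    rel = {"ever_relapse"}
    t_active = frozenset(rel | {"active_episode"})
    t_metro = frozenset(rel | {"ever_metro"})
    t_dual = frozenset(rel | {"ever_metro", "ever_dual"})
    t_carp = frozenset(t_dual | {"ever_carp"})
    t_ifx = frozenset(t_carp | {"ever_ifx"})
    on_p = frozenset({"on_probiotic"}) if probiotic else frozenset()

    states: list[HealthState] = [
        HealthState("rem0", "remission, no relapse yet", _WELL, prob_cost, tags=on_p),
        HealthState("cipro_rx", "cipro course", _ACTIVE, prob_cost,
                    tags=t_active | on_p),
        HealthState("rem_cipro", "remission, cipro-responsive", _WELL, prob_cost,
                    tags=frozenset(rel) | on_p),
        HealthState("metro_rx", "metronidazole course", _ACTIVE, prob_cost,
                    tags=t_active | t_metro | on_p),
        HealthState("rem_metro", "remission, metro-responsive", _WELL, prob_cost,
                    tags=t_metro | on_p),
        HealthState("dual_rx", "dual antibiotic course", _ACTIVE, prob_cost,
                    tags=t_active | t_dual | on_p),
        HealthState("rem_dual", "remission, dual-responsive", _WELL, prob_cost,
                    tags=t_dual | on_p),
    ]

    vdz = vdz_schedule_4wk()
    ifx = ifx_schedule_4wk(weight_kg)
    vdz_states, vdz_ind, vdz_maint = _biologic_states(
        "vdz", vdz, induction_utility=_ACTIVE, tags=t_carp | {"active_episode"})
    vdz_states = [
        s if s.id in vdz_ind else
        HealthState(s.id, s.label, s.utility_ref, s.cycle_cost_refs, tags=t_carp)
        for s in vdz_states
    ]
    ifx_states, ifx_ind, ifx_maint = _biologic_states(
        "ifx", ifx, induction_utility=_WELL, tags=t_ifx)
    states += vdz_states + ifx_states

    idx = {s.id: i for i, s in enumerate(states)}
    n = len(states)

    entry_costs = {
        ("rem0", "cipro_rx"): (("cost_cipro_4wk", 1.0),),
        ("rem_cipro", "cipro_rx"): (("cost_cipro_4wk", 1.0),),
        ("cipro_rx", "metro_rx"): (("cost_metro_4wk", 1.0),),
        ("rem_metro", "metro_rx"): (("cost_metro_4wk", 1.0),),
        ("metro_rx", "dual_rx"): (("cost_dual_4wk", 1.0),),
        ("rem_dual", "dual_rx"): (("cost_dual_4wk", 1.0),),
        ("dual_rx", "vdz_ind1"): (("cost_carp_eval", 1.0),),
    }

    def rule(cycle: int, p: ParameterSet) -> np.ndarray:
        qrel = to_cycle_probability(p[p_rel_ref], CYCLE_LENGTH_YEARS)
        qlor = to_cycle_probability(p["p_lor_vdz_annual"], CYCLE_LENGTH_YEARS)
        rc = p["p_resp_cipro_4wk"]
        rm = p["p_resp_metro_4wk"]
        rd = p["p_resp_dual_4wk"]
        pv = p["p_resp_vdz"]
        M = np.zeros((n, n))

        def t(src, dst, prob):
            M[idx[src], idx[dst]] += prob

        def stay(src):
            i = idx[src]
            M[i, i] += 1.0 - M[i].sum()

        t("rem0", "cipro_rx", qrel); stay("rem0")
        t("cipro_rx", "rem_cipro", rc)
        t("cipro_rx", "metro_rx", 1 - rc)
        t("rem_cipro", "cipro_rx", qrel); stay("rem_cipro")
        t("metro_rx", "rem_metro", rm)
        t("metro_rx", "dual_rx", 1 - rm)
        t("rem_metro", "metro_rx", qrel); stay("rem_metro")
        t("dual_rx", "rem_dual", rd)
        t("dual_rx", "vdz_ind1", 1 - rd)
        t("rem_dual", "dual_rx", qrel); stay("rem_dual")
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

    init = tuple(1.0 if s.id == "rem0" else 0.0 for s in states)
    name = f"secondary/{'probiotic' if probiotic else 'no_prophylaxis'}"
    return StrategyModel(name=name, states=tuple(states), initial_occupancy=init,
                         cycle_length_years=CYCLE_LENGTH_YEARS,
                         transition_rule=rule, entry_costs=entry_costs)


def build_secondary(ps: ParameterSet, weight_kg: float = 70.0
                    ) -> tuple[StrategyModel, StrategyModel]:
    """Build the (probiotic, no-prophylaxis) pair of secondary models."""
    violations = validate(ps, "secondary")
    if violations:
        raise ValueError("invalid parameter set: " + "; ".join(violations))
    return (_build_arm(ps, "probiotic", weight_kg),
            _build_arm(ps, "no_prophylaxis", weight_kg))
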