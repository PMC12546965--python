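"""Structure of the primary and secondary prevention models."""

import numpy as np
import pytest

from pouchcea.biologics import (biologic_cycle_cost, ifx_dose_scale,
                                ifx_schedule_4wk, vdz_schedule_4wk)
from pouchcea.engine import run_cohort
from pouchcea.params import load_defaults, override
from pouchcea.primary import antibiotic_course_cost, build_primary
from pouchcea.secondary import build_secondary


def test_two_year_first_pouchitis_incidence_is_exact(primary_ps, primary_models):
    """1-(1-p)^2 under constant-hazard conversion: 19% vs 64%."""
    probiotic, no_ppx = primary_models
    tr_p = run_cohort(probiotic, primary_ps, 2.0)
    tr_n = run_cohort(no_ppx, primary_ps, 2.0)
    assert tr_p.final_incidence("ever_pouchitis") == pytest.approx(0.19, abs=1e-10)
    assert tr_n.final_incidence("ever_pouchitis") == pytest.approx(0.64, abs=1e-10)


def test_dual_antibiotic_reach_matches_reported_landmarks(primary_ps, primary_models):
    """About 2% (probiotic) and 7.3% (no prophylaxis) ever reach the
    dual-antibiotic line by 2 years."""
    probiotic, no_ppx = primary_models
    tr_p = run_cohort(probiotic, primary_ps, 2.0)
    tr_n = run_cohort(no_ppx, primary_ps, 2.0)
    assert tr_p.final_incidence("ever_dual") == pytest.approx(0.02, abs=0.015)
    assert tr_n.final_incidence("ever_dual") == pytest.approx(0.073, abs=0.015)


def test_probiotic_cost_only_while_never_pouchitis(primary_ps, primary_models):
    probiotic, _ = primary_models
    [well] = [s for s in probiotic.states if s.id == "well"]
    assert ("cost_probiotic_2wk", 1.0) in well.cycle_cost_refs
    for s in probiotic.states:
        if s.id != "well":
            assert all(ref != "cost_probiotic_2wk" for ref, _ in s.cycle_cost_refs)


def test_zero_first_pouchitis_probability_equalises_arms(primary_ps):
    ps = override(primary_ps, "p_first_pouchitis_ppx_annual", 0.0)
    ps = override(ps, "p_first_pouchitis_no_ppx_annual", 0.0)
    probiotic, no_ppx = build_primary(ps)
    tr_p = run_cohort(probiotic, ps, 2.0)
    tr_n = run_cohort(no_ppx, ps, 2.0)
    assert tr_p.cumulative_qaly == pytest.approx(tr_n.cumulative_qaly)
    assert tr_p.final_incidence("ever_pouchitis") == 0.0


def test_full_cipro_response_prevents_escalation(primary_ps):
    ps = override(primary_ps, "p_resp_cipro_2wk", 1.0)
    _, no_ppx = build_primary(ps)
    tr = run_cohort(no_ppx, ps, 2.0)
    assert tr.final_incidence("ever_metro") == 0.0
    assert tr.final_incidence("ever_dual") == 0.0


def test_empirical_variant_changes_costs_not_qalys(primary_ps):
    base_pair = build_primary(primary_ps, "base")
    emp_pair = build_primary(primary_ps, "empirical")
    for base_model, emp_model in zip(base_pair, emp_pair):
        tb = run_cohort(base_model, primary_ps, 2.0)
        te = run_cohort(emp_model, primary_ps, 2.0)
        assert te.cumulative_qaly == pytest.approx(tb.cumulative_qaly, rel=1e-12)
        assert te.cumulative_cost < tb.cumulative_cost  # workup deferred


def test_extended_variant_keeps_conclusion(primary_ps):
    """Escalating dual-antibiotic failures to VDZ/IFX does not change the
    cost-effectiveness conclusion: no prophylaxis stays preferred at the
    $100k/QALY threshold."""
    from pouchcea.cea import compare_traces

    def result_for(variant):
        a, b = build_primary(primary_ps, variant)
        return compare_traces(run_cohort(a, primary_ps, 2.0),
                              run_cohort(b, primary_ps, 2.0))

    base, ext = result_for("base"), result_for("extended")
    assert ext.classification == base.classification == "not_cost_effective"
    assert ext.icer > 100_000
    ext_pair = build_primary(primary_ps, "extended")
    assert any(s.id.startswith("vdz_") for s in ext_pair[1].states)

    with pytest.raises(ValueError, match="unknown primary variant"):
        build_primary(primary_ps, "nonsense")


def test_secondary_terminal_ifx_reach_matches_reported(secondary_ps, secondary_models):
    """About 0.4% (probiotic) and 1.1% (none) reach IFX within 2 years."""
    probiotic, no_ppx = secondary_models
    tr_p = run_cohort(probiotic, secondary_ps, 2.0)
    tr_n = run_cohort(no_ppx, secondary_ps, 2.0)
    assert tr_p.final_incidence("ever_ifx") == pytest.approx(0.004, abs=0.015)
    assert tr_n.final_incidence("ever_ifx") == pytest.approx(0.011, abs=0.015)


def test_secondary_relapse_dominance_every_cycle(secondary_ps, secondary_models):
    probiotic, no_ppx = secondary_models
    inc_p = run_cohort(probiotic, secondary_ps, 2.0).event_incidence["ever_relapse"]
    inc_n = run_cohort(no_ppx, secondary_ps, 2.0).event_incidence["ever_relapse"]
    assert np.all(inc_p[1:] < inc_n[1:])
    assert inc_n[-1] == pytest.approx(1 - (1 - 0.39) ** 2, abs=1e-10)
    assert inc_p[-1] == pytest.approx(1 - (1 - 0.14) ** 2, abs=1e-10)


def test_secondary_probiotic_cost_continues_until_carp(secondary_models):
    probiotic, _ = secondary_models
    for s in probiotic.states:
        on_probiotic = any(ref == "cost_probiotic_4wk" for ref, _ in s.cycle_cost_refs)
        in_biologic_phase = s.id.startswith(("vdz_", "ifx_"))
        assert on_probiotic != in_biologic_phase, s.id


def test_secondary_zero_relapse_limit(secondary_ps):
    ps = override(secondary_ps, "p_relapse_ppx_annual", 0.0)
    ps = override(ps, "p_relapse_no_ppx_annual", 0.0)
    probiotic, no_ppx = build_secondary(ps)
    tr_p = run_cohort(probiotic, ps, 2.0)
    tr_n = run_cohort(no_ppx, ps, 2.0)
    assert tr_n.cumulative_cost == 0.0
    assert tr_p.cumulative_qaly == pytest.approx(tr_n.cumulative_qaly)
    dfs = sum(1.03 ** (-k) for k in range(26))
    assert tr_p.cumulative_cost == pytest.approx(174 * dfs, rel=1e-12)


def test_perfect_vdz_response_prevents_ifx(secondary_ps):
    ps = override(secondary_ps, "p_resp_vdz", 1.0)
    ps = override(ps, "p_lor_vdz_annual", 0.0)
    _, no_ppx = build_secondary(ps)
    tr = run_cohort(no_ppx, ps, 2.0)
    assert tr.final_incidence("ever_ifx") == 0.0
    assert tr.final_incidence("ever_carp") > 0.0


def test_escalation_ladder_is_monotone(secondary_ps, secondary_models):
    """No transition moves from a higher treatment line to a lower one."""
    order = {"rem0": 0, "cipro_rx": 1, "rem_cipro": 1, "metro_rx": 2,
             "rem_metro": 2, "dual_rx": 3, "rem_dual": 3}
    for model in secondary_models:
        M = model.transition_rule(0, secondary_ps)
        ids = model.state_ids
        for i, src in enumerate(ids):
            for j, dst in enumerate(ids):
                if M[i, j] > 0:
                    lo = order.get(src, 4)
                    hi = order.get(dst, 4)
                    assert hi >= lo, (src, dst)


def test_antibiotic_course_costs_and_tunnels():
    assert antibiotic_course_cost("cipro", "primary") == ("cost_cipro_2wk", 1)
    assert antibiotic_course_cost("dual", "primary") == ("cost_dual_4wk", 2)
    assert antibiotic_course_cost("dual", "secondary") == ("cost_dual_4wk", 1)
    with pytest.raises(ValueError):
        antibiotic_course_cost("dual", "tertiary")


def test_biologic_cycle_cost_schedule(secondary_ps):
    vdz = vdz_schedule_4wk()
    assert biologic_cycle_cost(vdz, 0, secondary_ps) == 6803
    assert biologic_cycle_cost(vdz, 1, secondary_ps) == 2 * 6803
    assert biologic_cycle_cost(vdz, 2, secondary_ps) == 0   # off the Q8-week grid
    assert biologic_cycle_cost(vdz, 3, secondary_ps) == 6803
    assert biologic_cycle_cost(vdz, 4, secondary_ps) == 0
    ifx = ifx_schedule_4wk(70.0)
    assert ifx_dose_scale(70.0) == pytest.approx(350 / 300)
    assert biologic_cycle_cost(ifx, 3, secondary_ps) == pytest.approx(987 * 350 / 300)


def test_model_dose_states_match_schedule_account(secondary_ps, secondary_models):
    """Dose multiplicities baked into the VDZ state chain equal an
    independent per-cycle account from the schedule (double entry)."""
    _, no_ppx = secondary_models
    vdz = vdz_schedule_4wk()
    by_id = {s.id: s for s in no_ppx.states}

    def state_cost(sid):
        return sum(secondary_ps[ref] * mult
                   for ref, mult in by_id[sid].cycle_cost_refs)

    # a patient entering VDZ occupies: ind1, ind2, m0(off), m1(on), m0, ...
    chain = ["vdz_ind1", "vdz_ind2"] + ["vdz_m0", "vdz_m1"] * 4
    for cycles_since_start, sid in enumerate(chain):
        assert state_cost(sid) == pytest.approx(
            biologic_cycle_cost(vdz, cycles_since_start, secondary_ps)), sid
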