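"""Parameter registry: tabulated values, validation, triangular sampler."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pouchcea.params import (ParameterError, ParameterSet, ParamSpec,
                             load_defaults, override, registry,
                             registry_frame, sample_triangular,
                             triangular_mean, validate)

# Every tabulated base-case value and Monte Carlo range, by scope.
PRIMARY_TABLE = {
    "p_first_pouchitis_ppx_annual": (0.1, 0.05, 0.25),
    "p_first_pouchitis_no_ppx_annual": (0.4, 0.25, 0.50),
    "p_recurrent_pouchitis_annual": (0.39, 0.20, 0.50),
    "p_resp_cipro_2wk": (0.77, 0.60, 0.95),
    "p_resp_metro_2wk": (0.70, 0.55, 0.90),
    "cost_probiotic_2wk": (87.2, 50.0, 150.0),
    "cost_cipro_2wk": (12.0, 6.0, 24.0),
    "cost_metro_2wk": (22.68, 11.0, 45.0),
    "cost_dual_4wk": (270.0, 140.0, 500.0),
    "cost_first_episode_workup": (612.6, 300.0, 1000.0),
    "utility_no_pouchitis": (0.91, 0.70, 0.95),
    "utility_active_pouchitis": (0.46, 0.30, 0.60),
}
SECONDARY_TABLE = {
    "p_relapse_ppx_annual": (0.14, 0.1, 0.5),
    "p_relapse_no_ppx_annual": (0.39, 0.25, 0.55),
    "p_resp_cipro_4wk": (0.77, 0.5, 0.9),
    "p_resp_metro_4wk": (0.70, 0.5, 0.9),
    "p_resp_dual_4wk": (0.69, 0.5, 0.9),
    "p_resp_vdz": (0.52, 0.3, 0.7),
    "p_resp_ifx": (1.0, 1.0, 1.0),
    "p_lor_vdz_annual": (0.40, 0.2, 0.6),
    "cost_probiotic_4wk": (174.0, 100.0, 300.0),
    "cost_cipro_4wk": (24.0, 12.0, 48.0),
    "cost_metro_4wk": (45.4, 25.0, 80.0),
    "cost_dual_4wk": (270.0, 150.0, 500.0),
    "cost_vdz_dose": (6803.0, 3500.0, 10000.0),
    "cost_ifx_dose": (987.0, 500.0, 1500.0),
    "cost_carp_eval": (128.4, 70.0, 200.0),
    "utility_no_pouchitis": (0.91, 0.70, 0.95),
    "utility_active_pouchitis": (0.46, 0.30, 0.60),
}


@pytest.mark.parametrize("scope,table",
                         [("primary", PRIMARY_TABLE),
                          ("secondary", SECONDARY_TABLE)])
def test_registry_contains_every_tabulated_value(scope, table):
    reg = registry(scope)
    for name, (base, lo, hi) in table.items():
        assert name in reg, name
        spec = reg[name]
        assert spec.base == base
        assert (spec.mc_min, spec.mc_max) == (lo, hi)


def test_load_defaults_matches_table_and_is_idempotent():
    ps1 = load_defaults("primary")
    ps2 = load_defaults("primary")
    assert ps1.values == ps2.values
    assert ps1["p_first_pouchitis_no_ppx_annual"] == 0.4
    assert load_defaults("secondary")["cost_vdz_dose"] == 6803


def test_load_defaults_unknown_scope():
    with pytest.raises(ParameterError, match="unknown model scope"):
        load_defaults("tertiary")


def test_override_returns_new_set_without_mutating(primary_ps):
    out = override(primary_ps, "cost_probiotic_2wk", 41)
    assert out["cost_probiotic_2wk"] == 41
    assert primary_ps["cost_probiotic_2wk"] == 87.2
    changed = {k for k in out.values if out[k] != primary_ps[k]}
    assert changed == {"cost_probiotic_2wk"}
    # identity override allowed
    same = override(primary_ps, "utility_no_pouchitis", 0.91)
    assert same.values == primary_ps.values


def test_override_validation(primary_ps):
    with pytest.raises(ParameterError, match="p_resp_cipro_2wk"):
        override(primary_ps, "p_resp_cipro_2wk", 1.5)
    with pytest.raises(ParameterError, match="unknown parameter"):
        override(primary_ps, "no_such_param", 1.0)
    with pytest.raises(ParameterError):
        override(primary_ps, "cost_cipro_2wk", -5.0)
    # beyond the MC range but within role bounds is explicitly permitted
    assert override(primary_ps, "cost_probiotic_2wk", 5000)["cost_probiotic_2wk"] == 5000


def test_validate_flags_missing_and_out_of_bounds(primary_ps):
    assert validate(primary_ps, "primary") == []
    bad = dict(primary_ps.values)
    bad["p_resp_metro_2wk"] = -0.1
    viols = validate(ParameterSet("primary", bad), "primary")
    assert len(viols) == 1 and "p_resp_metro_2wk" in viols[0]
    missing = dict(primary_ps.values)
    del missing["utility_active_pouchitis"]
    viols = validate(ParameterSet("primary", missing), "primary")
    assert len(viols) == 1 and "missing" in viols[0]


def test_paramspec_invariants_enforced():
    with pytest.raises(ParameterError):
        ParamSpec("x", "probability", 0.5, 0.6, 0.9, "annual", "primary", "s")
    with pytest.raises(ParameterError):
        ParamSpec("x", "probability", 0.5, 0.1, 1.2, "annual", "primary", "s")
    with pytest.raises(ParameterError):
        ParamSpec("x", "cost", 5.0, -1.0, 9.0, "per_course", "primary", "s")


def test_triangular_endpoints_and_mode():
    spec = registry("primary")["cost_probiotic_2wk"]  # tri(50, 87.2, 150)
    assert sample_triangular(spec, 0.0) == spec.mc_min
    assert sample_triangular(spec, 1.0) == spec.mc_max
    # CDF at the mode equals (mode-min)/(max-min)
    u_mode = (spec.base - spec.mc_min) / (spec.mc_max - spec.mc_min)
    assert sample_triangular(spec, u_mode) == pytest.approx(spec.base)
    with pytest.raises(ValueError):
        sample_triangular(spec, 1.5)


def test_triangular_matches_scipy_and_empirical_mean():
    from scipy import stats

    spec = registry("primary")["p_first_pouchitis_no_ppx_annual"]
    a, c, b = spec.mc_min, spec.base, spec.mc_max
    dist = stats.triang((c - a) / (b - a), loc=a, scale=b - a)
    for u in (0.01, 0.2, 0.37, 0.5, 0.8, 0.99):
        assert sample_triangular(spec, u) == pytest.approx(dist.ppf(u), abs=1e-12)

    rng = np.random.default_rng(20_200)
    draws = np.array([sample_triangular(spec, u) for u in rng.random(100_000)])
    se = draws.std(ddof=1) / math.sqrt(draws.size)
    assert abs(draws.mean() - triangular_mean(spec)) < 3 * se


@settings(max_examples=100, derandomize=True)
@given(u1=st.floats(0, 1), u2=st.floats(0, 1))
def test_triangular_inverse_cdf_is_monotone(u1, u2):
    spec = registry("secondary")["cost_vdz_dose"]
    lo, hi = sorted((u1, u2))
    assert sample_triangular(spec, lo) <= sample_triangular(spec, hi)


def test_registry_frame_exports_expected_columns():
    df = registry_frame("secondary")
    assert list(df.columns) == ["name", "role", "base", "mc_min", "mc_max",
                                "time_basis", "source"]
    assert len(df) == len(registry("secondary"))
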