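"""Typed registry of model parameters.

Every probability, cost, and utility used by the primary- and
secondary-prevention models lives here as a :class:`ParamSpec` carrying its
base-case value, the triangular Monte Carlo range, a role (which implies
validity bounds), and the time basis its name is suffixed with.  Parameter
sets are immutable value objects; :func:`override` returns a new set.

Naming convention: snake-case with an explicit time-basis suffix
(``..._annual``, ``..._2wk``, ``..._4wk``, ``..._dose``) because the models
mix annual probabilities with per-course and per-dose costs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Mapping, Optional

import pandas as pd

Role = Literal["probability", "cost", "utility", "structural"]
TimeBasis = Literal["annual", "per_course", "per_cycle", "per_dose", "dimensionless"]
Scope = Literal["primary", "secondary", "shared"]

#: scopes a model can request parameters for
MODEL_SCOPES = ("primary", "secondary")


class ParameterError(ValueError):
    """Raised for unknown parameter names or role-bound violations."""


@dataclass(frozen=True)
class ParamSpec:
    """One named model input with base value and Monte Carlo range.

    ``mc_min == mc_max`` marks a degenerate range: the parameter is held
    fixed in probabilistic sensitivity analysis.
    """

    name: str
    role: Role
    base: float
    mc_min: float
    mc_max: float
    time_basis: TimeBasis
    model_scope: Scope
    source: str

    def __post_init__(self) -> None:
        if not (self.mc_min <= self.base <= self.mc_max):
            raise ParameterError(
                f"{self.name}: base {self.base} outside MC range "
                f"[{self.mc_min}, {self.mc_max}]"
            )
        lo, hi = role_bounds(self.role)
        if self.mc_min < lo or self.mc_max > hi:
            raise ParameterError(
                f"{self.name}: MC range [{self.mc_min}, {self.mc_max}] violates "
                f"{self.role} bounds [{lo}, {hi}]"
            )

    @property
    def degenerate(self) -> bool:
        return self.mc_min == self.mc_max


def role_bounds(role: Role) -> tuple[float, float]:
    """Validity interval implied by a parameter role."""
    if role in ("probability", "utility"):
        return (0.0, 1.0)
    if role == "cost":
        return (0.0, math.inf)
    return (-math.inf, math.inf)


def _spec(name, role, base, mc_min, mc_max, time_basis, scope, source) -> ParamSpec:
    return ParamSpec(name, role, float(base), float(mc_min), float(mc_max),
                     time_basis, scope, source)


# Utilities are common to both models (same base values and MC ranges).
_SHARED_UTILITIES = [
    _spec("utility_no_pouchitis", "utility", 0.91, 0.70, 0.95,
          "annual", "shared", "published utility literature"),
    _spec("utility_active_pouchitis", "utility", 0.46, 0.30, 0.60,
          "annual", "shared", "published utility literature"),
]

# Biologic-pathway parameters are printed with the secondary model but are
# shared: the extended primary variant escalates to the same VDZ/IFX ladder.
_SHARED_BIOLOGICS = [
    _spec("p_resp_dual_4wk", "probability", 0.69, 0.5, 0.9,
          "per_course", "shared", "AGA guideline estimates"),
    _spec("p_resp_vdz", "probability", 0.52, 0.3, 0.7,
          "per_course", "shared", "AGA guideline estimates"),
    _spec("p_resp_ifx", "probability", 1.0, 1.0, 1.0,
          "per_course", "shared", "terminal-response assumption"),
    _spec("p_lor_vdz_annual", "probability", 0.40, 0.2, 0.6,
          "annual", "shared", "published VDZ durability literature"),
    _spec("cost_vdz_dose", "cost", 6803.0, 3500.0, 10000.0,
          "per_dose", "shared", "Medicare Part B"),
    _spec("cost_ifx_dose", "cost", 987.0, 500.0, 1500.0,
          "per_dose", "shared", "Medicare Part B"),
]

_PRIMARY_SPECS = [
    _spec("p_first_pouchitis_ppx_annual", "probability", 0.1, 0.05, 0.25,
          "annual", "primary", "placebo-controlled RCT"),
    _spec("p_first_pouchitis_no_ppx_annual", "probability", 0.4, 0.25, 0.50,
          "annual", "primary", "placebo-controlled RCT"),
    _spec("p_recurrent_pouchitis_annual", "probability", 0.39, 0.20, 0.50,
          "annual", "primary", "observational cohort"),
    _spec("p_resp_cipro_2wk", "probability", 0.77, 0.60, 0.95,
          "per_course", "primary", "AGA guideline estimates"),
    _spec("p_resp_metro_2wk", "probability", 0.70, 0.55, 0.90,
          "per_course", "primary", "AGA guideline estimates"),
    _spec("cost_probiotic_2wk", "cost", 87.2, 50.0, 150.0,
          "per_cycle", "primary", "manufacturer US list price"),
    _spec("cost_cipro_2wk", "cost", 12.0, 6.0, 24.0,
          "per_course", "primary", "Medicare Part D"),
    _spec("cost_metro_2wk", "cost", 22.68, 11.0, 45.0,
          "per_course", "primary", "Medicare Part D"),
    _spec("cost_dual_4wk", "cost", 270.0, 140.0, 500.0,
          "per_course", "primary", "Medicare Part D"),
    _spec("cost_first_episode_workup", "cost", 612.6, 300.0, 1000.0,
          "per_course", "primary", "Medicare fee schedule"),
]

_SECONDARY_SPECS = [
    _spec("p_relapse_ppx_annual", "probability", 0.14, 0.1, 0.5,
          "annual", "secondary", "meta-analysis of RCTs"),
    _spec("p_relapse_no_ppx_annual", "probability", 0.39, 0.25, 0.55,
          "annual", "secondary", "claims database study"),
    _spec("p_resp_cipro_4wk", "probability", 0.77, 0.5, 0.9,
          "per_course", "secondary", "AGA guideline estimates"),
    _spec("p_resp_metro_4wk", "probability", 0.70, 0.5, 0.9,
          "per_course", "secondary", "AGA guideline estimates"),
    _spec("cost_probiotic_4wk", "cost", 174.0, 100.0, 300.0,
          "per_cycle", "secondary", "manufacturer US list price"),
    _spec("cost_cipro_4wk", "cost", 24.0, 12.0, 48.0,
          "per_course", "secondary", "Medicare Part D"),
    _spec("cost_metro_4wk", "cost", 45.4, 25.0, 80.0,
          "per_course", "secondary", "Medicare Part D"),
    _spec("cost_dual_4wk", "cost", 270.0, 150.0, 500.0,
          "per_course", "secondary", "Medicare Part D"),
    _spec("cost_carp_eval", "cost", 128.4, 70.0, 200.0,
          "per_course", "secondary", "Medicare fee schedule"),
]


def _build_registries() -> dict[str, dict[str, ParamSpec]]:
    reg: dict[str, dict[str, ParamSpec]] = {}
    reg["primary"] = {
        s.name: s for s in (*_PRIMARY_SPECS, *_SHARED_UTILITIES, *_SHARED_BIOLOGICS)
    }
    reg["secondary"] = {
        s.name: s for s in (*_SECONDARY_SPECS, *_SHARED_UTILITIES, *_SHARED_BIOLOGICS)
    }
    return reg


_REGISTRY = _build_registries()


def registry(model: str) -> dict[str, ParamSpec]:
    """Ordered name → :class:`ParamSpec` map for a model scope."""
    try:
        return dict(_REGISTRY[model])
    except KeyError:
        raise ParameterError(
            f"unknown model scope {model!r}; expected one of {MODEL_SCOPES}"
        ) from None


@dataclass(frozen=True)
class ParameterSet:
    """Immutable mapping of parameter name → value for one model scope."""

    scope: str
    values: Mapping[str, float]
    provenance: Literal["base_case", "override", "psa_draw"] = "base_case"
    seed_info: Optional[int] = None

    def __getitem__(self, name: str) -> float:
        try:
            return self.values[name]
        except KeyError:
            raise ParameterError(f"unknown parameter {name!r} in scope {self.scope!r}") from None

    def __contains__(self, name: str) -> bool:
        return name in self.values

    def as_dict(self) -> dict[str, float]:
        return dict(self.values)


def load_defaults(model: str) -> ParameterSet:
    """Base-case :class:`ParameterSet` for ``model`` exactly as tabulated."""
    reg = registry(model)
    return ParameterSet(scope=model, values={n: s.base for n, s in reg.items()})


def _check_role_bounds(spec: ParamSpec, value: float) -> Optional[str]:
    lo, hi = role_bounds(spec.role)
    if not (lo <= value <= hi):
        return (f"{spec.name}: value {value} violates {spec.role} "
                f"bounds [{lo}, {hi}]")
    return None


def override(ps: ParameterSet, name: str, value: float) -> ParameterSet:
    """Return a copy of ``ps`` with ``name`` set to ``value``.

    Values outside the Monte Carlo range are permitted (one-way sweeps go
    far beyond it) but role bounds are enforced.
    """
    reg = registry(ps.scope)
    if name not in reg:
        raise ParameterError(f"unknown parameter {name!r} in scope {ps.scope!r}")
    msg = _check_role_bounds(reg[name], value)
    if msg is not None:
        raise ParameterError(msg)
    values = dict(ps.values)
    values[name] = float(value)
    return ParameterSet(scope=ps.scope, values=values, provenance="override",
                        seed_info=ps.seed_info)


def sample_triangular(spec: ParamSpec, u: float) -> float:
    """Inverse CDF of triangular(mc_min, mode=base, mc_max) at ``u``.

    Monotone non-decreasing in ``u``; returns the endpoints at u=0 and u=1.
    """
    if not (0.0 <= u <= 1.0):
        raise ValueError(f"u={u} outside [0, 1]")
    a, c, b = spec.mc_min, spec.base, spec.mc_max
    if a == b:
        return a
    fc = (c - a) / (b - a)
    if u < fc:
        return a + math.sqrt(u * (b - a) * (c - a))
    return b - math.sqrt((1.0 - u) * (b - a) * (b - c))


def triangular_mean(spec: ParamSpec) -> float:
    return (spec.mc_min + spec.base + spec.mc_max) / 3.0


def validate(ps: ParameterSet, model: Optional[str] = None) -> list[str]:
    """List of invariant violations (empty when the set is valid).

    Violations are data, not exceptions: each entry names the parameter and
    the broken rule.
    """
    scope = model if model is not None else ps.scope
    reg = registry(scope)
    violations: list[str] = []
    for name, spec in reg.items():
        if name not in ps.values:
            violations.append(f"{name}: missing from parameter set")
            continue
        msg = _check_role_bounds(spec, ps.values[name])
        if msg is not None:
            violations.append(msg)
    for name in ps.values:
        if name not in reg:
            violations.append(f"{name}: not in the {scope!r} registry")
    return violations


def registry_frame(model: str) -> pd.DataFrame:
    """Registry as a DataFrame (exportable to CSV)."""
    rows = [
        {"name": s.name, "role": s.role, "base": s.base, "mc_min": s.mc_min,
         "mc_max": s.mc_max, "time_basis": s.time_basis, "source": s.source}
        for s in registry(model).values()
    ]
    return pd.DataFrame(rows)


def export_registry_csv(model: str, path) -> None:
    registry_frame(model).to_csv(path, index=False)
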