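"""Biologic dosing schedules mapped onto the Markov cycle grid.

VDZ and IFX are dosed at weeks 0, 2 and 6 (induction) then every 8 weeks.
Neither a 2-week nor a 4-week cycle grid can place every dose exactly, so
the induction doses are compressed onto the grid (total dose count
preserved) and maintenance dosing snaps to the nearest on-grid cycle.  The
chosen placements are encoded here as data so model builders and tests can
cross-check the per-state dose multiplicities against an independent
per-cycle account.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

from .params import ParameterSet

#: base-case body weight (kg) for weight-based IFX dosing, 5 mg/kg
BASE_CASE_WEIGHT_KG = 70.0
#: the printed IFX price is per 300 mg
IFX_PRICE_PER_MG = 1.0 / 300.0


def ifx_dose_scale(weight_kg: float = BASE_CASE_WEIGHT_KG) -> float:
    """Linear pro-rating of the per-300 mg IFX price at 5 mg/kg."""
    if weight_kg <= 0:
        raise ValueError("weight_kg must be positive")
    return 5.0 * weight_kg * IFX_PRICE_PER_MG


@dataclass(frozen=True)
class BiologicSchedule:
    """Dose placement for one drug on one cycle grid.

    ``induction_cycles``/``induction_doses`` give the on-grid cycles of the
    induction phase and the number of doses charged in each;
    ``maintenance_start_cycle`` is the first maintenance dose cycle, with a
    dose every ``maintenance_interval_cycles`` thereafter.
    """

    drug: Literal["VDZ", "IFX"]
    induction_cycles: tuple[int, ...]
    induction_doses: tuple[int, ...]
    induction_length_cycles: int
    maintenance_start_cycle: int
    maintenance_interval_cycles: int
    dose_cost_ref: str
    dose_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.maintenance_interval_cycles < 1:
            raise ValueError("maintenance_interval_cycles must be >= 1")
        if any(c < 0 for c in self.induction_cycles):
            raise ValueError("induction cycle offsets must be non-negative")
        if list(self.induction_cycles) != sorted(set(self.induction_cycles)):
            raise ValueError("induction cycle offsets must be strictly increasing")
        if len(self.induction_cycles) != len(self.induction_doses):
            raise ValueError("induction_cycles/induction_doses length mismatch")

    def doses_at(self, cycles_since_start: int) -> int:
        """Number of doses charged in the given cycle since drug start."""
        if cycles_since_start < 0:
            raise ValueError("cycles_since_start must be >= 0")
        if cycles_since_start < self.induction_length_cycles:
            for c, d in zip(self.induction_cycles, self.induction_doses):
                if c == cycles_since_start:
                    return d
            return 0
        rel = cycles_since_start - self.maintenance_start_cycle
        if rel >= 0 and rel % self.maintenance_interval_cycles == 0:
            return 1
        return 0


def biologic_cycle_cost(schedule: BiologicSchedule, cycles_since_start: int,
                        ps: ParameterSet) -> float:
    """Drug cost charged in one cycle since the start of the biologic."""
    doses = schedule.doses_at(cycles_since_start)
    return doses * ps[schedule.dose_cost_ref] * schedule.dose_scale


# 4-week grid (secondary model): induction weeks 0/2/6 -> one dose in cycle
# 0, two in cycle 1; next dose week 14 -> cycle 3, then every 2 cycles.
def vdz_schedule_4wk() -> BiologicSchedule:
    return BiologicSchedule("VDZ", (0, 1), (1, 2), 2, 3, 2, "cost_vdz_dose")


def ifx_schedule_4wk(weight_kg: float = BASE_CASE_WEIGHT_KG) -> BiologicSchedule:
    return BiologicSchedule("IFX", (0, 1), (1, 2), 2, 3, 2, "cost_ifx_dose",
                            ifx_dose_scale(weight_kg))


# 2-week grid (extended primary variant): weeks 0/2/6 land exactly on
# cycles 0, 1 and 3; next dose week 14 -> cycle 7, then every 4 cycles.
def vdz_schedule_2wk() -> BiologicSchedule:
    return BiologicSchedule("VDZ", (0, 1, 3), (1, 1, 1), 4, 7, 4, "cost_vdz_dose")


def ifx_schedule_2wk(weight_kg: float = BASE_CASE_WEIGHT_KG) -> BiologicSchedule:
    return BiologicSchedule("IFX", (0, 1, 3), (1, 1, 1), 4, 7, 4, "cost_ifx_dose",
                            ifx_dose_scale(weight_kg))
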