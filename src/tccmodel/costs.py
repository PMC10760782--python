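"""Discounted cost accumulation and physical resource totals.

Costs per person-cycle follow the resource-use bottom-up recipe: task
frequency per day x days per cycle x minutes per task x staff per task x
blended wage per minute for labour; daily product counts x price for
absorbent products; hygiene applied at every product change; dry product
weight x disposal tariff; event rates x cost per event; a per-cycle severe
dermatitis (SHL5) treatment episode; and a per-person-year technology price
for the intervention arm. Care hours and disposal kilograms are accumulated
undiscounted, as physical lifetime totals per group.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np
import pandas as pd

from .engine import Trajectory, shl_distribution
from .params import (
    CareStage,
    EventType,
    NeedGroup,
    ParameterSet,
    SkinHealthLevel,
    Strategy,
    Task,
)
from .effects import discount_factor

__all__ = ["CostBreakdown", "ResourceTotals", "cycle_cost", "accumulate_costs", "accumulate_resources"]

_STAGES = tuple(CareStage)
_COST_FIELDS = (
    "technology",
    "labour",
    "absorbent_products",
    "hygiene",
    "disposal",
    "care_consequences",
    "shl5_treatment",
)


@dataclass
class CostBreakdown:
    """Cost by category; ``total`` is always the sum of the seven categories."""

    technology: float = 0.0
    labour: float = 0.0
    absorbent_products: float = 0.0
    hygiene: float = 0.0
    disposal: float = 0.0
    care_consequences: float = 0.0
    shl5_treatment: float = 0.0

    @property
    def total(self) -> float:
        return float(sum(getattr(self, f) for f in _COST_FIELDS))

    def as_dict(self) -> dict[str, float]:
        d = {f: getattr(self, f) for f in _COST_FIELDS}
        d["total"] = self.total
        return d

    def to_frame(self) -> pd.DataFrame:
        d = self.as_dict()
        return pd.DataFrame({"category": list(d), "cost": list(d.values())})

    def __add__(self, other: "CostBreakdown") -> "CostBreakdown":
        return CostBreakdown(**{f: getattr(self, f) + getattr(other, f) for f in _COST_FIELDS})

    def scaled(self, k: float) -> "CostBreakdown":
        return CostBreakdown(**{f: k * getattr(self, f) for f in _COST_FIELDS})


@dataclass
class ResourceTotals:
    """Undiscounted lifetime care hours and disposal mass per group."""

    care_hours: dict[NeedGroup, float]
    disposal_kg: dict[NeedGroup, float]

    @property
    def total_hours(self) -> float:
        return float(sum(self.care_hours.values()))

    @property
    def total_kg(self) -> float:
        return float(sum(self.disposal_kg.values()))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "group": [g.name for g in self.care_hours],
                "care_hours": list(self.care_hours.values()),
                "disposal_kg": list(self.disposal_kg.values()),
            }
        )


def _require_economics(ps: ParameterSet):
    if ps.economics is None:
        raise ValueError(
            "economics block not populated: attach a unit-cost/resource-use "
            "fixture (e.g. load_case_study(with_economics=True))"
        )
    return ps.economics


def blended_wage_per_min(ps: ParameterSet) -> float:
    eco = _require_economics(ps)
    s = eco.informal_share
    return s * eco.wage_informal_per_min + (1.0 - s) * eco.wage_formal_per_min


def _task_minutes(ps: ParameterSet, strategy: Strategy, group: NeedGroup, cs: CareStage) -> dict[Task, float]:
    """Staff-minutes per cycle per task (frequency x days x minutes x staff)."""
    eco = _require_economics(ps)
    days = ps.settings.days_per_cycle
    freqs = eco.task_frequencies[strategy][group][cs]
    out: dict[Task, float] = {}
    for task, per_day in freqs.items():
        minutes = ps.care_tasks.minutes[task][group]
        staff = ps.care_tasks.staff[task][group]
        out[task] = per_day * days * minutes * staff
    return out


def _shl5_applications_per_cycle(ps: ParameterSet, strategy: Strategy, group: NeedGroup, cs: CareStage) -> float:
    """Expected SHL5 treatment applications per person-cycle.

    An SHL5 assignment triggers one 7-day treatment episode per cycle, with
    the topical treatment applied at every product change during the episode.
    """
    eco = _require_economics(ps)
    p_shl5 = float(shl_distribution(ps, strategy, cs)[SkinHealthLevel.SHL5 - 1])
    changes_per_day = eco.task_frequencies[strategy][group][cs].get(Task.PRODUCT_CHANGE, 0.0)
    return p_shl5 * changes_per_day * eco.shl5_treatment.duration_days


def cycle_cost(ps: ParameterSet, strategy: Strategy | str, group: NeedGroup, cs: CareStage) -> CostBreakdown:
    """Cost per person spending one full cycle alive in state (group, cs)."""
    strategy = Strategy(strategy)
    eco = _require_economics(ps)
    st = ps.settings
    days = st.days_per_cycle
    wage = blended_wage_per_min(ps)

    task_minutes = _task_minutes(ps, strategy, group, cs)
    labour = wage * sum(task_minutes.values())

    counts = eco.daily_product_counts[strategy][cs]
    absorbent = days * sum(n * eco.product_types[p].price for p, n in counts.items())
    disposal = (
        days
        * eco.disposal_tariff_per_kg
        * sum(n * eco.product_types[p].dry_weight_kg for p, n in counts.items())
    )

    changes_per_cycle = eco.task_frequencies[strategy][group][cs].get(Task.PRODUCT_CHANGE, 0.0) * days
    hygiene = changes_per_cycle * eco.hygiene_cost_per_application[strategy]

    er = ps.event_rates[strategy]
    consequences = float(sum(er.rate(e, group) * eco.event_costs[e] for e in EventType))

    apps = _shl5_applications_per_cycle(ps, strategy, group, cs)
    tr = eco.shl5_treatment
    shl5 = apps * (
        tr.minutes_per_application * ps.care_tasks.staff[Task.SHL5_TREATMENT][group] * wage
        + tr.unit_cost_per_application
    )

    technology = eco.technology_cost_per_person_year[strategy] * st.cycle_length_years
    return CostBreakdown(
        technology=technology,
        labour=labour,
        absorbent_products=absorbent,
        hygiene=hygiene,
        disposal=disposal,
        care_consequences=consequences,
        shl5_treatment=shl5,
    )


def _state_vectors(ps: ParameterSet, strategy: Strategy, traj: Trajectory) -> dict[str, np.ndarray]:
    space = traj.state_space
    vecs = {f: np.empty(space.n_alive) for f in _COST_FIELDS}
    for idx in range(space.n_alive):
        g, c = space.state(idx)
        cb = cycle_cost(ps, strategy, g, c)
        for f in _COST_FIELDS:
            vecs[f][idx] = getattr(cb, f)
    return vecs


def _check_match(traj: Trajectory, ps: ParameterSet, strategy: Strategy) -> None:
    if traj.fingerprint != ps.fingerprint():
        raise ValueError("trajectory fingerprint does not match the parameter set")
    if traj.strategy != strategy:
        raise ValueError(f"trajectory was run for {traj.strategy.value!r}, not {strategy.value!r}")


def accumulate_costs(traj: Trajectory, ps: ParameterSet, strategy: Strategy | str) -> CostBreakdown:
    """Occupancy-weighted, half-cycle-corrected, discounted lifetime costs.

    Per-cycle state costs are treated as a spend rate over the cycle, so each
    cycle contributes the average of the discounted start- and end-of-cycle
    occupancy times the state's cycle cost.
    """
    strategy = Strategy(strategy)
    _check_match(traj, ps, strategy)
    st = ps.settings
    occ = traj.alive_occupancy()
    disc = discount_factor(np.arange(occ.shape[0]), st.discount_rate, st.cycle_length_years)
    vecs = _state_vectors(ps, strategy, traj)
    out = {}
    for f, w in vecs.items():
        stream = (occ @ w) * disc
        out[f] = float(0.5 * stream[0] + stream[1:-1].sum() + 0.5 * stream[-1])
    return CostBreakdown(**out)


def accumulate_resources(traj: Trajectory, ps: ParameterSet, strategy: Strategy | str) -> ResourceTotals:
    """Undiscounted lifetime care hours and disposal kilograms, per group."""
    strategy = Strategy(strategy)
    _check_match(traj, ps, strategy)
    eco = _require_economics(ps)
    space = traj.state_space
    days = ps.settings.days_per_cycle

    hours_w = np.empty(space.n_alive)
    kg_w = np.empty(space.n_alive)
    for idx in range(space.n_alive):
        g, c = space.state(idx)
        minutes = sum(_task_minutes(ps, strategy, g, c).values())
        minutes += (
            _shl5_applications_per_cycle(ps, strategy, g, c)
            * eco.shl5_treatment.minutes_per_application
            * ps.care_tasks.staff[Task.SHL5_TREATMENT][g]
        )
        hours_w[idx] = minutes / 60.0
        counts = eco.daily_product_counts[strategy][c]
        kg_w[idx] = days * sum(n * eco.product_types[p].dry_weight_kg for p, n in counts.items())

    occ = traj.alive_occupancy()
    # trapezoid person-cycles in each state, undiscounted
    person_cycles = 0.5 * occ[0] + occ[1:-1].sum(axis=0) + 0.5 * occ[-1]
    hours_by_state = person_cycles * hours_w
    kg_by_state = person_cycles * kg_w

    care_hours: dict[NeedGroup, float] = {g: 0.0 for g in space.groups}
    disposal_kg: dict[NeedGroup, float] = {g: 0.0 for g in space.groups}
    for idx in range(space.n_alive):
        g, _ = space.state(idx)
        care_hours[g] += float(hours_by_state[idx])
        disposal_kg[g] += float(kg_by_state[idx])
    return ResourceTotals(care_hours=care_hours, disposal_kg=disposal_kg)
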