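"""Cost-effectiveness comparison and sensitivity analyses.

``run_deterministic`` compares the two strategy arms on discounted QALYs and
(when an economics block is attached) discounted costs, classifying the
result as dominant/dominated or reporting an ICER. ``run_owsa`` re-evaluates
the comparison at the 95% bounds of each scalar parameter; ``run_psa`` draws
all non-fixed parameters simultaneously from their uncertainty families
(Beta/Gamma moment-matched at SE = 20% of the mean where no interval is
reported, Normal for age, mortality and utility decrements, Dirichlet for
stochastic rows) and ``ceac`` turns the resulting incremental cloud into a
cost-effectiveness acceptability curve.

Inputs shared between the arms (mortality, group transitions, initial
distributions, utilities, arm-independent unit costs) are drawn once per PSA
iteration and applied to both arms; arm-specific tables (care-stage and
skin-health transitions, event rates, arm-specific resource use) are drawn
independently per arm.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .costs import CostBreakdown, accumulate_costs
from .effects import QalyResult, accumulate_effects
from .engine import run_cohort
from .params import (
    CareStage,
    DistributionSpec,
    EventType,
    MortalityTable,
    NeedGroup,
    ParameterSet,
    SkinHealthLevel,
    Strategy,
    Task,
)

__all__ = [
    "CeResult",
    "PsaResult",
    "CeacCurve",
    "TornadoEntry",
    "ParamHandle",
    "FIXED_PARAMETERS",
    "build_registry",
    "run_deterministic",
    "run_owsa",
    "psa_draw",
    "run_psa",
    "ceac",
]

logger = logging.getLogger(__name__)

_STAGES = tuple(CareStage)

#: Parameters held fixed in every sensitivity analysis.
FIXED_PARAMETERS = (
    "settings.cycle_length_years",
    "settings.max_cycles",
    "settings.discount_rate",
    "utilities.cs_decrement[CS1]",
    "utilities.shl_decrement[SHL1]",
    "care_tasks.staff[G2-G3]",
)

DEFAULT_LAMBDA_GRID = np.arange(0.0, 150_001.0, 1000.0)


# ---------------------------------------------------------------------------
# Result containers
# ---------------------------------------------------------------------------


@dataclass
class CeResult:
    """Incremental comparison of the intervention arm against the comparator."""

    delta_cost: float | None
    delta_qaly: float
    icer: float | None
    label: str | None  # "dominant" | "dominated" | None
    effects: dict[Strategy, QalyResult]
    costs: dict[Strategy, CostBreakdown] | None

    @property
    def has_costs(self) -> bool:
        return self.costs is not None


@dataclass
class PsaResult:
    """Monte-Carlo store of incremental (cost, QALY) pairs."""

    delta_cost: np.ndarray
    delta_qaly: np.ndarray
    seeds: np.ndarray
    has_costs: bool

    @property
    def n_iter(self) -> int:
        return self.delta_qaly.size

    @property
    def mean_delta_qaly(self) -> float:
        return float(self.delta_qaly.mean())

    @property
    def mean_delta_cost(self) -> float:
        return float(self.delta_cost.mean())

    def quadrant_shares(self) -> dict[str, float]:
        """CE-plane shares: effect gain east/west, cost increase north/south.

        The south (cost-saving) half takes the boundary: ``SE`` is
        delta_qaly > 0 and delta_cost <= 0 (intervention dominant).
        """
        de, dc = self.delta_qaly, self.delta_cost
        n = self.n_iter
        return {
            "SE": float(((de > 0) & (dc <= 0)).sum() / n),
            "NE": float(((de > 0) & (dc > 0)).sum() / n),
            "SW": float(((de <= 0) & (dc <= 0)).sum() / n),
            "NW": float(((de <= 0) & (dc > 0)).sum() / n),
        }

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "iteration": np.arange(self.n_iter),
                "seed": self.seeds,
                "delta_cost": self.delta_cost,
                "delta_qaly": self.delta_qaly,
            }
        )


@dataclass
class CeacCurve:
    """Probability of non-negative net monetary benefit per WTP threshold."""

    lambdas: np.ndarray
    probabilities: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"wtp": self.lambdas, "p_cost_effective": self.probabilities})


@dataclass
class TornadoEntry:
    """One-way sensitivity result for a single parameter."""

    pid: str
    low: float
    high: float
    delta_cost_low: float | None
    delta_cost_high: float | None
    delta_qaly_low: float
    delta_qaly_high: float

    @property
    def qaly_range(self) -> float:
        return abs(self.delta_qaly_high - self.delta_qaly_low)

    @property
    def cost_range(self) -> float:
        if self.delta_cost_low is None or self.delta_cost_high is None:
            return 0.0
        return abs(self.delta_cost_high - self.delta_cost_low)


# ---------------------------------------------------------------------------
# Deterministic comparison
# ---------------------------------------------------------------------------


def _classify(delta_cost: float | None, delta_qaly: float) -> tuple[float | None, str | None]:
    if delta_cost is None:
        return None, None
    if delta_cost == 0.0 and delta_qaly == 0.0:
        return None, None
    if delta_cost <= 0.0 and delta_qaly >= 0.0:
        return None, "dominant"
    if delta_cost >= 0.0 and delta_qaly <= 0.0:
        return None, "dominated"
    return delta_cost / delta_qaly, None


def run_deterministic(
    ps_conv: ParameterSet,
    ps_dht: ParameterSet,
    include_costs: bool | None = None,
) -> CeResult:
    """Run both arms and compare (intervention minus comparator).

    ``include_costs`` defaults to whether both parameter sets carry an
    economics block; effect-only runs report ``delta_cost = None``.
    """
    if include_costs is None:
        include_costs = ps_conv.economics is not None and ps_dht.economics is not None
    traj_c = run_cohort(ps_conv, Strategy.CONVENTIONAL)
    traj_d = run_cohort(ps_dht, Strategy.DHT)
    eff = {
        Strategy.CONVENTIONAL: accumulate_effects(traj_c, ps_conv, Strategy.CONVENTIONAL),
        Strategy.DHT: accumulate_effects(traj_d, ps_dht, Strategy.DHT),
    }
    delta_qaly = eff[Strategy.DHT].total_qalys - eff[Strategy.CONVENTIONAL].total_qalys
    costs = None
    delta_cost: float | None = None
    if include_costs:
        costs = {
            Strategy.CONVENTIONAL: accumulate_costs(traj_c, ps_conv, Strategy.CONVENTIONAL),
            Strategy.DHT: accumulate_costs(traj_d, ps_dht, Strategy.DHT),
        }
        delta_cost = costs[Strategy.DHT].total - costs[Strategy.CONVENTIONAL].total
    icer, label = _classify(delta_cost, delta_qaly)
    return CeResult(
        delta_cost=delta_cost,
        delta_qaly=delta_qaly,
        icer=icer,
        label=label,
        effects=eff,
        costs=costs,
    )


# ---------------------------------------------------------------------------
# Parameter registry
# ---------------------------------------------------------------------------


@dataclass
class ParamHandle:
    """Named access to one uncertain parameter inside a ParameterSet pair.

    ``shared`` parameters are drawn once per PSA iteration and written to both
    arms; arm-specific handles address the tables of a single strategy (each
    ParameterSet carries both arms' tables, so setters are plain writes).
    """

    pid: str
    family: str
    shared: bool
    getter: Callable[[ParameterSet], float | np.ndarray]
    setter: Callable[[ParameterSet, object], None]
    se: float | None = None
    low: float | None = None
    high: float | None = None
    lo_bound: float = -math.inf
    hi_bound: float = math.inf

    def spec(self, base: ParameterSet) -> DistributionSpec:
        value = self.getter(base)
        return DistributionSpec(family=self.family, mean=value, se=self.se, low=self.low, high=self.high)


def _dirichlet_alpha(mean: np.ndarray) -> np.ndarray | None:
    """Concentration for a stochastic row: scale so the largest-mean component
    has SE = 20% of its mean, floored at total concentration 1 for rows too
    concentrated to admit that spread. Degenerate rows return ``None``."""
    support = mean > 0
    if support.sum() <= 1:
        return None
    p = float(mean[support].max())
    alpha0 = (1.0 - p) / (0.04 * p) - 1.0
    alpha0 = max(alpha0, 1.0)
    return mean * alpha0


def draw_from_spec(spec: DistributionSpec, rng: np.random.Generator, lo: float = -math.inf, hi: float = math.inf):
    """Draw one value (or row) from an uncertainty specification."""
    mean = spec.mean
    if spec.family == "fixed" or mean is None:
        return mean
    if spec.family == "dirichlet_row":
        mean = np.asarray(mean, dtype=float)
        alpha = _dirichlet_alpha(mean)
        if alpha is None:
            return mean.copy()
        out = np.zeros_like(mean)
        support = mean > 0
        out[support] = rng.dirichlet(alpha[support])
        return out
    mean = float(mean)
    se = spec.se if spec.se is not None else DistributionSpec.DEFAULT_SE_FRAC * abs(mean)
    if spec.family == "beta":
        if mean <= 0.0 or mean >= 1.0 or se <= 0.0:
            return mean
        var = min(se**2, 0.9 * mean * (1 - mean))  # keep moment matching feasible
        nu = mean * (1 - mean) / var - 1.0
        return float(rng.beta(mean * nu, (1 - mean) * nu))
    if spec.family == "gamma":
        if mean <= 0.0 or se <= 0.0:
            return mean
        shape = (mean / se) ** 2
        return float(rng.gamma(shape, mean / shape))
    if spec.family == "normal":
        if se <= 0.0:
            return mean
        for _ in range(1000):  # truncate to the admissible range by resampling
            v = float(rng.normal(mean, se))
            if lo <= v <= hi:
                return v
        return float(np.clip(mean, lo, hi))
    raise ValueError(f"unknown family {spec.family!r}")


def build_registry(base: ParameterSet, include_economics: bool | None = None) -> list[ParamHandle]:
    """Enumerate the non-fixed parameters of a scenario as draw/set handles."""
    if include_economics is None:
        include_economics = base.economics is not None
    handles: list[ParamHandle] = []
    groups = tuple(base.settings.included_groups)

    def add(pid, family, shared, getter, setter, **kw):
        handles.append(ParamHandle(pid, family, shared, getter, setter, **kw))

    # cohort start age: modest prior spread (years), truncated to the model range
    add(
        "settings.start_age",
        "normal",
        True,
        lambda ps: ps.settings.start_age,
        lambda ps, v: setattr(ps.settings, "start_age", float(v)),
        se=2.0,
        lo_bound=65.0,
        hi_bound=110.0,
    )

    # mortality: Normal with the reported 95% CI per age band and group class
    used_classes = sorted({MortalityTable.group_class(g) for g in groups})
    for cls in used_classes:
        for band in range(len(base.mortality.mean[cls])):
            mean = float(base.mortality.mean[cls][band])
            lo = float(base.mortality.ci_low[cls][band])
            hi = float(base.mortality.ci_high[cls][band])
            add(
                f"mortality[{cls}][band{band}]",
                "normal",
                True,
                lambda ps, c=cls, b=band: float(ps.mortality.mean[c][b]),
                lambda ps, v, c=cls, b=band: ps.mortality.mean[c].__setitem__(b, float(v)),
                se=(hi - lo) / (2 * 1.96),
                low=lo,
                high=hi,
                lo_bound=0.0,
                hi_bound=1.0,
            )

    # stochastic rows: Dirichlet (initial distributions, group transitions)
    def dist_row_handle(pid, dist_getter):
        def getter(ps):
            d = dist_getter(ps)
            return np.array(list(d.values()), dtype=float)

        def setter(ps, row):
            d = dist_getter(ps)
            d.update(zip(list(d), np.asarray(row, dtype=float)))

        add(pid, "dirichlet_row", True, getter, setter)

    dist_row_handle("initial_group_dist", lambda ps: ps.initial_group_dist)
    dist_row_handle("initial_cs_dist", lambda ps: ps.initial_cs_dist)
    dist_row_handle("initial_shl_dist", lambda ps: ps.initial_shl_dist)
    for g in groups:
        dist_row_handle(f"group_transition[{g.name}]", lambda ps, g=g: ps.group_transition[g])

    # utilities: Normal baselines and decrement magnitudes; Beta event decrements
    for g in groups:
        add(
            f"utilities.baseline[{g.name}]",
            "normal",
            True,
            lambda ps, g=g: ps.utilities.baseline[g],
            lambda ps, v, g=g: ps.utilities.baseline.__setitem__(g, float(v)),
            lo_bound=0.0,
            hi_bound=1.0,
        )
    for c in (CareStage.CS2, CareStage.CS3):
        add(
            f"utilities.cs_decrement[{c.name}]",
            "normal",
            True,
            lambda ps, c=c: ps.utilities.cs_decrement[c],
            lambda ps, v, c=c: ps.utilities.cs_decrement.__setitem__(c, float(v)),
            lo_bound=0.0,
            hi_bound=1.0,
        )
    for l in (SkinHealthLevel.SHL2, SkinHealthLevel.SHL3, SkinHealthLevel.SHL4, SkinHealthLevel.SHL5):
        add(
            f"utilities.shl_decrement[{l.name}]",
            "normal",
            True,
            lambda ps, l=l: ps.utilities.shl_decrement[l],
            lambda ps, v, l=l: ps.utilities.shl_decrement.__setitem__(l, float(v)),
            lo_bound=0.0,
            hi_bound=1.0,
        )
    for e in EventType:
        if base.utilities.event_decrement[e] > 0:
            add(
                f"utilities.event_decrement[{e.value}]",
                "beta",
                True,
                lambda ps, e=e: ps.utilities.event_decrement[e],
                lambda ps, v, e=e: ps.utilities.event_decrement.__setitem__(e, float(v)),
            )

    # arm-specific effectiveness tables
    for strat in Strategy:
        for c in _STAGES:
            def cs_getter(ps, s=strat, c=c):
                return np.array([ps.cs_transition[s][c][c2] for c2 in _STAGES])

            def cs_setter(ps, row, s=strat, c=c):
                ps.cs_transition[s][c].update(zip(_STAGES, np.asarray(row, dtype=float)))

            add(f"cs_transition[{strat.value}][{c.name}]", "dirichlet_row", False, cs_getter, cs_setter)

            def shl_getter(ps, s=strat, c=c):
                return np.asarray(ps.shl_given_cs[s][c], dtype=float)

            def shl_setter(ps, row, s=strat, c=c):
                ps.shl_given_cs[s][c] = np.asarray(row, dtype=float)

            add(f"shl_given_cs[{strat.value}][{c.name}]", "dirichlet_row", False, shl_getter, shl_setter)

        for fname in ("fracture_g2_g4", "uti", "constipation", "pu1", "pu2", "pu3", "pu4"):
            if getattr(base.event_rates[strat], fname) > 0:
                add(
                    f"event_rates[{strat.value}].{fname}",
                    "beta",
                    False,
                    lambda ps, s=strat, f=fname: getattr(ps.event_rates[s], f),
                    lambda ps, v, s=strat, f=fname: setattr(ps.event_rates[s], f, float(v)),
                )

    if include_economics and base.economics is not None:
        eco = base.economics
        add(
            "economics.wage_formal_per_min",
            "gamma",
            True,
            lambda ps: ps.economics.wage_formal_per_min,
            lambda ps, v: setattr(ps.economics, "wage_formal_per_min", float(v)),
        )
        if eco.informal_share > 0:
            add(
                "economics.wage_informal_per_min",
                "gamma",
                True,
                lambda ps: ps.economics.wage_informal_per_min,
                lambda ps, v: setattr(ps.economics, "wage_informal_per_min", float(v)),
            )
        for strat in Strategy:
            for c in _STAGES:
                for task in (t for t in Task if t is not Task.SHL5_TREATMENT):
                    if eco.task_frequencies[strat][groups[0]][c].get(task, 0.0) <= 0:
                        continue

                    def f_getter(ps, s=strat, c=c, t=task):
                        return ps.economics.task_frequencies[s][groups[0]][c][t]

                    def f_setter(ps, v, s=strat, c=c, t=task):
                        for g in ps.economics.task_frequencies[s]:
                            ps.economics.task_frequencies[s][g][c][t] = float(v)

                    add(
                        f"economics.task_frequency[{strat.value}][{c.name}][{task.value}]",
                        "gamma",
                        False,
                        f_getter,
                        f_setter,
                    )
                for pname in eco.daily_product_counts[strat][c]:
                    if eco.daily_product_counts[strat][c][pname] <= 0:
                        continue
                    add(
                        f"economics.daily_product_counts[{strat.value}][{c.name}][{pname}]",
                        "gamma",
                        False,
                        lambda ps, s=strat, c=c, p=pname: ps.economics.daily_product_counts[s][c][p],
                        lambda ps, v, s=strat, c=c, p=pname: ps.economics.daily_product_counts[s][c].__setitem__(
                            p, float(v)
                        ),
                    )
            add(
                f"economics.hygiene_cost[{strat.value}]",
                "gamma",
                False,
                lambda ps, s=strat: ps.economics.hygiene_cost_per_application[s],
                lambda ps, v, s=strat: ps.economics.hygiene_cost_per_application.__setitem__(s, float(v)),
            )
            if eco.technology_cost_per_person_year[strat] > 0:
                add(
                    f"economics.technology_cost[{strat.value}]",
                    "gamma",
                    False,
                    lambda ps, s=strat: ps.economics.technology_cost_per_person_year[s],
                    lambda ps, v, s=strat: ps.economics.technology_cost_per_person_year.__setitem__(s, float(v)),
                )
        for pname in eco.product_types:
            add(
                f"economics.product_price[{pname}]",
                "gamma",
                True,
                lambda ps, p=pname: ps.economics.product_types[p].price,
                lambda ps, v, p=pname: setattr(ps.economics.product_types[p], "price", float(v)),
            )
            add(
                f"economics.product_dry_weight[{pname}]",
                "gamma",
                True,
                lambda ps, p=pname: ps.economics.product_types[p].dry_weight_kg,
                lambda ps, v, p=pname: setattr(ps.economics.product_types[p], "dry_weight_kg", float(v)),
            )
        add(
            "economics.disposal_tariff_per_kg",
            "gamma",
            True,
            lambda ps: ps.economics.disposal_tariff_per_kg,
            lambda ps, v: setattr(ps.economics, "disposal_tariff_per_kg", float(v)),
        )
        for e in EventType:
            if eco.event_costs[e] > 0:
                add(
                    f"economics.event_costs[{e.value}]",
                    "gamma",
                    True,
                    lambda ps, e=e: ps.economics.event_costs[e],
                    lambda ps, v, e=e: ps.economics.event_costs.__setitem__(e, float(v)),
                )
        if eco.shl5_treatment.unit_cost_per_application > 0:
            add(
                "economics.shl5_unit_cost",
                "gamma",
                True,
                lambda ps: ps.economics.shl5_treatment.unit_cost_per_application,
                lambda ps, v: setattr(ps.economics.shl5_treatment, "unit_cost_per_application", float(v)),
            )
    return handles


# ---------------------------------------------------------------------------
# One-way sensitivity
# ---------------------------------------------------------------------------


def run_owsa(
    ps_conv: ParameterSet,
    ps_dht: ParameterSet,
    registry: Sequence[ParamHandle] | None = None,
) -> list[TornadoEntry]:
    """Re-run the deterministic comparison at each scalar parameter's bounds.

    Stochastic rows (Dirichlet families) carry no printed interval and are
    varied in the PSA only. Entries are sorted by the incremental-cost range
    when costs are available, else by the incremental-QALY range.
    """
    for pid in FIXED_PARAMETERS:
        logger.info("OWSA: parameter %s is fixed by design, skipped", pid)
    if registry is None:
        registry = build_registry(ps_conv)
    entries: list[TornadoEntry] = []
    for h in registry:
        if h.family in ("dirichlet_row", "fixed"):
            continue
        lo, hi = h.spec(ps_conv if h.shared else (ps_conv if _is_conv(h) else ps_dht)).bounds()
        lo = max(lo, h.lo_bound)
        hi = min(hi, h.hi_bound)
        results = []
        for bound in (lo, hi):
            pc, pd_ = ps_conv.copy(), ps_dht.copy()
            if h.shared:
                h.setter(pc, bound)
                h.setter(pd_, bound)
            else:
                # arm-specific tables live inside both copies; writing both
                # keeps the pair consistent while only the owning arm reads it
                h.setter(pc, bound)
                h.setter(pd_, bound)
            results.append(run_deterministic(pc, pd_))
        entries.append(
            TornadoEntry(
                pid=h.pid,
                low=lo,
                high=hi,
                delta_cost_low=results[0].delta_cost,
                delta_cost_high=results[1].delta_cost,
                delta_qaly_low=results[0].delta_qaly,
                delta_qaly_high=results[1].delta_qaly,
            )
        )
    entries.sort(key=lambda e: (e.cost_range, e.qaly_range), reverse=True)
    return entries


def _is_conv(h: ParamHandle) -> bool:
    return f"[{Strategy.CONVENTIONAL.value}]" in h.pid or f".{Strategy.CONVENTIONAL.value}" in h.pid


def owsa_frame(entries: Sequence[TornadoEntry]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "parameter": e.pid,
                "low": e.low,
                "high": e.high,
                "delta_cost_low": e.delta_cost_low,
                "delta_cost_high": e.delta_cost_high,
                "delta_qaly_low": e.delta_qaly_low,
                "delta_qaly_high": e.delta_qaly_high,
            }
            for e in entries
        ]
    )


# ---------------------------------------------------------------------------
# Probabilistic sensitivity
# ---------------------------------------------------------------------------


def psa_draw(
    ps_conv: ParameterSet,
    ps_dht: ParameterSet,
    registry: Sequence[ParamHandle],
    rng: np.random.Generator,
) -> tuple[ParameterSet, ParameterSet]:
    """One PSA parameter draw: shared handles once, arm handles independently."""
    pc, pd_ = ps_conv.copy(), ps_dht.copy()
    for h in registry:
        spec = h.spec(ps_conv)
        if h.shared:
            v = draw_from_spec(spec, rng, h.lo_bound, h.hi_bound)
            h.setter(pc, v)
            h.setter(pd_, v)
        else:
            # independent draws per arm; each written to both copies so the
            # pair stays interchangeable for either arm's tables
            spec_d = h.spec(ps_dht)
            v_c = draw_from_spec(spec, rng, h.lo_bound, h.hi_bound)
            v_d = draw_from_spec(spec_d, rng, h.lo_bound, h.hi_bound)
            if _is_conv(h):
                h.setter(pc, v_c)
                h.setter(pd_, v_c)
            else:
                h.setter(pc, v_d)
                h.setter(pd_, v_d)
    return pc, pd_


def run_psa(
    ps_conv: ParameterSet,
    ps_dht: ParameterSet,
    n_iter: int = 5000,
    seed: int = 0,
    registry: Sequence[ParamHandle] | None = None,
) -> PsaResult:
    """Monte-Carlo uncertainty analysis: draw, run, store (dCost, dQALY).

    Reproducible given ``seed``; each iteration records its own child seed so
    any single draw can be regenerated in isolation.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    if registry is None:
        registry = build_registry(ps_conv)
    root = np.random.default_rng(seed)
    seeds = root.integers(0, 2**31 - 1, size=n_iter)
    include_costs = ps_conv.economics is not None and ps_dht.economics is not None
    dq = np.empty(n_iter)
    dc = np.zeros(n_iter)
    for i, s in enumerate(seeds):
        rng = np.random.default_rng(int(s))
        pc, pd_ = psa_draw(ps_conv, ps_dht, registry, rng)
        res = run_deterministic(pc, pd_, include_costs=include_costs)
        dq[i] = res.delta_qaly
        if include_costs:
            dc[i] = res.delta_cost
    return PsaResult(delta_cost=dc, delta_qaly=dq, seeds=seeds, has_costs=include_costs)


def ceac(psa: PsaResult, lambdas: np.ndarray | Sequence[float] | None = None) -> CeacCurve:
    """Fraction of PSA samples with non-negative net monetary benefit per WTP."""
    if psa.n_iter == 0:
        raise ValueError("empty PSA result")
    lambdas = np.asarray(DEFAULT_LAMBDA_GRID if lambdas is None else lambdas, dtype=float)
    nmb = lambdas[:, None] * psa.delta_qaly[None, :] - psa.delta_cost[None, :]
    return CeacCurve(lambdas=lambdas, probabilities=(nmb >= 0).mean(axis=1))
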