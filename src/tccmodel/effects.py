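"""Discounted life-year and QALY accumulation.

QALYs decompose into three streams: a care-stage component (group baseline
utility minus the care-stage decrement), a skin-health loss (expected
skin-level decrement under the per-cycle skin mixture), and a care-consequence
loss (adverse-event rate times the event decrement, each event costing one
cycle of the decrement). Accumulation uses a half-cycle (trapezoid)
correction on the discounted occupancy stream, which also reproduces the
expected undiscounted life years from the mortality inputs.
"""

from __future__ import annotations

from dataclasses import dataclass

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
)

__all__ = [
    "QalyResult",
    "discount_factor",
    "cycle_utility",
    "event_disutility_rate",
    "accumulate_effects",
]

_STAGES = tuple(CareStage)
_SHLS = tuple(SkinHealthLevel)


@dataclass
class QalyResult:
    """Discounted QALY totals with their additive decomposition."""

    total_qalys: float
    cs_component: float
    shl_loss: float
    event_loss: float
    discounted_lys: float
    undiscounted_lys: float

    def __post_init__(self) -> None:
        recomposed = self.cs_component - self.shl_loss - self.event_loss
        if abs(self.total_qalys - recomposed) > 1e-9:
            raise ValueError("QALY components do not add up to the total")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "component": [
                    "total_qalys",
                    "cs_component",
                    "shl_loss",
                    "event_loss",
                    "discounted_lys",
                    "undiscounted_lys",
                ],
                "value": [
                    self.total_qalys,
                    self.cs_component,
                    self.shl_loss,
                    self.event_loss,
                    self.discounted_lys,
                    self.undiscounted_lys,
                ],
            }
        )


def discount_factor(cycle: int | np.ndarray, r: float, dt: float) -> float | np.ndarray:
    """Discount factor (1 + r)^(-cycle * dt) for an annual rate ``r``."""
    if r < 0:
        raise ValueError("discount rate must be non-negative")
    return (1.0 + r) ** (-np.asarray(cycle, dtype=float) * dt)


def expected_shl_decrement(ps: ParameterSet, strategy: Strategy, cs: CareStage) -> float:
    """Expected skin-health utility decrement under the per-cycle SHL mixture."""
    probs = shl_distribution(ps, strategy, cs)
    decs = np.array([ps.utilities.shl_decrement[l] for l in _SHLS])
    return float(probs @ decs)


def cycle_utility(ps: ParameterSet, strategy: Strategy, group: NeedGroup, cs: CareStage) -> float:
    """Per-cycle utility of an alive state: baseline minus CS and expected SHL
    decrements, floored at zero (dead contributes zero by construction)."""
    u = (
        ps.utilities.baseline[group]
        - ps.utilities.cs_decrement[cs]
        - expected_shl_decrement(ps, strategy, cs)
    )
    return max(u, 0.0)


def event_disutility_rate(ps: ParameterSet, strategy: Strategy, group: NeedGroup) -> float:
    """Expected utility loss per cycle from adverse care consequences."""
    er = ps.event_rates[Strategy(strategy)]
    return float(
        sum(er.rate(e, group) * ps.utilities.event_decrement[e] for e in EventType)
    )


def _trapezoid_accumulate(traj: Trajectory, weights: np.ndarray, r: float, dt: float) -> float:
    """Half-cycle-corrected discounted sum of an occupancy-weighted stream.

    ``weights`` is a per-alive-state rate (per year); each cycle contributes
    dt * average of the discounted start- and end-of-cycle values.
    """
    occ = traj.alive_occupancy()
    f = (occ @ weights) * discount_factor(np.arange(occ.shape[0]), r, dt)
    return float(dt * (0.5 * f[0] + f[1:-1].sum() + 0.5 * f[-1]))


def accumulate_effects(traj: Trajectory, ps: ParameterSet, strategy: Strategy | str) -> QalyResult:
    """Accumulate discounted QALYs and life years over a trajectory.

    The trajectory must have been produced from the same parameter set
    (checked through the content fingerprint).
    """
    strategy = Strategy(strategy)
    if traj.fingerprint != ps.fingerprint():
        raise ValueError("trajectory fingerprint does not match the parameter set")
    if traj.strategy != strategy:
        raise ValueError(f"trajectory was run for {traj.strategy.value!r}, not {strategy.value!r}")

    space = traj.state_space
    st = ps.settings
    n_alive = space.n_alive
    w_cs = np.empty(n_alive)
    w_shl = np.empty(n_alive)
    w_event = np.empty(n_alive)
    for idx in range(n_alive):
        g, c = space.state(idx)
        w_cs[idx] = ps.utilities.baseline[g] - ps.utilities.cs_decrement[c]
        w_shl[idx] = expected_shl_decrement(ps, strategy, c)
        w_event[idx] = event_disutility_rate(ps, strategy, g)

    r, dt = st.discount_rate, st.cycle_length_years
    ones = np.ones(n_alive)
    cs_component = _trapezoid_accumulate(traj, w_cs, r, dt)
    shl_loss = _trapezoid_accumulate(traj, w_shl, r, dt)
    event_loss = _trapezoid_accumulate(traj, w_event, r, dt)
    discounted_lys = _trapezoid_accumulate(traj, ones, r, dt)
    undiscounted_lys = _trapezoid_accumulate(traj, ones, 0.0, dt)
    return QalyResult(
        total_qalys=cs_component - shl_loss - event_loss,
        cs_component=cs_component,
        shl_loss=shl_loss,
        event_loss=event_loss,
        discounted_lys=discounted_lys,
        undiscounted_lys=undiscounted_lys,
    )
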