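import numpy as np
import pytest

import tccmodel as t


@pytest.fixture(scope="session")
def ps():
    """Effect-side case-study parameters (no economics block)."""
    return t.load_case_study()


@pytest.fixture(scope="session")
def ps_eco():
    """Case-study parameters with the synthetic economics fixture attached."""
    return t.load_case_study(with_economics=True)


@pytest.fixture(scope="session")
def traj_conv(ps):
    return t.run_cohort(ps, t.Strategy.CONVENTIONAL)


@pytest.fixture(scope="session")
def traj_dht(ps):
    return t.run_cohort(ps, t.Strategy.DHT)


@pytest.fixture(scope="session")
def traj_conv_eco(ps_eco):
    return t.run_cohort(ps_eco, t.Strategy.CONVENTIONAL)


@pytest.fixture(scope="session")
def traj_dht_eco(ps_eco):
    return t.run_cohort(ps_eco, t.Strategy.DHT)


def microsimulate(ps, strategy, n, n_cycles, seed, rule=None):
    """Independent per-individual simulation of the cohort rules.

    Vectorised but logically individual-level: each resident draws death,
    then a group transition, then a care-stage update each cycle, following
    the same verbal rules as the cohort engine but through per-person
    pseudo-random draws rather than matrix algebra. Returns the occupancy
    distribution over (group, cs) states plus dead after ``n_cycles``.
    """
    rng = np.random.default_rng(seed)
    strategy = t.Strategy(strategy)
    groups = tuple(ps.settings.included_groups)
    rule = rule or ps.settings.group_change_cs_rule
    g_idx = rng.choice(len(groups), size=n, p=[ps.initial_group_dist[g] for g in groups])
    c_idx = rng.choice(3, size=n, p=[ps.initial_cs_dist[c] for c in t.CareStage])
    alive = np.ones(n, dtype=bool)

    gt_cum = {}
    for gi, g in enumerate(groups):
        row = np.array([ps.group_transition[g].get(g2, 0.0) for g2 in groups])
        gt_cum[gi] = np.cumsum(row)
    cs_cum = np.cumsum(
        [[ps.cs_transition[strategy][c][c2] for c2 in t.CareStage] for c in t.CareStage], axis=1
    )

    age = ps.settings.start_age
    for _ in range(n_cycles):
        u = rng.random(n)
        for gi, g in enumerate(groups):
            mask = alive & (g_idx == gi)
            dead_now = mask & (u < t.mortality_prob(ps, g, age))
            alive[dead_now] = False
        new_g = g_idx.copy()
        u = rng.random(n)
        for gi in range(len(groups)):
            mask = alive & (g_idx == gi)
            new_g[mask] = np.searchsorted(gt_cum[gi], u[mask], side="right")
        moved = alive & (new_g != g_idx)
        stayed = alive & (new_g == g_idx)
        u = rng.random(n)
        new_c = c_idx.copy()
        for ci in range(3):
            mask = stayed & (c_idx == ci)
            new_c[mask] = np.searchsorted(cs_cum[ci], u[mask], side="right")
        if rule == "trial":
            for ci in range(3):
                mask = moved & (c_idx == ci)
                new_c[mask] = np.searchsorted(cs_cum[ci], u[mask], side="right")
        else:  # stay/worsen shift rule
            worsen = u < ps.cs_shift_worsen
            new_c[moved & worsen] = np.minimum(c_idx[moved & worsen] + 1, 2)
            new_c[moved & ~worsen] = c_idx[moved & ~worsen]
        g_idx, c_idx = new_g, new_c
        age += ps.settings.cycle_length_years

    occ = np.zeros(len(groups) * 3 + 1)
    for gi in range(len(groups)):
        for ci in range(3):
            occ[gi * 3 + ci] = np.sum(alive & (g_idx == gi) & (c_idx == ci))
    occ[-1] = np.sum(~alive)
    return occ / n
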