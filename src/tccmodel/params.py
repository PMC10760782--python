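"""Domain types, parameter containers, validation, and fixtures.

The model state is three-dimensional: a care-need profile (group G1..G6), a
care stage describing toileting success (CS1..CS3, operationalised through
total 24-hour product absorbency), and a skin-health level (SHL1..SHL5)
assigned memorylessly each cycle. A :class:`ParameterSet` carries every input
the cohort engine, outcome accumulators and sensitivity analyses need:
transition tables, age-band mortality, adverse-event rates, utilities and
utility decrements, and (optionally) the economics block with unit costs and
resource-use frequencies.
"""

from __future__ import annotations

import copy
import hashlib
import json
from dataclasses import dataclass, field, asdict
from enum import Enum, IntEnum
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import yaml

__all__ = [
    "NeedGroup",
    "CareStage",
    "SkinHealthLevel",
    "Strategy",
    "Task",
    "EventType",
    "AGE_BAND_EDGES",
    "ABSORBENCY_CUTOFFS",
    "Settings",
    "MortalityTable",
    "EventRates",
    "Utilities",
    "CareTasks",
    "Economics",
    "ParameterSet",
    "ValidationReport",
    "DistributionSpec",
    "normalize_rows",
    "classify_care_stage",
    "validate_parameter_set",
    "load_case_study",
    "load_parameter_file",
    "generate_synthetic_params",
]


class NeedGroup(IntEnum):
    """Care-dependency profile, ordered by increasing need for assistance."""

    G1 = 1
    G2 = 2
    G3 = 3
    G4 = 4
    G5 = 5
    G6 = 6


class CareStage(IntEnum):
    """Degree of toileting success: CS1 mainly toileting .. CS3 mainly containment."""

    CS1 = 1
    CS2 = 2
    CS3 = 3


class SkinHealthLevel(IntEnum):
    """Skin-health severity, SHL1 (no problems) to SHL5 (very severe)."""

    SHL1 = 1
    SHL2 = 2
    SHL3 = 3
    SHL4 = 4
    SHL5 = 5


class Strategy(str, Enum):
    """Care strategy arm."""

    CONVENTIONAL = "conventional"
    DHT = "dht"


class Task(str, Enum):
    """Continence-care task types with per-group minutes and staffing."""

    PRODUCT_CHECK = "product_check"
    PRODUCT_CHANGE = "product_change"
    TOILETING_ASSISTANCE = "toileting_assistance"
    LEAKAGE_CHANGE = "leakage_change"
    SHL5_TREATMENT = "shl5_treatment"


class EventType(str, Enum):
    """Adverse care consequences of incontinence management."""

    FRACTURE = "fracture"
    UTI = "uti"
    CONSTIPATION = "constipation"
    PU1 = "pu1"
    PU2 = "pu2"
    PU3 = "pu3"
    PU4 = "pu4"


#: Age-band lower edges in years; the last band is open-ended.
AGE_BAND_EDGES = (65.0, 75.0, 85.0, 95.0)

#: Care-stage cut-offs on total 24-hour absorbency (Rothwell units) per
#: resident size class: (CS1/CS2 threshold, CS2/CS3 threshold).
ABSORBENCY_CUTOFFS = {"average": (3800.0, 5700.0), "large": (4500.0, 6750.0)}

_GROUPS_ALL = tuple(NeedGroup)
_STAGES = tuple(CareStage)
_SHLS = tuple(SkinHealthLevel)

DAYS_PER_YEAR = 365.0


# ---------------------------------------------------------------------------
# Parameter containers
# ---------------------------------------------------------------------------


@dataclass
class Settings:
    cycle_length_years: float = 1.0 / 6.0
    discount_rate: float = 0.05
    start_age: float = 86.0
    max_cycles: int = 240
    included_groups: tuple[NeedGroup, ...] = (
        NeedGroup.G2,
        NeedGroup.G3,
        NeedGroup.G4,
        NeedGroup.G5,
        NeedGroup.G6,
    )
    survival_epsilon: float = 1e-6
    #: Care-stage update for residents who change group within a cycle:
    #: "trial" applies the strategy's care-stage transition matrix to movers
    #: and stayers alike (this reproduces the published cohort movement);
    #: "shift" applies the stay/worsen rule (10%/90%, CS3 absorbing) instead.
    group_change_cs_rule: str = "trial"

    @property
    def days_per_cycle(self) -> float:
        return self.cycle_length_years * DAYS_PER_YEAR


@dataclass
class MortalityTable:
    """Probability of death per cycle by age band and group class.

    Group classes share rows: G1 alone, G4 alone, and G2/G3/G5/G6 together
    (key ``other``). 95% CI bounds accompany each mean for sensitivity use.
    """

    mean: dict[str, np.ndarray]
    ci_low: dict[str, np.ndarray]
    ci_high: dict[str, np.ndarray]

    CLASSES = ("G1", "G4", "other")

    @staticmethod
    def group_class(group: NeedGroup) -> str:
        if group == NeedGroup.G1:
            return "G1"
        if group == NeedGroup.G4:
            return "G4"
        return "other"

    @staticmethod
    def age_band_index(age: float) -> int:
        if age < AGE_BAND_EDGES[0]:
            raise ValueError(f"age {age} below modelled range (>= 65 years)")
        return int(np.searchsorted(AGE_BAND_EDGES, age, side="right")) - 1

    def prob(self, group: NeedGroup, age: float) -> float:
        return float(self.mean[self.group_class(group)][self.age_band_index(age)])


@dataclass
class EventRates:
    """Per-cycle adverse-event probabilities for one strategy arm."""

    fracture_g2_g4: float
    fracture_g5_g6: float
    uti: float
    constipation: float
    pu1: float
    pu2: float
    pu3: float
    pu4: float

    def rate(self, event: EventType, group: NeedGroup) -> float:
        if event == EventType.FRACTURE:
            if group in (NeedGroup.G5, NeedGroup.G6):
                return self.fracture_g5_g6
            return self.fracture_g2_g4
        return float(getattr(self, event.value))


@dataclass
class Utilities:
    """Baseline utility per group plus decrement magnitudes (subtracted)."""

    baseline: dict[NeedGroup, float]
    cs_decrement: dict[CareStage, float]
    shl_decrement: dict[SkinHealthLevel, float]
    event_decrement: dict[EventType, float]


@dataclass
class CareTasks:
    """Minutes per task per staff member, and staff count per task, by group."""

    minutes: dict[Task, dict[NeedGroup, float]]
    staff: dict[Task, dict[NeedGroup, float]]


@dataclass
class ProductType:
    name: str
    price: float
    absorbency: float
    dry_weight_kg: float


@dataclass
class Shl5Treatment:
    minutes_per_application: float = 1.0
    duration_days: float = 7.0
    unit_cost_per_application: float = 0.0


@dataclass
class Economics:
    """Unit costs and resource-use frequencies for the cost side.

    ``placeholder`` marks fixtures whose values are synthetic stand-ins rather
    than transcribed source data; downstream reports carry the flag through.
    """

    wage_formal_per_min: float
    wage_informal_per_min: float
    informal_share: float
    # task -> occurrences per day, keyed by (strategy, group, care stage)
    task_frequencies: dict[Strategy, dict[NeedGroup, dict[CareStage, dict[Task, float]]]]
    product_types: dict[str, ProductType]
    # products per day, keyed by (strategy, care stage, product type)
    daily_product_counts: dict[Strategy, dict[CareStage, dict[str, float]]]
    hygiene_cost_per_application: dict[Strategy, float]
    disposal_tariff_per_kg: float
    event_costs: dict[EventType, float]
    technology_cost_per_person_year: dict[Strategy, float]
    shl5_treatment: Shl5Treatment = field(default_factory=Shl5Treatment)
    placeholder: bool = False


@dataclass
class ParameterSet:
    """Every input the cohort model needs, for one or both strategy arms."""

    settings: Settings
    initial_group_dist: dict[NeedGroup, float]
    initial_cs_dist: dict[CareStage, float]
    initial_shl_dist: dict[SkinHealthLevel, float]
    group_transition: dict[NeedGroup, dict[NeedGroup, float]]
    cs_shift_stay: float
    cs_shift_worsen: float
    mortality: MortalityTable
    cs_transition: dict[Strategy, dict[CareStage, dict[CareStage, float]]]
    shl_given_cs: dict[Strategy, dict[CareStage, np.ndarray]]
    event_rates: dict[Strategy, EventRates]
    utilities: Utilities
    care_tasks: CareTasks
    economics: Economics | None = None
    meta: dict = field(default_factory=dict)

    def copy(self) -> "ParameterSet":
        return copy.deepcopy(self)

    def fingerprint(self) -> str:
        """Stable content hash used to tie trajectories to their inputs."""

        def default(o):
            if isinstance(o, np.ndarray):
                return o.tolist()
            if isinstance(o, Enum):
                return o.value
            return str(o)

        payload = json.dumps(asdict(self), sort_keys=True, default=default)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class ValidationReport:
    errors: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors


@dataclass
class DistributionSpec:
    """Uncertainty family attached to one parameter (or stochastic row).

    ``beta`` and ``gamma`` are moment-matched from (mean, se); ``normal``
    draws are truncated to the admissible range by resampling;
    ``dirichlet_row`` perturbs a whole stochastic row around its mean.
    When no interval is reported the standard error defaults to 20% of the
    mean (``DEFAULT_SE_FRAC``).
    """

    family: str  # beta | gamma | normal | dirichlet_row | fixed
    mean: float | np.ndarray | None = None
    se: float | None = None
    low: float | None = None
    high: float | None = None

    DEFAULT_SE_FRAC = 0.20

    def __post_init__(self) -> None:
        allowed = {"beta", "gamma", "normal", "dirichlet_row", "fixed"}
        if self.family not in allowed:
            raise ValueError(f"unknown distribution family {self.family!r}")
        if self.family in ("beta", "gamma", "normal") and self.se is None and self.mean is not None:
            self.se = self.DEFAULT_SE_FRAC * abs(float(self.mean))

    def bounds(self) -> tuple[float, float]:
        """95% interval for one-way sensitivity: reported CI or mean +/- 1.96 SE."""
        if self.low is not None and self.high is not None:
            return float(self.low), float(self.high)
        if self.mean is None or self.se is None:
            raise ValueError("bounds unavailable: no CI and no (mean, se)")
        m, s = float(self.mean), float(self.se)
        lo, hi = m - 1.96 * s, m + 1.96 * s
        if self.family == "beta":
            lo, hi = max(lo, 0.0), min(hi, 1.0)
        elif self.family == "gamma":
            lo = max(lo, 0.0)
        return lo, hi


# ---------------------------------------------------------------------------
# Primitive operations
# ---------------------------------------------------------------------------


def normalize_rows(rows: np.ndarray, tol: float = 0.02, labels: Iterable[str] | None = None) -> np.ndarray:
    """Renormalize a row-stochastic table printed with rounding error.

    Each row is divided by its sum provided the sum lies within ``tol`` of 1;
    otherwise a ``ValueError`` names the offending row. Idempotent.
    """
    rows = np.asarray(rows, dtype=float)
    arr = np.atleast_2d(rows)
    sums = arr.sum(axis=1)
    labels = list(labels) if labels is not None else [str(i) for i in range(arr.shape[0])]
    for i, s in enumerate(sums):
        if abs(s - 1.0) > tol:
            raise ValueError(f"row {labels[i]} sums to {s:.4f}, outside 1 +/- {tol}")
    out = arr / sums[:, None]
    return out.reshape(rows.shape)


def classify_care_stage(total_absorbency_24h: float, size_class: str = "average") -> CareStage:
    """Map total 24-hour absorbency (Rothwell units) to a care stage.

    Band endpoints belong to CS2, making the three stages an exhaustive
    partition of the non-negative line.
    """
    if total_absorbency_24h < 0:
        raise ValueError("total 24-hour absorbency must be non-negative")
    try:
        lo, hi = ABSORBENCY_CUTOFFS[size_class]
    except KeyError:
        raise ValueError(f"unknown size class {size_class!r}") from None
    if total_absorbency_24h < lo:
        return CareStage.CS1
    if total_absorbency_24h <= hi:
        return CareStage.CS2
    return CareStage.CS3


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------


def _check_prob(report: ValidationReport, name: str, value: float) -> None:
    if not (0.0 <= value <= 1.0):
        report.errors.append(f"{name} = {value} outside [0, 1]")


def _check_row(report: ValidationReport, name: str, row: np.ndarray, tol: float = 0.02) -> None:
    row = np.asarray(row, dtype=float)
    if (row < 0).any():
        report.errors.append(f"{name} has negative entries")
        return
    s = float(row.sum())
    if abs(s - 1.0) > tol:
        report.errors.append(f"{name} sums to {s:.4f}, outside 1 +/- {tol}")
    elif abs(s - 1.0) > 1e-9:
        report.warnings.append(f"{name} sums to {s:.4f}: renormalizable row")


def validate_parameter_set(ps: ParameterSet) -> ValidationReport:
    """Check every structural invariant; report-only, never mutates ``ps``."""
    rep = ValidationReport()
    st = ps.settings
    if st.cycle_length_years <= 0:
        rep.errors.append("cycle_length_years must be positive")
    if st.discount_rate < 0:
        rep.errors.append("discount_rate must be non-negative")
    if not ps.settings.included_groups:
        rep.errors.append("included_groups is empty")
    if st.group_change_cs_rule not in ("trial", "shift"):
        rep.errors.append(f"unknown group_change_cs_rule {st.group_change_cs_rule!r}")

    for dist, name in (
        (ps.initial_group_dist, "initial_group_dist"),
        (ps.initial_cs_dist, "initial_cs_dist"),
        (ps.initial_shl_dist, "initial_shl_dist"),
    ):
        _check_row(rep, name, np.array(list(dist.values())))

    for g, row in ps.group_transition.items():
        for g2, p in row.items():
            _check_prob(rep, f"group_transition[{g.name}->{g2.name}]", p)
            if g2 < g and p > 0:
                rep.errors.append(
                    f"group_transition[{g.name}->{g2.name}] = {p}: "
                    "no mass may flow to a lower-indexed group"
                )
        _check_row(rep, f"group_transition[{g.name}]", np.array(list(row.values())))

    for p, name in ((ps.cs_shift_stay, "cs_shift_stay"), (ps.cs_shift_worsen, "cs_shift_worsen")):
        _check_prob(rep, name, p)
    if abs(ps.cs_shift_stay + ps.cs_shift_worsen - 1.0) > 1e-9:
        rep.errors.append("cs_shift_stay + cs_shift_worsen must equal 1")

    for cls in MortalityTable.CLASSES:
        for arr, label in (
            (ps.mortality.mean[cls], "mean"),
            (ps.mortality.ci_low[cls], "ci_low"),
            (ps.mortality.ci_high[cls], "ci_high"),
        ):
            for i, v in enumerate(np.asarray(arr, dtype=float)):
                _check_prob(rep, f"mortality.{label}[{cls}][band {i}]", float(v))

    for strat, table in ps.cs_transition.items():
        for c, row in table.items():
            _check_row(
                rep,
                f"cs_transition[{strat.value}][{c.name}]",
                np.array([row.get(c2, 0.0) for c2 in _STAGES]),
            )
    for strat, table in ps.shl_given_cs.items():
        for c, row in table.items():
            _check_row(rep, f"shl_given_cs[{strat.value}][{c.name}]", row)

    for strat, er in ps.event_rates.items():
        for f in ("fracture_g2_g4", "fracture_g5_g6", "uti", "constipation", "pu1", "pu2", "pu3", "pu4"):
            _check_prob(rep, f"event_rates[{strat.value}].{f}", getattr(er, f))

    for g, u in ps.utilities.baseline.items():
        if not (0.0 <= u <= 1.0):
            rep.errors.append(f"utilities.baseline[{g.name}] = {u} outside [0, 1]")
    for table, name in (
        (ps.utilities.cs_decrement, "cs_decrement"),
        (ps.utilities.shl_decrement, "shl_decrement"),
        (ps.utilities.event_decrement, "event_decrement"),
    ):
        for k, d in table.items():
            if d < 0:
                rep.errors.append(f"utilities.{name}[{getattr(k, 'name', k)}] = {d} is negative")

    for task in Task:
        for g in st.included_groups:
            for table, name in ((ps.care_tasks.minutes, "minutes"), (ps.care_tasks.staff, "staff")):
                v = table.get(task, {}).get(g)
                if v is None:
                    rep.errors.append(f"care_tasks.{name}[{task.value}][{g.name}] missing")
                elif v < 0:
                    rep.errors.append(f"care_tasks.{name}[{task.value}][{g.name}] = {v} is negative")

    if ps.economics is not None:
        eco = ps.economics
        for nm in ("wage_formal_per_min", "wage_informal_per_min", "disposal_tariff_per_kg"):
            if getattr(eco, nm) < 0:
                rep.errors.append(f"economics.{nm} is negative")
        if not (0.0 <= eco.informal_share <= 1.0):
            rep.errors.append("economics.informal_share outside [0, 1]")
        for strat, by_group in eco.task_frequencies.items():
            for g, by_cs in by_group.items():
                for c, by_task in by_cs.items():
                    for t, f in by_task.items():
                        if f < 0:
                            rep.errors.append(
                                f"economics.task_frequencies[{strat.value}][{g.name}][{c.name}][{t.value}] negative"
                            )
        for pt in eco.product_types.values():
            if min(pt.price, pt.absorbency, pt.dry_weight_kg) < 0:
                rep.errors.append(f"economics.product_types[{pt.name}] has negative fields")
        for strat, by_cs in eco.daily_product_counts.items():
            for c, counts in by_cs.items():
                for pname, n in counts.items():
                    if pname not in eco.product_types:
                        rep.errors.append(f"economics.daily_product_counts references unknown product {pname!r}")
                    if n < 0:
                        rep.errors.append(
                            f"economics.daily_product_counts[{strat.value}][{c.name}][{pname}] negative"
                        )
        for ev, cst in eco.event_costs.items():
            if cst < 0:
                rep.errors.append(f"economics.event_costs[{ev.value}] negative")
    return rep


# ---------------------------------------------------------------------------
# Fixture loading
# ---------------------------------------------------------------------------


def _data_path(name: str) -> Path:
    return Path(resources.files("tccmodel").joinpath("data", name))  # type: ignore[arg-type]


def _groups_from_keys(d: Mapping[str, float]) -> dict[NeedGroup, float]:
    return {NeedGroup[k]: float(v) for k, v in d.items()}


def _parse_economics(doc: Mapping) -> Economics:
    meta = doc.get("meta", {})
    lab = doc["labour"]
    freqs: dict[Strategy, dict[NeedGroup, dict[CareStage, dict[Task, float]]]] = {}
    for strat_key, by_cs in doc["task_frequencies_per_day"].items():
        strat = Strategy(strat_key)
        per_cs = {
            CareStage[c]: {Task(t): float(v) for t, v in tasks.items()} for c, tasks in by_cs.items()
        }
        # fixture frequencies are broadcast across included groups
        freqs[strat] = {g: copy.deepcopy(per_cs) for g in _GROUPS_ALL}
    ptypes = {
        name: ProductType(name=name, **{k: float(v) for k, v in spec.items()})
        for name, spec in doc["products"]["types"].items()
    }
    counts = {
        Strategy(s): {CareStage[c]: {p: float(n) for p, n in row.items()} for c, row in by_cs.items()}
        for s, by_cs in doc["products"]["daily_counts"].items()
    }
    shl5 = doc.get("shl5_treatment", {})
    return Economics(
        wage_formal_per_min=float(lab["wage_formal_per_min"]),
        wage_informal_per_min=float(lab["wage_informal_per_min"]),
        informal_share=float(lab.get("informal_share", 0.0)),
        task_frequencies=freqs,
        product_types=ptypes,
        daily_product_counts=counts,
        hygiene_cost_per_application={Strategy(s): float(v) for s, v in doc["hygiene_cost_per_application"].items()},
        disposal_tariff_per_kg=float(doc["disposal_tariff_per_kg"]),
        event_costs={EventType(e): float(v) for e, v in doc["event_costs"].items()},
        technology_cost_per_person_year={
            Strategy(s): float(v) for s, v in doc["technology_cost_per_person_year"].items()
        },
        shl5_treatment=Shl5Treatment(**{k: float(v) for k, v in shl5.items()}),
        placeholder=bool(meta.get("placeholder", False)),
    )


def load_parameter_file(path: str | Path, economics_path: str | Path | None = None) -> ParameterSet:
    """Load a ParameterSet from a YAML scenario document.

    Transition rows printed with rounding error are renormalized to exact
    row-stochasticity. ``economics_path`` optionally attaches the cost-side
    block; without it the effect side is fully runnable.
    """
    path = Path(path)
    try:
        doc = yaml.safe_load(path.read_text())
    except FileNotFoundError:
        raise FileNotFoundError(f"parameter file not found: {path}") from None

    required = [
        "settings",
        "initial_distributions",
        "group_transition",
        "cs_shift_on_group_change",
        "mortality",
        "cs_transition",
        "shl_given_cs",
        "event_rates",
        "utilities",
        "care_tasks",
    ]
    missing = [k for k in required if k not in doc]
    if missing:
        raise ValueError(f"parameter file {path} missing fields: {', '.join(missing)}")

    s = doc["settings"]
    settings = Settings(
        cycle_length_years=float(s["cycle_length_years"]),
        discount_rate=float(s["discount_rate"]),
        start_age=float(s["start_age"]),
        max_cycles=int(s["max_cycles"]),
        included_groups=tuple(NeedGroup[g] for g in s["included_groups"]),
        survival_epsilon=float(s["survival_epsilon"]),
        group_change_cs_rule=str(s.get("group_change_cs_rule", "trial")),
    )

    init = doc["initial_distributions"]
    group_dist = _groups_from_keys(init["group"])
    gvals = normalize_rows(np.array(list(group_dist.values())))
    group_dist = dict(zip(group_dist, gvals))
    cs_vals = normalize_rows(np.array([float(init["care_stage"][c.name]) for c in _STAGES]))
    cs_dist = dict(zip(_STAGES, cs_vals))
    shl_vals = normalize_rows(np.array([float(init["skin_health"][l.name]) for l in _SHLS]))
    shl_dist = dict(zip(_SHLS, shl_vals))

    gt: dict[NeedGroup, dict[NeedGroup, float]] = {}
    for gk, row in doc["group_transition"].items():
        g = NeedGroup[gk]
        targets = {NeedGroup[k]: float(v) for k, v in row.items()}
        vals = normalize_rows(np.array(list(targets.values())), labels=[f"group_transition[{gk}]"] )
        gt[g] = dict(zip(targets, vals))

    shift = doc["cs_shift_on_group_change"]

    m = doc["mortality"]
    mortality = MortalityTable(
        mean={c: np.array(m[c]["mean"], dtype=float) for c in MortalityTable.CLASSES},
        ci_low={c: np.array(m[c]["ci_low"], dtype=float) for c in MortalityTable.CLASSES},
        ci_high={c: np.array(m[c]["ci_high"], dtype=float) for c in MortalityTable.CLASSES},
    )

    cs_tr: dict[Strategy, dict[CareStage, dict[CareStage, float]]] = {}
    for sk, table in doc["cs_transition"].items():
        strat = Strategy(sk)
        cs_tr[strat] = {}
        for ck, row in table.items():
            c = CareStage[ck]
            vec = np.array([float(row.get(c2.name, 0.0)) for c2 in _STAGES])
            vec = normalize_rows(vec, labels=[f"cs_transition[{sk}][{ck}]"])
            cs_tr[strat][c] = dict(zip(_STAGES, vec))

    shl_cs: dict[Strategy, dict[CareStage, np.ndarray]] = {}
    for sk, table in doc["shl_given_cs"].items():
        strat = Strategy(sk)
        shl_cs[strat] = {
            CareStage[ck]: normalize_rows(np.array(row, dtype=float), labels=[f"shl_given_cs[{sk}][{ck}]"])
            for ck, row in table.items()
        }

    ev = {Strategy(sk): EventRates(**{k: float(v) for k, v in row.items()}) for sk, row in doc["event_rates"].items()}

    u = doc["utilities"]
    utilities = Utilities(
        baseline=_groups_from_keys(u["baseline"]),
        cs_decrement={CareStage[k]: abs(float(v)) for k, v in u["cs_decrement"].items()},
        shl_decrement={SkinHealthLevel[k]: abs(float(v)) for k, v in u["shl_decrement"].items()},
        event_decrement={EventType(k): abs(float(v)) for k, v in u["event_decrement"].items()},
    )

    ct = doc["care_tasks"]
    care_tasks = CareTasks(
        minutes={Task(t): _groups_from_keys(row) for t, row in ct["minutes"].items()},
        staff={Task(t): _groups_from_keys(row) for t, row in ct["staff"].items()},
    )

    economics = None
    if economics_path is not None:
        eco_doc = yaml.safe_load(Path(economics_path).read_text())
        economics = _parse_economics(eco_doc)

    return ParameterSet(
        settings=settings,
        initial_group_dist=group_dist,
        initial_cs_dist=cs_dist,
        initial_shl_dist=shl_dist,
        group_transition=gt,
        cs_shift_stay=float(shift["stay"]),
        cs_shift_worsen=float(shift["worsen"]),
        mortality=mortality,
        cs_transition=cs_tr,
        shl_given_cs=shl_cs,
        event_rates=ev,
        utilities=utilities,
        care_tasks=care_tasks,
        economics=economics,
        meta=dict(doc.get("meta", {})),
    )


def load_case_study(strategy: Strategy | str = Strategy.CONVENTIONAL, with_economics: bool = False) -> ParameterSet:
    """Load the bundled Canadian residential-care scenario.

    The returned set carries the tables for both arms; ``strategy`` records
    which arm a caller intends to run (stored in ``meta['strategy']``). With
    ``with_economics`` the synthetic placeholder cost fixture is attached.
    """
    strategy = Strategy(strategy)
    eco = _data_path("economics_synthetic.yaml") if with_economics else None
    ps = load_parameter_file(_data_path("case_study_main.yaml"), economics_path=eco)
    ps.meta["strategy"] = strategy.value
    return ps


# ---------------------------------------------------------------------------
# Synthetic parameter generation
# ---------------------------------------------------------------------------


def _dirichlet_around(rng: np.random.Generator, mean: np.ndarray, uniform: bool) -> np.ndarray:
    """Draw a stochastic row: Dirichlet about ``mean`` (structural zeros kept),
    or uniform on the simplex over the non-zero support when ``uniform``."""
    mean = np.asarray(mean, dtype=float)
    support = mean > 0
    k = int(support.sum())
    out = np.zeros_like(mean)
    if k == 1:
        out[support] = 1.0
        return out
    if uniform:
        out[support] = rng.dirichlet(np.ones(k))
        return out
    conc = 50.0  # moderate spread about the template row
    out[support] = rng.dirichlet(mean[support] * conc)
    return out


def generate_synthetic_params(
    seed: int,
    template: ParameterSet | None = None,
    with_economics: bool = True,
) -> ParameterSet:
    """Generate a fully valid random ParameterSet, deterministic given ``seed``.

    Stochastic rows are Dirichlet draws around the template means (uniform on
    the admissible simplex when no template is given); scalar rates, utilities
    and unit costs are perturbed within their default uncertainty families.
    Structural zeros (group ordering, impossible fractures) are preserved, so
    every draw passes :func:`validate_parameter_set` with zero errors.
    """
    rng = np.random.default_rng(seed)
    uniform = template is None
    base = template if template is not None else load_case_study(with_economics=with_economics)
    ps = base.copy()

    def beta_like(mean: float) -> float:
        if mean <= 0.0 or mean >= 1.0:
            return mean
        se = min(0.2 * mean, 0.5 * np.sqrt(mean * (1 - mean)))
        nu = mean * (1 - mean) / se**2 - 1.0
        return float(rng.beta(mean * nu, (1 - mean) * nu))

    def gamma_like(mean: float) -> float:
        if mean <= 0:
            return mean
        shape = 25.0  # SE = 20% of mean
        return float(rng.gamma(shape, mean / shape))

    for dist in (ps.initial_group_dist, ps.initial_cs_dist):
        keys = list(dist)
        row = _dirichlet_around(rng, np.array([dist[k] for k in keys]), uniform)
        dist.update(zip(keys, row))
    keys = list(ps.initial_shl_dist)
    row = _dirichlet_around(rng, np.array([ps.initial_shl_dist[k] for k in keys]), uniform)
    ps.initial_shl_dist.update(zip(keys, row))

    for g, grow in ps.group_transition.items():
        keys = list(grow)
        row = _dirichlet_around(rng, np.array([grow[k] for k in keys]), uniform)
        grow.update(zip(keys, row))

    for strat, table in ps.cs_transition.items():
        for c, crow in table.items():
            keys = list(crow)
            row = _dirichlet_around(rng, np.array([crow[k] for k in keys]), uniform)
            crow.update(zip(keys, row))

    for strat, table in ps.shl_given_cs.items():
        for c in list(table):
            table[c] = _dirichlet_around(rng, table[c], uniform)

    for cls in MortalityTable.CLASSES:
        mean = ps.mortality.mean[cls]
        drawn = np.array([beta_like(float(v)) for v in mean])
        ps.mortality.mean[cls] = drawn
        ps.mortality.ci_low[cls] = np.clip(drawn * 0.9, 0.0, 1.0)
        ps.mortality.ci_high[cls] = np.clip(drawn * 1.1, 0.0, 1.0)

    for strat, er in ps.event_rates.items():
        for f in ("fracture_g2_g4", "fracture_g5_g6", "uti", "constipation", "pu1", "pu2", "pu3", "pu4"):
            setattr(er, f, beta_like(getattr(er, f)))

    for g in list(ps.utilities.baseline):
        ps.utilities.baseline[g] = beta_like(ps.utilities.baseline[g])
    for table in (ps.utilities.cs_decrement, ps.utilities.shl_decrement, ps.utilities.event_decrement):
        for k in list(table):
            table[k] = beta_like(table[k])

    if ps.economics is not None:
        eco = ps.economics
        eco.wage_formal_per_min = gamma_like(eco.wage_formal_per_min)
        eco.wage_informal_per_min = gamma_like(eco.wage_informal_per_min)
        for by_group in eco.task_frequencies.values():
            for by_cs in by_group.values():
                for by_task in by_cs.values():
                    for t in list(by_task):
                        by_task[t] = gamma_like(by_task[t])
        for pt in eco.product_types.values():
            pt.price = gamma_like(pt.price)
            pt.dry_weight_kg = gamma_like(pt.dry_weight_kg)
        for by_cs in eco.daily_product_counts.values():
            for counts in by_cs.values():
                for p in list(counts):
                    counts[p] = gamma_like(counts[p])
        for strat in list(eco.hygiene_cost_per_application):
            eco.hygiene_cost_per_application[strat] = gamma_like(eco.hygiene_cost_per_application[strat])
        eco.disposal_tariff_per_kg = gamma_like(eco.disposal_tariff_per_kg)
        for evt in list(eco.event_costs):
            eco.event_costs[evt] = gamma_like(eco.event_costs[evt])
        for strat in list(eco.technology_cost_per_person_year):
            eco.technology_cost_per_person_year[strat] = gamma_like(
                eco.technology_cost_per_person_year[strat]
            )
        eco.shl5_treatment.unit_cost_per_application = gamma_like(eco.shl5_treatment.unit_cost_per_application)

    ps.meta = dict(ps.meta, synthetic=True, seed=int(seed))
    return ps
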