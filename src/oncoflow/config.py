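"""Model parameterization: types, defaults, presets, validation, file I/O.

The whole model is driven by a :class:`ModelConfig`: the ordered diagnostic
pathway (tasks with automation/interoperability susceptibilities), the
finite resource pools with their shift calendars, the stochastic case mix,
the mechanism coefficients, and the simulation horizon.  The canonical
default parameterization below is stylized — chosen from standard oncology
operating figures and then calibrated so that the four corner scenarios of
the strategy space reproduce the reference operational signatures (baseline
constrained by CT imaging; automation without interoperability saturating
governance; interoperability-led operation constrained by the molecular
laboratory; full integration constrained by chemotherapy chairs).

Config files are YAML (``schema: 1``); durations carry ``_hours`` suffixes
and horizon quantities ``_days`` suffixes.  ``save_config`` /
``load_config`` round-trip exactly.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Tuple

import numpy as np
import yaml

from .calendar import ShiftPattern

SCHEMA_VERSION = 1

TUMOR_TYPES = ("lung", "breast", "colorectal")
STAGES = ("early", "late")
DISTRIBUTIONS = ("deterministic", "exponential", "lognormal")
SCHEDULE_CLASSES = ("clinical_shift", "continuous")


@dataclass(frozen=True)
class ScenarioCoordinate:
    """A point (A, I) in the normalized strategy space.

    ``A`` is AI automation intensity, ``I`` data interoperability, both in
    [0, 1].
    """

    A: float
    I: float

    def __post_init__(self):
        if not (0.0 <= self.A <= 1.0 and 0.0 <= self.I <= 1.0):
            raise ValueError(f"coordinate ({self.A}, {self.I}) outside unit square")


@dataclass
class TaskSpec:
    """One pathway task with its automation/interoperability response."""

    name: str
    base_duration_hours: float
    alpha: float  # automation susceptibility
    beta: float   # interoperability susceptibility
    resource_pool: str
    atomic: bool = True
    duration_distribution: str = "lognormal"
    dispersion: float = 0.25  # CV for lognormal; unused otherwise
    schedule_class: str | None = None  # None = inherit from resource pool


@dataclass
class ResourcePoolSpec:
    """A finite-capacity server pool with a shift calendar.

    ``working_days`` (Monday = 0) restricts a clinical-shift pool to
    specific weekdays, e.g. session-based services such as MDT boards;
    ``None`` means Monday-Friday.
    """

    name: str
    capacity: int
    schedule_class: str = "clinical_shift"
    shift_start_hour: float = 8.0
    shift_end_hour: float = 17.0
    working_days: List[int] | None = None

    def pattern(self) -> ShiftPattern:
        if self.schedule_class == "continuous":
            return ShiftPattern.continuous()
        days = (frozenset(self.working_days) if self.working_days is not None
                else None)
        if days is None:
            return ShiftPattern.clinical(self.shift_start_hour,
                                         self.shift_end_hour)
        return ShiftPattern("clinical_shift",
                            ((self.shift_start_hour, self.shift_end_hour),),
                            days)


@dataclass
class CaseMixSpec:
    """Stochastic arrival process and tumor/stage mix."""

    arrival_rate_per_day: float = 3.15
    tumor_probs: Dict[str, float] = field(
        default_factory=lambda: {"lung": 0.40, "breast": 0.35, "colorectal": 0.25}
    )
    stage_probs: Dict[str, Dict[str, float]] = field(
        default_factory=lambda: {
            t: {"early": 0.55, "late": 0.45} for t in TUMOR_TYPES
        }
    )


@dataclass
class MechanismParams:
    """Coefficients of the parametric operational mechanisms.

    Probability-producing coefficient sets must keep their *unclamped*
    outputs inside [0, 1] over the whole unit square (checked by
    :func:`validate_config` on a grid scan).
    """

    # governance audits (blocking manual verification of automated steps)
    gov_base: float = 0.02
    gov_slope: float = 0.88
    gov_audit_duration_hours: float = 0.25
    # AI-triage false positives (benign workups displacing confirmed cases)
    fp_base: float = 0.10
    fp_slope: float = 0.33
    fp_interop_relief: float = 0.65
    induction_scale: float = 1.0
    # virtual MDT adoption
    vmdt_base: float = 0.10
    vmdt_slope: float = 0.80
    vmdt_speedup: float = 0.40
    # pathology rework
    rework_base: float = 0.12
    rework_interop_relief: float = 0.50
    # wait-elastic induced demand
    demand_elasticity: float = 0.55
    demand_reference_wait_days: float = 28.9
    # throughput strain
    strain_threshold: float = 0.90
    strain_penalty: float = 0.08
    # audit trigger: tasks with alpha >= this count as automated
    automated_alpha_threshold: float = 0.1
    # per-mechanism switches
    enable_governance: bool = True
    enable_triage_fp: bool = True
    enable_vmdt: bool = True
    enable_rework: bool = True
    enable_induced_demand: bool = True
    enable_strain: bool = True


@dataclass
class CostWeights:
    """Weights of the four normalized transition-cost components."""

    w_rtti_mean: float = 0.25
    w_rtti_sd: float = 0.25
    w_thr_inv: float = 0.25
    w_thr_sd: float = 0.25

    def validate(self) -> None:
        total = self.w_rtti_mean + self.w_rtti_sd + self.w_thr_inv + self.w_thr_sd
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"cost weights must sum to 1 (got {total})")
        if min(self.w_rtti_mean, self.w_rtti_sd, self.w_thr_inv, self.w_thr_sd) < 0:
            raise ValueError("cost weights must be non-negative")


@dataclass
class ModelConfig:
    """Complete model parameterization."""

    tasks: List[TaskSpec]
    resources: List[ResourcePoolSpec]
    casemix: CaseMixSpec
    mechanisms: MechanismParams
    treatment_rules: Dict[Tuple[str, str], List[str]]
    horizon_days: float = 1095.0
    warmup_days: float = 150.0

    def resource(self, name: str) -> ResourcePoolSpec:
        for r in self.resources:
            if r.name == name:
                return r
        raise KeyError(name)

    def task(self, name: str) -> TaskSpec:
        for t in self.tasks:
            if t.name == name:
                return t
        raise KeyError(name)


# ---------------------------------------------------------------------------
# canonical defaults
# ---------------------------------------------------------------------------

def default_config() -> ModelConfig:
    """The canonical (calibrated) default parameterization.

    A generic high-volume cancer center: about 3.2 referrals per day across
    lung, breast and colorectal cancer, a single heavily loaded CT scanner,
    a continuously operating molecular laboratory, and modest treatment
    capacity.  Automation susceptibility ``alpha`` is high for
    administrative and pathology work and near zero for hands-on treatment;
    interoperability susceptibility ``beta`` is highest where coordination
    and data exchange dominate (intake, imaging scheduling, MDT).
    """
    resources = [
        ResourcePoolSpec("admin_staff", 40, "clinical_shift"),
        ResourcePoolSpec("ct_scanner", 1, "clinical_shift"),
        ResourcePoolSpec("biopsy_suite", 1, "clinical_shift"),
        ResourcePoolSpec("pathologist", 21, "clinical_shift"),
        ResourcePoolSpec("molecular_lab", 16, "continuous"),
        # weekly tumor board (Monday, three parallel review slots)
        ResourcePoolSpec("mdt_slot", 3, "clinical_shift",
                         working_days=[0]),
        ResourcePoolSpec("operating_room", 2, "clinical_shift"),
        ResourcePoolSpec("chemo_chair", 2, "clinical_shift"),
        ResourcePoolSpec("rt_linac", 1, "clinical_shift"),
        # manual-verification review board sits on Fridays
        ResourcePoolSpec("governance_officer", 4, "clinical_shift",
                         working_days=[4]),
    ]
    tasks = [
        # base durations are end-to-end processing times (admin handling of
        # a referral, pathology turnaround, molecular assay) rather than
        # hands-on minutes, so queueing stays moderate at every stage
        TaskSpec("intake", 64.0, 0.60, 0.50, "admin_staff", atomic=False,
                 duration_distribution="exponential"),
        TaskSpec("imaging", 1.735, 0.30, 0.40, "ct_scanner"),
        TaskSpec("biopsy", 1.70, 0.16, 0.10, "biopsy_suite"),
        TaskSpec("pathology", 31.5, 0.50, 0.30, "pathologist", atomic=False),
        TaskSpec("molecular", 113.0, 0.15, 0.0, "molecular_lab", atomic=False),
        TaskSpec("mdt", 0.5, 0.20, 0.50, "mdt_slot"),
        TaskSpec("surgery", 3.2, 0.05, 0.10, "operating_room"),
        TaskSpec("chemo_start", 4.52, 0.0, 0.0, "chemo_chair", atomic=False),
        TaskSpec("rt_start", 2.0, 0.10, 0.10, "rt_linac"),
    ]
    treatment_rules = {
        ("lung", "early"): ["surgery"],
        ("breast", "early"): ["surgery", "chemo_start"],
        ("colorectal", "early"): ["surgery", "chemo_start"],
        ("lung", "late"): ["chemo_start", "rt_start"],
        ("breast", "late"): ["chemo_start"],
        ("colorectal", "late"): ["chemo_start"],
    }
    return ModelConfig(
        tasks=tasks,
        resources=resources,
        casemix=CaseMixSpec(),
        mechanisms=MechanismParams(),
        treatment_rules=treatment_rules,
    )


def corner_scenarios() -> Dict[str, ScenarioCoordinate]:
    """The four corner scenarios of the 2x2 strategy matrix."""
    return {
        "S_I": ScenarioCoordinate(0.0, 0.0),    # analog oncology
        "S_II": ScenarioCoordinate(1.0, 0.0),   # automation islands
        "S_III": ScenarioCoordinate(0.0, 1.0),  # interconnected clinicians
        "S_IV": ScenarioCoordinate(1.0, 1.0),   # AI-orchestrated care
    }


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

def _probability_scan(m: MechanismParams, n: int = 101) -> List[str]:
    """Check unclamped mechanism probabilities over an n x n unit-square grid."""
    out: List[str] = []
    g = np.linspace(0.0, 1.0, n)
    A, I = np.meshgrid(g, g)
    surfaces = {
        "governance_audit_probability":
            m.gov_base + m.gov_slope * A * (1.0 - I),
        "triage_false_positive_rate":
            (m.fp_base + m.fp_slope * A) * (1.0 - m.fp_interop_relief * I),
        "virtual_mdt_probability": m.vmdt_base + m.vmdt_slope * I,
        "rework_probability":
            m.rework_base * (1.0 - m.rework_interop_relief * I),
    }
    for name, surf in surfaces.items():
        lo, hi = float(surf.min()), float(surf.max())
        if lo < -1e-12 or hi > 1.0 + 1e-12:
            out.append(
                f"mechanisms.{name}: output range [{lo:.4g}, {hi:.4g}] "
                "leaves [0, 1] on the unit square"
            )
    return out


def validate_config(config: ModelConfig) -> List[str]:
    """Return a list of invariant violations (empty iff the config is valid)."""
    v: List[str] = []
    pools = {r.name: r for r in config.resources}

    for r in config.resources:
        if r.capacity < 1:
            v.append(f"resources.{r.name}.capacity: must be >= 1 (got {r.capacity})")
        if r.schedule_class not in SCHEDULE_CLASSES:
            v.append(f"resources.{r.name}.schedule_class: unknown "
                     f"'{r.schedule_class}'")
        if not (0.0 <= r.shift_start_hour < r.shift_end_hour <= 24.0):
            v.append(f"resources.{r.name}: invalid shift window "
                     f"({r.shift_start_hour}, {r.shift_end_hour})")

    for t in config.tasks:
        loc = f"tasks.{t.name}"
        if t.base_duration_hours <= 0:
            v.append(f"{loc}.base_duration_hours: must be > 0")
        if not (0.0 <= t.alpha < 1.0):
            v.append(f"{loc}.alpha: must lie in [0, 1) (got {t.alpha})")
        if not (0.0 <= t.beta < 1.0):
            v.append(f"{loc}.beta: must lie in [0, 1) (got {t.beta})")
        if t.duration_distribution not in DISTRIBUTIONS:
            v.append(f"{loc}.duration_distribution: unknown "
                     f"'{t.duration_distribution}'")
        pool = pools.get(t.resource_pool)
        if pool is None:
            v.append(f"{loc}.resource_pool: unknown pool '{t.resource_pool}'")
        else:
            if t.schedule_class is not None and t.schedule_class != pool.schedule_class:
                v.append(f"{loc}.schedule_class: '{t.schedule_class}' conflicts "
                         f"with pool '{pool.name}' ({pool.schedule_class})")
            if t.atomic:
                # worst case: base duration at (0,0); atomic task must fit a window
                if t.base_duration_hours > pool.pattern().max_window_hours + 1e-12:
                    v.append(f"{loc}: atomic task of {t.base_duration_hours} h "
                             f"exceeds every window of pool '{pool.name}' "
                             "(unschedulable)")

    cm = config.casemix
    if cm.arrival_rate_per_day <= 0:
        v.append("casemix.arrival_rate: must be > 0 "
                 f"(got {cm.arrival_rate_per_day})")
    if abs(sum(cm.tumor_probs.values()) - 1.0) > 1e-9:
        v.append("casemix.tumor_probs: probabilities must sum to 1")
    if set(cm.tumor_probs) != set(TUMOR_TYPES):
        v.append(f"casemix.tumor_probs: keys must be {sorted(TUMOR_TYPES)}")
    for t, sp in cm.stage_probs.items():
        if abs(sum(sp.values()) - 1.0) > 1e-9:
            v.append(f"casemix.stage_probs.{t}: probabilities must sum to 1")
        if set(sp) != set(STAGES):
            v.append(f"casemix.stage_probs.{t}: keys must be {sorted(STAGES)}")

    if not config.warmup_days < config.horizon_days:
        v.append(f"warmup_days ({config.warmup_days}) must be < horizon_days "
                 f"({config.horizon_days})")

    m = config.mechanisms
    for name in ("gov_audit_duration_hours", "demand_reference_wait_days"):
        if getattr(m, name) <= 0:
            v.append(f"mechanisms.{name}: must be > 0")
    if not (0.0 <= m.strain_threshold < 1.0):
        v.append("mechanisms.strain_threshold: must lie in [0, 1)")
    if m.strain_penalty < 0 or m.demand_elasticity < 0:
        v.append("mechanisms: strain_penalty and demand_elasticity must be >= 0")
    if not (0.0 <= m.vmdt_speedup < 1.0):
        v.append("mechanisms.vmdt_speedup: must lie in [0, 1)")
    v.extend(_probability_scan(m))

    task_names = {t.name for t in config.tasks}
    for (tumor, stage), plan in config.treatment_rules.items():
        if tumor not in TUMOR_TYPES or stage not in STAGES:
            v.append(f"treatment_rules: unknown case ({tumor}, {stage})")
        if not plan:
            v.append(f"treatment_rules.{tumor}.{stage}: empty modality list")
        for modality in plan:
            if modality not in task_names:
                v.append(f"treatment_rules.{tumor}.{stage}: unknown task "
                         f"'{modality}'")
    for tumor in TUMOR_TYPES:
        for stage in STAGES:
            if (tumor, stage) not in config.treatment_rules:
                v.append(f"treatment_rules: missing case ({tumor}, {stage})")
    return v


# ---------------------------------------------------------------------------
# file round-trip (YAML, schema 1)
# ---------------------------------------------------------------------------

def _config_to_dict(config: ModelConfig) -> dict:
    return {
        "schema": SCHEMA_VERSION,
        "horizon_days": config.horizon_days,
        "warmup_days": config.warmup_days,
        "resources": [dataclasses.asdict(r) for r in config.resources],
        "tasks": [dataclasses.asdict(t) for t in config.tasks],
        "casemix": dataclasses.asdict(config.casemix),
        "mechanisms": dataclasses.asdict(config.mechanisms),
        "treatment_rules": {
            f"{tumor}.{stage}": list(plan)
            for (tumor, stage), plan in sorted(config.treatment_rules.items())
        },
    }


class ConfigError(ValueError):
    """Raised on schema or invariant violations when loading a config file."""


def _build(cls, data: dict, where: str):
    known = {f.name for f in dataclasses.fields(cls)}
    extra = set(data) - known
    if extra:
        raise ConfigError(f"{where}: unknown field(s) {sorted(extra)}")
    try:
        return cls(**data)
    except TypeError as exc:
        raise ConfigError(f"{where}: {exc}") from None


def save_config(config: ModelConfig, path) -> None:
    """Write ``config`` as a YAML file (schema 1)."""
    Path(path).write_text(
        yaml.safe_dump(_config_to_dict(config), sort_keys=False)
    )


def load_config(path) -> ModelConfig:
    """Load, schema-check, and invariant-check a YAML config file."""
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(p)
    data = yaml.safe_load(p.read_text())
    if not isinstance(data, dict):
        raise ConfigError("config file is not a mapping")
    if data.get("schema") != SCHEMA_VERSION:
        raise ConfigError(f"unsupported schema version {data.get('schema')!r}")
    known_keys = {"schema", "horizon_days", "warmup_days", "resources",
                  "tasks", "casemix", "mechanisms", "treatment_rules"}
    extra = set(data) - known_keys
    if extra:
        raise ConfigError(f"unknown top-level field(s): {sorted(extra)}")
    rules: Dict[Tuple[str, str], List[str]] = {}
    for key, plan in data.get("treatment_rules", {}).items():
        tumor, _, stage = key.partition(".")
        rules[(tumor, stage)] = list(plan)
    config = ModelConfig(
        tasks=[_build(TaskSpec, t, f"tasks[{i}]")
               for i, t in enumerate(data.get("tasks", []))],
        resources=[_build(ResourcePoolSpec, r, f"resources[{i}]")
                   for i, r in enumerate(data.get("resources", []))],
        casemix=_build(CaseMixSpec, data.get("casemix", {}), "casemix"),
        mechanisms=_build(MechanismParams, data.get("mechanisms", {}),
                          "mechanisms"),
        treatment_rules=rules,
        horizon_days=float(data.get("horizon_days", 1095.0)),
        warmup_days=float(data.get("warmup_days", 150.0)),
    )
    violations = validate_config(config)
    if violations:
        raise ConfigError("invalid config:\n  " + "\n  ".join(violations))
    return config
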