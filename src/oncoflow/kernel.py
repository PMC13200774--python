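"""Discrete-event engine for the referral-to-treatment pathway.

A heap-based event calculus (no external DES framework): events are
``(time, sequence, kind)`` tuples, pools are FIFO multi-server queues with
shift calendars, and one replication executes every patient from stochastic
arrival through diagnostic workup to treatment initiation under a fixed
scenario coordinate (A, I).

Determinism contract: the same ``(config, coordinate, seed)`` produces a
bit-identical event log.  All randomness flows through three generators
spawned from the replication seed (arrival process + case mix; service
times + virtual-MDT draws; mechanism Bernoullis), consumed in event order,
and simultaneous events are totally ordered by an insertion sequence
number.

Time is in fractional days (day 0 is a Monday); durations are in hours.
"""

from __future__ import annotations

import heapq
import json
import random
from collections import deque
from dataclasses import dataclass, field
from math import exp, log, sqrt
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np

from .calendar import ShiftPattern, service_end_time, task_start_time
from .config import ModelConfig, ScenarioCoordinate, TaskSpec, validate_config
from .mechanisms import (
    governance_audit_probability,
    induced_demand_multiplier,
    rework_probability,
    strain_multiplier,
    triage_false_positive_rate,
    virtual_mdt_probability,
)

AUDIT_TASK_NAME = "governance_audit"
GOVERNANCE_POOL = "governance_officer"

#: strain / demand rolling-window length (days)
ROLLING_WINDOW_DAYS = 30


# ---------------------------------------------------------------------------
# public helpers (unit operations)
# ---------------------------------------------------------------------------

def effective_duration(task: TaskSpec, coord: ScenarioCoordinate) -> float:
    """Scenario-adjusted mean task duration, in hours.

    ``T = T_base * (1 - alpha * A) * (1 - beta * I)`` — the dynamic task
    acceleration at the heart of the model.  Strictly positive because
    ``alpha, beta < 1``.
    """
    return (task.base_duration_hours
            * (1.0 - task.alpha * coord.A)
            * (1.0 - task.beta * coord.I))


def generate_arrivals(rate: float, horizon: float, rng: np.random.Generator
                      ) -> np.ndarray:
    """Homogeneous Poisson arrival times in ``[0, horizon)`` (days).

    Strictly increasing; expected count ``rate * horizon``.
    """
    if rate <= 0:
        raise ValueError("rate must be positive")
    if horizon <= 0:
        return np.empty(0)
    # draw in blocks of exponential gaps until the horizon is passed
    out: List[np.ndarray] = []
    t = 0.0
    block = max(16, int(rate * horizon * 1.1))
    while t < horizon:
        gaps = rng.exponential(1.0 / rate, size=block)
        times = t + np.cumsum(gaps)
        out.append(times)
        t = times[-1]
        block = max(16, int(rate * (horizon - t) * 1.2))
    times = np.concatenate(out)
    return times[times < horizon]


def sample_service_time(mean: float, distribution: str,
                        rng: np.random.Generator,
                        dispersion: float = 0.25) -> float:
    """One positive service-time draw with expectation ``mean`` (hours)."""
    if mean <= 0:
        raise ValueError("mean must be positive")
    if distribution == "deterministic":
        return mean
    if distribution == "exponential":
        return float(rng.exponential(mean))
    if distribution == "lognormal":
        sigma2 = log(1.0 + dispersion * dispersion)
        mu = log(mean) - 0.5 * sigma2
        return float(exp(mu + sqrt(sigma2) * rng.standard_normal()))
    raise ValueError(f"unknown distribution '{distribution}'")


def treatment_plan(config: ModelConfig, tumor_type: str, stage: str
                   ) -> List[str]:
    """Ordered treatment modalities for a case; first entry stops the RTTI clock."""
    try:
        return list(config.treatment_rules[(tumor_type, stage)])
    except KeyError:
        raise KeyError(f"no treatment rule for ({tumor_type}, {stage})") from None


# ---------------------------------------------------------------------------
# result containers
# ---------------------------------------------------------------------------

@dataclass
class PatientRecord:
    """One simulated patient trajectory."""

    id: int
    tumor_type: str
    stage: str
    arrival_time: float
    is_triage_induced: bool
    #: ordered (task, pool, queue_entry, service_start, service_end), days
    event_log: List[Tuple[str, str, float, float, float]] = field(
        default_factory=list)
    treatment_start_time: Optional[float] = None
    disposition: str = "censored_at_horizon"

    @property
    def rtti(self) -> Optional[float]:
        """Referral-to-treatment interval in days (None if never treated)."""
        if self.treatment_start_time is None:
            return None
        return self.treatment_start_time - self.arrival_time


@dataclass
class RunResult:
    """Full output of one replication."""

    coordinate: ScenarioCoordinate
    seed: int
    patients: List[PatientRecord]
    busy_hours: Dict[str, float]
    #: per-pool, per-day service-hour buckets (index = simulation day)
    busy_day_hours: Dict[str, np.ndarray]
    audit_count: int
    audit_times: np.ndarray
    arrivals_total: int
    horizon_days: float
    warmup_days: float
    pool_info: Dict[str, Tuple[int, ShiftPattern]]


# ---------------------------------------------------------------------------
# internal engine structures
# ---------------------------------------------------------------------------

class _Pool:
    __slots__ = ("name", "capacity", "pattern", "busy", "queue",
                 "strain", "day_hours", "total_hours", "open_cum")

    def __init__(self, name: str, capacity: int, pattern: ShiftPattern,
                 n_days: int):
        self.name = name
        self.capacity = capacity
        self.pattern = pattern
        self.busy = 0
        self.queue: deque = deque()
        self.strain = 1.0
        self.day_hours = np.zeros(n_days + 2)
        self.total_hours = 0.0
        # cumulative scheduled open hours at each day boundary
        self.open_cum = np.array([pattern.open_hours_until(float(d))
                                  for d in range(n_days + 2)])


class _PTask:
    __slots__ = ("name", "pool", "mean", "dist", "sigma", "mu_shift",
                 "dispersion", "atomic", "automated", "is_mdt",
                 "is_pathology", "is_treatment")

    def __init__(self, name, pool, mean, dist, dispersion, atomic, automated,
                 is_mdt, is_pathology, is_treatment):
        self.name = name
        self.pool = pool
        self.mean = mean
        self.dist = dist
        self.dispersion = dispersion
        sigma2 = log(1.0 + dispersion * dispersion)
        self.sigma = sqrt(sigma2)
        self.mu_shift = -0.5 * sigma2
        self.atomic = atomic
        self.automated = automated
        self.is_mdt = is_mdt
        self.is_pathology = is_pathology
        self.is_treatment = is_treatment


class _Patient:
    __slots__ = ("rec", "plan", "pos")

    def __init__(self, rec: PatientRecord, plan: List[_PTask]):
        self.rec = rec
        self.plan = plan
        self.pos = 0


class _Job:
    __slots__ = ("patient", "ptask", "resume_task")

    def __init__(self, patient: _Patient, ptask: _PTask,
                 resume_task: Optional[_PTask] = None):
        self.patient = patient
        self.ptask = ptask
        self.resume_task = resume_task  # original task when ptask is an audit


# event kinds
_EV_CONTROLLER = 0
_EV_ARRIVAL = 1
_EV_END = 2


# ---------------------------------------------------------------------------
# the replication
# ---------------------------------------------------------------------------

def run_replication(config: ModelConfig, coord: ScenarioCoordinate,
                    seed: int) -> RunResult:
    """Execute one full replication of the pathway model.

    Every arrival flows intake -> imaging -> biopsy -> pathology (with
    probabilistic rework) -> molecular -> MDT -> treatment modalities;
    triage-induced benign patients leave after pathology.  Automated task
    completions may trigger blocking governance audits.  Queues are FIFO
    per pool, service non-preemptive, and patients still in flight at the
    horizon are censored.
    """
    violations = validate_config(config)
    if violations:
        raise ValueError("invalid config:\n  " + "\n  ".join(violations))

    m = config.mechanisms
    horizon = float(config.horizon_days)
    n_days = int(np.ceil(horizon))

    ss = np.random.SeedSequence(seed)
    s_arr, s_svc, s_mech = ss.spawn(3)
    g_arr = np.random.Generator(np.random.PCG64(s_arr))
    # scalar event-level draws use the stdlib Mersenne generator (much
    # cheaper per call than a Generator method); streams stay independent
    g_svc = random.Random(int(s_svc.generate_state(1)[0]))
    g_mech = random.Random(int(s_mech.generate_state(1)[0]))

    # --- static, per-replication precomputation --------------------------
    pools: Dict[str, _Pool] = {
        r.name: _Pool(r.name, r.capacity, r.pattern(), n_days)
        for r in config.resources
    }
    p_gov = governance_audit_probability(coord, m) if m.enable_governance else 0.0
    p_fp = (min(1.0, triage_false_positive_rate(coord, m) * m.induction_scale)
            if m.enable_triage_fp else 0.0)
    p_vmdt = virtual_mdt_probability(coord, m) if m.enable_vmdt else 0.0
    p_rework = rework_probability(coord, m) if m.enable_rework else 0.0
    vmdt_factor = 1.0 - m.vmdt_speedup

    treatment_names = {t for plan in config.treatment_rules.values()
                       for t in plan}
    dist_code = {"deterministic": 0, "exponential": 1, "lognormal": 2}

    ptasks: Dict[str, _PTask] = {}
    for t in config.tasks:
        ptasks[t.name] = _PTask(
            name=t.name,
            pool=pools[t.resource_pool],
            mean=effective_duration(t, coord),
            dist=dist_code[t.duration_distribution],
            dispersion=t.dispersion,
            atomic=t.atomic,
            automated=t.alpha >= m.automated_alpha_threshold,
            is_mdt=t.name == "mdt",
            is_pathology=t.name == "pathology",
            is_treatment=t.name in treatment_names,
        )
    diagnostic_prefix = [ptasks[t.name] for t in config.tasks
                         if t.name not in treatment_names]
    benign_prefix: List[_PTask] = []
    for pt in diagnostic_prefix:
        benign_prefix.append(pt)
        if pt.is_pathology:
            break

    audit_task = None
    if m.enable_governance and GOVERNANCE_POOL in pools:
        audit_task = _PTask(
            name=AUDIT_TASK_NAME, pool=pools[GOVERNANCE_POOL],
            mean=m.gov_audit_duration_hours, dist=0, dispersion=0.25,
            atomic=True, automated=False, is_mdt=False, is_pathology=False,
            is_treatment=False,
        )

    tumor_names = list(config.casemix.tumor_probs)
    tumor_cdf = np.cumsum([config.casemix.tumor_probs[t] for t in tumor_names])
    p_late = {t: config.casemix.stage_probs[t]["late"] for t in tumor_names}
    plans_by_case = {
        (t, s): [ptasks[name] for name in config.treatment_rules[(t, s)]]
        for t in tumor_names for s in ("early", "late")
    }
    base_rate = config.casemix.arrival_rate_per_day

    patients: List[PatientRecord] = []
    audit_times: List[float] = []
    audit_count = 0
    # demand mechanism state: the advertised wait is the lag-free Little's
    # law estimate census / treatment rate (pre-treatment patients in the
    # system over the recent rate of first-treatment starts)
    census = 0
    treated_per_day = np.zeros(n_days + 2)

    events: List[tuple] = []
    seq = 0

    def push(t, kind, obj):
        nonlocal seq
        heapq.heappush(events, (t, seq, kind, obj))
        seq += 1

    # --- service machinery ----------------------------------------------

    def start_service(pool: _Pool, job: _Job, queue_entry: float, now: float):
        ptask = job.ptask
        mean = ptask.mean * pool.strain
        if ptask.is_mdt and p_vmdt > 0.0 and g_svc.random() < p_vmdt:
            mean *= vmdt_factor
        d = ptask.dist
        if d == 0:
            svc = mean
        elif d == 1:
            svc = g_svc.expovariate(1.0 / mean)
        else:
            svc = exp(log(mean) + ptask.mu_shift
                      + ptask.sigma * g_svc.gauss(0.0, 1.0))
        if ptask.atomic:
            # an atomic task can never outgrow its shift window: cap the
            # draw at the longest window (rare upper-tail truncation)
            svc = min(svc, pool.pattern.max_window_hours)
        start = task_start_time(now, svc, pool.pattern, ptask.atomic)
        end = service_end_time(start, svc, pool.pattern, ptask.atomic)
        pool.busy += 1
        patient = job.patient
        if patient is not None:
            rec = patient.rec
            rec.event_log.append((ptask.name, pool.name, queue_entry, start, end))
            if ptask.is_treatment and rec.treatment_start_time is None:
                rec.treatment_start_time = start
                nonlocal census
                census -= 1
                if start < horizon:
                    treated_per_day[int(start)] += 1
        # attribute service hours to day buckets, clipped at the horizon
        if end > start:
            counted = svc * (min(end, horizon) - start) / (end - start)
        else:
            counted = svc
        if start < horizon:
            pool.day_hours[int(start)] += counted
            pool.total_hours += counted
        push(end, _EV_END, (pool, job))

    def request(pool: _Pool, job: _Job, now: float):
        if pool.busy < pool.capacity:
            start_service(pool, job, now, now)
        else:
            pool.queue.append((job, now))

    def finish(patient: _Patient):
        nonlocal census
        rec = patient.rec
        if rec.is_triage_induced:
            rec.disposition = "benign_exit"
            census -= 1
        elif rec.treatment_start_time is not None:
            rec.disposition = "treated"

    def continue_after_task(patient: _Patient, ptask: _PTask, now: float):
        if ptask.is_pathology and p_rework > 0.0 and g_mech.random() < p_rework:
            request(ptask.pool, _Job(patient, ptask), now)
            return
        patient.pos += 1
        if patient.pos < len(patient.plan):
            nxt = patient.plan[patient.pos]
            request(nxt.pool, _Job(patient, nxt), now)
        else:
            finish(patient)

    # --- event handlers --------------------------------------------------

    def handle_end(now: float, pool: _Pool, job: _Job):
        nonlocal audit_count
        pool.busy -= 1
        if pool.queue:
            nxt_job, entered = pool.queue.popleft()
            start_service(pool, nxt_job, entered, now)
        ptask = job.ptask
        if job.resume_task is not None:  # an audit just completed
            audit_count += 1
            audit_times.append(now)
            continue_after_task(job.patient, job.resume_task, now)
            return
        if (ptask.automated and p_gov > 0.0 and audit_task is not None
                and g_mech.random() < p_gov):
            request(audit_task.pool,
                    _Job(job.patient, audit_task, resume_task=ptask), now)
            return
        continue_after_task(job.patient, ptask, now)

    def handle_arrival(now: float, patient: _Patient):
        first = patient.plan[0]
        request(first.pool, _Job(patient, first), now)

    def handle_controller(day: int):
        nonlocal census
        # throughput strain: rolling utilization inflates service times
        if m.enable_strain and day > 0:
            lo = max(0, day - ROLLING_WINDOW_DAYS)
            for pool in pools.values():
                open_h = pool.open_cum[day] - pool.open_cum[lo]
                if open_h <= 0:
                    continue
                util = min(1.0, pool.day_hours[lo:day].sum()
                           / (pool.capacity * open_h))
                pool.strain = strain_multiplier(util, m)
        # wait-elastic demand: today's rate responds to the advertised wait
        # (held neutral during burn-in, while no full reporting cycle of
        # waiting-time statistics exists yet)
        rate = base_rate
        if m.enable_induced_demand and day >= config.warmup_days:
            lo = max(0, day - ROLLING_WINDOW_DAYS)
            recent = float(treated_per_day[lo:day].sum())
            if recent > 0:
                advertised = census / (recent / max(1, day - lo))
            else:
                advertised = m.demand_reference_wait_days  # no signal yet
            rate *= induced_demand_multiplier(advertised, m)
        # today's arrivals: piecewise-constant-rate Poisson, daily blocks
        n = g_arr.poisson(rate)
        if n:
            times = np.sort(day + g_arr.random(n))
            tumors_u = g_arr.random(n)
            stage_u = g_arr.random(n)
            benign_u = g_arr.random(n)
            for i in range(n):
                tumor = tumor_names[int(np.searchsorted(tumor_cdf, tumors_u[i]))]
                stage = "late" if stage_u[i] < p_late[tumor] else "early"
                benign = benign_u[i] < p_fp
                rec = PatientRecord(
                    id=len(patients), tumor_type=tumor, stage=stage,
                    arrival_time=float(times[i]), is_triage_induced=benign,
                )
                patients.append(rec)
                census += 1
                plan = (benign_prefix if benign
                        else diagnostic_prefix + plans_by_case[(tumor, stage)])
                push(float(times[i]), _EV_ARRIVAL, _Patient(rec, plan))

    # --- main loop --------------------------------------------------------

    for day in range(n_days):
        push(float(day), _EV_CONTROLLER, day)

    while events:
        t, _, kind, obj = heapq.heappop(events)
        if t >= horizon:
            break
        if kind == _EV_END:
            handle_end(t, obj[0], obj[1])
        elif kind == _EV_ARRIVAL:
            handle_arrival(t, obj)
        else:
            handle_controller(obj)

    for rec in patients:
        if rec.disposition == "censored_at_horizon":
            if rec.treatment_start_time is not None:
                rec.disposition = "treated"

    return RunResult(
        coordinate=coord,
        seed=seed,
        patients=patients,
        busy_hours={name: p.total_hours for name, p in pools.items()},
        busy_day_hours={name: p.day_hours for name, p in pools.items()},
        audit_count=audit_count,
        audit_times=np.asarray(audit_times),
        arrivals_total=len(patients),
        horizon_days=horizon,
        warmup_days=float(config.warmup_days),
        pool_info={name: (p.capacity, p.pattern) for name, p in pools.items()},
    )


# ---------------------------------------------------------------------------
# export
# ---------------------------------------------------------------------------

def export_event_log(run: RunResult, path) -> None:
    """Write the full event log as CSV (one row per service episode)."""
    lines = ["patient_id,task,pool,queue_entry,service_start,service_end"]
    for rec in run.patients:
        for task, pool, tq, ts, te in rec.event_log:
            lines.append(f"{rec.id},{task},{pool},{tq:.6f},{ts:.6f},{te:.6f}")
    Path(path).write_text("\n".join(lines) + "\n")


def run_summary(run: RunResult) -> dict:
    """JSON-serializable replication summary."""
    dispositions: Dict[str, int] = {}
    for rec in run.patients:
        dispositions[rec.disposition] = dispositions.get(rec.disposition, 0) + 1
    return {
        "coordinate": {"A": run.coordinate.A, "I": run.coordinate.I},
        "seed": run.seed,
        "arrivals_total": run.arrivals_total,
        "audit_count": run.audit_count,
        "dispositions": dispositions,
        "horizon_days": run.horizon_days,
        "warmup_days": run.warmup_days,
    }


def save_run_summary(run: RunResult, path) -> None:
    Path(path).write_text(json.dumps(run_summary(run), indent=2) + "\n")
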