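"""Discrete-event engine: unit operations, invariants, queueing behavior."""

import numpy as np
import pytest

from oncoflow import (
    ScenarioCoordinate,
    effective_duration,
    generate_arrivals,
    run_replication,
    sample_service_time,
    treatment_plan,
)
from oncoflow.config import TaskSpec
from oncoflow.kernel import export_event_log


def task(base, alpha, beta):
    return TaskSpec("t", base, alpha, beta, "pool")


class TestEffectiveDuration:
    @pytest.mark.parametrize("base,alpha,beta,A,I,expected", [
        (2.0, 0.5, 0.2, 0.0, 0.0, 2.0),       # origin: no relief
        (2.0, 0.5, 0.2, 1.0, 1.0, 0.8),       # 2 * 0.5 * 0.8
        (7.3, 0.0, 0.0, 0.6, 0.9, 7.3),       # insensitive task
        (10.0, 0.3, 0.0, 0.5, 1.0, 8.5),
    ])
    def test_formula(self, base, alpha, beta, A, I, expected):
        assert effective_duration(
            task(base, alpha, beta), ScenarioCoordinate(A, I)
        ) == pytest.approx(expected)

    def test_strictly_positive_and_monotone(self):
        t = task(4.0, 0.9, 0.9)
        prev = np.inf
        for x in np.linspace(0, 1, 11):
            d = effective_duration(t, ScenarioCoordinate(x, x))
            assert 0 < d <= prev
            prev = d


class TestSampleServiceTime:
    def test_deterministic_returns_mean(self):
        rng = np.random.default_rng(0)
        assert sample_service_time(1.5, "deterministic", rng) == 1.5

    def test_lognormal_mean(self):
        rng = np.random.default_rng(1)
        draws = [sample_service_time(2.0, "lognormal", rng)
                 for _ in range(100_000)]
        assert np.mean(draws) == pytest.approx(2.0, rel=0.01)

    def test_exponential_variance(self):
        rng = np.random.default_rng(2)
        draws = [sample_service_time(1.0, "exponential", rng)
                 for _ in range(100_000)]
        assert np.var(draws) == pytest.approx(1.0, rel=0.05)

    def test_unknown_distribution(self):
        with pytest.raises(ValueError):
            sample_service_time(1.0, "weibull", np.random.default_rng(0))


class TestGenerateArrivals:
    def test_poisson_mean_count(self):
        # expected count = 3.2 * 1095 = 3504; 200 seeds, SE = sqrt(3504/200)
        counts = [len(generate_arrivals(3.2, 1095.0,
                                        np.random.default_rng(s)))
                  for s in range(200)]
        se = np.sqrt(3504 / 200)
        assert abs(np.mean(counts) - 3504) < 3 * se

    def test_zero_horizon_is_empty(self):
        assert len(generate_arrivals(3.2, 0.0, np.random.default_rng(0))) == 0

    def test_strictly_increasing_and_deterministic(self):
        a = generate_arrivals(5.0, 50.0, np.random.default_rng(42))
        b = generate_arrivals(5.0, 50.0, np.random.default_rng(42))
        assert np.array_equal(a, b)
        assert np.all(np.diff(a) > 0)
        assert a[-1] < 50.0


class TestTreatmentPlan:
    @pytest.mark.parametrize("tumor,stage,expected", [
        ("breast", "early", ["surgery", "chemo_start"]),
        ("lung", "late", ["chemo_start", "rt_start"]),
        ("lung", "early", ["surgery"]),
    ])
    def test_rules(self, config, tumor, stage, expected):
        assert treatment_plan(config, tumor, stage) == expected

    def test_unknown_case(self, config):
        with pytest.raises(KeyError):
            treatment_plan(config, "melanoma", "early")

    def test_plans_non_empty(self, config):
        for (tumor, stage) in config.treatment_rules:
            assert len(treatment_plan(config, tumor, stage)) >= 1


@pytest.fixture(scope="module")
def fast_run():
    from oncoflow import default_config
    cfg = default_config()
    cfg.horizon_days = 260.0
    cfg.warmup_days = 60.0
    return cfg, run_replication(cfg, ScenarioCoordinate(0.3, 0.4), seed=11)


class TestRunInvariants:
    def test_conservation_of_patients(self, fast_run):
        _, run = fast_run
        counts = {"treated": 0, "benign_exit": 0, "censored_at_horizon": 0}
        for rec in run.patients:
            counts[rec.disposition] += 1
        assert sum(counts.values()) == run.arrivals_total == len(run.patients)
        assert counts["treated"] > 0 and counts["benign_exit"] > 0

    def test_causality_within_each_trajectory(self, fast_run):
        _, run = fast_run
        for rec in run.patients:
            prev_end = rec.arrival_time
            for _task, _pool, tq, ts, te in rec.event_log:
                assert tq >= prev_end - 1e-9
                assert tq <= ts + 1e-9 <= te + 2e-9
                prev_end = te

    def test_capacity_never_exceeded(self, fast_run):
        cfg, run = fast_run
        intervals = {}
        for rec in run.patients:
            for _task, pool, _tq, ts, te in rec.event_log:
                # round away sub-nanosecond float noise from the
                # hours-of-week round trip before the boundary sort
                intervals.setdefault(pool, []).append((round(ts, 9), 1))
                intervals.setdefault(pool, []).append((round(te, 9), -1))
        for pool, events in intervals.items():
            cap = run.pool_info[pool][0]
            level = 0
            # ends sort before starts at equal times
            for _, step in sorted(events, key=lambda e: (e[0], e[1])):
                level += step
                assert level <= cap

    def test_rtti_consistency(self, fast_run):
        _, run = fast_run
        for rec in run.patients:
            if rec.disposition == "treated":
                assert rec.rtti == pytest.approx(
                    rec.treatment_start_time - rec.arrival_time)
            if rec.disposition == "benign_exit":
                assert rec.treatment_start_time is None
                assert rec.rtti is None

    def test_benign_exit_stops_after_pathology(self, fast_run):
        _, run = fast_run
        for rec in run.patients:
            if rec.disposition == "benign_exit":
                tasks = [t for t, *_ in rec.event_log
                         if t != "governance_audit"]
                assert "molecular" not in tasks
                assert tasks[-1] == "pathology"

    def test_busy_hours_bounded_by_capacity(self, fast_run):
        _, run = fast_run
        for pool, (cap, pattern) in run.pool_info.items():
            limit = cap * pattern.available_hours(0.0, run.horizon_days)
            assert run.busy_hours[pool] <= limit + 1e-6


class TestDeterminism:
    def test_same_seed_bit_identical_event_log(self, fast_config, tmp_path):
        coord = ScenarioCoordinate(0.7, 0.2)
        p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
        export_event_log(run_replication(fast_config, coord, 99), p1)
        export_event_log(run_replication(fast_config, coord, 99), p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_different_seed_differs(self, fast_config):
        coord = ScenarioCoordinate(0.7, 0.2)
        r1 = run_replication(fast_config, coord, 1)
        r2 = run_replication(fast_config, coord, 2)
        assert r1.arrivals_total != r2.arrivals_total or \
            r1.patients[0].event_log != r2.patients[0].event_log


class TestQueueDiscipline:
    def test_fifo_back_to_back_service_on_saturated_server(self):
        """On a busy capacity-1 continuous pool, a queued patient starts
        service exactly when the previous service ends."""
        from oncoflow.config import (CaseMixSpec, MechanismParams,
                                     ModelConfig, ResourcePoolSpec, TaskSpec)
        cfg = ModelConfig(
            tasks=[TaskSpec("service", 1.0, 0.0, 0.0, "server", atomic=False,
                            duration_distribution="deterministic")],
            resources=[ResourcePoolSpec("server", 1, "continuous")],
            casemix=CaseMixSpec(arrival_rate_per_day=30.0),
            mechanisms=MechanismParams(
                enable_governance=False, enable_triage_fp=False,
                enable_vmdt=False, enable_rework=False,
                enable_induced_demand=False, enable_strain=False),
            treatment_rules={(t, s): ["service"]
                             for t in ("lung", "breast", "colorectal")
                             for s in ("early", "late")},
            horizon_days=30.0, warmup_days=1.0,
        )
        run = run_replication(cfg, ScenarioCoordinate(0.0, 0.0), 5)
        episodes = sorted(
            ((tq, ts, te) for rec in run.patients
             for _t, _p, tq, ts, te in rec.event_log),
            key=lambda e: e[1])
        queued_pairs = 0
        for (_, _, prev_end), (tq, ts, _) in zip(episodes, episodes[1:]):
            if tq < prev_end - 1e-12:  # successor queued while server busy
                assert ts == pytest.approx(prev_end)
                queued_pairs += 1
        assert queued_pairs > 100


class TestDownstreamAcceleration:
    def test_chemo_interarrivals_shrink_at_full_integration(self, fast_config):
        """Faster upstream stages compress arrivals at the chemotherapy
        queue (emergent downstream-acceleration mechanism)."""
        def mean_gap(coord):
            run = run_replication(fast_config, coord, 21)
            times = sorted(tq for rec in run.patients
                           for t, _p, tq, _s, _e in rec.event_log
                           if t == "chemo_start")
            return float(np.mean(np.diff(times)))

        assert mean_gap(ScenarioCoordinate(1.0, 1.0)) < \
            mean_gap(ScenarioCoordinate(0.0, 0.0))
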