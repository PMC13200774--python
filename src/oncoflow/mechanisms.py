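"""The coupled operational mechanisms linking (A, I) to queue behavior.

Beyond the task-acceleration formula applied inside the kernel, six
parametric responses are defined here as pure functions of the scenario
coordinate and the mechanism coefficients.  All probability outputs are
clamped to [0, 1]; config validation additionally scans the unit square to
reject coefficient sets whose *unclamped* values leave that range.

The full mechanism census (eight, each with one implementation site):

1. dynamic task acceleration  — ``kernel.effective_duration``
2. governance audits          — ``governance_audit_probability`` (blocking
   manual-verification step after automated task completions)
3. triage false positives     — ``triage_false_positive_rate`` (benign
   AI-triggered workups displacing confirmed cases in the referral stream)
4. virtual MDT adoption       — ``virtual_mdt_probability``
5. downstream arrival acceleration — emergent: faster upstream stages
   compress inter-arrival times at the treatment queues (no parameter)
6. pathology rework           — ``rework_probability``
7. wait-elastic demand        — ``induced_demand_multiplier``
8. throughput strain          — ``strain_multiplier``

The functional forms are linear-with-clamp reconstructions: audits scale
with A·(1−I), false positives with A (relieved by I), virtual MDT adoption
with I, rework is relieved by I.
"""

from __future__ import annotations


def _clamp01(x: float) -> float:
    return 0.0 if x < 0.0 else (1.0 if x > 1.0 else x)


def governance_audit_probability(coord, params) -> float:
    """Probability that an automated task completion triggers a manual audit.

    ``p = gov_base + gov_slope * A * (1 - I)``, clamped to [0, 1].  High
    automation without interoperability maximizes verification load; full
    interoperability relieves the automation term entirely.  Each triggered
    audit is a blocking job on the governance pool with duration
    ``gov_audit_duration_hours``.
    """
    return _clamp01(params.gov_base + params.gov_slope * coord.A * (1.0 - coord.I))


def triage_false_positive_rate(coord, params) -> float:
    """Benign fraction among AI-triage-triggered workups.

    ``fp = (fp_base + fp_slope * A) * (1 - fp_interop_relief * I)``, clamped.
    Sensitivity-driven false positives grow with automation intensity;
    access to longitudinal records (interoperability) lets the triage model
    rule out benign presentations without a tissue workup, relieving the
    rate.  With ``fp_interop_relief = 0`` this reduces to the plain
    ``fp_base + fp_slope * A`` form.
    """
    raw = params.fp_base + params.fp_slope * coord.A
    return _clamp01(raw * (1.0 - params.fp_interop_relief * coord.I))


def virtual_mdt_probability(coord, params) -> float:
    """Probability that an MDT review is held virtually.

    ``v = vmdt_base + vmdt_slope * I``, clamped.  A virtual MDT multiplies
    the MDT task's effective duration by ``(1 - vmdt_speedup)``.
    """
    return _clamp01(params.vmdt_base + params.vmdt_slope * coord.I)


def rework_probability(coord, params) -> float:
    """Probability that a pathology result must be reworked.

    ``r = rework_base * (1 - rework_interop_relief * I)``, clamped: data
    stewardship minimizes duplication and lost-specimen loops.
    """
    return _clamp01(
        params.rework_base * (1.0 - params.rework_interop_relief * coord.I)
    )


def induced_demand_multiplier(recent_mean_wait: float, params) -> float:
    """Arrival-rate multiplier from wait-elastic demand.

    ``m = 1 + demand_elasticity * max(0, 1 - wait / demand_reference_wait)``.
    Short recent waits (rolling 30-day window of realized
    referral-to-treatment intervals) attract additional referrals; the
    multiplier never falls below 1, so long waits do not suppress baseline
    demand.
    """
    if recent_mean_wait < 0:
        raise ValueError("recent_mean_wait must be non-negative")
    relief = 1.0 - recent_mean_wait / params.demand_reference_wait_days
    return 1.0 + params.demand_elasticity * max(0.0, relief)


def strain_multiplier(utilization: float, params) -> float:
    """Service-duration multiplier under high rolling utilization.

    ``s = 1 + strain_penalty * max(0, u - threshold) / (1 - threshold)``:
    above the strain threshold, congestion overhead (coordination, errors,
    fatigue) inflates service times, reaching ``1 + strain_penalty`` at
    full utilization.  Continuous and non-decreasing in ``u``.
    """
    if not 0.0 <= utilization <= 1.0 + 1e-9:
        raise ValueError("utilization must lie in [0, 1]")
    t = params.strain_threshold
    excess = max(0.0, min(utilization, 1.0) - t)
    return 1.0 + params.strain_penalty * excess / (1.0 - t)
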