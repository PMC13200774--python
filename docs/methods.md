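# Methods

## Model overview

`oncoflow` simulates individual patient trajectories through a
resource-constrained cancer center as a discrete-event system: a heap of
timestamped events (arrivals, service completions, a daily controller
tick), FIFO multi-server pools with shift calendars, and non-preemptive
service. Two exogenous, static levers govern all dynamic behavior: AI
automation intensity `A` and data interoperability `I`, both normalized
to [0, 1]. Adoption is a *state*, not a process — a simulation answers
"how does this operating point behave at steady state", and transition
dynamics are reconstructed afterwards by path analysis over the grid of
operating points.

Simulation time is measured in fractional days; day 0 is fixed to a
Monday so a weekly pattern is fully determined by the time-of-week and
replications differ only by seed. Durations are in hours.

## Pathway and calendar

Every patient passes intake → imaging → biopsy → pathology → molecular →
MDT, then the treatment modalities given by the case's rule
(early-stage: surgery, plus adjuvant chemotherapy for breast/colorectal;
late-stage: chemotherapy, plus radiotherapy for lung). The RTTI clock
stops at the *start* of the first treatment task; later modalities still
consume capacity.

The calendar distinguishes three schedule types: standard clinical
shifts (08:00–17:00 Mon–Fri), session-based pools (the tumor board meets
Mondays; the governance review board sits Fridays), and continuous
operation (molecular laboratory). Atomic tasks (imaging, biopsy, MDT
review, surgery, radiotherapy start, audits) must fit inside a single
open window and are deferred — with their assigned server held — until
the next window that can hold them; a stochastic draw that exceeds the
longest window is truncated to it (rare upper-tail event). Non-atomic
tasks (intake processing, pathology turnaround, molecular assay,
chemotherapy infusion start) begin at the next open instant and accrue
service only while the calendar is open, holding their server through
pauses. Making the multi-hour processing stages non-atomic is a
deliberate design choice: a 20-hour turnaround modeled as one atomic
block would waste most of each server-day to deferral and turn nominal
80% loads into unstable queues.

Base durations are end-to-end processing times, not hands-on minutes —
e.g. 64 h of referral handling across a 40-person office, a 31.5 h
pathology turnaround across 21 bench positions, a 113 h molecular assay
across 16 positions. This spreads the baseline referral-to-treatment
interval over many moderately utilized stages (intake backlog ≈ 8 d, CT
queue ≈ 3 d, pathology ≈ 4 d, molecular ≈ 4.7 d, weekly tumor board
≈ 3 d), which is what makes the baseline mean reproducible across
replications: a single near-critical queue producing a 29-day wait has a
relaxation time of months and drifts by many days between replications.

## Mechanisms

Eight coupled mechanisms connect (A, I) to queue behavior; each is
individually switchable and all coefficients live in the `mechanisms`
config block.

1. **Task acceleration** — `T = T_base (1 − αA)(1 − βI)`, applied to
   every task's mean duration.
2. **Governance audits** — each completion of an automated task (α ≥ 0.1)
   triggers, with probability `gov_base + gov_slope·A(1−I)` (defaults
   0.02, 0.88), a *blocking* manual verification: the patient cannot
   proceed until a 0.25 h review completes on the Friday governance
   board (4 officers). Blocking is the reading that makes automation
   without interoperability degrade system performance — a
   fire-and-forget audit stream would load the officers without delaying
   anyone. The weekly batch structure makes the audit wait
   (≈ 3.5 d per audit, ~5 audits per patient at (1, 0)) essentially
   deterministic, which is why the automation-islands scenario has a
   large mean delay but a small cross-replication SD.
3. **Triage false positives** — each admitted workup is benign with
   probability `(fp_base + fp_slope·A)(1 − relief·I)` (defaults 0.10,
   0.33, 0.65). Benign patients consume intake/imaging/biopsy/pathology
   capacity and exit after pathology, *displacing* confirmed cases
   within the referral stream: sensitive AI triage admits low-yield
   investigations at the expense of true cases, and interoperable
   records let the triage model rule out benign presentations without a
   tissue workup. Displacement, rather than a purely additive benign
   stream, is what lets throughput collapse at (1, 0) while the RTTI of
   treated patients stays finite.
4. **Virtual MDT** — a review is virtual with probability
   `vmdt_base + vmdt_slope·I`; virtual reviews take `(1 − vmdt_speedup)`
   of the in-person duration.
5. **Downstream arrival acceleration** — emergent, no parameter: faster
   upstream stages compress inter-arrival times at the treatment queues
   (asserted as a test property, not coded anywhere).
6. **Pathology rework** — after each pathology completion the task
   repeats with probability `rework_base(1 − relief·I)` (defaults 0.12,
   0.5); repeats are unbounded but geometric.
7. **Wait-elastic demand** — the daily arrival rate is
   `base_rate · (1 + e·max(0, 1 − w/ref))` with elasticity e = 0.55 and
   reference wait ref = 28.9 d. The advertised wait `w` is a lag-free
   Little's-law estimate: pre-treatment census divided by the trailing
   30-day rate of first-treatment starts. An estimator built on the
   realized RTTIs of recently treated patients lags the system state by
   one full pathway transit and produced start-up overshoot and slow
   limit cycles in development; the census-based estimate removes the
   lag and gives the feedback loop a stable fixed point. The mechanism
   is held neutral during the 150-day burn-in, when no full reporting
   cycle of waiting statistics exists yet.
8. **Throughput strain** — when a pool's rolling 30-day utilization
   exceeds 0.90, its service times inflate by up to 8% at full
   utilization (congestion overhead: coordination, errors, fatigue).

Mechanisms 3 and 7 jointly pin the high-interoperability corners: at
(0, 1) the molecular laboratory's capacity caps the treated flow and the
demand feedback settles at the wait where offered demand equals that
cap; at (1, 1) the same logic applies with chemotherapy chairs as the
cap. The corner RTTIs are therefore equilibrium properties of the
feedback, not tuned queue waits.

## Randomness and determinism

Each replication seeds a `numpy` `SeedSequence`, spawned into three
independent streams: (1) arrival counts, arrival times and case-mix
draws (numpy PCG64, batched per day — arrivals are generated as a
piecewise-constant-rate Poisson process in daily blocks, exact for the
daily-updated rate); (2) service times and virtual-MDT draws; (3)
mechanism Bernoullis (audit, rework). Streams 2 and 3 use the stdlib
Mersenne Twister for cheap scalar draws. Draws are consumed in event
order; simultaneous events are totally ordered by an insertion sequence
number, so the same (config, coordinate, seed) yields a byte-identical
event log. Service distributions: lognormal with CV 0.25 for clinical
tasks (positive, right-skewed, as procedure times are), exponential for
intake handling.

## Measurement

All outcomes are measured on [warm-up, horizon) = [150 d, 1095 d).
RTTI eligibility is by arrival time and disposition `treated`;
throughput counts first-treatment starts in the window, annualized by
365/945; governance density is audits completed per arrival;
utilization is service hours over scheduled capacity hours (service
hours are binned by start day; a job's hours are clipped at the horizon
pro rata). Patients still in flight at the horizon are censored and
excluded from RTTI and throughput. The bottleneck is the arg-max
utilization pool, ties broken alphabetically. Aggregation across
replications uses the sample SD (n − 1). The combined volatility
surface is the mean of the min–max-normalized RTTI-SD and
throughput-SD surfaces over the grid; a constant surface normalizes to
zeros.

## Transition optimization

The sweep grid becomes a DAG whose edges are single-step monotone moves
in one lever. Node cost is `0.25·n(RTTI) + 0.25·n(RTTI SD) +
0.25·n(1/throughput) + 0.25·n(throughput SD)` with min–max
normalization over the 121 cells; "inverse throughput" is read as the
reciprocal (the alternative, `1 − n(throughput)`, is a config switch).
Edge weight is the cost of the state being entered, so a path's total is
its cumulative operational friction excluding the unavoidable origin;
the mean-of-endpoints alternative is likewise a switch. Zero-throughput
cells (which do not occur on the calibrated model) would be flagged and
priced at the grid maximum. Dijkstra via networkx gives the optimum;
ties are resolved to the lexicographically smallest node sequence by an
explicit dynamic program over the lattice (processed in anti-diagonal
order), and the DP total is cross-checked against the networkx path
length at runtime. For resolutions ≤ 6 the result is verified in tests
against exhaustive enumeration of all monotone paths.

## Calibration

The default parameterization is stylized, assembled from standard
oncology operating figures and then calibrated so the four corner
scenarios reproduce the reference operational signatures: baseline
(0,0) ≈ 29.4 d RTTI / ≈ 1022 patients·yr⁻¹, CT-scanner-bound;
automation islands (1,0) ≈ 37.1 d / ≈ 647, governance-bound;
interconnected clinicians (0,1) ≈ 27.3 d / ≈ 1127, molecular-bound;
AI-orchestrated care (1,1) ≈ 14.9 d / ≈ 1244, chemotherapy-bound. The
procedure: fix the baseline first (arrival rate, CT load, stage
turnaround times), then set the false-positive slope from the (1,0)
throughput deficit, the governance coefficients from the (1,0) RTTI
excess, and solve elasticity and reference wait jointly from the (0,1)
and (1,1) equilibria described above. The calibrated values are the
package defaults; they are illustrative of a *generic* high-volume
center, not any institution.

## What the synthetic model does and does not capture

The generator emulates: Poisson referral arrivals with a realistic
three-tumor case mix, capacity-constrained diagnostic and treatment
stages with shift calendars and session-based services, governance
friction, benign-workup displacement, demand elasticity, and congestion
strain. It does not capture: patient acuity classes or prioritization,
abandonment/reneging, holidays and staffing variation, clinician
behavior (trust, oversight burden), financial cost, clinical outcomes,
or equity strata. Passing tests therefore demonstrate internal
mechanistic consistency and reproducibility of the stylized system —
directional, structural conclusions — not calibrated forecasts for any
real pathway.

## Numerical choices and edge cases

- Atomic service draws are truncated at the longest open window.
- Queue ties and simultaneous events: FIFO per pool; global event order
  by (time, insertion sequence) — deterministic total order.
- Config validation scans mechanism probabilities on a 101 × 101 grid of
  the unit square using the *unclamped* linear forms and rejects
  coefficient sets that leave [0, 1].
- Zero eligible RTTI patients yield `mean_rtti = None` (flagged), never
  an exception mid-sweep; aggregation requires ≥ 2 replications.
- Sweep seeds are `base_seed·10⁶ + coordinate_index·100 + rep_index` —
  collision-free below 2³¹ for base seeds up to ~2000, and the rep
  component is coordinate-independent to support common-random-number
  comparisons.
- Floating-point round-trips through the hours-of-week calendar carry
  sub-nanosecond noise; consumers comparing boundary times should round
  to ~1e-9 days.

## Problem sizes

The shipped experiment sizes are those of the study design: 1095-day
horizon, 150-day warm-up, 11 × 11 grid × 10 replications (1210 runs,
roughly 4–5 minutes on one CPU), 10 replications per corner for the
scenario table, and ≥ 10⁵ arrivals for the M/M/2 Erlang-C validation of
the kernel (observed agreement within ~2.5%, tolerance 5%). Unit and
property tests use a 260-day horizon to keep the suite fast.

## Known limitations

- The corner signatures at (0,1) are equilibria of a near-critical
  queue under feedback; their 10-replication means carry a sampling SE
  of ~0.5 d, so individual experiment seeds can land ~1 d from the
  long-run center even though the center itself is calibrated.
- The strain and demand mechanisms update on a daily controller tick;
  sub-day rate modulation is not modeled.
- Non-atomic tasks hold their server through closed periods; releasing
  and re-queuing overnight would model some services better but breaks
  FIFO fairness and was not adopted.
- The optimizer treats the grid aggregates as exact; it does not
  propagate replication uncertainty into the path choice beyond the SD
  cost components.
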