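# Methods

## Queueing model

Demand for tele-emergency physician (TEP) consultations is modeled as a
homogeneous Poisson process with rate λ (configured per day) and i.i.d.
service durations with mean E[S] minutes, served by k interchangeable
physicians in FIFO order with an unbounded waiting room — an M/M/k
queue under the default exponential service family, M/G/k otherwise.
Homogeneity is an assumption: the calibration data report only an
average daily rate, with no information about hour-of-day or seasonal
structure, so no time-varying rate is modeled (the simulator, not the
analytic module, would be the place to add one).

All analytic measures derive from the Erlang B recursion
B(0,a)=1, B(i,a) = aB(i−1,a)/(i + aB(i−1,a)), which is numerically
stable for pool sizes far beyond anything a regional EMS would staff
(each step is a bounded rational update; the factorial-sum form would
overflow long before). Erlang C follows by its defining identity, then
Wq = C/(kμ−λ), W = Wq + E[S], and L, Lq by Little's law in consistent
per-minute units — so Little's law and the sojourn identity hold to
machine precision by construction, and the simulator provides the
genuinely independent check.

**Service-level reading.** "Delayed physician contact" is formalized as
P(wait > 0) = C(k, a), with an inclusive threshold (C ≤ target passes).
This is the standard call-center service-level reading. An alternative —
P(wait > t) for some patience t — would need a patience threshold that
the available calibration does not supply; with the default target of
5% and the loads of interest the two readings select the same staffing
for any small t, because conditional waits are short when C is small.

**Saturation.** Configurations with a ≥ k return flagged infinite
waiting measures instead of raising, so scenario sweeps and sensitivity
grids never abort mid-table.

**Inverse problems.** `min_servers` scans k upward from ⌊a⌋+1 (C is
strictly decreasing in k and → 0, so termination is guaranteed);
`max_arrival_rate` bisects on λ over [0, k/E[S]) to relative tolerance
1e−9 (C is continuous and strictly increasing in the load, from 0
toward 1 at saturation, so the crossing is unique). The derived
`max_supported_units` divides by a per-ambulance consultation rate that
must be supplied by the caller: it is a property of the regional EMS
system, and no defensible default exists.

## Synthetic call logs

The generator emulates what a retrospective extract from an EMS
dispatch IT system would provide to this analysis: arrival timestamps,
consultation durations, and three Bernoulli case attributes
(medication delegated, transport avoided, severe pain). Defaults are
the calibrated study conditions — λ = 3.96/day, E[S] = 24.6 min,
p(delegation) = 0.178, p(no transport) = 0.243, p(NRS ≥ 7) = 0.123.

* **Time base:** minutes internally, rates per day with 1 day = 1440
  min and a 365-day year; continuous 24/7 coverage, no calendar
  effects.
* **Service families:** exponential by default (the M/M/k assumption,
  CV ≡ 1); lognormal (CV configurable, moment-matched:
  σ² = ln(1+cv²), μ = ln m − σ²/2) and deterministic are provided for
  sensitivity runs through the simulator.
* **Pain scores:** only the ≥ 7 tail mass is calibrated; scores are
  drawn uniformly within {7..10} and {0..6} respectively. Any
  within-bin shape with the right tail mass would serve; uniform is
  the least committal.
* **RNG contract:** one root seed is split into four child streams
  (arrivals, services, attributes, pain scores) via
  `SeedSequence.spawn`, so re-parameterizing or adding attributes never
  perturbs arrival times, and identical (model, horizon, seed) triples
  are byte-identical after serialization.

What the generator does **not** emulate: time-of-day and seasonal
demand cycles, correlation between case attributes and service
duration, spatial structure, and duplicate or malformed dispatch
records. Tests that pass against synthetic logs therefore validate the
pipeline's statistical machinery under the stated assumptions, not the
fidelity of those assumptions to any particular region's data.

## Discrete-event simulator

Next-event time advance over a binary-heap event list; simultaneous
events are processed arrival-before-completion in deterministic
insertion order, so a fixed seed reproduces an identical event trace.
Service durations are attached at arrival (same coupling as the
generator). Arrivals stop at the horizon and the system drains, so
every customer who arrived inside the horizon contributes a wait.

Customer statistics (waiting probability, mean wait) count arrivals
after a warm-up cut, default 7 simulated days; queue length and busy
servers are time-integrated over [warm-up, horizon]. Replications use
child seeds spawned from one root seed and are pooled with Student-t
95% intervals on replication means (replications are independent by
construction; 50 replications and a 1-year horizon are the defaults,
chosen so that routine cross-checks resolve the loads of interest
well). Waits within a replication are positively correlated, so tests
compare against analytic values with a multiple of the replication
half-width rather than a binomial standard error.

## Cost accounting

Three component kinds with distinct units: **fixed** (EUR/year),
**jump-fixed** (EUR per staffed 24/7 physician position per year — a
step function of k, constant between steps), and **variable**
(EUR/case). Annual cost is Σfixed + k·Σjump-fixed + cases·Σvariable;
amounts are held as exact floats and rounded to whole EUR only in
reports.

The shipped decentralized default books EUR 148,876 as fixed and the
entire EUR 548,073 staff/equipment/licence block as one jump-fixed
component per position. The underlying accounts do not separate a
per-case tariff out of that block; booking it per position reproduces
the observed k = 1 annual total of EUR 696,949 exactly and for any
caseload, which is the behaviour a planning baseline needs. A known
per-case tariff can be re-split via the `[costs]` configuration.

The centralized center's own cost structure (overhead, per-position
cost, sharing rule) is not observable from a single-district operation;
it is exposed as free parameters plus a calibration helper that
back-solves the per-position amount from a target per-district share
(`examples/central_calibrated.toml` pins the configuration under which
20 districts each pay EUR 57,300). Costs are annual; no discounting or
multi-year horizon.

## Scenario engine

Districts are homogeneous by default: D districts superpose to a
Poisson process of rate D·λ with unchanged service and case mix. Each
scenario staffs the center with `min_servers` against the target
(override available), evaluates performance analytically, prices it
with the chosen cost model using the expected annual caseload
D·λ·365 (a deterministic quantity — a simulated draw would make cost
tables seed-dependent for no informational gain), and shares the total
equally. The reduction column is always computed against the standalone
decentralized baseline (one district, k = 1, decentral cost model).
Every emitted scenario is re-checked post hoc against its own target
via Erlang C.

## Numerical choices and degenerate inputs

* Zero arrival rate: empty logs, zero loads, p_wait = 0 — never an
  error. Empty call logs estimate rate 0 with an undefined (None)
  service mean.
* `max_supported_units` adds a 1e−9 relative guard before flooring so
  bisection round-off cannot drop a whole unit.
* Validation errors always name the offending field; saturated
  analytics are flagged, not raised.
* Exponential service silently normalizes CV to 1; a lognormal with
  CV = 0 degenerates to deterministic.

## Problem sizes

Routine tests cross-validate simulator against closed forms with 8–10
replications of 200 simulated days at loads up to ρ = 0.9; calibration
checks use 50 one-year logs and 10-year single runs for law-of-large-
numbers recovery. These sizes resolve every asserted comparison with
comfortable Monte-Carlo margin.

## Limitations

* No abandonment, retrials, priorities, or server schedules; no
  time-varying arrival rates in the analytic module.
* The "ambulances supported" question requires an externally supplied
  per-ambulance consultation rate.
* Cost conclusions inherit the jump-fixed booking choice; a genuinely
  per-case cost structure would weaken the economies of scale the
  default configuration shows.
* The centralized comparison assumes homogeneous districts and equal
  cost sharing; heterogeneous rates are accepted but untested against
  any observed multi-district operation.
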