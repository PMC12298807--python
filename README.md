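# tepqueue

Capacity and cost planning for **tele-emergency physician (TEP) services**
in rural emergency medical systems.

A TEP is a remote physician who supervises paramedics over live data
links (vitals, ECG, structured assessments) and can delegate medication
or decide against hospital transport without being on scene. Rural
districts that staff such a unit around the clock face a planning
dilemma: demand is low (a few consultations a day), so a dedicated 24/7
physician position sits idle most of the time, yet the full annual cost
of running the unit is substantial. `tepqueue` quantifies that dilemma
and the economics of the obvious remedy — several districts sharing one
centralized TEP center — for health-services researchers and regional
EMS planners.

## The model

Consultation demand is a homogeneous Poisson process with rate λ
(cases/day) and i.i.d. service times with mean E[S] minutes; a pool of
k physicians serves it as an **M/M/k queue (infinite waiting room,
FIFO)**. With offered load a = λ·E[S] (Erlangs) and utilization
ρ = a/k, the probability an incoming consultation finds all physicians
busy is the Erlang C formula

    C(k, a) = k·B(k, a) / (k − a·(1 − B(k, a))),

where B is the Erlang B blocking probability computed by its stable
ascending recursion B(i, a) = a·B(i−1, a)/(i + a·B(i−1, a)), B(0, a)=1.
Waiting and queue-length measures follow from C via Wq = C/(kμ − λ) and
Little's law (L = λW, Lq = λWq). "Delayed physician contact" is
formalized as P(wait > 0) = C(k, a); staffing questions are inverse
problems on C: the minimal k with C ≤ target, or the maximal λ a pool
sustains.

Around the queueing core the package provides:

* a **seeded synthetic call-log generator** (Poisson arrivals;
  exponential, lognormal or deterministic service; Bernoulli case
  attributes for medication delegation, transport avoidance and severe
  pain), standing in for EMS dispatch-system extracts;
* a **discrete-event simulator** (binary-heap event list, warm-up,
  independent replications with Student-t confidence intervals) that
  cross-validates the closed forms and extends them to M/G/k;
* **full-cost accounting** with fixed (EUR/year), jump-fixed (EUR per
  staffed 24/7 position per year) and variable (EUR/case) components;
* a **scenario engine** comparing decentralized operation (one unit per
  district) with a centralized center staffed to a service-level target
  for D districts.

Defaults are calibrated to an observed rural single-district service:
λ = 3.96 cases/day, E[S] = 24.6 min, EUR 148,876/year fixed plus
EUR 548,073 per 24/7 position (total EUR 696,949 at k = 1), case mix
17.8% medication delegation, 24.3% non-transport, 12.3% severe pain
(NRS ≥ 7).

## Worked example

One district on its own (`tepqueue analyze`):

```json
"performance": {
  "servers": 1,
  "offered_load": 0.06765,
  "utilization": 0.06765,
  "p_wait": 0.06765,
  "idle_fraction": 0.93235,
  "Wq": 1.784941277417279
},
"cost": { "annual_total_eur": 696949 }
```

At 3.96 cases/day × 24.6 min the offered load is 0.068 Erlangs: the
physician is idle **93.2%** of the time, yet the unit still costs
**EUR 696,949** a year — and even so, 6.8% of callers would find the
single physician busy, missing a 5% service-level target.

Twenty districts sharing one center
(`tepqueue scenario --districts 20 --config examples/central_calibrated.toml`):

```json
{
  "districts": 20,
  "aggregate_arrival_rate": 79.2,
  "servers": 5,
  "p_wait": 0.013376614589362935,
  "total_cost_eur": 1146000.0,
  "cost_per_district_eur": 57300.0,
  "reduction_vs_standalone_pct": 91.77845150792956
}
```

The aggregate load of 1.353 Erlangs needs only **5** positions (not 20)
to keep the waiting probability at 1.3%, well under the 5% target.
Under the example center cost structure each district pays
**EUR 57,300** a year — a **91.8% reduction** against standalone
operation. `tepqueue sweep` writes the full cost-per-district curve over
D = 1..20; `tepqueue simulate` cross-checks any configuration by
discrete-event simulation; `tepqueue generate` emits synthetic call
logs; `tepqueue sensitivity` evaluates a grid over λ, E[S] and the
target. `tepqueue show-config` prints every effective default.

The per-ambulance consultation rate needed to translate a sustainable
arrival rate into "how many ambulances can one TEP support" is a
property of the regional EMS system, not of the queueing model; it is
an explicit parameter of `max_supported_units`, never a default.

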