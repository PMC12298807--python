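"""Closed-form M/M/k (infinite queue, FIFO) performance analysis.

Implements the Erlang B and Erlang C formulas and the derived
steady-state measures for a pool of k tele-emergency physicians serving
Poisson consultation demand, plus the two inverse problems the planning
questions need: the minimal number of physicians meeting a waiting
target, and the maximal demand a fixed pool can absorb.

Notation (standard queueing symbols):

* lambda — arrival rate; mu = 1/E[S] — service rate per server
* a = lambda * E[S] — offered load in Erlangs; rho = a/k — utilization
* B(k, a) — Erlang B blocking probability (M/M/k/k loss system)
* C(k, a) — Erlang C probability an arrival must wait (all k busy)
* Lq, L — mean number waiting / in system; Wq, W — mean wait / sojourn

"Delayed physician contact" is formalized as P(wait > 0) = C(k, a),
the standard call-center service-level reading, with an inclusive
threshold (C <= target satisfies the target).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict
from typing import List, Optional, Sequence, Tuple

from .demand import (
    CallRecord,
    DemandModel,
    MINUTES_PER_DAY,
    ValidationError,
    _require,
)


def offered_load(arrival_rate: float, service_mean: float) -> float:
    """Offered load a = lambda * E[S] in Erlangs (rate per day, mean in minutes)."""
    _require(arrival_rate >= 0, "arrival_rate", "must be >= 0")
    _require(service_mean > 0, "service_mean", "must be > 0")
    return arrival_rate * service_mean / MINUTES_PER_DAY


def erlang_b(k: int, a: float) -> float:
    """Erlang B blocking probability via the stable ascending recursion.

    B(0, a) = 1 and B(k, a) = a B(k-1, a) / (k + a B(k-1, a)).
    Numerically stable for k well beyond 10^4 (each step is a convex
    combination bounded in (0, 1]).
    """
    _require(k >= 0 and k == int(k), "k", "must be a non-negative integer")
    _require(a >= 0, "a", "must be >= 0")
    b = 1.0
    for i in range(1, int(k) + 1):
        b = a * b / (i + a * b)
    return b


def erlang_c(k: int, a: float) -> float:
    """Erlang C waiting probability C(k, a) = P(all k servers busy).

    Returns 1.0 for a saturated system (a >= k); use
    :func:`performance` for the flagged variant.
    """
    _require(k >= 1 and k == int(k), "k", "must be a positive integer")
    _require(a >= 0, "a", "must be >= 0")
    if a >= k:
        return 1.0
    if a == 0:
        return 0.0
    b = erlang_b(k, a)
    return k * b / (k - a * (1.0 - b))


@dataclass(frozen=True)
class PerformanceMeasures:
    """Steady-state measures for a (k, demand) pair.

    Waiting measures are in minutes; counts are expected numbers of
    cases. ``idle_fraction`` is the long-run idle share per server,
    1 - rho. A saturated system (a >= k) carries infinite waiting
    measures and ``saturated=True`` instead of raising, so scenario
    sweeps never abort.
    """

    servers: int
    offered_load: float
    utilization: float
    erlang_b: float
    p_wait: float
    idle_fraction: float
    Lq: float
    L: float
    Wq: float
    W: float
    saturated: bool

    def to_dict(self) -> dict:
        return asdict(self)


def performance(k: int, model: DemandModel) -> PerformanceMeasures:
    """Full M/M/k steady-state analysis of ``model`` demand on k servers.

    Little's law (L = lambda W, Lq = lambda Wq, in consistent per-minute
    units) and W = Wq + E[S] hold exactly by construction.
    """
    _require(k >= 1 and k == int(k), "k", "must be a positive integer")
    k = int(k)
    a = model.offered_load
    rho = a / k
    b = erlang_b(k, a)
    lam_min = model.arrival_rate_per_min
    es = model.service_mean
    if a >= k:
        inf = math.inf
        return PerformanceMeasures(
            servers=k,
            offered_load=a,
            utilization=rho,
            erlang_b=b,
            p_wait=1.0,
            idle_fraction=max(0.0, 1.0 - rho),
            Lq=inf,
            L=inf,
            Wq=inf,
            W=inf,
            saturated=True,
        )
    c = erlang_c(k, a)
    mu_min = 1.0 / es
    wq = c / (k * mu_min - lam_min) if lam_min > 0 else 0.0
    w = wq + es
    lq = lam_min * wq
    ell = lam_min * w
    return PerformanceMeasures(
        servers=k,
        offered_load=a,
        utilization=rho,
        erlang_b=b,
        p_wait=c,
        idle_fraction=1.0 - rho,
        Lq=lq,
        L=ell,
        Wq=wq,
        W=w,
        saturated=False,
    )


def min_servers(model: DemandModel, target_p_wait: float) -> int:
    """Smallest k with a < k and C(k, a) <= target_p_wait.

    Linear scan upward from the first stable staffing level; always
    terminates because C(k, a) -> 0 as k grows.
    """
    _require(0 < target_p_wait < 1, "target_p_wait", "must be in (0, 1)")
    a = model.offered_load
    k = max(1, math.floor(a) + 1)
    while not (a < k and erlang_c(k, a) <= target_p_wait):
        k += 1
    return k


def max_arrival_rate(
    k: int, service_mean: float, target_p_wait: float, rel_tol: float = 1e-9
) -> float:
    """Largest arrival rate (per day) a pool of k servers can absorb.

    Solves C(k, lambda E[S]/1440) = target_p_wait for lambda by
    bisection (C is continuous and strictly increasing in the load,
    rising from 0 to 1 as a -> k). Monotone non-decreasing in k.
    """
    _require(k >= 1 and k == int(k), "k", "must be a positive integer")
    _require(service_mean > 0, "service_mean", "must be > 0")
    _require(0 < target_p_wait < 1, "target_p_wait", "must be in (0, 1)")
    k = int(k)
    lam_sat = k * MINUTES_PER_DAY / service_mean  # load a = k
    lo, hi = 0.0, lam_sat
    while hi - lo > rel_tol * max(hi, 1.0):
        mid = 0.5 * (lo + hi)
        if erlang_c(k, offered_load(mid, service_mean)) <= target_p_wait:
            lo = mid
        else:
            hi = mid
    return lo


def max_supported_units(
    k: int, per_unit_rate: float, service_mean: float, target_p_wait: float
) -> int:
    """How many demand units (e.g. ambulances) a pool of k servers supports.

    Each unit contributes ``per_unit_rate`` cases/day; the answer is the
    floor of the sustainable aggregate rate divided by the per-unit
    rate. The per-unit rate is an explicit input: it is a property of
    the regional EMS system, not of the queueing model.
    """
    _require(per_unit_rate > 0, "per_unit_rate", "must be > 0")
    lam_max = max_arrival_rate(k, service_mean, target_p_wait)
    # guard against floor(n - eps) from bisection round-off
    return int(math.floor(lam_max / per_unit_rate + 1e-9))


def estimate_rates(
    log: Sequence[CallRecord], horizon_days: float
) -> Tuple[float, Optional[float]]:
    """Empirical (arrival_rate per day, mean service minutes) from a call log.

    An empty log yields rate 0 and an undefined (``None``) service mean.
    """
    _require(horizon_days > 0, "horizon_days", "must be > 0")
    n = len(log)
    rate = n / horizon_days
    if n == 0:
        return 0.0, None
    mean = sum(r.service_duration for r in log) / n
    return rate, mean
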