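"""Discrete-event simulation of a k-server FIFO queue with infinite buffer.

Cross-validates the closed-form M/M/k analysis and extends it to
non-exponential service (M/G/k) via the ``service_distribution`` of the
demand model. The engine is a classic next-event time advance over a
binary-heap event list; ties between simultaneous events are processed
arrival-before-completion in deterministic insertion order, so identical
seeds reproduce identical event traces.

Statistics (waiting probability, mean wait, time-averaged queue length,
per-server busy fraction) are collected only after a warm-up period to
limit initialization bias. Replications use independent child seeds
spawned from one root seed, and the pooled 95% confidence intervals are
Student-t intervals on the replication means.
"""

from __future__ import annotations

import heapq
import math
from dataclasses import dataclass, field
from typing import Dict, List

import numpy as np
from scipy import stats

from .demand import DemandModel, MINUTES_PER_DAY, _require
from .synthetic import _sample_services

_ARRIVAL = 0  # sorts before completion on time ties
_COMPLETION = 1


@dataclass(frozen=True)
class ReplicationEstimates:
    """Point estimates from a single post-warm-up replication."""

    p_wait: float
    mean_wait: float  # minutes
    mean_queue_length: float
    busy_fraction: float
    n_customers: int
    arrival_rate_observed: float  # per day, post-warm-up


def simulate(
    model: DemandModel,
    k: int,
    horizon_days: float,
    warmup_days: float = 7.0,
    seed: int = 0,
) -> ReplicationEstimates:
    """Run one replication of the k-server FIFO queue.

    Arrivals after the warm-up cut contribute to customer averages
    (waiting probability, mean wait); the queue-length and busy-server
    processes are time-integrated over [warmup, horizon].
    """
    _require(k >= 1 and k == int(k), "k", "must be a positive integer")
    _require(warmup_days >= 0, "warmup_days", "must be >= 0")
    _require(
        horizon_days > warmup_days, "horizon_days", "must exceed warmup_days"
    )
    k = int(k)
    horizon = horizon_days * MINUTES_PER_DAY
    warmup = warmup_days * MINUTES_PER_DAY

    ss = np.random.SeedSequence(seed).spawn(2)
    rng_arr = np.random.default_rng(ss[0])
    rng_svc = np.random.default_rng(ss[1])

    if model.arrival_rate == 0:
        return ReplicationEstimates(0.0, 0.0, 0.0, 0.0, 0, 0.0)
    mean_gap = MINUTES_PER_DAY / model.arrival_rate

    # event heap entries: (time, kind, seq); kind 0 = arrival first on ties
    events: List[tuple] = []
    seq = 0

    def push(t: float, kind: int) -> None:
        nonlocal seq
        heapq.heappush(events, (t, kind, seq))
        seq += 1

    busy = 0
    queue: List[tuple] = []  # (arrival_time, service_duration), FIFO
    qhead = 0

    # integrators over [warmup, horizon]
    area_q = 0.0
    area_busy = 0.0
    last_t = warmup

    n_obs = 0
    n_waited = 0
    total_wait = 0.0

    def integrate(now: float) -> None:
        nonlocal area_q, area_busy, last_t
        if now > last_t:
            hi = min(now, horizon)
            if hi > last_t:
                dt = hi - last_t
                area_q += dt * (len(queue) - qhead)
                area_busy += dt * busy
                last_t = hi

    def start_service(arrival_t: float, service: float, now: float) -> None:
        nonlocal busy, n_obs, n_waited, total_wait
        busy += 1
        if arrival_t >= warmup:
            wait = now - arrival_t
            n_obs += 1
            total_wait += wait
            if wait > 0.0:
                n_waited += 1
        push(now + service, _COMPLETION)

    push(float(rng_arr.exponential(mean_gap)), _ARRIVAL)

    # Arrivals stop at the horizon; the system then drains so that every
    # customer who arrived inside the horizon still has a wait recorded.
    while events:
        t, kind, _ = heapq.heappop(events)
        if t >= warmup:
            integrate(t)
        if kind == _ARRIVAL:
            if t >= horizon:
                continue  # past the horizon: drop, stop regenerating
            service = float(_sample_services(rng_svc, model, 1)[0])
            if busy < k:
                start_service(t, service, t)
            else:
                queue.append((t, service))
            push(t + float(rng_arr.exponential(mean_gap)), _ARRIVAL)
        else:  # completion
            busy -= 1
            if qhead < len(queue):
                a_t, service = queue[qhead]
                qhead += 1
                if qhead > 4096 and qhead * 2 > len(queue):
                    del queue[:qhead]
                    qhead = 0
                start_service(a_t, service, t)
    integrate(horizon)

    window = horizon - warmup
    obs_days = window / MINUTES_PER_DAY
    return ReplicationEstimates(
        p_wait=n_waited / n_obs if n_obs else 0.0,
        mean_wait=total_wait / n_obs if n_obs else 0.0,
        mean_queue_length=area_q / window,
        busy_fraction=area_busy / (k * window),
        n_customers=n_obs,
        arrival_rate_observed=n_obs / obs_days,
    )


_METRICS = ("p_wait", "mean_wait", "mean_queue_length", "busy_fraction")


@dataclass(frozen=True)
class SimulationResult:
    """Pooled estimates over independent replications.

    ``pooled`` maps each metric to its arithmetic mean over replication
    estimates; ``half_width`` holds the 95% Student-t confidence
    half-widths around those means.
    """

    replications: int
    horizon_days: float
    warmup_days: float
    per_replication: List[ReplicationEstimates]
    pooled: Dict[str, float]
    half_width: Dict[str, float]

    def ci(self, metric: str) -> tuple:
        m, h = self.pooled[metric], self.half_width[metric]
        return (m - h, m + h)

    def to_frame(self):
        """One row per replication, metric columns in fixed order."""
        import pandas as pd

        return pd.DataFrame(
            [
                {
                    "replication": i,
                    **{m: getattr(r, m) for m in _METRICS},
                    "n_customers": r.n_customers,
                }
                for i, r in enumerate(self.per_replication)
            ]
        )

    def summary(self) -> dict:
        return {
            "replications": self.replications,
            "horizon_days": self.horizon_days,
            "warmup_days": self.warmup_days,
            "pooled": dict(self.pooled),
            "half_width_95": dict(self.half_width),
        }


def replicate(
    model: DemandModel,
    k: int,
    n_reps: int = 50,
    horizon_days: float = 365.0,
    warmup_days: float = 7.0,
    root_seed: int = 0,
) -> SimulationResult:
    """Run independent replications and pool with Student-t 95% intervals.

    Child seeds are spawned from ``root_seed`` and are distinct by
    construction of ``SeedSequence.spawn``.
    """
    _require(n_reps >= 2, "n_reps", "must be >= 2")
    children = np.random.SeedSequence(root_seed).spawn(n_reps)
    # distinct entropy streams; derive plain int seeds for simulate()
    seeds = [int(c.generate_state(1, np.uint32)[0]) for c in children]
    if len(set(seeds)) != len(seeds):  # pragma: no cover - astronomically rare
        raise RuntimeError("replication seeds collided; choose another root_seed")
    reps = [
        simulate(model, k, horizon_days, warmup_days, seed=s) for s in seeds
    ]
    pooled: Dict[str, float] = {}
    half: Dict[str, float] = {}
    tcrit = stats.t.ppf(0.975, n_reps - 1)
    for m in _METRICS:
        vals = np.array([getattr(r, m) for r in reps], dtype=float)
        pooled[m] = float(vals.mean())
        half[m] = float(tcrit * vals.std(ddof=1) / math.sqrt(n_reps))
    return SimulationResult(
        replications=n_reps,
        horizon_days=horizon_days,
        warmup_days=warmup_days,
        per_replication=reps,
        pooled=pooled,
        half_width=half,
    )
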