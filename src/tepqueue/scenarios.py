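"""Decentral-versus-central deployment scenarios.

Composes the demand, queueing and cost modules: for D participating
districts with homogeneous per-district demand, the aggregate arrival
process is the superposition of D Poisson processes (rate D * lambda),
the center is staffed with the minimal number of physicians meeting the
waiting-probability target, and the annual cost is shared equally.

The reduction column compares each scenario's per-district share with
the standalone decentralized baseline (one unit, one district, k = 1).
Caseload entering variable costs is the expected annual count
D * lambda * 365 — a deterministic quantity, not a simulated draw.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Iterable, List, Optional, Sequence

import pandas as pd

from .costs import (
    CostModel,
    annual_cost,
    cost_per_district,
    cost_reduction,
    default_decentralized_cost_model,
)
from .demand import DAYS_PER_YEAR, DemandModel, _require
from .queueing import PerformanceMeasures, erlang_c, min_servers, performance

#: Default service-level target: probability of delayed physician
#: contact (any wait at all) at most 5%.
DEFAULT_TARGET_P_WAIT = 0.05


@dataclass(frozen=True)
class ScenarioResult:
    """One centralization scenario: D districts sharing one TEP center."""

    districts: int
    aggregate_arrival_rate: float
    servers: int
    performance: PerformanceMeasures
    total_cost: float
    cost_per_district: float
    reduction_vs_standalone: float
    target_p_wait: float

    def to_row(self) -> dict:
        return {
            "districts": self.districts,
            "aggregate_arrival_rate": self.aggregate_arrival_rate,
            "servers": self.servers,
            "offered_load": self.performance.offered_load,
            "utilization": self.performance.utilization,
            "p_wait": self.performance.p_wait,
            "idle_fraction": self.performance.idle_fraction,
            "Wq_min": self.performance.Wq,
            "total_cost_eur": self.total_cost,
            "cost_per_district_eur": self.cost_per_district,
            "reduction_vs_standalone_pct": self.reduction_vs_standalone,
            "target_p_wait": self.target_p_wait,
        }


def standalone_baseline_cost(
    per_district_model: DemandModel,
    baseline_cost_model: Optional[CostModel] = None,
) -> float:
    """Annual cost of one decentralized single-district unit (k = 1)."""
    cm = baseline_cost_model or default_decentralized_cost_model()
    cases = per_district_model.arrival_rate * DAYS_PER_YEAR
    return annual_cost(cm, servers=1, cases_per_year=cases)


def run_scenario(
    per_district_model: DemandModel,
    districts: int,
    target_p_wait: float = DEFAULT_TARGET_P_WAIT,
    cost_model: Optional[CostModel] = None,
    baseline_cost_model: Optional[CostModel] = None,
    servers: Optional[int] = None,
    district_rates: Optional[Sequence[float]] = None,
) -> ScenarioResult:
    """Evaluate one centralization scenario for ``districts`` districts.

    Staffing defaults to the minimal k meeting the target; pass
    ``servers`` to override (the performance block then reports whatever
    waiting probability that staffing yields, possibly above target).
    Heterogeneous districts are supported via ``district_rates``, a list
    of per-district arrival rates; their Poisson superposition has rate
    sum(rates) and ``districts`` must equal the list length.
    """
    _require(districts >= 1, "districts", "must be >= 1")
    if district_rates is not None:
        _require(
            len(district_rates) == districts,
            "district_rates",
            "length must equal districts",
        )
        from dataclasses import replace

        agg = replace(
            per_district_model, arrival_rate=float(sum(district_rates))
        )
    else:
        agg = per_district_model.scaled(districts)
    k = servers if servers is not None else min_servers(agg, target_p_wait)
    perf = performance(k, agg)
    cm = cost_model or default_decentralized_cost_model()
    cases = agg.arrival_rate * DAYS_PER_YEAR
    total = annual_cost(cm, servers=k, cases_per_year=cases)
    share = cost_per_district(total, districts)
    baseline = standalone_baseline_cost(per_district_model, baseline_cost_model)
    return ScenarioResult(
        districts=districts,
        aggregate_arrival_rate=agg.arrival_rate,
        servers=k,
        performance=perf,
        total_cost=total,
        cost_per_district=share,
        reduction_vs_standalone=cost_reduction(baseline, share),
        target_p_wait=target_p_wait,
    )


def sweep_districts(
    per_district_model: DemandModel,
    d_max: int,
    target_p_wait: float = DEFAULT_TARGET_P_WAIT,
    cost_model: Optional[CostModel] = None,
    baseline_cost_model: Optional[CostModel] = None,
) -> List[ScenarioResult]:
    """Scenarios for every D in 1..d_max — the cost-per-district curve."""
    _require(d_max >= 1, "d_max", "must be >= 1")
    return [
        run_scenario(
            per_district_model,
            d,
            target_p_wait=target_p_wait,
            cost_model=cost_model,
            baseline_cost_model=baseline_cost_model,
        )
        for d in range(1, d_max + 1)
    ]


def sweep_frame(results: Sequence[ScenarioResult]) -> pd.DataFrame:
    """Stable-column-order DataFrame, one row per scenario."""
    return pd.DataFrame([r.to_row() for r in results])


def sensitivity(
    arrival_rates: Iterable[float],
    service_means: Iterable[float],
    targets: Iterable[float],
    districts: int = 1,
    base_model: Optional[DemandModel] = None,
    cost_model: Optional[CostModel] = None,
) -> pd.DataFrame:
    """Cartesian sensitivity grid, long format, one scenario per row."""
    base = base_model or DemandModel()
    rows = []
    grid = list(product(arrival_rates, service_means, targets))
    _require(len(grid) > 0, "grid", "must be non-empty")
    for lam, es, tgt in grid:
        model = DemandModel(
            arrival_rate=lam,
            service_mean=es,
            service_distribution=base.service_distribution,
            service_cv=base.service_cv,
            p_delegation=base.p_delegation,
            p_no_transport=base.p_no_transport,
            p_nrs_ge7=base.p_nrs_ge7,
        )
        res = run_scenario(model, districts, target_p_wait=tgt, cost_model=cost_model)
        row = {"arrival_rate": lam, "service_mean": es, "target_p_wait": tgt}
        row.update(res.to_row())
        rows.append(row)
    return pd.DataFrame(rows)


def verify_targets(results: Sequence[ScenarioResult]) -> bool:
    """Post-hoc re-check that every scenario meets its own target via Erlang C."""
    return all(
        erlang_c(r.servers, r.performance.offered_load) <= r.target_p_wait
        for r in results
    )
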