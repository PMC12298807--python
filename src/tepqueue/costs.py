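"""Full-cost accounting of tele-emergency physician (TEP) operation.

Three component kinds, each with its own unit semantics:

* ``fixed`` — EUR per year regardless of scale (office infrastructure,
  administration);
* ``jump_fixed`` — EUR per staffed 24/7 physician position per year:
  a step cost that jumps when one more position is staffed and is
  constant in between (salaries, telemedicine equipment, licenses);
* ``variable`` — EUR per handled case.

The shipped decentralized default mirrors the observed single-district
unit: EUR 148,876/year fixed plus EUR 548,073 per position, which sums
to EUR 696,949 at k = 1 regardless of caseload. The observed accounts
do not split the 548,073 between per-case and per-position parts, so
the default books it entirely as jump-fixed; re-split via configuration
if a per-case tariff is known. Amounts are kept in exact integer-safe
floats and rounded to whole EUR only at report time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Sequence

from .demand import ValidationError, _require

KINDS = ("fixed", "jump_fixed", "variable")

#: Observed annual fixed cost of one decentralized 24/7 TEP unit (EUR).
DEFAULT_FIXED_EUR = 148_876.0
#: Observed annual variable + jump-fixed cost of the same unit (EUR),
#: booked per staffed 24/7 position.
DEFAULT_JUMP_FIXED_EUR = 548_073.0


@dataclass(frozen=True)
class CostComponent:
    """One cost line: a label, a kind and an amount in the kind's unit."""

    label: str
    kind: str
    amount: float

    def __post_init__(self) -> None:
        _require(self.kind in KINDS, "kind", f"must be one of {KINDS}")
        _require(self.amount >= 0, "amount", "must be >= 0")


@dataclass(frozen=True)
class CostModel:
    """A collection of cost components; annual cost is additive over them."""

    components: tuple
    currency: str = "EUR"

    def __post_init__(self) -> None:
        _require(len(self.components) >= 1, "components", "must be non-empty")
        object.__setattr__(self, "components", tuple(self.components))

    def total(self, kind: str) -> float:
        return sum(c.amount for c in self.components if c.kind == kind)


def default_decentralized_cost_model() -> CostModel:
    """Cost structure of one decentralized 24/7 TEP unit (k = 1 baseline)."""
    return CostModel(
        components=(
            CostComponent(
                "office infrastructure & administration", "fixed", DEFAULT_FIXED_EUR
            ),
            CostComponent(
                "staff, telemedicine equipment & licenses",
                "jump_fixed",
                DEFAULT_JUMP_FIXED_EUR,
            ),
        )
    )


def central_cost_model_from_per_district(
    per_district_target: float,
    districts: int,
    servers: int,
    fixed: float = DEFAULT_FIXED_EUR,
) -> CostModel:
    """Back-solve a centralized cost structure from a per-district target.

    The centralized center's own accounts (overhead, per-position cost,
    sharing rule) are free parameters of the planning exercise; this
    helper calibrates the per-position amount so that ``districts``
    participants sharing a center staffed with ``servers`` positions
    each pay ``per_district_target`` EUR/year:

        jump_fixed = (per_district_target * D - fixed) / servers
    """
    _require(districts >= 1, "districts", "must be >= 1")
    _require(servers >= 1, "servers", "must be >= 1")
    total = per_district_target * districts
    _require(total >= fixed, "per_district_target", "total below fixed cost")
    per_position = (total - fixed) / servers
    return CostModel(
        components=(
            CostComponent("central infrastructure & administration", "fixed", fixed),
            CostComponent(
                "central staff, equipment & licenses", "jump_fixed", per_position
            ),
        )
    )


def annual_cost(model: CostModel, servers: int, cases_per_year: float) -> float:
    """Total annual cost: sum(fixed) + sum(jump_fixed) * k + sum(variable) * cases."""
    _require(servers >= 1, "servers", "must be >= 1")
    _require(cases_per_year >= 0, "cases_per_year", "must be >= 0")
    return (
        model.total("fixed")
        + model.total("jump_fixed") * servers
        + model.total("variable") * cases_per_year
    )


def cost_per_district(total: float, districts: int) -> float:
    """Equal sharing of a total annual cost among participating districts."""
    _require(districts >= 1, "districts", "must be >= 1")
    return total / districts


def cost_reduction(baseline_per_district: float, scenario_per_district: float) -> float:
    """Percent reduction of the scenario share versus the standalone baseline."""
    _require(baseline_per_district > 0, "baseline_per_district", "must be > 0")
    return 100.0 * (1.0 - scenario_per_district / baseline_per_district)


def cost_report_rows(
    model: CostModel, servers: int, cases_per_year: float
) -> List[dict]:
    """Per-component contribution rows (whole-EUR rounding at report time)."""
    rows = []
    for c in model.components:
        if c.kind == "fixed":
            contribution = c.amount
        elif c.kind == "jump_fixed":
            contribution = c.amount * servers
        else:
            contribution = c.amount * cases_per_year
        rows.append(
            {
                "component": c.label,
                "kind": c.kind,
                "amount": c.amount,
                "contribution_eur": round(contribution),
            }
        )
    return rows
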