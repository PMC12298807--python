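"""Demand parameterization for a tele-emergency physician (TEP) service.

A :class:`DemandModel` bundles everything the queueing, simulation and
synthetic-log modules need to know about demand: the arrival rate of TEP
consultations (a homogeneous Poisson process), the service-duration
distribution, and the case-mix probabilities used when synthesizing call
logs (medication delegation, transport avoidance, severe pain on the NRS).

Units follow one convention throughout the package: rates are configured
per day, durations are minutes, and 1 day = 1440 minutes with a 365-day
year (continuous 24/7 coverage; no calendar effects).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

MINUTES_PER_DAY = 1440.0
DAYS_PER_YEAR = 365.0

#: Service-time families supported by the generator and the simulator.
SERVICE_DISTRIBUTIONS = ("exponential", "lognormal", "deterministic")


class ValidationError(ValueError):
    """Raised when a model or argument violates its contract.

    The message always names the offending field.
    """


def _require(condition: bool, field_name: str, message: str) -> None:
    if not condition:
        raise ValidationError(f"{field_name}: {message}")


@dataclass(frozen=True)
class DemandModel:
    """Arrival, service and case-mix parameterization of TEP demand.

    Parameters
    ----------
    arrival_rate : float
        Consultations per day (lambda of the Poisson arrival process).
    service_mean : float
        Mean consultation duration in minutes (E[S]; mu = 1/E[S]).
    service_distribution : str
        One of ``exponential`` (the M/M/k assumption, CV fixed at 1),
        ``lognormal`` (CV configurable) or ``deterministic``.
    service_cv : float
        Coefficient of variation of service times; only meaningful for
        the lognormal family.
    p_delegation : float
        Probability a case involves physician-delegated medication.
    p_no_transport : float
        Probability a case is resolved without hospital transport.
    p_nrs_ge7 : float
        Probability of severe pain (numerical rating scale >= 7).

    Defaults are calibrated to the observed rural single-district service:
    3.96 cases/day, 24.6 min mean consultation, 17.8% delegation, 24.3%
    non-transport, 12.3% severe pain.
    """

    arrival_rate: float = 3.96
    service_mean: float = 24.6
    service_distribution: str = "exponential"
    service_cv: float = 1.0
    p_delegation: float = 0.178
    p_no_transport: float = 0.243
    p_nrs_ge7: float = 0.123

    def __post_init__(self) -> None:
        _require(self.arrival_rate >= 0, "arrival_rate", "must be >= 0")
        _require(self.service_mean > 0, "service_mean", "must be > 0")
        _require(
            self.service_distribution in SERVICE_DISTRIBUTIONS,
            "service_distribution",
            f"must be one of {SERVICE_DISTRIBUTIONS}",
        )
        if self.service_distribution == "exponential":
            # CV of an exponential is identically 1; silently normalise.
            object.__setattr__(self, "service_cv", 1.0)
        _require(self.service_cv >= 0, "service_cv", "must be >= 0")
        for name in ("p_delegation", "p_no_transport", "p_nrs_ge7"):
            p = getattr(self, name)
            _require(0.0 <= p <= 1.0, name, "must be a probability in [0, 1]")

    # -- derived quantities ------------------------------------------------

    @property
    def service_rate_per_min(self) -> float:
        """mu, completions per minute per busy server."""
        return 1.0 / self.service_mean

    @property
    def arrival_rate_per_min(self) -> float:
        """lambda converted to events per minute."""
        return self.arrival_rate / MINUTES_PER_DAY

    @property
    def offered_load(self) -> float:
        """a = lambda * E[S] in Erlangs."""
        return self.arrival_rate * self.service_mean / MINUTES_PER_DAY

    def scaled(self, districts: int) -> "DemandModel":
        """Aggregate demand of ``districts`` homogeneous districts.

        Superposition of independent Poisson processes: the aggregate is
        Poisson with rate D * lambda; service and case mix are unchanged.
        """
        _require(districts >= 1, "districts", "must be >= 1")
        return replace(self, arrival_rate=self.arrival_rate * districts)


@dataclass(frozen=True)
class CallRecord:
    """One synthetic TEP consultation.

    ``arrival_time`` is minutes since the start of the horizon;
    ``nrs_pain`` is an integer 0-10 or ``None`` when not recorded.
    """

    call_id: str
    arrival_time: float
    service_duration: float
    medication_delegated: bool
    transport_avoided: bool
    nrs_pain: Optional[int] = None

    def __post_init__(self) -> None:
        _require(self.arrival_time >= 0, "arrival_time", "must be >= 0")
        _require(self.service_duration > 0, "service_duration", "must be > 0")
        if self.nrs_pain is not None:
            _require(
                isinstance(self.nrs_pain, int) and 0 <= self.nrs_pain <= 10,
                "nrs_pain",
                "must be an integer in 0..10 or missing",
            )
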