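"""Seeded generator and plain-text I/O for synthetic TEP call logs.

The generator realizes the statistical structure the economic analysis
assumes: homogeneous Poisson arrivals, i.i.d. service durations from a
configurable family, and i.i.d. Bernoulli case attributes. It stands in
for retrospective extracts from an EMS dispatch IT system.

RNG contract
------------
One root seed is split into four independent child streams (arrivals,
service durations, case attributes, pain scores) via
``numpy.random.SeedSequence.spawn``. Adding or re-parameterizing
attributes therefore never perturbs the arrival process, and identical
``(model, horizon, seed)`` triples yield byte-identical logs.
"""

from __future__ import annotations

import csv
import json
import math
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .demand import CallRecord, DemandModel, MINUTES_PER_DAY, ValidationError, _require

_CSV_FIELDS = (
    "call_id",
    "arrival_time",
    "service_duration",
    "medication_delegated",
    "transport_avoided",
    "nrs_pain",
)


def _spawn_streams(seed: int) -> Tuple[np.random.Generator, ...]:
    children = np.random.SeedSequence(seed).spawn(4)
    return tuple(np.random.default_rng(c) for c in children)


def _sample_services(
    rng: np.random.Generator, model: DemandModel, n: int
) -> np.ndarray:
    m = model.service_mean
    if model.service_distribution == "exponential":
        return rng.exponential(m, size=n)
    if model.service_distribution == "deterministic":
        return np.full(n, m)
    # lognormal with mean m and coefficient of variation cv
    cv = model.service_cv
    if cv == 0:
        return np.full(n, m)
    sigma2 = math.log1p(cv * cv)
    mu = math.log(m) - sigma2 / 2.0
    return rng.lognormal(mean=mu, sigma=math.sqrt(sigma2), size=n)


def _sample_nrs(rng: np.random.Generator, p_ge7: float, n: int) -> np.ndarray:
    """NRS scores: severe (uniform 7..10) with probability p_ge7, else uniform 0..6.

    Only the >= 7 tail mass is calibrated; the within-bin shape is a
    modeling choice (uniform).
    """
    severe = rng.random(n) < p_ge7
    low = rng.integers(0, 7, size=n)
    high = rng.integers(7, 11, size=n)
    return np.where(severe, high, low)


def generate_log(
    model: DemandModel, horizon_days: float, seed: int
) -> List[CallRecord]:
    """Generate an ordered synthetic call log over ``horizon_days``.

    Interarrival times are i.i.d. exponential with mean
    ``1440 / arrival_rate`` minutes; service durations and case
    attributes are i.i.d. from the configured model. Arrival times are
    strictly increasing (a tie is a probability-zero event under
    continuous interarrivals).
    """
    _require(horizon_days > 0, "horizon_days", "must be > 0")
    rng_arr, rng_svc, rng_attr, rng_nrs = _spawn_streams(seed)

    horizon_min = horizon_days * MINUTES_PER_DAY
    if model.arrival_rate == 0:
        return []

    mean_gap = MINUTES_PER_DAY / model.arrival_rate
    # Draw interarrivals in blocks until the horizon is covered.
    times: List[float] = []
    t = 0.0
    block = max(16, int(horizon_min / mean_gap * 1.2) + 16)
    while True:
        gaps = rng_arr.exponential(mean_gap, size=block)
        arr = t + np.cumsum(gaps)
        inside = arr[arr < horizon_min]
        times.extend(inside.tolist())
        if len(inside) < len(arr):
            break
        t = float(arr[-1])
        block = max(16, block // 4)
    n = len(times)

    services = _sample_services(rng_svc, model, n)
    delegated = rng_attr.random(n) < model.p_delegation
    no_transport = rng_attr.random(n) < model.p_no_transport
    nrs = _sample_nrs(rng_nrs, model.p_nrs_ge7, n)

    width = max(4, len(str(max(n, 1))))
    return [
        CallRecord(
            call_id=f"C{i:0{width}d}",
            arrival_time=times[i],
            service_duration=float(services[i]),
            medication_delegated=bool(delegated[i]),
            transport_avoided=bool(no_transport[i]),
            nrs_pain=int(nrs[i]),
        )
        for i in range(n)
    ]


# ---------------------------------------------------------------------------
# plain-text I/O


class LogParseError(ValueError):
    """Malformed row in a call-log file; the message carries the line number."""


def _record_to_row(r: CallRecord) -> dict:
    return {
        "call_id": r.call_id,
        "arrival_time": repr(r.arrival_time),
        "service_duration": repr(r.service_duration),
        "medication_delegated": str(r.medication_delegated).lower(),
        "transport_avoided": str(r.transport_avoided).lower(),
        "nrs_pain": "" if r.nrs_pain is None else str(r.nrs_pain),
    }


def _parse_bool(s: str, field_name: str, lineno: int) -> bool:
    if s == "true":
        return True
    if s == "false":
        return False
    raise LogParseError(f"line {lineno}: {field_name} must be true/false, got {s!r}")


def _row_to_record(row: dict, lineno: int) -> CallRecord:
    try:
        nrs_raw = row.get("nrs_pain")
        nrs: Optional[int]
        if nrs_raw is None or nrs_raw == "":
            nrs = None
        else:
            nrs = int(nrs_raw)
        return CallRecord(
            call_id=row["call_id"],
            arrival_time=float(row["arrival_time"]),
            service_duration=float(row["service_duration"]),
            medication_delegated=_parse_bool(
                row["medication_delegated"], "medication_delegated", lineno
            ),
            transport_avoided=_parse_bool(
                row["transport_avoided"], "transport_avoided", lineno
            ),
            nrs_pain=nrs,
        )
    except LogParseError:
        raise
    except (KeyError, TypeError, ValueError, ValidationError) as exc:
        raise LogParseError(f"line {lineno}: malformed record ({exc})") from exc


def write_log(
    records: Sequence[CallRecord], path: str | Path, format: str = "csv"
) -> Path:
    """Write records to ``path`` as CSV (header row, UTF-8) or JSONL.

    Floats are written at full repr precision so that
    ``read_log(write_log(x)) == x`` field-for-field.
    """
    path = Path(path)
    if format == "csv":
        with path.open("w", newline="", encoding="utf-8") as fh:
            writer = csv.DictWriter(fh, fieldnames=_CSV_FIELDS)
            writer.writeheader()
            for r in records:
                writer.writerow(_record_to_row(r))
    elif format == "jsonl":
        with path.open("w", encoding="utf-8") as fh:
            for r in records:
                fh.write(
                    json.dumps(
                        {
                            "call_id": r.call_id,
                            "arrival_time": r.arrival_time,
                            "service_duration": r.service_duration,
                            "medication_delegated": r.medication_delegated,
                            "transport_avoided": r.transport_avoided,
                            "nrs_pain": r.nrs_pain,
                        }
                    )
                    + "\n"
                )
    else:
        raise ValidationError(f"format: must be 'csv' or 'jsonl', got {format!r}")
    return path


def read_log(path: str | Path, format: Optional[str] = None) -> List[CallRecord]:
    """Read a call log written by :func:`write_log`.

    The format is inferred from the suffix unless given explicitly.
    Malformed rows raise :class:`LogParseError` with the line number.
    """
    path = Path(path)
    if format is None:
        format = "jsonl" if path.suffix == ".jsonl" else "csv"
    records: List[CallRecord] = []
    if format == "csv":
        with path.open(newline="", encoding="utf-8") as fh:
            reader = csv.DictReader(fh)
            if reader.fieldnames is None or list(reader.fieldnames) != list(
                _CSV_FIELDS
            ):
                raise LogParseError(
                    f"line 1: expected header {','.join(_CSV_FIELDS)}"
                )
            for lineno, row in enumerate(reader, start=2):
                records.append(_row_to_record(row, lineno))
    elif format == "jsonl":
        with path.open(encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, start=1):
                if not line.strip():
                    continue
                try:
                    obj = json.loads(line)
                except json.JSONDecodeError as exc:
                    raise LogParseError(f"line {lineno}: invalid JSON ({exc})")
                obj = {k: ("" if v is None else v) for k, v in obj.items()}
                # JSONL carries native types; route bools through strings
                # only for the shared validator.
                obj["medication_delegated"] = str(obj["medication_delegated"]).lower()
                obj["transport_avoided"] = str(obj["transport_avoided"]).lower()
                records.append(_row_to_record(obj, lineno))
    else:
        raise ValidationError(f"format: must be 'csv' or 'jsonl', got {format!r}")
    return records
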