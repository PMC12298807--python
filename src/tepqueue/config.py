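"""Run configuration: a single TOML file with one section per module.

Every key has a documented default; unknown sections or keys are
rejected so that typos never silently fall back to defaults. CLI flags
override file values, which override defaults.
"""

from __future__ import annotations

import hashlib
import json
import tomllib
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any, Dict, List, Optional

from .costs import (
    CostComponent,
    CostModel,
    DEFAULT_FIXED_EUR,
    DEFAULT_JUMP_FIXED_EUR,
)
from .demand import DemandModel, ValidationError, _require

_DEFAULTS: Dict[str, Dict[str, Any]] = {
    "demand": {
        "arrival_rate": 3.96,
        "service_mean": 24.6,
        "service_distribution": "exponential",
        "service_cv": 1.0,
        "p_delegation": 0.178,
        "p_no_transport": 0.243,
        "p_nrs_ge7": 0.123,
    },
    "queue": {
        "target_p_wait": 0.05,
    },
    "costs": {
        # component triples: [label, kind, amount]
        "decentral": [
            ["office infrastructure & administration", "fixed", DEFAULT_FIXED_EUR],
            [
                "staff, telemedicine equipment & licenses",
                "jump_fixed",
                DEFAULT_JUMP_FIXED_EUR,
            ],
        ],
        "central": [],  # empty -> reuse the decentral structure
    },
    "scenario": {
        "districts": 20,
        "d_max": 20,
    },
    "simulation": {
        "horizon_days": 365.0,
        "warmup_days": 7.0,
        "n_reps": 50,
        "servers": 1,
    },
    "run": {
        "seed": 0,
        "horizon_days": 365.0,
        "output_dir": ".",
    },
}


@dataclass(frozen=True)
class RunConfig:
    """Validated, fully-defaulted configuration for all subcommands."""

    sections: Dict[str, Dict[str, Any]]

    # -- constructors ------------------------------------------------------

    @classmethod
    def default(cls) -> "RunConfig":
        return cls(sections=json.loads(json.dumps(_DEFAULTS)))

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        with Path(path).open("rb") as fh:
            user = tomllib.load(fh)
        merged = json.loads(json.dumps(_DEFAULTS))
        for section, values in user.items():
            if section not in merged:
                raise ValidationError(f"config: unknown section [{section}]")
            if not isinstance(values, dict):
                raise ValidationError(f"config: [{section}] must be a table")
            for key, val in values.items():
                if key not in merged[section]:
                    raise ValidationError(
                        f"config: unknown key {key!r} in section [{section}]"
                    )
                merged[section][key] = val
        cfg = cls(sections=merged)
        cfg.demand_model()  # validate eagerly
        cfg.decentral_cost_model()
        return cfg

    def override(self, section: str, key: str, value: Any) -> "RunConfig":
        _require(section in self.sections, "section", f"unknown section {section!r}")
        _require(
            key in self.sections[section], "key", f"unknown key {key!r} in {section}"
        )
        merged = json.loads(json.dumps(self.sections))
        merged[section][key] = value
        return RunConfig(sections=merged)

    # -- accessors ---------------------------------------------------------

    def __getitem__(self, section: str) -> Dict[str, Any]:
        return self.sections[section]

    def demand_model(self) -> DemandModel:
        return DemandModel(**self.sections["demand"])

    def _cost_model(self, key: str) -> Optional[CostModel]:
        triples = self.sections["costs"][key]
        if not triples:
            return None
        return CostModel(
            components=tuple(
                CostComponent(label=t[0], kind=t[1], amount=float(t[2]))
                for t in triples
            )
        )

    def decentral_cost_model(self) -> CostModel:
        model = self._cost_model("decentral")
        _require(model is not None, "costs.decentral", "must be non-empty")
        return model

    def central_cost_model(self) -> Optional[CostModel]:
        """Centralized center cost structure; None means reuse decentral."""
        return self._cost_model("central")

    # -- provenance --------------------------------------------------------

    def to_toml(self) -> str:
        """Echo every effective value as a TOML document."""
        lines: List[str] = []
        for section, values in self.sections.items():
            lines.append(f"[{section}]")
            for key, val in values.items():
                lines.append(f"{key} = {json.dumps(val)}")
            lines.append("")
        return "\n".join(lines)

    def digest(self) -> str:
        """Stable hash of the effective configuration, for run logging."""
        canonical = json.dumps(self.sections, sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()[:16]
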