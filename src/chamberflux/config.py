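"""Run configuration: unit declarations, formula choices, thresholds, seed.

A ``RunConfig`` is fully serializable and its hash is embedded in every
output table so that a result can always be traced back to the exact
settings that produced it.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, Optional

import yaml

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    """Settings shared across the pipeline stages.

    Attributes
    ----------
    default_volume_l : float, optional
        Chamber water volume (L) used when a cycle carries no explicit
        volume accounting and the chamber has no per-chamber entry.
    chamber_volumes : dict
        Per-chamber volume overrides (chamber id -> litres); consulted
        before ``default_volume_l``.
    density_constant : float, optional
        Fixed seawater density (kg L-1).  When unset, density is evaluated
        from each interval's mean salinity and temperature with the
        one-atmosphere equation of state.
    supersaturation_pct, hypoxia_pct, anoxia_conc :
        Oxygen-state thresholds (percent of equilibrium solubility for the
        first two, umol L-1 for the floor).
    k_detect : float
        Multiple of the analytic precision a drift must exceed to count as
        a detectable metabolic change.
    ta_precision, o2_precision :
        Analytic precisions: 2 umol kg-1 for alkalinity titration,
        0.05 umol L-1 for the optode oxygen reading.
    decision_hour : float
        Sampling hour at which the volume acceptance rule is applied
        (the flushing interval, 3 h).
    photoperiod_h : float
        Daylight hours assumed when reporting daily-integration coverage.
    control_match : str
        Keys controls are matched on: "day-phase" or "day-phase-site".
    seed : int, optional
        Seed for any stochastic step launched from this config.
    """

    default_volume_l: Optional[float] = None
    chamber_volumes: Dict[str, float] = field(default_factory=dict)
    density_constant: Optional[float] = None
    density_formula: str = "eos80"
    solubility_formula: str = "garcia-gordon-1992"
    supersaturation_pct: float = 200.0
    hypoxia_pct: float = 30.0
    anoxia_conc: float = 5.0
    k_detect: float = 3.0
    ta_precision: float = 2.0
    o2_precision: float = 0.05
    decision_hour: float = 3.0
    photoperiod_h: float = 12.0
    control_match: str = "day-phase-site"
    extrapolate_daily: bool = False
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.control_match not in ("day-phase", "day-phase-site"):
            raise ValueError(
                f"control_match={self.control_match!r}: expected 'day-phase' or "
                "'day-phase-site'"
            )
        if self.default_volume_l is not None and self.default_volume_l <= 0:
            raise ValueError("default_volume_l must be > 0")
        if self.density_constant is not None and not (
            0.99 <= self.density_constant <= 1.05
        ):
            raise ValueError("density_constant must lie in [0.99, 1.05] kg L-1")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError(f"{path}: config file must contain a mapping")
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @property
    def config_hash(self) -> str:
        """Short stable digest of the canonical JSON form."""
        canon = json.dumps(self.to_dict(), sort_keys=True, separators=(",", ":"))
        return hashlib.sha256(canon.encode()).hexdigest()[:12]
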