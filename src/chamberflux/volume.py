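"""Chamber-volume safety analysis and the water-extraction error budget.

Before deploying sealed incubation chambers, the water-volume-to-biomass
ratio must be tuned: too little water and dark-phase respiration drives the
chamber hypoxic or anoxic (and light-phase photosynthesis supersaturates
it, risking oxidative stress); too much water and the concentration drift
over a flushing interval falls below the analytic detection limit.  This
module classifies per-sample oxygen states, tests drifts for detectability
against instrument precision, collapses replicate flags into consensus
codes (-, ±, +), and applies the volume acceptance rule at the flushing
hour.  It also quantifies the relative rate error introduced by chamber
water that is not re-extracted during sampling.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, List, Optional, Sequence

import numpy as np
import pandas as pd

from .core import Phase, SeawaterState

__all__ = [
    "OxygenStateThresholds",
    "DecisionMatrix",
    "VolumeDecision",
    "ExtractionErrorSummary",
    "classify_oxygen_state",
    "detectable_change",
    "consensus",
    "build_decision_matrix",
    "accept_volumes",
    "extraction_error",
]

NEGATIVE, MIXED, POSITIVE = "-", "±", "+"
_CODES = (NEGATIVE, MIXED, POSITIVE)


@dataclass(frozen=True)
class OxygenStateThresholds:
    """Thresholds defining unsafe oxygen states.

    ``supersaturation_pct`` flags a light-phase sample whose O2 exceeds
    this percentage of the equilibrium solubility (zooxanthellae can push
    host-tissue O2 beyond 200% saturation in shallow water, the basis of
    the default).  ``hypoxia_pct`` and ``anoxia_conc`` flag dark-phase
    samples: below the given percent of saturation, or below an absolute
    concentration floor (umol L-1), respectively.
    """

    supersaturation_pct: float = 200.0
    hypoxia_pct: float = 30.0
    anoxia_conc: float = 5.0

    def __post_init__(self) -> None:
        if not self.anoxia_conc > 0:
            raise ValueError("anoxia_conc must be > 0")
        if not (0 < self.hypoxia_pct < 100 < self.supersaturation_pct):
            raise ValueError(
                "thresholds must satisfy 0 < hypoxia_pct < 100 < supersaturation_pct"
            )


def classify_oxygen_state(
    O2: float,
    seawater_state: SeawaterState,
    phase: Phase,
    thresholds: OxygenStateThresholds = OxygenStateThresholds(),
    dark_criterion: str = "anoxia",
) -> bool:
    """True when the oxygen state is unsafe for the incubated organism.

    Light phase: unsafe when O2 exceeds the supersaturation threshold
    (photosynthetic O2 accumulation).  Dark phase: unsafe when O2 falls
    below the anoxia floor (``dark_criterion="anoxia"``) or below the
    hypoxia percentage of saturation (``dark_criterion="hypoxia"``).
    """
    if O2 < 0:
        raise ValueError(f"O2={O2!r}: must be >= 0")
    sat = seawater_state.O2_sat
    if phase == "light":
        return O2 > thresholds.supersaturation_pct / 100.0 * sat
    if phase == "dark":
        if dark_criterion == "anoxia":
            return O2 < thresholds.anoxia_conc
        if dark_criterion == "hypoxia":
            return O2 < thresholds.hypoxia_pct / 100.0 * sat
        raise ValueError(f"dark_criterion={dark_criterion!r}")
    raise ValueError(f"phase={phase!r}: must be 'light' or 'dark'")


def detectable_change(
    drift: float, analytic_precision: float, k: float = 3.0
) -> bool:
    """True when |drift| exceeds k times the analytic precision.

    The default k = 3 requires the concentration change to stand three
    precision units clear of zero; a drift exactly at k * precision is not
    detectable (strict inequality).
    """
    if analytic_precision <= 0:
        raise ValueError("analytic_precision must be > 0")
    if k <= 0:
        raise ValueError("k must be > 0")
    return abs(drift) > k * analytic_precision


def detectable_metabolic_change(
    ta_drift: float,
    o2_drift: float,
    ta_precision: float = 2.0,
    o2_precision: float = 0.05,
    k: float = 3.0,
) -> bool:
    """Combined detectability: both the TA and the O2 drift must clear k sigma."""
    return detectable_change(ta_drift, ta_precision, k) and detectable_change(
        o2_drift, o2_precision, k
    )


def consensus(flags: Sequence[bool]) -> str:
    """Collapse replicate booleans to a consensus code.

    All false -> "-" (unanimous negative), all true -> "+" (unanimous
    positive), otherwise "±" (mixed).  Permutation-invariant by
    construction.
    """
    flags = list(flags)
    if not flags:
        raise ValueError("consensus requires at least one replicate flag")
    if all(flags):
        return POSITIVE
    if not any(flags):
        return NEGATIVE
    return MIXED


@dataclass
class DecisionMatrix:
    """Per-(volume, hour, phase) consensus codes for the safety analysis.

    ``table`` columns: volume_ml, hour, phase, o2_code, dmet_code,
    n_replicates.  ``o2_code`` summarises the unsafe-oxygen-state flags of
    the replicate colonies, ``dmet_code`` the detectable-metabolic-change
    flags.
    """

    table: pd.DataFrame
    meta: dict = field(default_factory=dict)

    _COLS = ("volume_ml", "hour", "phase", "o2_code", "dmet_code", "n_replicates")

    def __post_init__(self) -> None:
        missing = [c for c in self._COLS if c not in self.table.columns]
        if missing:
            raise ValueError(f"decision matrix missing columns: {missing}")
        bad = ~self.table["o2_code"].isin(_CODES) | ~self.table["dmet_code"].isin(_CODES)
        if bad.any():
            raise ValueError(
                f"invalid consensus codes: {self.table.loc[bad].to_dict('records')}"
            )

    @property
    def volumes(self) -> List[float]:
        return sorted(self.table["volume_ml"].unique())

    @property
    def hours(self) -> List[float]:
        return sorted(self.table["hour"].unique())

    def cell(self, volume_ml: float, hour: float, phase: str) -> pd.Series:
        sel = self.table[
            (self.table["volume_ml"] == volume_ml)
            & (self.table["hour"] == hour)
            & (self.table["phase"] == phase)
        ]
        if len(sel) != 1:
            raise KeyError(f"no unique cell for ({volume_ml} ml, {hour} h, {phase})")
        return sel.iloc[0]


def build_decision_matrix(
    trajectories: pd.DataFrame,
    thresholds: OxygenStateThresholds = OxygenStateThresholds(),
    ta_precision: float = 2.0,
    o2_precision: float = 0.05,
    k: float = 3.0,
) -> DecisionMatrix:
    """Classify simulated or logged volume-trial trajectories into codes.

    ``trajectories`` holds one row per (volume_ml, hour, phase, replicate)
    with columns O2, dTA, dO2 (drifts relative to the cycle start),
    salinity and temperature.  Each (volume, hour, phase) cell is reduced
    to two consensus codes over its replicates.
    """
    required = {"volume_ml", "hour", "phase", "replicate", "O2", "dTA", "dO2",
                "salinity", "temperature"}
    missing = required - set(trajectories.columns)
    if missing:
        raise ValueError(f"trajectory table missing columns: {sorted(missing)}")
    rows = []
    for (vol, hour, phase), grp in trajectories.groupby(
        ["volume_ml", "hour", "phase"], sort=True
    ):
        o2_flags, met_flags = [], []
        for _, r in grp.iterrows():
            state = SeawaterState.from_conditions(r["salinity"], r["temperature"])
            o2_flags.append(
                classify_oxygen_state(r["O2"], state, phase, thresholds)
            )
            met_flags.append(
                detectable_metabolic_change(
                    r["dTA"], r["dO2"], ta_precision, o2_precision, k
                )
            )
        rows.append(
            {
                "volume_ml": vol,
                "hour": hour,
                "phase": phase,
                "o2_code": consensus(o2_flags),
                "dmet_code": consensus(met_flags),
                "n_replicates": len(grp),
            }
        )
    return DecisionMatrix(
        table=pd.DataFrame(rows),
        meta={"thresholds": thresholds, "k": k,
              "ta_precision": ta_precision, "o2_precision": o2_precision},
    )


@dataclass(frozen=True)
class VolumeDecision:
    """Outcome of the volume acceptance rule."""

    accepted: tuple
    minimum: Optional[float]
    decision_hour: float


def accept_volumes(matrix: DecisionMatrix, decision_hour: float = 3.0) -> VolumeDecision:
    """Apply the acceptance rule at the flushing hour.

    A volume passes iff, at ``decision_hour``, the oxygen-state code is
    "-" (no replicate unsafe) AND the metabolic-change code is "+"
    (all replicates detectable) in BOTH the light and the dark table.
    """
    if decision_hour not in matrix.hours:
        raise ValueError(
            f"decision_hour={decision_hour} not sampled; available: {matrix.hours}"
        )
    accepted = []
    for vol in matrix.volumes:
        ok = True
        for phase in ("light", "dark"):
            cell = matrix.cell(vol, decision_hour, phase)
            if cell["o2_code"] != NEGATIVE or cell["dmet_code"] != POSITIVE:
                ok = False
                break
        if ok:
            accepted.append(vol)
    return VolumeDecision(
        accepted=tuple(accepted),
        minimum=min(accepted) if accepted else None,
        decision_hour=decision_hour,
    )


@dataclass(frozen=True)
class ExtractionErrorSummary:
    """Relative metabolic-rate error from unrecovered chamber water.

    A millilitre of water left in the chamber biases the reconstructed
    volume, and hence every rate, by (1 ml / reference volume); errors are
    reported in percent.
    """

    per_sample_pct: tuple
    mean_pct: float
    max_pct: float
    per_ml_pct: float
    reference_volume_ml: float


def extraction_error(
    unaccounted_volumes_ml: Iterable[float], reference_volume_ml: float = 250.0
) -> ExtractionErrorSummary:
    """Error budget for the syringe water-extraction step.

    ``unaccounted_volumes_ml`` are per-trial shortfalls between the known
    fill volume and the total recovered; ``reference_volume_ml`` is the
    bench fill volume the trials used.
    """
    if reference_volume_ml <= 0:
        raise ValueError("reference_volume_ml must be > 0")
    vols = np.asarray(list(unaccounted_volumes_ml), dtype=float)
    if len(vols) == 0:
        raise ValueError("at least one unaccounted volume is required")
    if (vols < 0).any():
        raise ValueError("unaccounted volumes must be >= 0")
    pct = vols / reference_volume_ml * 100.0
    return ExtractionErrorSummary(
        per_sample_pct=tuple(pct),
        mean_pct=float(pct.mean()),
        max_pct=float(pct.max()),
        per_ml_pct=100.0 / reference_volume_ml,
        reference_volume_ml=reference_volume_ml,
    )
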