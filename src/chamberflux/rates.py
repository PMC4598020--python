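"""Reduction of chamber chemistry to metabolic rates.

Three quantities are derived from each sealed incubation cycle, always
after subtracting the mean drift of coral-free control chambers run in
parallel (the blank correction for water-column microbial activity):

* calcification ``G`` by the alkalinity-anomaly method — precipitating one
  mole of CaCO3 removes two equivalents of total alkalinity, so

      G = (dTA * rho * 0.5 * V) / (I_t * SA) / 1000      [mmol CaCO3 m-2 h-1]

  with dTA in umol kg-1 (start - end), rho the seawater density in kg L-1,
  V the chamber water volume in L, I_t the cycle duration in h and SA the
  colony surface area in m2;

* net photosynthesis ``P_N`` (light) and dark respiration ``R`` from the
  dissolved-oxygen drift,

      P_N, R = (dO2 * V) / (I_t * SA) / 1000             [mmol O2 m-2 h-1]

  with dO2 in umol L-1 (end - start); the dark-phase value is multiplied
  by -1 so respiration is reported positive;

* gross photosynthesis ``P_G = P_N + R``.

Daily rates are stepwise sums of the measured windows, ``sum(rate * dt)``.

Alkalinity is measured per kilogram and oxygen per litre; the density
factor that reconciles them appears only here, in the calcification
kernel — never at call sites.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd

from .config import RunConfig
from .core import IncubationInterval, seawater_density

__all__ = [
    "CorrectedDrift",
    "DailyIntegral",
    "RatesResult",
    "control_corrected_drift",
    "calcification_rate",
    "oxygen_flux_rate",
    "gross_photosynthesis",
    "integrate_daily",
    "process_incubation_set",
]


class CorrectedDrift(NamedTuple):
    """A treatment drift minus the mean of its matched control drifts."""

    value: float
    n_controls: int


def control_corrected_drift(
    treatment_drift: float, control_drifts: Sequence[float]
) -> CorrectedDrift:
    """Subtract the mean control (blank) drift from a treatment drift.

    Both drifts must be in the same concentration units (umol kg-1 for TA,
    umol L-1 for O2) and come from the same phase and sampling cycle.
    Raises if no controls are supplied: a missing blank is an error, never
    a silent zero-correction.
    """
    controls = list(control_drifts)
    if not controls:
        raise ValueError("no control drifts supplied; blank correction is mandatory")
    return CorrectedDrift(
        value=float(treatment_drift) - float(np.mean(controls)),
        n_controls=len(controls),
    )


def _calcification_kernel(dta, rho, V, I_t, SA):
    return (dta * rho * 0.5 * V) / (I_t * SA) / 1000.0


def _oxygen_kernel(do2, V, I_t, SA):
    return (do2 * V) / (I_t * SA) / 1000.0


def calcification_rate(interval: IncubationInterval, corrected_dTA: float) -> float:
    """Hourly calcification G (mmol CaCO3 m-2 h-1) for a treatment interval.

    ``corrected_dTA`` is the control-corrected alkalinity drawdown
    (start - end, umol kg-1).
    """
    if interval.role != "treatment":
        raise ValueError("calcification is defined only for treatment intervals")
    return float(
        _calcification_kernel(
            corrected_dTA, interval.rho, interval.V, interval.I_t, interval.SA
        )
    )


def oxygen_flux_rate(interval: IncubationInterval, corrected_dO2: float) -> float:
    """Hourly O2 flux (mmol O2 m-2 h-1) for a treatment interval.

    Light-phase output is net photosynthesis P_N; dark-phase output is
    sign-flipped so that respiration R is positive when O2 is consumed.
    """
    if interval.role != "treatment":
        raise ValueError("oxygen flux is defined only for treatment intervals")
    flux = _oxygen_kernel(corrected_dO2, interval.V, interval.I_t, interval.SA)
    if interval.phase == "dark":
        flux = -flux
    return float(flux)


def gross_photosynthesis(P_N, R):
    """Gross photosynthesis P_G = P_N + R (same units, same colony)."""
    return P_N + R


@dataclass(frozen=True)
class DailyIntegral:
    """A stepwise daily integral with its window coverage.

    ``value`` is sum(rate * dt) over the measured windows (mmol m-2 d-1).
    ``coverage_h`` is the summed window length; when it falls short of the
    declared photoperiod the integral covers only the measured part of the
    day — it is reported as-is unless mean-rate extrapolation was requested
    explicitly.
    """

    value: float
    coverage_h: float
    photoperiod_h: Optional[float] = None
    extrapolated: bool = False

    @property
    def coverage_fraction(self) -> Optional[float]:
        if self.photoperiod_h is None:
            return None
        return self.coverage_h / self.photoperiod_h


def integrate_daily(
    rates_by_window: Iterable,
    *,
    photoperiod_h: Optional[float] = None,
    extrapolate: bool = False,
) -> DailyIntegral:
    """Stepwise daily integration: sum of rate * dt over measured windows.

    ``rates_by_window`` holds either ``(rate, dt)`` pairs or
    ``(rate, start_h, end_h)`` triples; with triples, overlapping windows
    are rejected.  ``extrapolate=True`` scales the sum by
    photoperiod / coverage (a constant-mean-rate assumption) and marks the
    result; by default partial coverage is reported, never extrapolated.
    """
    pairs = []
    spans = []
    for w in rates_by_window:
        w = tuple(w)
        if len(w) == 2:
            rate, dt = w
        elif len(w) == 3:
            rate, t0, t1 = w
            dt = t1 - t0
            spans.append((float(t0), float(t1)))
        else:
            raise ValueError(f"window {w!r}: expected (rate, dt) or (rate, start, end)")
        if dt <= 0:
            raise ValueError(f"window {w!r}: duration must be > 0")
        pairs.append((float(rate), float(dt)))
    for (a0, a1), (b0, b1) in zip(sorted(spans), sorted(spans)[1:]):
        if b0 < a1 - 1e-12:
            raise ValueError(
                f"overlapping windows: [{a0}, {a1}] and [{b0}, {b1}]"
            )
    value = sum(r * dt for r, dt in pairs)
    coverage = sum(dt for _, dt in pairs)
    extrapolated = False
    if extrapolate:
        if photoperiod_h is None:
            raise ValueError("extrapolation requires a declared photoperiod")
        if coverage > 0 and coverage < photoperiod_h:
            value *= photoperiod_h / coverage
            extrapolated = True
    return DailyIntegral(
        value=value,
        coverage_h=coverage,
        photoperiod_h=photoperiod_h,
        extrapolated=extrapolated,
    )


# --------------------------------------------------------------------------
# batch reduction


@dataclass
class RatesResult:
    """Output of :func:`process_incubation_set`.

    Attributes
    ----------
    rates : DataFrame
        One row per treatment cycle: corrected drifts, G, and P_N or R,
        with provenance (controls used, density, volume source).
    summary : DataFrame
        One row per colony per day: hourly G_light, G_dark, P_N, R and
        P_G = P_N + R, averaged over that day's cycles per phase.
    daily : DataFrame
        Stepwise daily integrals per colony per day with coverage hours.
    anomalies : DataFrame
        Flagged-but-kept oddities: negative respiration before sign flip,
        cycles missing an end sample.
    provenance : dict
        Config hash and formula choices stamped on every written output.
    """

    rates: pd.DataFrame
    summary: pd.DataFrame
    daily: pd.DataFrame
    anomalies: pd.DataFrame
    provenance: dict = field(default_factory=dict)


_REQUIRED_SAMPLE_COLS = (
    "chamber_id",
    "role",
    "phase",
    "time_h",
    "TA",
    "O2",
    "salinity",
    "temperature",
)
_REQUIRED_COLONY_COLS = ("chamber_id", "colony_id", "species", "site", "surface_area_m2")


def _resolve_volume(group: pd.DataFrame, chamber_id: str, config: RunConfig):
    """Volume resolution order: per-cycle accounting > per-chamber config > error."""
    if {"extracted_volume_ml", "residual_volume_ml"} <= set(group.columns):
        ext = group["extracted_volume_ml"].dropna()
        res = group["residual_volume_ml"].dropna()
        if len(ext) and len(res):
            v = (float(ext.iloc[-1]) + float(res.iloc[-1])) / 1000.0
            if v <= 0:
                raise ValueError(f"chamber {chamber_id!r}: non-positive cycle volume")
            return v, "cycle"
    if chamber_id in config.chamber_volumes:
        return float(config.chamber_volumes[chamber_id]), "config:chamber"
    if config.default_volume_l is not None:
        return float(config.default_volume_l), "config:default"
    raise ValueError(
        f"chamber {chamber_id!r}: no volume accounting in the log and no "
        "configured volume"
    )


def process_incubation_set(
    samples: pd.DataFrame,
    colony_metadata: pd.DataFrame,
    config: Optional[RunConfig] = None,
) -> RatesResult:
    """Reduce a sample log to per-colony hourly and daily metabolic rates.

    ``samples`` holds one row per chamber per sampled time point (see
    :mod:`chamberflux.io` for the schema); ``colony_metadata`` maps
    treatment chambers to colony, species, site and surface area.  Every
    treatment cycle must have at least one same-phase control cycle in the
    same day (and site, under the default matching policy); otherwise the
    reduction fails rather than silently skipping the blank correction.
    """
    config = config or RunConfig()
    samples = samples.copy()
    missing = [c for c in _REQUIRED_SAMPLE_COLS if c not in samples.columns]
    if missing:
        raise ValueError(f"sample log missing required columns: {missing}")
    missing = [c for c in _REQUIRED_COLONY_COLS if c not in colony_metadata.columns]
    if missing:
        raise ValueError(f"colony metadata missing required columns: {missing}")
    for col, default in (("day", 0), ("cycle", 0)):
        if col not in samples.columns:
            samples[col] = default

    key_cols = ["chamber_id", "day", "cycle", "phase", "time_h"]
    dup = samples.duplicated(subset=key_cols)
    if dup.any():
        rows = samples.loc[dup, key_cols].to_dict("records")
        raise ValueError(f"duplicate (chamber, day, cycle, phase, time) rows: {rows}")

    meta = colony_metadata.set_index("chamber_id")
    if meta.index.has_duplicates:
        raise ValueError("colony metadata has duplicate chamber ids")

    has_site = "site" in samples.columns
    match_on_site = config.control_match == "day-phase-site" and has_site

    interval_rows = []
    anomaly_rows = []
    for (day, cycle, phase, chamber), grp in samples.groupby(
        ["day", "cycle", "phase", "chamber_id"], sort=True
    ):
        grp = grp.sort_values("time_h")
        if len(grp) < 2:
            anomaly_rows.append(
                {
                    "chamber_id": chamber,
                    "day": day,
                    "cycle": cycle,
                    "phase": phase,
                    "flag": "missing_end_sample",
                    "detail": f"only {len(grp)} sample(s) in cycle",
                }
            )
            continue
        start, end = grp.iloc[0], grp.iloc[-1]
        i_t = float(end["time_h"] - start["time_h"])
        if i_t <= 0:
            raise ValueError(
                f"chamber {chamber!r} day {day} cycle {cycle}: non-positive duration"
            )
        volume, vol_source = _resolve_volume(grp, chamber, config)
        s_mean = 0.5 * (float(start["salinity"]) + float(end["salinity"]))
        t_mean = 0.5 * (float(start["temperature"]) + float(end["temperature"]))
        if config.density_constant is not None:
            rho, rho_source = config.density_constant, "config:constant"
        else:
            rho, rho_source = seawater_density(s_mean, t_mean), config.density_formula
        interval_rows.append(
            {
                "chamber_id": chamber,
                "role": str(start["role"]),
                "day": day,
                "cycle": cycle,
                "phase": phase,
                "site": start["site"] if has_site else None,
                "start_h": float(start["time_h"]),
                "end_h": float(end["time_h"]),
                "I_t_h": i_t,
                "volume_l": volume,
                "volume_source": vol_source,
                "rho_kg_l": rho,
                "rho_source": rho_source,
                "dTA_raw": float(start["TA"] - end["TA"]),
                "dO2_raw": float(end["O2"] - start["O2"]),
            }
        )

    intervals = pd.DataFrame(interval_rows)
    anomalies = pd.DataFrame(
        anomaly_rows,
        columns=["chamber_id", "day", "cycle", "phase", "flag", "detail"],
    )
    provenance = {
        "config_hash": config.config_hash,
        "density": config.density_formula
        if config.density_constant is None
        else f"constant:{config.density_constant}",
        "solubility": config.solubility_formula,
        "control_match": "day-cycle-phase-site" if match_on_site else "day-cycle-phase",
    }
    empty_summary_cols = [
        "colony_id", "species", "site", "day",
        "G_light", "G_dark", "P_N", "R", "P_G",
    ]
    if intervals.empty or not (intervals["role"] == "treatment").any():
        warnings.warn("no treatment cycles found; returning empty rates tables")
        return RatesResult(
            rates=pd.DataFrame(),
            summary=pd.DataFrame(columns=empty_summary_cols),
            daily=pd.DataFrame(),
            anomalies=anomalies,
            provenance=provenance,
        )

    controls = intervals[intervals["role"] == "control"]
    treatments = intervals[intervals["role"] == "treatment"].copy()

    def _matched_controls(row):
        m = controls[
            (controls["day"] == row["day"])
            & (controls["cycle"] == row["cycle"])
            & (controls["phase"] == row["phase"])
        ]
        if match_on_site:
            m = m[m["site"] == row["site"]]
        return m

    rate_rows = []
    for _, row in treatments.iterrows():
        chamber = row["chamber_id"]
        if chamber not in meta.index:
            raise ValueError(f"treatment chamber {chamber!r} missing colony metadata")
        colony = meta.loc[chamber]
        sa = float(colony["surface_area_m2"])
        if not sa > 0:
            raise ValueError(f"colony {colony['colony_id']!r}: surface area must be > 0")
        ctrl = _matched_controls(row)
        if ctrl.empty:
            raise ValueError(
                f"no control cycle matches treatment chamber {chamber!r} "
                f"(day={row['day']}, cycle={row['cycle']}, phase={row['phase']})"
            )
        dta = control_corrected_drift(row["dTA_raw"], ctrl["dTA_raw"].tolist())
        do2 = control_corrected_drift(row["dO2_raw"], ctrl["dO2_raw"].tolist())
        g = _calcification_kernel(
            dta.value, row["rho_kg_l"], row["volume_l"], row["I_t_h"], sa
        )
        flux = _oxygen_kernel(do2.value, row["volume_l"], row["I_t_h"], sa)
        p_n = r = np.nan
        if row["phase"] == "light":
            p_n = flux
        else:
            r = -flux  # respiration reported positive
            if r < 0:
                anomaly_rows.append(
                    {
                        "chamber_id": chamber,
                        "day": row["day"],
                        "cycle": row["cycle"],
                        "phase": "dark",
                        "flag": "negative_respiration",
                        "detail": f"O2 rose in the dark (R={r:.4g})",
                    }
                )
        rate_rows.append(
            {
                "colony_id": colony["colony_id"],
                "species": colony["species"],
                "site": colony["site"],
                "chamber_id": chamber,
                "day": row["day"],
                "cycle": row["cycle"],
                "phase": row["phase"],
                "I_t_h": row["I_t_h"],
                "volume_l": row["volume_l"],
                "volume_source": row["volume_source"],
                "rho_kg_l": row["rho_kg_l"],
                "n_controls": dta.n_controls,
                "dTA": dta.value,
                "dO2": do2.value,
                "G": g,
                "P_N": p_n,
                "R": r,
            }
        )

    rates = pd.DataFrame(rate_rows)
    anomalies = pd.DataFrame(
        anomaly_rows,
        columns=["chamber_id", "day", "cycle", "phase", "flag", "detail"],
    )

    # hourly summary: per colony per day, averaged within phase
    def _summarise(g: pd.DataFrame) -> pd.Series:
        light = g[g["phase"] == "light"]
        dark = g[g["phase"] == "dark"]
        p_n = light["P_N"].mean() if len(light) else np.nan
        r = dark["R"].mean() if len(dark) else np.nan
        return pd.Series(
            {
                "species": g["species"].iloc[0],
                "site": g["site"].iloc[0],
                "G_light": light["G"].mean() if len(light) else np.nan,
                "G_dark": dark["G"].mean() if len(dark) else np.nan,
                "P_N": p_n,
                "R": r,
                "P_G": gross_photosynthesis(p_n, r),
            }
        )

    summary = (
        rates.groupby(["colony_id", "day"], sort=True)
        .apply(_summarise, include_groups=False)
        .reset_index()
    )

    daily_rows = []
    for (colony, day), g in rates.groupby(["colony_id", "day"], sort=True):
        light = g[g["phase"] == "light"]
        dark = g[g["phase"] == "dark"]
        pn_int = integrate_daily(
            zip(light["P_N"], light["I_t_h"]),
            photoperiod_h=config.photoperiod_h,
            extrapolate=config.extrapolate_daily,
        )
        r_int = integrate_daily(
            zip(dark["R"], dark["I_t_h"]),
            photoperiod_h=24.0 - config.photoperiod_h,
            extrapolate=config.extrapolate_daily,
        )
        gl_int = integrate_daily(zip(light["G"], light["I_t_h"]))
        gd_int = integrate_daily(zip(dark["G"], dark["I_t_h"]))
        daily_rows.append(
            {
                "colony_id": colony,
                "day": day,
                "P_N_daily": pn_int.value,
                "R_daily": r_int.value,
                "G_light_daily": gl_int.value,
                "G_dark_daily": gd_int.value,
                "light_coverage_h": pn_int.coverage_h,
                "dark_coverage_h": r_int.coverage_h,
                "extrapolated": pn_int.extrapolated or r_int.extrapolated,
            }
        )
    daily = pd.DataFrame(daily_rows)

    return RatesResult(
        rates=rates,
        summary=summary,
        daily=daily,
        anomalies=anomalies,
        provenance=provenance,
    )
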