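"""Domain types, unit conventions and seawater physical properties.

Units used throughout the package:

* total alkalinity (TA): umol kg-1
* dissolved oxygen (O2): umol L-1
* salinity: practical salinity (dimensionless)
* temperature: degrees Celsius
* chamber water volume: litres
* colony surface area: m2
* time: fractional hours since incubation start
* seawater density: kg L-1

The asymmetry between per-kilogram alkalinity and per-litre oxygen is
resolved once, in :mod:`chamberflux.rates`, via the seawater density.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Optional

__all__ = [
    "Role",
    "Phase",
    "WaterSample",
    "VolumeAccounting",
    "IncubationInterval",
    "SeawaterState",
    "seawater_density",
    "oxygen_saturation_concentration",
    "saturation_percent",
    "drift",
]

Role = Literal["treatment", "control"]
Phase = Literal["light", "dark"]

_ROLES = ("treatment", "control")
_PHASES = ("light", "dark")


def _check_range(name: str, value: float, lo: float, hi: float) -> None:
    if not (lo <= value <= hi):
        raise ValueError(f"{name}={value!r} outside valid range [{lo}, {hi}]")


@dataclass(frozen=True)
class WaterSample:
    """One chamber x time-point water chemistry observation.

    Parameters
    ----------
    chamber_id : str
        Identifier of the incubation chamber the aliquot was drawn from.
    role : {"treatment", "control"}
        Whether the chamber encloses a colony or is a seawater blank.
    phase : {"light", "dark"}
        Illumination state of the incubation cycle.
    time_h : float
        Hours since the start of the incubation.
    TA : float
        Total alkalinity, umol kg-1.
    O2 : float
        Dissolved oxygen, umol L-1.
    salinity : float
        Practical salinity.
    temperature : float
        Water temperature, degrees C.
    pH : float, optional
        pH on the total scale, carried as metadata only.
    """

    chamber_id: str
    role: Role
    phase: Phase
    time_h: float
    TA: float
    O2: float
    salinity: float
    temperature: float
    pH: Optional[float] = None

    def __post_init__(self) -> None:
        if self.role not in _ROLES:
            raise ValueError(f"role={self.role!r}: must be one of {_ROLES}")
        if self.phase not in _PHASES:
            raise ValueError(f"phase={self.phase!r}: must be one of {_PHASES}")
        if self.TA <= 0:
            raise ValueError(f"TA={self.TA!r}: total alkalinity must be positive")
        if self.O2 < 0:
            raise ValueError(f"O2={self.O2!r}: dissolved oxygen must be >= 0")
        _check_range("salinity", self.salinity, 0.0, 45.0)
        if self.time_h < 0:
            raise ValueError(f"time_h={self.time_h!r}: must be >= 0")


@dataclass(frozen=True)
class VolumeAccounting:
    """Water-volume bookkeeping for one sampled incubation cycle.

    The chamber volume is reconstructed as the extracted aliquot plus the
    residual volume emptied from the chamber afterwards.  ``unaccounted_volume``
    records any bench-test shortfall between a known fill volume and the total
    recovered, and feeds the extraction error budget.
    All volumes in litres.
    """

    extracted_volume: float
    residual_volume: float
    unaccounted_volume: float = 0.0

    def __post_init__(self) -> None:
        for name in ("extracted_volume", "residual_volume", "unaccounted_volume"):
            v = getattr(self, name)
            if v < 0:
                raise ValueError(f"{name}={v!r}: must be >= 0")
        if self.total <= 0:
            raise ValueError("total chamber volume (extracted + residual) must be > 0")

    @property
    def total(self) -> float:
        """Chamber water volume, litres."""
        return self.extracted_volume + self.residual_volume


@dataclass(frozen=True)
class IncubationInterval:
    """A paired start/end sample: the unit on which rates are computed.

    ``SA`` (colony surface area, m2) is required for treatment chambers and
    must be absent for controls, which contain no colony.  ``rho`` is the
    seawater density (kg L-1) used to convert per-kilogram alkalinity to
    per-litre units.
    """

    chamber_id: str
    role: Role
    phase: Phase
    start: WaterSample
    end: WaterSample
    V: float
    rho: float
    SA: Optional[float] = None

    def __post_init__(self) -> None:
        if self.start.chamber_id != self.end.chamber_id:
            raise ValueError(
                f"start/end chamber mismatch: {self.start.chamber_id!r} vs "
                f"{self.end.chamber_id!r}"
            )
        if self.start.phase != self.end.phase:
            raise ValueError("start and end samples must share a phase")
        if self.end.time_h <= self.start.time_h:
            raise ValueError("end.time_h must exceed start.time_h")
        if self.V <= 0:
            raise ValueError(f"V={self.V!r}: chamber volume must be > 0")
        _check_range("rho", self.rho, 0.99, 1.05)
        if self.role == "treatment":
            if self.SA is None or self.SA <= 0:
                raise ValueError("treatment interval requires SA > 0 (m2)")
        elif self.SA is not None:
            raise ValueError("control interval must not carry a surface area")

    @property
    def I_t(self) -> float:
        """Incubation duration, hours."""
        return self.end.time_h - self.start.time_h

    @property
    def mean_salinity(self) -> float:
        return 0.5 * (self.start.salinity + self.end.salinity)

    @property
    def mean_temperature(self) -> float:
        return 0.5 * (self.start.temperature + self.end.temperature)


@dataclass(frozen=True)
class SeawaterState:
    """Physical state of the incubation water: density and O2 solubility."""

    salinity: float
    temperature: float
    rho: float
    O2_sat: float

    @classmethod
    def from_conditions(cls, salinity: float, temperature: float) -> "SeawaterState":
        return cls(
            salinity=salinity,
            temperature=temperature,
            rho=seawater_density(salinity, temperature),
            O2_sat=oxygen_saturation_concentration(salinity, temperature),
        )


def _validate_st(salinity: float, temperature: float) -> None:
    if not (0.0 <= salinity <= 45.0):
        raise ValueError(f"salinity={salinity!r} outside valid range [0, 45]")
    if not (-2.0 <= temperature <= 40.0):
        raise ValueError(f"temperature={temperature!r} outside valid range [-2, 40] degC")


def seawater_density(salinity: float, temperature: float) -> float:
    """One-atmosphere seawater density, kg L-1.

    International one-atmosphere equation of state of seawater (EOS-80,
    Millero & Poisson 1981): a polynomial in practical salinity and
    temperature (ITS scale, degC), valid for S 0-42 and T -2-40 degC.
    Pressure dependence is ignored — the chambers sit within a few metres
    of the surface.
    """
    _validate_st(salinity, temperature)
    t = temperature
    s = salinity
    rho_w = (
        999.842594
        + 6.793952e-2 * t
        - 9.095290e-3 * t**2
        + 1.001685e-4 * t**3
        - 1.120083e-6 * t**4
        + 6.536332e-9 * t**5
    )
    a = (
        0.824493
        - 4.0899e-3 * t
        + 7.6438e-5 * t**2
        - 8.2467e-7 * t**3
        + 5.3875e-9 * t**4
    )
    b = -5.72466e-3 + 1.0227e-4 * t - 1.6546e-6 * t**2
    rho = rho_w + a * s + b * s**1.5 + 4.8314e-4 * s**2
    return rho / 1000.0  # kg m-3 -> kg L-1


# Benson & Krause solubility coefficients refit by Garcia & Gordon (1992),
# umol kg-1 at one atmosphere of water-saturated air.
_GG_A = (5.80871, 3.20291, 4.17887, 5.10006, -9.86643e-2, 3.80369)
_GG_B = (-7.01577e-3, -7.70028e-3, -1.13864e-2, -9.51519e-3)
_GG_C0 = -2.75915e-7


def oxygen_saturation_concentration(salinity: float, temperature: float) -> float:
    """Equilibrium O2 solubility, umol L-1.

    Garcia & Gordon (1992) fit to the Benson & Krause data, evaluated in
    umol kg-1 and converted to umol L-1 with :func:`seawater_density` so
    that saturation states are directly comparable to the probe readings.
    """
    _validate_st(salinity, temperature)
    ts = math.log((298.15 - temperature) / (273.15 + temperature))
    ln_c = sum(a * ts**i for i, a in enumerate(_GG_A))
    ln_c += salinity * sum(b * ts**i for i, b in enumerate(_GG_B))
    ln_c += _GG_C0 * salinity**2
    per_kg = math.exp(ln_c)
    return per_kg * seawater_density(salinity, temperature)


def saturation_percent(O2: float, salinity: float, temperature: float) -> float:
    """Dissolved O2 as percent of the equilibrium solubility at (S, T)."""
    if O2 < 0:
        raise ValueError(f"O2={O2!r}: must be >= 0")
    return 100.0 * O2 / oxygen_saturation_concentration(salinity, temperature)


def drift(start: WaterSample, end: WaterSample, analyte: Literal["TA", "O2"]) -> float:
    """Signed concentration change over an incubation interval.

    Sign conventions match the way rates are reported downstream:

    * ``TA``: start - end (umol kg-1), so CaCO3 precipitation, which draws
      down alkalinity by two equivalents per mole, yields a positive value;
    * ``O2``: end - start (umol L-1), so net photosynthesis in the light
      yields a positive value and dark respiration a negative one.
    """
    if start.chamber_id != end.chamber_id:
        raise ValueError(
            f"chamber mismatch: {start.chamber_id!r} vs {end.chamber_id!r}"
        )
    if start.phase != end.phase:
        raise ValueError(f"phase mismatch: {start.phase!r} vs {end.phase!r}")
    if end.time_h <= start.time_h:
        raise ValueError("end sample must be later than start sample")
    if analyte == "TA":
        return start.TA - end.TA
    if analyte == "O2":
        return end.O2 - start.O2
    raise ValueError(f"analyte={analyte!r}: must be 'TA' or 'O2'")
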