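"""Well-mixed single-zone indoor-air model with pulsed emissions.

A volatile release into a ventilated room of volume ``V`` (m³) with outdoor
airflow ``Q`` (m³/min) is modelled under the spatially well-mixed assumption:
an instantaneous release of mass ``m`` raises the room concentration by
``m/V`` everywhere at once, and ventilation removes mass first-order at the
air-change rate ``k = Q/V``.  For a train of pulses ``(t_j, m_j)`` the
concentration is the superposition of decaying exponentials::

    C(t) = sum_{t_j <= t}  (m_j / V) * exp(-k * (t - t_j))

Times at the interface are hours; the air-change rate is per minute
internally because ventilation rates are conventionally quoted in m³/min.
Concentrations are g/m³ except where a function documents mg/m³.

Evaporation of the released ethanol is treated as instantaneous: measured
evaporation half-lives of gel films on skin (~11 s) are negligible against
the hours-scale pulse spacing of hand-rub scenarios.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, model_validator

__all__ = [
    "RoomSpec",
    "EmissionPulse",
    "EmissionSchedule",
    "AirProfile",
    "pulse_emission_mass",
    "concentration_at",
    "concentration_series",
    "window_mean",
]


class RoomSpec(BaseModel):
    """Single-zone room geometry and ventilation.

    Parameters
    ----------
    volume : float
        Room air volume in m³ (> 0).
    vent_rate : float
        Outdoor airflow in m³/min (>= 0).  Zero means a sealed room in
        which emitted mass is conserved.
    """

    model_config = ConfigDict(extra="forbid", frozen=True)

    volume: float = Field(gt=0)
    vent_rate: float = Field(ge=0)

    @property
    def loss_rate_per_h(self) -> float:
        """First-order air-change loss rate Q/V, converted to h⁻¹."""
        return self.vent_rate / self.volume * 60.0


class EmissionPulse(BaseModel):
    """One instantaneous mass release: `mass` g of ethanol at `time` h."""

    model_config = ConfigDict(extra="forbid", frozen=True)

    time: float = Field(ge=0)
    mass: float = Field(ge=0)


class EmissionSchedule(BaseModel):
    """Ordered train of instantaneous releases with strictly increasing times.

    Simultaneous releases must be merged into a single pulse; use
    :meth:`from_pairs` to build a schedule from possibly-coincident events.
    """

    model_config = ConfigDict(extra="forbid", frozen=True)

    pulses: tuple[EmissionPulse, ...] = ()

    @model_validator(mode="after")
    def _strictly_increasing(self) -> "EmissionSchedule":
        times = [p.time for p in self.pulses]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError(
                "pulse times must be strictly increasing; merge simultaneous "
                "releases into one pulse (see EmissionSchedule.from_pairs)"
            )
        return self

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[float, float]]) -> "EmissionSchedule":
        """Build a schedule from (time h, mass g) pairs, merging coincident times."""
        merged: dict[float, float] = {}
        for t, m in pairs:
            merged[t] = merged.get(t, 0.0) + m
        return cls(
            pulses=tuple(
                EmissionPulse(time=t, mass=m) for t, m in sorted(merged.items())
            )
        )

    @property
    def times(self) -> np.ndarray:
        return np.array([p.time for p in self.pulses])

    @property
    def masses(self) -> np.ndarray:
        return np.array([p.mass for p in self.pulses])

    @property
    def total_mass(self) -> float:
        return float(sum(p.mass for p in self.pulses))


@dataclass
class AirProfile:
    """Sampled air-concentration time series.

    Attributes
    ----------
    times : ndarray
        Strictly increasing sample grid, h.
    concentrations : ndarray
        Ethanol concentration at each grid point, g/m³.  At a pulse time the
        stored value is the post-jump value.
    windows : list of (t_start, t_end, mean_mg_m3), optional
        Time-weighted window means in mg/m³, if computed.
    """

    times: np.ndarray
    concentrations: np.ndarray
    windows: list[tuple[float, float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        if self.times.shape != self.concentrations.shape:
            raise ValueError("times and concentrations must have equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.concentrations < 0):
            raise ValueError("concentrations must be non-negative")


def pulse_emission_mass(
    n_frictions: float,
    volume_per_friction_ml: float,
    ethanol_mass_fraction: float,
    density_g_per_ml: float,
) -> float:
    """Ethanol mass (g) released by a batch of hand-rub frictions.

    ``n × v_mL × ρ × w``: each friction dispenses ``v_mL`` of gel of density
    ``ρ`` g/mL containing ethanol at mass fraction ``w``.

    >>> pulse_emission_mass(30, 3, 0.70, 0.8)
    50.4
    """
    for name, val in (
        ("n_frictions", n_frictions),
        ("volume_per_friction_ml", volume_per_friction_ml),
        ("ethanol_mass_fraction", ethanol_mass_fraction),
        ("density_g_per_ml", density_g_per_ml),
    ):
        if val < 0:
            raise ValueError(f"{name} must be non-negative, got {val}")
    if ethanol_mass_fraction > 1:
        raise ValueError("ethanol_mass_fraction must be <= 1")
    return n_frictions * volume_per_friction_ml * density_g_per_ml * ethanol_mass_fraction


def concentration_at(
    schedule: EmissionSchedule, room: RoomSpec, t: float | np.ndarray
) -> float | np.ndarray:
    """Room concentration (g/m³) at time ``t`` h, post-jump at pulse times.

    Superposition of the decaying contribution of every pulse released at or
    before ``t``.  Accepts a scalar or an array of times.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("t must be non-negative")
    k = room.loss_rate_per_h
    out = np.zeros_like(t_arr, dtype=float)
    for p in schedule.pulses:
        active = t_arr >= p.time
        out[active] += p.mass / room.volume * np.exp(-k * (t_arr[active] - p.time))
    return float(out) if np.isscalar(t) or t_arr.ndim == 0 else out


def concentration_series(
    schedule: EmissionSchedule, room: RoomSpec, t_grid: Sequence[float]
) -> AirProfile:
    """Evaluate the closed-form solution on a strictly increasing grid."""
    grid = np.asarray(t_grid, dtype=float)
    if grid.ndim != 1 or grid.size == 0:
        raise ValueError("t_grid must be a non-empty 1-D sequence")
    if np.any(np.diff(grid) <= 0):
        raise ValueError("t_grid must be strictly increasing")
    conc = concentration_at(schedule, room, grid)
    return AirProfile(times=grid, concentrations=np.asarray(conc))


def window_mean(
    schedule: EmissionSchedule, room: RoomSpec, t_start: float, t_end: float
) -> float:
    """Time-weighted mean concentration over ``[t_start, t_end)``, in mg/m³.

    Computed by exact integration of the piecewise-exponential solution:
    a pulse ``(t_j, m_j)`` overlapping the window on ``[a, b]`` contributes
    ``(m_j/V) (e^{-k(a-t_j)} - e^{-k(b-t_j)}) / k`` to the integral
    (``(m_j/V)(b-a)`` in the unventilated limit k → 0).
    """
    if t_end <= t_start:
        raise ValueError("t_end must exceed t_start")
    if t_start < 0:
        raise ValueError("window must not start before t = 0")
    k = room.loss_rate_per_h
    total = 0.0
    for p in schedule.pulses:
        if p.time >= t_end:
            continue
        lo = max(t_start, p.time)
        amp = p.mass / room.volume
        if k == 0.0:
            total += amp * (t_end - lo)
        else:
            # expm1 keeps the integral stable as k -> 0 (near-sealed rooms)
            total += (
                amp
                * math.exp(-k * (lo - p.time))
                * -math.expm1(-k * (t_end - lo))
                / k
            )
    return total / (t_end - t_start) * 1000.0
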