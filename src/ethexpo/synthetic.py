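"""Seeded generators of randomized exposure scenarios and parameter sets.

Structural coverage for property testing: the sampled objects share the
analysis assumptions (pulse-train emissions, first-order room loss,
piecewise-constant inhalation) but randomize room size, ventilation, crowd
size, rub frequency, gel strength and body weight over broad plausible
ranges.  Sampling is uniform within ranges — the goal is coverage of the
model's input space, not population realism.
"""

from __future__ import annotations

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .pbpk import TISSUES, PBPKParameters
from .scenario import TSDDScenario
from .room import RoomSpec

__all__ = ["ScenarioDistribution", "sample_scenario", "perturb_parameters"]

Range = tuple[float, float]


class ScenarioDistribution(BaseModel):
    """Uniform sampling ranges for scenario and subject properties."""

    model_config = ConfigDict(extra="forbid", frozen=True)

    room_volume_m3: Range = (50.0, 500.0)
    vent_rate_m3_per_min: Range = (0.0, 5.0)
    persons: tuple[int, int] = (1, 50)
    frictions_per_day: tuple[int, int] = (1, 10)
    gel_ml_per_friction: Range = (0.5, 5.0)
    ethanol_mass_fraction: Range = (0.4, 0.9)
    body_weight_kg: Range = (40.0, 110.0)
    days: tuple[int, int] = (1, 3)

    @model_validator(mode="after")
    def _ordered(self) -> "ScenarioDistribution":
        for name in type(self).model_fields:
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name}: lower bound {lo} exceeds upper {hi}")
        if self.room_volume_m3[0] <= 0 or self.gel_ml_per_friction[0] <= 0:
            raise ValueError("room volume and gel volume must be positive")
        if self.vent_rate_m3_per_min[0] < 0:
            raise ValueError("ventilation rate must be non-negative")
        if not (0 < self.ethanol_mass_fraction[0] and self.ethanol_mass_fraction[1] <= 1):
            raise ValueError("ethanol mass fraction range must lie in (0, 1]")
        return self


def sample_scenario(
    dist: ScenarioDistribution, seed: int
) -> tuple[TSDDScenario, PBPKParameters]:
    """Draw one (scenario, subject) pair; deterministic for a given seed."""
    rng = np.random.default_rng(seed)
    n_frictions = int(rng.integers(dist.frictions_per_day[0], dist.frictions_per_day[1] + 1))
    n_days = int(rng.integers(dist.days[0], dist.days[1] + 1))
    exposure_hours = 8.0
    # distinct event times on a 0.25 h lattice inside the working day
    lattice = np.arange(0.0, exposure_hours - 0.5, 0.25)
    event_times = np.sort(rng.choice(lattice, size=n_frictions, replace=False))
    scenario = TSDDScenario(
        room=RoomSpec(
            volume=float(rng.uniform(*dist.room_volume_m3)),
            vent_rate=float(rng.uniform(*dist.vent_rate_m3_per_min)),
        ),
        persons=int(rng.integers(dist.persons[0], dist.persons[1] + 1)),
        frictions_per_person_per_day=n_frictions,
        gel_ml_per_friction=float(rng.uniform(*dist.gel_ml_per_friction)),
        ethanol_mass_fraction=float(rng.uniform(*dist.ethanol_mass_fraction)),
        event_times_day=tuple(float(t) for t in event_times),
        day_starts=tuple(24.0 * d for d in range(n_days)),
        exposure_hours_per_day=exposure_hours,
    )
    params = PBPKParameters(body_weight=float(rng.uniform(*dist.body_weight_kg)))
    return scenario, params


def perturb_parameters(
    params: PBPKParameters, relative_sd: float, seed: int
) -> PBPKParameters:
    """Multiplicative log-normal jitter of the physiological parameters.

    Log-normal noise (sigma = ``relative_sd`` on the log scale) preserves
    positivity; flow fractions are renormalized to sum to exactly 1 and
    volume fractions to their original total, so the perturbed set passes
    the same invariants.  The absorbed fraction is capped at 1.
    """
    if not 0.0 <= relative_sd <= 0.5:
        raise ValueError("relative_sd must be in [0, 0.5]")
    if relative_sd == 0.0:
        return params
    rng = np.random.default_rng(seed)

    def jitter(x: float) -> float:
        return float(x * rng.lognormal(0.0, relative_sd))

    flows = {i: jitter(params.flow_fractions[i]) for i in TISSUES}
    flow_sum = sum(flows.values())
    flows = {i: v / flow_sum for i, v in flows.items()}

    vols = {i: jitter(params.volume_fractions[i]) for i in TISSUES}
    vol_total = sum(params.volume_fractions.values())
    vol_sum = sum(vols.values())
    vols = {i: v / vol_sum * vol_total for i, v in vols.items()}
    # blood must fit in the body-volume budget left by the tissues
    blood_cap = 0.999 * (1.0 - vol_total)

    return PBPKParameters(
        body_weight=jitter(params.body_weight),
        cardiac_output_coef=jitter(params.cardiac_output_coef),
        alveolar_vent_coef=jitter(params.alveolar_vent_coef),
        absorbed_fraction=min(1.0, jitter(params.absorbed_fraction)),
        flow_fractions=flows,
        volume_fractions=vols,
        blood_volume_fraction=min(blood_cap, jitter(params.blood_volume_fraction)),
        partition_air={k: jitter(v) for k, v in params.partition_air.items()},
        vmax_coef=jitter(params.vmax_coef),
        km=jitter(params.km),
        uptake_model=params.uptake_model,
    )
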