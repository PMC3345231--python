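"""Config-file and tabular I/O.

All configuration is plain-text YAML key-value files validated through the
pydantic domain types (unknown keys are rejected with the offending key
named); exposure profiles and trajectories travel as CSV.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, ValidationError

from .pbpk import ExposureProfile, PBPKParameters, PBPKTrajectory
from .room import AirProfile, EmissionSchedule, RoomSpec
from .scenario import TSDDScenario

__all__ = [
    "ConfigError",
    "AirConfig",
    "load_yaml",
    "load_air_config",
    "load_scenario",
    "load_parameters",
    "default_parameters",
    "default_scenario",
    "load_exposure_csv",
    "save_exposure_csv",
    "save_air_profile",
    "save_trajectory",
]


class ConfigError(ValueError):
    """A config file could not be parsed or failed validation."""


class AirConfig(BaseModel):
    """Flat scenario config for the stand-alone room-air command."""

    model_config = ConfigDict(extra="forbid", frozen=True)

    room_volume_m3: float
    vent_rate_m3_per_min: float
    friction_times_h: tuple[float, ...]
    frictions_per_event: int
    gel_ml_per_friction: float
    ethanol_mass_fraction: float
    gel_density_g_per_ml: float

    def room(self) -> RoomSpec:
        return RoomSpec(volume=self.room_volume_m3, vent_rate=self.vent_rate_m3_per_min)

    def schedule(self) -> EmissionSchedule:
        from .room import pulse_emission_mass

        mass = pulse_emission_mass(
            self.frictions_per_event,
            self.gel_ml_per_friction,
            self.ethanol_mass_fraction,
            self.gel_density_g_per_ml,
        )
        return EmissionSchedule.from_pairs((t, mass) for t in self.friction_times_h)


def load_yaml(path: str | Path) -> dict:
    """Parse a YAML mapping, reporting line context on malformed input."""
    text = Path(path).read_text()
    try:
        data = yaml.safe_load(text)
    except yaml.YAMLError as exc:  # yaml errors carry line/column marks
        raise ConfigError(f"{path}: malformed config: {exc}") from exc
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: expected a key-value mapping at top level")
    return data


def _validated(model, data: dict, path) -> BaseModel:
    try:
        return model.model_validate(data)
    except ValidationError as exc:
        raise ConfigError(f"{path}: {exc}") from exc


def load_air_config(path: str | Path) -> AirConfig:
    return _validated(AirConfig, load_yaml(path), path)


def load_scenario(path: str | Path) -> TSDDScenario:
    return _validated(TSDDScenario, load_yaml(path), path)


def load_parameters(path: str | Path) -> PBPKParameters:
    return _validated(PBPKParameters, load_yaml(path), path)


def _packaged(name: str) -> Path:
    return resources.files("ethexpo").joinpath("data", name)


def default_parameters() -> PBPKParameters:
    """The packaged reference human parameter set (`ethanol_human_table1`)."""
    return load_parameters(_packaged("ethanol_human_table1.yaml"))


def default_scenario() -> TSDDScenario:
    """The packaged worst-case two-day classroom scenario."""
    return load_scenario(_packaged("tsdd_classroom.yaml"))


def load_exposure_csv(path: str | Path) -> ExposureProfile:
    """Read segments from CSV columns t_start_h, t_end_h, conc_mg_per_m3."""
    df = pd.read_csv(path)
    required = {"t_start_h", "t_end_h", "conc_mg_per_m3"}
    if not required.issubset(df.columns):
        raise ConfigError(f"{path}: exposure CSV needs columns {sorted(required)}")
    try:
        return ExposureProfile(
            segments=tuple(
                (float(r.t_start_h), float(r.t_end_h), float(r.conc_mg_per_m3))
                for r in df.itertuples()
            )
        )
    except ValidationError as exc:
        raise ConfigError(f"{path}: {exc}") from exc


def save_exposure_csv(exposure: ExposureProfile, path: str | Path) -> None:
    pd.DataFrame(
        exposure.segments, columns=["t_start_h", "t_end_h", "conc_mg_per_m3"]
    ).to_csv(path, index=False)


def save_air_profile(profile: AirProfile, out_dir: str | Path, stem: str = "air") -> None:
    """Write the time series and (if present) the window table as CSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        {"time_h": profile.times, "conc_g_per_m3": profile.concentrations}
    ).to_csv(out / f"{stem}_series.csv", index=False)
    if profile.windows:
        pd.DataFrame(
            profile.windows, columns=["t_start_h", "t_end_h", "mean_mg_per_m3"]
        ).to_csv(out / f"{stem}_windows.csv", index=False)


def save_trajectory(traj: PBPKTrajectory, path: str | Path) -> None:
    traj.to_frame().to_csv(path, index=False)
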