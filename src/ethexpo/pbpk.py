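"""Six-compartment flow-limited PBPK model of inhaled ethanol.

Compartments: blood plus five perfused tissues (fat, liver, rapidly
perfused, slowly perfused, brain) connected by cardiac output.  Each tissue
is perfusion-limited: venous blood leaving tissue *i* is in equilibrium with
the tissue at the tissue:blood partition coefficient ``P_i``, so

    dA_i/dt = Q_i * (C_b - C_i / P_i)                      [mg/h]

with ``C_i = A_i / V_i``.  The liver additionally clears ethanol by
saturable Michaelis–Menten metabolism acting on the liver-exit (venous)
concentration ``C_vL = C_L / P_L``::

    rate = Vmax * C_vL / (Km + C_vL)

Blood closes the loop and receives the inhaled input::

    dA_b/dt = sum_i Q_i * C_i/P_i  -  QC * C_b  +  uptake(t)

Two inhalation formulations are provided (``uptake_model``):

``fractional`` (default)
    Net systemic uptake ``F * QP * C_inh(t) / 1000`` mg/h, where ``F`` is
    the empirical net fractional airway uptake (0.62 by default) and the
    division by 1000 converts the mg/m³ air concentration to mg/L.  ``F``
    is net of exhaled back-flux, so no explicit exhalation term appears and
    the blood:air partition coefficient is inert.

``alveolar``
    Conventional alveolar equilibration, ``QP * (C_inh/1000 - C_b/P_b:air)``;
    with ethanol's very high blood:air coefficient (2280) this is nearly
    complete absorption and predicts higher uptake than ``fractional``.

Flows, ventilation and Vmax scale allometrically as ``coef × BW^0.75``;
compartment volumes as ``fraction × BW`` with the 1 kg ≈ 1 L convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, model_validator
from scipy.integrate import solve_ivp

__all__ = [
    "TISSUES",
    "PBPKParameters",
    "ScaledParameters",
    "ExposureProfile",
    "PBPKTrajectory",
    "scale_parameters",
    "derivatives",
    "simulate",
    "blood_concentration_at",
]

#: Perfused-tissue compartments, in state-vector order after blood.
TISSUES: tuple[str, ...] = ("fat", "liver", "rapid", "slow", "brain")

ALLOMETRIC_EXPONENT = 0.75


def _tissue_dict(values: Mapping[str, float], what: str) -> dict[str, float]:
    missing = set(TISSUES) - set(values)
    extra = set(values) - set(TISSUES)
    if missing or extra:
        raise ValueError(f"{what} must have exactly keys {TISSUES}; "
                         f"missing {sorted(missing)}, unexpected {sorted(extra)}")
    return {k: float(values[k]) for k in TISSUES}


class PBPKParameters(BaseModel):
    """Unscaled human parameter set for the inhaled-ethanol model.

    Defaults are the reference 70 kg adult set: allometric coefficients of
    18 (L/h)/kg^0.75 for both cardiac output and alveolar ventilation, net
    fractional airway uptake 0.62, flow fractions summing to 1, volume
    fractions summing to 0.91 of body volume (the remainder is blood,
    default fraction 0.079, and unperfused residual mass), tissue:air
    partition coefficients, and hepatic Vmax 359.5 (mg/h)/kg^0.75 with
    Km 82.1 mg/L.
    """

    model_config = ConfigDict(extra="forbid", frozen=True)

    body_weight: float = Field(default=70.0, gt=0, description="kg")
    cardiac_output_coef: float = Field(default=18.0, gt=0, description="(L/h)/kg^0.75")
    alveolar_vent_coef: float = Field(default=18.0, gt=0, description="(L/h)/kg^0.75")
    absorbed_fraction: float = Field(default=0.62, gt=0, le=1)
    flow_fractions: dict[str, float] = Field(
        default={"fat": 0.05, "liver": 0.25, "rapid": 0.39, "slow": 0.19, "brain": 0.12}
    )
    volume_fractions: dict[str, float] = Field(
        default={"fat": 0.213, "liver": 0.0257, "rapid": 0.0443, "slow": 0.607, "brain": 0.02}
    )
    blood_volume_fraction: float = Field(default=0.079, gt=0, lt=1)
    partition_air: dict[str, float] = Field(
        default={"blood": 2280.0, "fat": 226.0, "liver": 1730.0,
                 "rapid": 2030.0, "slow": 1710.0, "brain": 1870.0}
    )
    vmax_coef: float = Field(default=359.5, gt=0, description="(mg/h)/kg^0.75")
    km: float = Field(default=82.1, gt=0, description="mg/L")
    uptake_model: Literal["fractional", "alveolar"] = "fractional"

    @model_validator(mode="after")
    def _validate_fractions(self) -> "PBPKParameters":
        flows = _tissue_dict(self.flow_fractions, "flow_fractions")
        vols = _tissue_dict(self.volume_fractions, "volume_fractions")
        if abs(sum(flows.values()) - 1.0) > 1e-6:
            raise ValueError(
                f"flow_fractions must sum to 1, got {sum(flows.values()):.6f}"
            )
        if any(v <= 0 for v in list(flows.values()) + list(vols.values())):
            raise ValueError("flow and volume fractions must be positive")
        if sum(vols.values()) + self.blood_volume_fraction > 1.0 + 1e-9:
            raise ValueError("tissue volume fractions plus blood exceed body volume")
        part = dict(self.partition_air)
        if set(part) != set(TISSUES) | {"blood"}:
            raise ValueError(
                f"partition_air must have keys {sorted(set(TISSUES) | {'blood'})}"
            )
        if any(v <= 0 for v in part.values()):
            raise ValueError("partition coefficients must be positive")
        return self


@dataclass(frozen=True)
class ScaledParameters:
    """Body-weight-scaled parameters in working units (L/h, L, mg/h)."""

    cardiac_output: float            # L/h
    alveolar_ventilation: float      # L/h
    tissue_flows: dict[str, float]   # L/h
    tissue_volumes: dict[str, float]  # L
    blood_volume: float              # L
    vmax: float                      # mg/h
    km: float                        # mg/L
    absorbed_fraction: float
    partition_blood: dict[str, float]  # tissue:blood
    partition_air_blood: float         # blood:air
    uptake_model: str


def scale_parameters(params: PBPKParameters) -> ScaledParameters:
    """Apply allometric scaling (BW^0.75 for flows and Vmax, BW for volumes).

    Tissue:blood partition coefficients are derived as the ratio of
    tissue:air to blood:air.
    """
    bw_a = params.body_weight ** ALLOMETRIC_EXPONENT
    qc = params.cardiac_output_coef * bw_a
    p_blood_air = params.partition_air["blood"]
    return ScaledParameters(
        cardiac_output=qc,
        alveolar_ventilation=params.alveolar_vent_coef * bw_a,
        tissue_flows={i: params.flow_fractions[i] * qc for i in TISSUES},
        tissue_volumes={
            i: params.volume_fractions[i] * params.body_weight for i in TISSUES
        },
        blood_volume=params.blood_volume_fraction * params.body_weight,
        vmax=params.vmax_coef * bw_a,
        km=params.km,
        absorbed_fraction=params.absorbed_fraction,
        partition_blood={
            i: params.partition_air[i] / p_blood_air for i in TISSUES
        },
        partition_air_blood=p_blood_air,
        uptake_model=params.uptake_model,
    )


class ExposureProfile(BaseModel):
    """Piecewise-constant inhaled air concentration.

    ``segments`` are sorted, non-overlapping ``(t_start h, t_end h,
    concentration mg/m³)`` triples; time not covered by a segment means
    zero exposure.
    """

    model_config = ConfigDict(extra="forbid", frozen=True)

    segments: tuple[tuple[float, float, float], ...] = ()

    @model_validator(mode="after")
    def _validate_segments(self) -> "ExposureProfile":
        prev_end = -np.inf
        for a, b, c in self.segments:
            if b <= a:
                raise ValueError(f"segment ({a}, {b}) has non-positive duration")
            if a < prev_end:
                raise ValueError("segments must be sorted and non-overlapping")
            if c < 0:
                raise ValueError("air concentration must be non-negative")
            prev_end = b
        return self

    def concentration_at(self, t: float) -> float:
        """Air concentration in mg/m³ at time t h (0 in gaps)."""
        for a, b, c in self.segments:
            if a <= t < b:
                return c
        return 0.0

    def breakpoints(self) -> list[float]:
        return sorted({edge for a, b, _ in self.segments for edge in (a, b)})


@dataclass
class PBPKTrajectory:
    """Simulation output on the reporting grid.

    ``amounts`` has one row per time point and one column per compartment in
    the order blood, fat, liver, rapid, slow, brain (mg).  Cumulative uptake
    and metabolism are integrated as auxiliary states so that mass balance
    (uptake = body burden + metabolised) can be checked exactly.
    """

    times: np.ndarray                 # h
    amounts: np.ndarray               # mg, shape (n_times, 6)
    blood_conc: np.ndarray            # mg/L
    cumulative_uptake: np.ndarray     # mg
    cumulative_metabolized: np.ndarray  # mg
    compartments: tuple[str, ...] = field(default=("blood",) + TISSUES)

    def to_frame(self):
        """Trajectory as a pandas DataFrame (one column per compartment)."""
        import pandas as pd

        data = {"time_h": self.times}
        for j, name in enumerate(self.compartments):
            data[f"{name}_mg"] = self.amounts[:, j]
        data["blood_mg_per_L"] = self.blood_conc
        data["uptake_mg"] = self.cumulative_uptake
        data["metabolized_mg"] = self.cumulative_metabolized
        return pd.DataFrame(data)


def _uptake_rate(scaled: ScaledParameters, c_inh_mg_m3: float, c_blood: float) -> float:
    c_air_mg_l = c_inh_mg_m3 / 1000.0
    if scaled.uptake_model == "fractional":
        return scaled.absorbed_fraction * scaled.alveolar_ventilation * c_air_mg_l
    # alveolar equilibration with exhaled back-flux
    return scaled.alveolar_ventilation * (
        c_air_mg_l - c_blood / scaled.partition_air_blood
    )


def derivatives(
    state: Sequence[float],
    t: float,
    scaled: ScaledParameters,
    exposure: ExposureProfile,
) -> np.ndarray:
    """Right-hand side of the mass-balance ODE system, mg/h.

    ``state`` is ``[A_blood, A_fat, A_liver, A_rapid, A_slow, A_brain,
    cumulative_uptake, cumulative_metabolized]`` in mg.
    """
    state = np.asarray(state, dtype=float)
    if np.any(state[:6] < -1e-9):
        raise ValueError("compartment amounts must be non-negative")
    c_inh = exposure.concentration_at(t)
    return _rhs(t, state, scaled, c_inh)


def _rhs(t: float, y: np.ndarray, s: ScaledParameters, c_inh: float) -> np.ndarray:
    c_blood = y[0] / s.blood_volume
    d = np.empty(8)
    venous_return = 0.0
    metab = 0.0
    for j, i in enumerate(TISSUES):
        c_ven = y[1 + j] / s.tissue_volumes[i] / s.partition_blood[i]
        q = s.tissue_flows[i]
        rate = q * (c_blood - c_ven)
        if i == "liver":
            metab = s.vmax * c_ven / (s.km + c_ven)
            rate -= metab
        d[1 + j] = rate
        venous_return += q * c_ven
    uptake = _uptake_rate(s, c_inh, c_blood)
    d[0] = venous_return - s.cardiac_output * c_blood + uptake
    d[6] = uptake
    d[7] = metab
    return d


class SolverError(RuntimeError):
    """Raised when the ODE integrator fails to converge."""


def simulate(
    params: PBPKParameters,
    exposure: ExposureProfile,
    t_end: float,
    report_step: float = 0.1,
    initial_amounts: Sequence[float] | None = None,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> PBPKTrajectory:
    """Integrate the model from 0 to ``t_end`` h.

    The integration is restarted at every exposure-segment boundary so the
    piecewise-constant input is seen exactly (no smoothing across
    discontinuities).  Uses adaptive LSODA (stiff-capable) at rtol 1e-8 /
    atol 1e-10 mg by default.  Reporting times are the ``report_step`` grid
    plus all segment boundaries.

    Raises
    ------
    SolverError
        If the integrator reports failure; amounts are never silently clipped.
    """
    if t_end <= 0:
        raise ValueError("t_end must be positive")
    if report_step <= 0:
        raise ValueError("report_step must be positive")
    scaled = scale_parameters(params)

    y = np.zeros(8)
    if initial_amounts is not None:
        init = np.asarray(initial_amounts, dtype=float)
        if init.shape != (6,) or np.any(init < 0):
            raise ValueError("initial_amounts must be 6 non-negative values")
        y[:6] = init

    breaks = [b for b in exposure.breakpoints() if 0.0 < b < t_end]
    edges = np.array(sorted({0.0, t_end, *breaks}))
    grid = np.arange(0.0, t_end + report_step / 2, report_step)
    report_times = np.unique(np.concatenate([grid, edges]))

    times: list[float] = [0.0]
    states: list[np.ndarray] = [y.copy()]
    for a, b in zip(edges[:-1], edges[1:]):
        c_inh = exposure.concentration_at((a + b) / 2)
        t_eval = report_times[(report_times > a) & (report_times <= b)]
        sol = solve_ivp(
            _rhs,
            (a, b),
            y,
            t_eval=t_eval if t_eval.size else None,
            args=(scaled, c_inh),
            method="LSODA",
            rtol=rtol,
            atol=atol,
        )
        if not sol.success:
            raise SolverError(
                f"ODE integration failed on [{a}, {b}] h "
                f"(C_inh={c_inh} mg/m³): {sol.message}"
            )
        for tk, yk in zip(sol.t, sol.y.T):
            times.append(float(tk))
            states.append(yk.copy())
        y = sol.y[:, -1].copy() if sol.y.size else y

    t_arr = np.array(times)
    y_arr = np.vstack(states)
    # boundary points appear once per adjacent segment; keep the last copy
    keep = np.concatenate([np.diff(t_arr) > 0, [True]])
    t_arr, y_arr = t_arr[keep], y_arr[keep]

    return PBPKTrajectory(
        times=t_arr,
        amounts=y_arr[:, :6],
        blood_conc=y_arr[:, 0] / scaled.blood_volume,
        cumulative_uptake=y_arr[:, 6],
        cumulative_metabolized=y_arr[:, 7],
    )


def blood_concentration_at(traj: PBPKTrajectory, t: float) -> float:
    """Blood concentration (mg/L) at time t h, linearly interpolated."""
    if t < traj.times[0] or t > traj.times[-1]:
        raise ValueError(
            f"t={t} outside trajectory range [{traj.times[0]}, {traj.times[-1]}]"
        )
    return float(np.interp(t, traj.times, traj.blood_conc))
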