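"""Independent numerical oracles, deliberately kept separate from the
implementation paths they check.

- trapezoid_window_mean: brute-force 1 s quadrature of the room model's
  point solution, checking the analytic window-mean integral.
- euler_blood_conc: fixed-step explicit Euler integration of the PBPK
  mass-balance equations written out longhand, checking the adaptive
  solver (and the packaged right-hand side) end to end.
"""

from __future__ import annotations

import numpy as np

from ethexpo import EmissionSchedule, ExposureProfile, PBPKParameters, RoomSpec
from ethexpo.room import concentration_at


def trapezoid_window_mean(
    schedule: EmissionSchedule, room: RoomSpec, t_start: float, t_end: float
) -> float:
    """Window mean in mg/m³ by 1 s trapezoid quadrature, piecewise between
    pulse times so the jump discontinuities are never straddled."""
    edges = [t_start, t_end] + [
        p.time for p in schedule.pulses if t_start < p.time < t_end
    ]
    edges = sorted(set(edges))
    total = 0.0
    for lo, hi in zip(edges[:-1], edges[1:]):
        n = max(2, int(round((hi - lo) * 3600)))
        grid = np.linspace(lo, hi, n + 1)
        conc = np.asarray(concentration_at(schedule, room, grid))
        # the stored value AT a pulse time is post-jump, which is right for
        # each subinterval's left endpoint; the right endpoint must be the
        # pre-jump limit, so strip any pulse sitting exactly on it
        conc[-1] -= sum(
            p.mass / room.volume for p in schedule.pulses if p.time == hi
        )
        total += np.trapezoid(conc, grid)
    return total / (t_end - t_start) * 1000.0


def euler_blood_conc(
    params: PBPKParameters,
    exposure: ExposureProfile,
    t_end: float,
    dt: float = 1e-4,
) -> float:
    """Blood concentration (mg/L) at ``t_end`` by explicit Euler at step
    ``dt`` h (1e-4 h = 0.36 s), with the model equations restated inline."""
    bw = params.body_weight
    qc = params.cardiac_output_coef * bw**0.75
    qp = params.alveolar_vent_coef * bw**0.75
    vmax = params.vmax_coef * bw**0.75
    km = params.km
    f = params.absorbed_fraction
    tissues = ("fat", "liver", "rapid", "slow", "brain")
    q = np.array([params.flow_fractions[i] * qc for i in tissues])
    v = np.array([params.volume_fractions[i] * bw for i in tissues])
    p = np.array(
        [params.partition_air[i] / params.partition_air["blood"] for i in tissues]
    )
    vb = params.blood_volume_fraction * bw
    liver = tissues.index("liver")

    a_blood = 0.0
    a = np.zeros(5)
    n_steps = int(round(t_end / dt))
    for n in range(n_steps):
        t = n * dt
        c_b = a_blood / vb
        c_ven = a / v / p
        metab = vmax * c_ven[liver] / (km + c_ven[liver])
        da = q * (c_b - c_ven)
        da[liver] -= metab
        d_blood = q @ c_ven - qc * c_b + f * qp * exposure.concentration_at(t) / 1000.0
        a_blood += dt * d_blood
        a += dt * da
    return a_blood / vb
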