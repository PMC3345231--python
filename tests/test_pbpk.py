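"""PBPK model: scaling, mass-balance equations, solver behaviour."""

import numpy as np
import pytest
from pydantic import ValidationError

from ethexpo import (
    ExposureProfile,
    PBPKParameters,
    blood_concentration_at,
    derivatives,
    scale_parameters,
    simulate,
)
from ethexpo.pbpk import TISSUES
from oracles import euler_blood_conc


class TestScaleParameters:
    def test_allometric_cardiac_output(self, default_params):
        scaled = scale_parameters(default_params)
        assert scaled.cardiac_output == pytest.approx(435.6081886488457)
        assert scaled.alveolar_ventilation == pytest.approx(435.6081886488457)

    def test_unit_body_weight_is_the_coefficient(self):
        scaled = scale_parameters(PBPKParameters(body_weight=1.0))
        assert scaled.cardiac_output == pytest.approx(18.0)

    def test_partition_blood_is_air_ratio(self, default_params):
        scaled = scale_parameters(default_params)
        assert scaled.partition_blood["liver"] == pytest.approx(1730 / 2280)

    def test_tissue_flows_sum_to_cardiac_output(self, default_params):
        scaled = scale_parameters(default_params)
        assert sum(scaled.tissue_flows.values()) == pytest.approx(
            scaled.cardiac_output
        )

    def test_volumes_scale_linearly_with_body_weight(self, default_params):
        scaled = scale_parameters(default_params)
        assert scaled.tissue_volumes["liver"] == pytest.approx(0.0257 * 70)
        assert scaled.blood_volume == pytest.approx(0.079 * 70)


class TestParameterValidation:
    def test_default_fraction_totals(self, default_params):
        assert sum(default_params.flow_fractions.values()) == pytest.approx(1.0)
        assert sum(default_params.volume_fractions.values()) == pytest.approx(0.91)

    def test_flow_fractions_must_sum_to_one(self):
        bad = {"fat": 0.1, "liver": 0.25, "rapid": 0.39, "slow": 0.19, "brain": 0.12}
        with pytest.raises(ValidationError):
            PBPKParameters(flow_fractions=bad)

    def test_unknown_tissue_rejected(self):
        bad = {"fat": 0.05, "liver": 0.25, "rapid": 0.39, "slow": 0.19, "spleen": 0.12}
        with pytest.raises(ValidationError):
            PBPKParameters(flow_fractions=bad)

    def test_absorbed_fraction_bounded(self):
        with pytest.raises(ValidationError):
            PBPKParameters(absorbed_fraction=1.5)


class TestDerivatives:
    def test_zero_state_zero_exposure_is_equilibrium(self, default_params):
        scaled = scale_parameters(default_params)
        rates = derivatives(np.zeros(8), 0.0, scaled, ExposureProfile())
        assert np.all(rates == 0.0)

    def test_zero_state_uptake_goes_to_blood_only(self, default_params):
        scaled = scale_parameters(default_params)
        exposure = ExposureProfile(segments=((0.0, 8.0, 1518.0),))
        rates = derivatives(np.zeros(8), 1.0, scaled, exposure)
        expected = 0.62 * scaled.alveolar_ventilation * 1.518
        assert rates[0] == pytest.approx(expected)  # = 409.977 mg/h
        assert np.all(rates[1:6] == 0.0)
        assert rates[6] == pytest.approx(expected)

    def test_partition_equilibrium_has_no_net_tissue_flux(self):
        params = PBPKParameters(vmax_coef=1e-12)
        scaled = scale_parameters(params)
        c_blood = 5.0  # mg/L
        state = np.zeros(8)
        state[0] = c_blood * scaled.blood_volume
        for j, i in enumerate(TISSUES):
            state[1 + j] = (
                c_blood * scaled.partition_blood[i] * scaled.tissue_volumes[i]
            )
        rates = derivatives(state, 0.0, scaled, ExposureProfile())
        assert np.allclose(rates[:6], 0.0, atol=1e-8)

    def test_negative_state_rejected(self, default_params):
        scaled = scale_parameters(default_params)
        state = np.zeros(8)
        state[2] = -1.0
        with pytest.raises(ValueError):
            derivatives(state, 0.0, scaled, ExposureProfile())


class TestSimulate:
    def test_zero_exposure_stays_zero(self, default_params):
        traj = simulate(default_params, ExposureProfile(), t_end=4.0)
        assert np.all(traj.blood_conc == 0.0)
        assert np.all(traj.amounts == 0.0)

    def test_no_metabolism_conserves_uptake(self):
        # with a vanishing Vmax the only pathway is accumulation
        params = PBPKParameters(vmax_coef=1e-12)
        exposure = ExposureProfile(segments=((0.0, 2.0, 500.0),))
        traj = simulate(params, exposure, t_end=2.0)
        scaled = scale_parameters(params)
        expected = 0.62 * scaled.alveolar_ventilation * 0.5 * 2.0
        assert traj.amounts[-1].sum() == pytest.approx(expected, rel=1e-6)

    def test_mass_balance_closes(self, default_params, two_day_exposure):
        traj = simulate(default_params, two_day_exposure, t_end=32.0)
        burden = traj.amounts.sum(axis=1) + traj.cumulative_metabolized
        np.testing.assert_allclose(
            traj.cumulative_uptake[1:], burden[1:], rtol=1e-6
        )

    def test_non_negative_amounts(self, default_params, two_day_exposure):
        traj = simulate(default_params, two_day_exposure, t_end=32.0)
        assert np.all(traj.amounts >= -1e-12)
        assert np.all(np.diff(traj.cumulative_uptake) >= -1e-9)
        assert np.all(np.diff(traj.cumulative_metabolized) >= -1e-9)

    def test_low_dose_linearity(self, default_params):
        """Far below Km the model is effectively first-order: doubling the
        air concentration doubles the steady-state blood concentration."""
        levels = {}
        for c in (100.0, 200.0):
            exposure = ExposureProfile(segments=((0.0, 24.0, c),))
            traj = simulate(default_params, exposure, t_end=24.0)
            levels[c] = blood_concentration_at(traj, 24.0)
        assert levels[200.0] / levels[100.0] == pytest.approx(2.0, rel=0.01)

    def test_steady_state_monotone_in_exposure(self, default_params):
        values = []
        for c in (200.0, 600.0, 1200.0, 1800.0):
            exposure = ExposureProfile(segments=((0.0, 24.0, c),))
            traj = simulate(default_params, exposure, t_end=24.0)
            values.append(blood_concentration_at(traj, 24.0))
        assert all(b > a for a, b in zip(values, values[1:]))

    def test_washout_after_exposure_ends(self, default_params, day1_exposure):
        """Blood ethanol clears to below reporting precision overnight."""
        traj = simulate(default_params, day1_exposure, t_end=24.0)
        post = traj.blood_conc[traj.times >= 8.0]
        assert np.all(np.diff(post) <= 1e-12)
        assert blood_concentration_at(traj, 24.0) < 0.01

    def test_adaptive_solver_matches_fine_euler(self, default_params, day1_exposure):
        """LSODA trajectory agrees with 0.36 s explicit Euler to 0.1%."""
        traj = simulate(default_params, day1_exposure, t_end=8.0)
        adaptive = blood_concentration_at(traj, 8.0)
        euler = euler_blood_conc(default_params, day1_exposure, t_end=8.0)
        assert adaptive == pytest.approx(euler, rel=1e-3)

    def test_endpoint_insensitive_to_blood_volume_fraction(self, day1_exposure):
        """The quasi-steady blood level is set by the uptake/elimination
        balance, so the unspecified blood-volume fraction barely matters."""
        ref = simulate(PBPKParameters(), day1_exposure, t_end=8.0)
        for bvf in (0.05, 0.09):
            alt = simulate(
                PBPKParameters(blood_volume_fraction=bvf), day1_exposure, t_end=8.0
            )
            assert blood_concentration_at(alt, 8.0) == pytest.approx(
                blood_concentration_at(ref, 8.0), rel=0.01
            )

    def test_alveolar_uptake_exceeds_fractional(self, day1_exposure):
        """With ethanol's blood:air coefficient of 2280 the conventional
        alveolar-equilibration formulation retains nearly everything
        inhaled, so it predicts more uptake than the net 0.62 fraction."""
        frac = simulate(PBPKParameters(), day1_exposure, t_end=8.0)
        alv = simulate(
            PBPKParameters(uptake_model="alveolar"), day1_exposure, t_end=8.0
        )
        ratio = blood_concentration_at(alv, 8.0) / blood_concentration_at(frac, 8.0)
        assert 1.3 < ratio < 1.7  # ~1/0.62, minus the small exhaled back-flux

    def test_invalid_arguments(self, default_params):
        with pytest.raises(ValueError):
            simulate(default_params, ExposureProfile(), t_end=-1.0)
        with pytest.raises(ValueError):
            simulate(default_params, ExposureProfile(), t_end=1.0, report_step=0.0)


class TestExposureProfile:
    def test_lookup_and_gaps(self, two_day_exposure):
        assert two_day_exposure.concentration_at(1.0) == 408.0
        assert two_day_exposure.concentration_at(12.0) == 0.0  # overnight gap
        assert two_day_exposure.concentration_at(31.9) == 1518.0
        assert two_day_exposure.concentration_at(32.0) == 0.0  # right-open

    def test_overlapping_segments_rejected(self):
        with pytest.raises(ValidationError):
            ExposureProfile(segments=((0.0, 3.0, 1.0), (2.0, 4.0, 1.0)))

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValidationError):
            ExposureProfile(segments=((0.0, 3.0, -1.0),))


class TestBloodConcentrationAt:
    def test_grid_point_and_midpoint(self, default_params, day1_exposure):
        traj = simulate(default_params, day1_exposure, t_end=8.0, report_step=0.5)
        idx = np.searchsorted(traj.times, 4.0)
        assert blood_concentration_at(traj, 4.0) == traj.blood_conc[idx]
        mid = blood_concentration_at(traj, 4.25)
        assert mid == pytest.approx(
            (traj.blood_conc[idx] + traj.blood_conc[idx + 1]) / 2
        )

    def test_out_of_range_rejected(self, default_params, day1_exposure):
        traj = simulate(default_params, day1_exposure, t_end=8.0)
        with pytest.raises(ValueError):
            blood_concentration_at(traj, 9.0)
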