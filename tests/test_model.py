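"""Unit and property tests for the HSR network kinetics."""

import dataclasses

import numpy as np
import pytest

from hsr.model import (
    CellParameters,
    CellState,
    CellTrajectory,
    ModelParameters,
    TemperatureProtocol,
    denaturation_rate,
    derivatives,
    foci_fraction,
    hsf1_free_fraction,
    hsp_free_fraction,
    quasi_steady_initial,
    simulate_trajectory,
    steady_state,
)


class TestDenaturationRate:
    @pytest.mark.parametrize(
        "theta, expected",
        [
            (37.0, 1.056),  # k_d * (1 - 0.4) * 1.4^0
            (43.0, 13.238844006960496),
        ],
    )
    def test_reference_values(self, params, theta, expected):
        assert denaturation_rate(theta, params) == pytest.approx(expected, rel=1e-12)

    def test_proportional_to_kd(self, params):
        doubled = dataclasses.replace(params, k_d=2 * params.k_d)
        for theta in (37.0, 40.0, 44.0):
            assert denaturation_rate(theta, doubled) == pytest.approx(
                2 * denaturation_rate(theta, params), rel=1e-12
            )
        # the rate vanishes with the denaturation scale
        tiny = dataclasses.replace(params, k_d=1e-12)
        assert denaturation_rate(37.0, tiny) == pytest.approx(0.0, abs=1e-12)

    def test_clamped_below_physiological_range(self, params):
        # raw expression is negative well below 37 degC; clamped at 0
        assert denaturation_rate(30.0, params) == 0.0
        assert denaturation_rate(34.0, params) == 0.0

    def test_strictly_increasing_above_37(self, params):
        grid = np.linspace(37.0, 45.0, 81)
        values = [denaturation_rate(t, params) for t in grid]
        assert all(b > a for a, b in zip(values, values[1:]))

    def test_nonfinite_theta_rejected(self, params):
        with pytest.raises(ValueError):
            denaturation_rate(float("nan"), params)


class TestFreeFractions:
    @pytest.mark.parametrize(
        "hsp, mfp, expected",
        [(1.0, 0.0, 1.0), (1.0, 1.0, 0.5), (0.45, 0.06, 0.45 / 0.51), (0.0, 0.0, 0.0)],
    )
    def test_hsp_free_fraction(self, hsp, mfp, expected):
        state = CellState(theta=37.0, mfp=mfp, hsp=hsp, mhsp=0.0)
        assert hsp_free_fraction(state) == pytest.approx(expected, abs=1e-12)

    def test_hsf1_free_no_chaperone(self):
        cell = CellParameters(hsf1_tot=0.04, hsp0=1.0)
        state = CellState(theta=37.0, mfp=0.5, hsp=0.0, mhsp=0.0)
        assert hsf1_free_fraction(state, cell) == 1.0

    def test_hsf1_free_reference_point(self):
        cell = CellParameters(hsf1_tot=0.04, hsp0=1.0)
        state = CellState(theta=37.0, mfp=0.06, hsp=0.45, mhsp=0.0)
        expected = 0.04 / (0.04 + 0.45 * (0.45 / 0.51))
        got = hsf1_free_fraction(state, cell)
        assert got == pytest.approx(expected, rel=1e-12)
        assert got == pytest.approx(0.0915, abs=2e-4)

    def test_hsf1_free_vanishes_at_high_chaperone(self):
        cell = CellParameters(hsf1_tot=0.04, hsp0=1.0)
        state = CellState(theta=37.0, mfp=0.0, hsp=1e9, mhsp=0.0)
        assert hsf1_free_fraction(state, cell) < 1e-8

    def test_nonpositive_hsf1_rejected(self):
        with pytest.raises(ValueError):
            CellParameters(hsf1_tot=0.0, hsp0=1.0)


class TestFociFraction:
    def test_unsequestered_hsf1_gives_full_foci(self):
        cell = CellParameters(hsf1_tot=0.04, hsp0=1.0)
        state = CellState(theta=43.0, mfp=2.0, hsp=0.0, mhsp=0.0)
        assert foci_fraction(state, cell) == 1.0

    def test_cubic_readout(self):
        # free fraction exactly 1/2: hsp * hsp_free == hsf1_tot
        cell = CellParameters(hsf1_tot=0.04, hsp0=1.0)
        state = CellState(theta=37.0, mfp=0.0, hsp=0.04, mhsp=0.0)
        assert foci_fraction(state, cell) == pytest.approx(0.125, rel=1e-12)

    def test_reference_point(self):
        cell = CellParameters(hsf1_tot=0.04, hsp0=1.0)
        state = CellState(theta=37.0, mfp=0.06, hsp=0.45, mhsp=0.0)
        assert foci_fraction(state, cell) == pytest.approx(7.67e-4, rel=2e-3)


class TestDerivatives:
    def test_vanish_at_steady_state(self, params, ref_cell, normothermic_state):
        d = derivatives(normothermic_state, ref_cell, 37.0, params)
        assert max(abs(d.theta), abs(d.mfp), abs(d.hsp), abs(d.mhsp)) < 1e-8

    def test_temperature_relaxation_rate(self, params, ref_cell, normothermic_state):
        d = derivatives(normothermic_state, ref_cell, 43.0, params)
        assert d.theta == pytest.approx(6.0 / params.tau_temp, rel=1e-12)  # 90 degC/h

    def test_empty_cell_transcription(self, params, ref_cell):
        # with no chaperone at all, HSF1 is fully free and transcription maximal
        state = CellState(theta=37.0, mfp=0.0, hsp=0.0, mhsp=0.0)
        d = derivatives(state, ref_cell, 37.0, params)
        expected = (params.mu + params.lam / (params.s0 ** 3 + 1.0)) / params.tau_mhsp
        assert d.mhsp == pytest.approx(expected, rel=1e-12)

    def test_nonfinite_state_rejected(self, params, ref_cell):
        state = CellState(theta=float("inf"), mfp=0.0, hsp=0.0, mhsp=0.0)
        with pytest.raises(ValueError):
            derivatives(state, ref_cell, 37.0, params)


class TestSteadyState:
    def test_baseline_below_detection_limit(self, params, ref_cell, normothermic_state):
        # unstressed cells must not display foci: F under the 1 % limit
        assert foci_fraction(normothermic_state, ref_cell) < 0.01

    def test_is_a_fixed_point_of_integration(self, params, normothermic_state):
        # integrating a long horizon from the fixed point goes nowhere
        cell = CellParameters(hsf1_tot=params.hsf1_tot_ref, hsp0=normothermic_state.hsp)
        protocol = TemperatureProtocol(segments=((0.0, 200.0, 37.0),))
        times = np.array([0.0, 50.0, 100.0, 200.0])
        traj, states = simulate_trajectory(
            cell, protocol, params, times, with_states=True
        )
        rel = np.abs(states - states[:, :1]) / np.abs(states[:, :1])
        assert rel.max() < 1e-6


class TestSimulateTrajectory:
    def test_constant_at_normothermia(self, params, normothermic_state):
        cell = CellParameters(hsf1_tot=params.hsf1_tot_ref, hsp0=normothermic_state.hsp)
        protocol = TemperatureProtocol(segments=((0.0, 6.0, 37.0),))
        times = np.arange(0, 37) / 6.0
        traj = simulate_trajectory(cell, protocol, params, times)
        assert np.ptp(traj.f_values) < 1e-6

    def test_stress_raises_foci_fraction(self, params, normothermic_state, protocol_43,
                                         sampling_grid):
        cell = CellParameters(hsf1_tot=params.hsf1_tot_ref, hsp0=normothermic_state.hsp)
        traj = simulate_trajectory(cell, protocol_43, params, sampling_grid)
        stress = (traj.times >= 0) & (traj.times <= 3)
        assert traj.f_values[stress].max() > traj.f_values[0]

    def test_peak_f_monotone_in_hsp0(self, params, normothermic_state, protocol_43,
                                     sampling_grid):
        # more chaperone can only suppress the response (activation function)
        peaks = []
        for hsp0 in normothermic_state.hsp * np.logspace(-1, 1, 9):
            traj = simulate_trajectory(
                CellParameters(params.hsf1_tot_ref, hsp0), protocol_43, params, sampling_grid
            )
            peaks.append(traj.f_values.max())
        assert all(b <= a + 1e-10 for a, b in zip(peaks, peaks[1:]))

    def test_bounds_and_positivity(self, params, normothermic_state, protocol_43,
                                   sampling_grid):
        cell = CellParameters(params.hsf1_tot_ref, normothermic_state.hsp)
        traj, states = simulate_trajectory(
            cell, protocol_43, params, sampling_grid, with_states=True
        )
        assert (traj.f_values >= 0).all() and (traj.f_values <= 1).all()
        assert states[1:].min() >= -1e-12  # concentrations

    def test_solver_tolerance_convergence(self, params, normothermic_state, protocol_43,
                                          sampling_grid):
        cell = CellParameters(params.hsf1_tot_ref, normothermic_state.hsp)
        coarse = simulate_trajectory(cell, protocol_43, params, sampling_grid)
        fine = simulate_trajectory(
            cell, protocol_43, params, sampling_grid, rtol=5e-9, atol=5e-11
        )
        assert np.abs(coarse.f_values - fine.f_values).max() < 1e-6

    def test_grid_outside_protocol_rejected(self, params, protocol_43):
        cell = CellParameters(0.04, 0.5)
        with pytest.raises(ValueError):
            simulate_trajectory(cell, protocol_43, params, np.array([0.0, 10.0]))

    def test_quasi_steady_initialisation_slaves_fast_variables(self, params, ref_cell):
        # MFP and mRNA nullclines hold exactly at the constructed state
        state = quasi_steady_initial(CellParameters(0.04, 0.2), params)
        d = derivatives(state, CellParameters(0.04, 0.2), 37.0, params)
        assert abs(d.mfp) < 1e-10 and abs(d.mhsp) < 1e-10


class TestProtocolAndTrajectoryTypes:
    def test_protocol_must_be_contiguous(self):
        with pytest.raises(ValueError):
            TemperatureProtocol(segments=((0.0, 1.0, 37.0), (2.0, 3.0, 43.0)))

    def test_setpoint_sanity_bounds(self):
        with pytest.raises(ValueError):
            TemperatureProtocol(segments=((0.0, 1.0, 60.0),))

    def test_setpoint_lookup(self, protocol_43):
        assert protocol_43.setpoint(-0.1) == 37.0
        assert protocol_43.setpoint(0.0) == 43.0
        assert protocol_43.setpoint(2.9) == 43.0
        assert protocol_43.setpoint(3.5) == 37.0

    def test_trajectory_validation(self):
        with pytest.raises(ValueError):
            CellTrajectory("c", np.array([0.0, 0.0]), np.array([0.0, 0.0]),
                           np.array([1.0, 1.0]))
        with pytest.raises(ValueError):
            CellTrajectory("c", np.array([0.0, 1.0]), np.array([0.0, 1.5]),
                           np.array([1.0, 1.0]))

    def test_parameters_must_be_positive(self):
        with pytest.raises(ValueError):
            ModelParameters(tau_hsp=0.0)
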