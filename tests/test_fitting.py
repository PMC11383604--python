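"""Inference-chain tests: conversion, segmentation, fitting, recovery."""

import math

import numpy as np
import pytest

from mmwrheo import (
    BurgersParams,
    ComplianceCurve,
    ForceProtocol,
    WireGeometry,
    analyze_trace,
    classify_gel,
    compliance_from_displacement,
    creep_compliance,
    curve_from_trace,
    fit_burgers,
    recovery_ratio,
    segment_protocol,
    simulate_trace,
    steady_state_compliance,
    stress_sweep_linearity,
)
from mmwrheo.fitting import LIQUID, SOLID, FitResult, ProtocolError


@pytest.fixture
def liquid_curve(params, geometry, protocol):
    trace = simulate_trace(params, geometry, protocol, noise_sigma=0.0, seed=0)
    return curve_from_trace(trace, geometry.drag)


class TestComplianceConversion:
    def test_zero_displacement_zero_compliance(self):
        J = compliance_from_displacement(np.zeros(10), 110e-9, 0.03)
        assert np.all(J == 0.0)

    def test_worked_value(self):
        """2 um at 110 nN with C = 3.007e-2 m gives ~0.547 1/Pa."""
        J = compliance_from_displacement(np.array([2.0e-6]), 110e-9, 3.0072e-2)
        assert J[0] == pytest.approx(0.5468, rel=1e-3)

    def test_linear_and_homogeneous(self):
        x = np.linspace(0.0, 3e-6, 20)
        J1 = compliance_from_displacement(x, 110e-9, 0.03)
        np.testing.assert_allclose(
            compliance_from_displacement(3.0 * x, 110e-9, 0.03), 3.0 * J1, rtol=1e-15
        )
        np.testing.assert_allclose(
            compliance_from_displacement(x, 55e-9, 0.03), 2.0 * J1, rtol=1e-15
        )

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            compliance_from_displacement(np.ones(3), 0.0, 0.03)
        with pytest.raises(ValueError):
            compliance_from_displacement(np.ones(3), 1e-9, -1.0)

    def test_round_trip_with_forward_model(self, params, geometry, protocol):
        """displacement -> compliance reproduces J(t) on the first
        on-phase to machine precision."""
        trace = simulate_trace(params, geometry, protocol, noise_sigma=0.0)
        curve = curve_from_trace(trace, geometry.drag)
        first_on = curve.t < protocol.t_on
        np.testing.assert_allclose(
            curve.J[first_on],
            creep_compliance(params, curve.t[first_on]),
            rtol=1e-12,
        )


class TestSegmentation:
    def test_default_protocol_window_counts(self, protocol):
        _, force = protocol.force_series()
        windows = segment_protocol(force, dt=protocol.dt)
        on = [w for w in windows if w.phase == "on"]
        off = [w for w in windows if w.phase == "off"]
        assert len(on) == 2 and len(off) == 2
        assert all(w.n == 20 for w in on)
        assert all(w.n == 40 for w in off)

    def test_constant_force_single_window(self):
        windows = segment_protocol(np.full(30, 1e-7), dt=0.5)
        assert len(windows) == 1
        assert windows[0].phase == "on" and windows[0].n == 30

    def test_single_sample_glitches_debounced(self, protocol):
        _, force = protocol.force_series()
        glitched = force.copy()
        glitched[10] = 0.0           # dropout inside an on window
        glitched[30] = protocol.F0   # spike inside an off window
        windows = segment_protocol(glitched, dt=protocol.dt, min_duration=1.0)
        clean = segment_protocol(force, dt=protocol.dt)
        assert [(w.phase, w.start, w.stop) for w in windows] == [
            (w.phase, w.start, w.stop) for w in clean
        ]

    def test_all_zero_force_is_protocol_error(self):
        with pytest.raises(ProtocolError):
            segment_protocol(np.zeros(20), dt=0.5)


class TestBurgersFit:
    def test_noiseless_recovery_to_machine_precision(self, liquid_curve):
        fit = fit_burgers(liquid_curve)
        assert fit.Je0 == pytest.approx(0.15, rel=1e-6)
        assert fit.eta0 == pytest.approx(200.0, rel=1e-6)
        assert fit.params.tau == pytest.approx(2.0, rel=1e-6)

    def test_newtonian_limit(self):
        """Pure viscous input J = t/eta drives the elastic compliances to
        zero and recovers the viscosity."""
        t = np.arange(0.5, 10.01, 0.5)
        curve = ComplianceCurve(t=t, J=t / 50.0, on=np.ones_like(t, bool), F0=1e-7)
        fit = fit_burgers(curve)
        assert fit.eta0 == pytest.approx(50.0, rel=1e-6)
        assert fit.params.J1 < 1e-4 * fit.Je0 + 0.05
        assert fit.params.J1 + fit.params.J2 < 0.02

    def test_noisy_recovery_accuracy(self, params, geometry, protocol):
        """2% displacement noise: median relative errors of Je0 and eta0
        stay below 10% over 50 seeds."""
        errs = []
        for seed in range(50):
            trace = simulate_trace(params, geometry, protocol, 0.02, seed)
            fit = analyze_trace(trace, geometry.drag, seed=seed)
            errs.append(
                (abs(fit.Je0 - 0.15) / 0.15, abs(fit.eta0 - 200.0) / 200.0)
            )
        med = np.median(np.array(errs), axis=0)
        assert med[0] < 0.10 and med[1] < 0.10

    def test_time_axis_offset_invariance(self, params, geometry, protocol):
        """Fitting is unchanged when the clock starts at an arbitrary
        absolute acquisition time."""
        trace = simulate_trace(params, geometry, protocol, 0.0, 0)
        curve = curve_from_trace(trace, geometry.drag)
        shifted = ComplianceCurve(
            t=curve.t + 1234.5, J=curve.J, on=curve.on, F0=curve.F0
        )
        a, b = fit_burgers(curve), fit_burgers(shifted)
        assert b.Je0 == pytest.approx(a.Je0, rel=1e-9)
        assert b.eta0 == pytest.approx(a.eta0, rel=1e-9)

    def test_solid_input_reported_with_solid_flag(self, solid_params, geometry, protocol):
        trace = simulate_trace(solid_params, geometry, protocol, 0.0, 0)
        fit = analyze_trace(trace, geometry.drag)
        assert fit.solid_limit
        assert math.isinf(fit.eta0)
        assert fit.classification == SOLID

    def test_per_cycle_quality_control_present(self, liquid_curve):
        fit = fit_burgers(liquid_curve)
        assert len(fit.per_cycle) == 2
        for cyc in fit.per_cycle:
            assert cyc["Je0"] == pytest.approx(0.15, rel=1e-5)

    def test_too_short_window_rejected(self):
        t = np.arange(0.0, 3.0, 0.5)
        curve = ComplianceCurve(t=t, J=t * 0.01 + 0.1, on=np.ones_like(t, bool))
        with pytest.raises(Exception):
            fit_burgers(curve)


class TestEndToEndIdentity:
    def test_parameter_recovery_over_three_decades(self, geometry, protocol):
        """simulate -> convert -> fit returns the generating (Je0, eta0)
        to 1e-6 relative for 100 log-uniform draws spanning 3 decades."""
        rng = np.random.default_rng(7)
        for _ in range(100):
            Je0 = 0.01 * 10 ** rng.uniform(0.0, 3.0)
            frac = rng.uniform(0.3, 0.8)
            tau = rng.uniform(0.5, 2.5)
            eta0 = protocol.t_on / (rng.uniform(0.1, 2.0) * Je0)
            p = BurgersParams(J1=frac * Je0, J2=(1 - frac) * Je0, tau=tau, eta0=eta0)
            trace = simulate_trace(p, geometry, protocol, 0.0, 0)
            fit = analyze_trace(trace, geometry.drag)
            assert fit.Je0 == pytest.approx(Je0, rel=1e-6)
            assert fit.eta0 == pytest.approx(eta0, rel=1e-6)


class TestRecoveryRatio:
    def test_matches_closed_form_for_liquid(self, params, geometry):
        """R = 1 - (t_on/eta0)/J(t_on) ~ 0.750 for the reference liquid
        when the off phase allows full retarded relaxation."""
        prot = ForceProtocol(F0=110e-9, t_on=10.0, t_off=25.0, n_cycles=2, dt=0.5)
        trace = simulate_trace(params, geometry, prot, 0.0, 0)
        curve = curve_from_trace(trace, geometry.drag)
        R = recovery_ratio(curve)
        closed = 1.0 - (10.0 / 200.0) / creep_compliance(params, 10.0)
        assert closed == pytest.approx(0.7496, abs=5e-4)
        assert R == pytest.approx(closed, rel=0.01)

    def test_solid_recoils_completely(self, solid_params, geometry, protocol):
        trace = simulate_trace(solid_params, geometry, protocol, 0.0, 0)
        R = recovery_ratio(curve_from_trace(trace, geometry.drag))
        assert R == pytest.approx(1.0, abs=1e-4)

    def test_maxwell_closed_form(self, geometry):
        """With no retarded element, R = J1/(J1 + t_on/eta0) for long on
        phases."""
        p = BurgersParams(J1=0.1, J2=0.0, tau=1.0, eta0=100.0)
        prot = ForceProtocol(F0=110e-9, t_on=50.0, t_off=50.0, n_cycles=1, dt=0.5)
        trace = simulate_trace(p, geometry, prot, 0.0, 0)
        R = recovery_ratio(curve_from_trace(trace, geometry.drag))
        # the last on sample sits dt before the force-off step, so the
        # sampled ratio sits slightly below the continuous-time limit
        assert R == pytest.approx(0.1 / (0.1 + 50.0 / 100.0), rel=0.05)

    def test_flat_curve_is_undefined(self):
        t = np.arange(0.0, 30.0, 0.5)
        on = t < 10.0
        curve = ComplianceCurve(t=t, J=np.zeros_like(t), on=on)
        with pytest.raises(ValueError):
            recovery_ratio(curve)


class TestClassification:
    def test_complete_recoil_is_solid(self):
        assert classify_gel(1.0) == SOLID

    def test_partial_recoil_is_liquid(self):
        assert classify_gel(0.75) == LIQUID

    def test_threshold_boundary(self):
        assert classify_gel(0.9) == SOLID
        assert classify_gel(0.899) == LIQUID

    def test_monotone_switch_in_eta0(self, geometry, protocol):
        """Sweeping eta0 upward at fixed elastic parameters flips the
        classification exactly once, liquid -> solid."""
        labels = []
        for eta0 in [10.0, 50.0, 200.0, 1e3, 1e4, 1e6, np.inf]:
            p = BurgersParams(J1=0.1, J2=0.05, tau=2.0, eta0=eta0)
            trace = simulate_trace(p, geometry, protocol, 0.0, 0)
            fit = analyze_trace(trace, geometry.drag)
            labels.append(fit.classification)
        switches = sum(a != b for a, b in zip(labels, labels[1:]))
        assert labels[0] == LIQUID and labels[-1] == SOLID
        assert switches == 1


class TestStressSweep:
    def _fit_at(self, Je0, eta0, F0):
        p = BurgersParams(J1=Je0 / 2, J2=Je0 / 2, tau=2.0, eta0=eta0)
        return FitResult(
            params=p, Je0=Je0, eta0=eta0, residual_norm=0.0, force_applied=F0
        )

    def test_identical_results_are_linear(self):
        fits = [self._fit_at(0.15, 200.0, F) for F in (50e-9, 110e-9, 460e-9)]
        out = stress_sweep_linearity(fits)
        assert out.verdict == "linear"
        assert out.cv_Je0 == 0.0 and abs(out.slope_logJe0_logF) < 1e-12

    def test_force_dependent_compliance_is_nonlinear(self):
        forces = [50e-9, 110e-9, 460e-9]
        fits = [self._fit_at(0.15 * F / 50e-9, 200.0, F) for F in forces]
        out = stress_sweep_linearity(fits)
        assert out.verdict == "nonlinear"
        assert out.slope_logJe0_logF == pytest.approx(1.0, abs=0.05)

    def test_forward_model_consistency_across_forces(self, params, geometry):
        """Noiseless fits of the same material at the experimental force
        range are declared within the linear regime."""
        fits = []
        for F0 in (50e-9, 110e-9, 460e-9):
            prot = ForceProtocol(F0=F0)
            trace = simulate_trace(params, geometry, prot, 0.0, 0)
            fits.append(analyze_trace(trace, geometry.drag))
        assert stress_sweep_linearity(fits).verdict == "linear"

    def test_insufficient_forces_rejected(self):
        fits = [self._fit_at(0.15, 200.0, F) for F in (50e-9, 110e-9)]
        with pytest.raises(ValueError):
            stress_sweep_linearity(fits)
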