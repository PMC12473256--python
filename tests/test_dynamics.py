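"""Time-varying ODE integration, drift propagation and scenario assembly."""

import numpy as np
import pytest

from conftest import fit_harmonic, tail
from pulsema.dynamics import (
    drift_pair_2dof,
    instantaneous_attributes,
    run_case_wall,
    simulate_1dof_tv,
    simulate_2dof_tv,
)
from pulsema.tcs import TCSParams, TVSPTrajectory, transfer_1dof, transfer_2dof
from pulsema.waveforms import (
    HarmonicSpec,
    PulseSignal,
    make_baseline_drift,
    DriftSpec,
    signal_derivative,
)

GRID8 = np.arange(8 * 200) / 200.0


class TestSimulate1DOF:
    def test_zero_excitation_stays_at_rest(self, params):
        y = PulseSignal(200.0, np.zeros(400))
        m = simulate_1dof_tv(params, None, y)
        assert np.max(np.abs(m.signal.samples)) < 1e-12

    def test_lti_steady_state_matches_transfer(self, params):
        """Eq.-of-motion integration vs the closed-form transfer function."""
        spec = HarmonicSpec(1.0, ((1, 1.0, 0.3),))
        m = simulate_1dof_tv(params, None, spec, grid=GRID8)
        sl = GRID8 >= 3.0
        measured = fit_harmonic(GRID8[sl], m.signal.samples[sl], 1.0)
        expected = np.exp(0.3j) * transfer_1dof(params, 1.0)
        assert abs(measured - expected) / abs(expected) < 1e-3

    def test_constant_tvsp_offset_equals_reparameterized_lti(self, params):
        """dk = -k0/3 held constant is the same as an LTI run at 2k0/3."""
        spec = HarmonicSpec(1.0, ((1, 1.0, 0.0),))
        traj = TVSPTrajectory(
            t=GRID8, dm=np.zeros_like(GRID8),
            dk=np.full_like(GRID8, -params.k0 / 3), dc=np.zeros_like(GRID8),
        )
        m_tv = simulate_1dof_tv(params, traj, spec, grid=GRID8)
        lti = TCSParams(m0=params.m0, k0=2 * params.k0 / 3, c0=params.c0,
                        f_c=params.f_c)
        m_eq = simulate_1dof_tv(lti, None, spec, grid=GRID8)
        scale = np.max(np.abs(m_eq.signal.samples))
        assert np.max(np.abs(m_tv.signal.samples - m_eq.signal.samples)) < 1e-6 * scale

    def test_superposition_in_lti_limit(self, params):
        s1 = HarmonicSpec(1.0, ((1, 1.0, 0.0),))
        s2 = HarmonicSpec(1.0, ((3, 0.5, 1.0),))
        s12 = HarmonicSpec(1.0, ((1, 1.0, 0.0), (3, 0.5, 1.0)))
        r1 = simulate_1dof_tv(params, None, s1, grid=GRID8).signal.samples
        r2 = simulate_1dof_tv(params, None, s2, grid=GRID8).signal.samples
        r12 = simulate_1dof_tv(params, None, s12, grid=GRID8).signal.samples
        scale = np.max(np.abs(r12))
        assert np.max(np.abs(r1 + r2 - r12)) < 1e-6 * scale

    def test_solver_refinement_converges(self, params, carotid, drift12):
        """Tightening tolerances changes the TV response only marginally."""
        from pulsema.tcs import tvsp_from_drift

        tvsp = tvsp_from_drift(drift12, params)
        coarse = simulate_1dof_tv(params, tvsp, carotid, grid=drift12.t)
        fine = simulate_1dof_tv(
            params, tvsp, carotid, grid=drift12.t,
            solver_opts={"rtol": 5e-9, "atol": 5e-11},
        )
        scale = np.max(np.abs(fine.signal.samples))
        assert np.max(np.abs(coarse.signal.samples - fine.signal.samples)) < 1e-4 * scale


class TestSimulate2DOF:
    def test_zero_force_stays_at_rest(self, params, artery):
        F = PulseSignal(200.0, np.zeros(400))
        m1, m2 = simulate_2dof_tv(params, artery, None, F)
        assert np.max(np.abs(m1.signal.samples)) < 1e-12
        assert np.max(np.abs(m2.signal.samples)) < 1e-12

    def test_lti_steady_state_matches_transfer(self, params, artery):
        spec = HarmonicSpec(1.0, ((1, 1.0, 0.0),))
        m1, m2 = simulate_2dof_tv(params, artery, None, spec, grid=GRID8)
        sl = GRID8 >= 3.0
        g10, g20 = transfer_2dof(params, artery, 1.0)
        c1 = fit_harmonic(GRID8[sl], m1.signal.samples[sl], 1.0)
        c2 = fit_harmonic(GRID8[sl], m2.signal.samples[sl], 1.0)
        assert abs(c1 - g10) / abs(g10) < 1e-3
        assert abs(c2 - g20) / abs(g20) < 1e-3

    def test_stiff_wall_limit(self, params):
        """Near-rigid wall: x1 ~ F/kA and x2/x1 ~ the 1DOF gain.

        The wall equation's time constant c0/(kA+k0) makes the system
        stiff, so this limit uses an implicit-capable solver.
        """
        from pulsema.waveforms import ArteryParams

        stiff = ArteryParams(kA=1e4 * params.k0, a=1.0)
        spec = HarmonicSpec(1.0, ((1, 1.0, 0.0),))
        m1, m2 = simulate_2dof_tv(params, stiff, None, spec, grid=GRID8,
                                  solver_opts={"method": "LSODA"})
        sl = GRID8 >= 3.0
        c1 = fit_harmonic(GRID8[sl], m1.signal.samples[sl], 1.0)
        c2 = fit_harmonic(GRID8[sl], m2.signal.samples[sl], 1.0)
        assert abs(c1 - 1.0 / stiff.kA) / (1.0 / stiff.kA) < 0.01
        assert abs(c2 / c1 - transfer_1dof(params, 1.0)) < 0.01


class TestDriftPair:
    def test_zero_drift(self, params, artery):
        x2b = PulseSignal(200.0, np.zeros(400))
        x1b, fb = drift_pair_2dof(params, artery, x2b)
        assert np.max(np.abs(x1b.samples)) < 1e-12
        assert np.max(np.abs(fb.samples)) < 1e-12

    def test_static_ratio_one_seventh(self, params, artery):
        """Constant mass drift settles the wall at C*k0/(kA+k0) = C/7."""
        C = 0.8
        x2b = PulseSignal(200.0, np.full(1600, C))
        x1b, fb = drift_pair_2dof(params, artery, x2b)
        assert x1b.samples[-1] == pytest.approx(C / 7, rel=1e-6)
        expected_fb = C * params.k0 * artery.kA / (artery.kA + params.k0)
        assert fb.samples[-1] == pytest.approx(expected_fb, rel=1e-6)

    def test_harmonic_ratio_matches_frequency_domain(self, params, artery):
        """Steady ratio x1b/x2b equals (k0+jwc0)/(kA+k0+jwc0) at 0.2 Hz."""
        t = np.arange(20 * 200) / 200.0
        x2b = PulseSignal(200.0, np.sin(2 * np.pi * 0.2 * t))
        x1b, _ = drift_pair_2dof(params, artery, x2b)
        sl = (t > 5) & (t < 15)
        c1 = fit_harmonic(t[sl], x1b.samples[sl], 0.2)
        c2 = fit_harmonic(t[sl], x2b.samples[sl], 0.2)
        w = 2 * np.pi * 0.2
        H = (params.k0 + 1j * params.c0 * w) / (
            artery.kA + params.k0 + 1j * params.c0 * w)
        assert abs(c1 / c2 - H) / abs(H) < 1e-3

    def test_equation_residual_small_in_interior(self, params, artery, drift12):
        x1b, fb = drift_pair_2dof(params, artery, drift12)
        r = ((artery.kA + params.k0) * x1b.samples
             - params.k0 * drift12.samples
             + params.c0 * (signal_derivative(x1b, 1)
                            - signal_derivative(drift12, 1)))
        interior = (drift12.t > 1.0) & (drift12.t < 11.0)
        assert np.max(np.abs(r[interior])) < 1e-6 * np.max(np.abs(fb.samples))


class TestRunCaseWall:
    def test_ma_free_case_identities(self, params, carotid):
        res = run_case_wall(params, carotid, None, grid=GRID8)
        assert np.array_equal(res.x_ACC, res.x_C)
        assert np.allclose(res.x_PPG, res.y)
        assert np.all(res.x_TVSP == 0)

    def test_ppg_and_acc_distortion_identity(self, wall_result):
        """With identity transduction, x_PPG - y = x_ACC - x_C pointwise."""
        lhs = wall_result.x_PPG - wall_result.y
        rhs = wall_result.x_ACC - wall_result.x_C
        assert np.allclose(lhs, rhs, atol=1e-14)

    def test_reconstruction_identity_machine_precision(self, wall_result):
        resid = (wall_result.x_ACC - wall_result.x_C - wall_result.x_b
                 - wall_result.x_TVSP)
        assert np.max(np.abs(resid)) < 1e-12

    def test_tvsp_distortion_invariant_to_drift_amplitude(self, params, carotid,
                                                          wall_result, drift12):
        """Eq.-24 normalization: scaling the drift rescales x_b and x_ACC
        but leaves the TVSP distortion unchanged."""
        res_big = run_case_wall(params, carotid, drift12 * 3.0)
        scale = np.max(np.abs(wall_result.x_TVSP))
        assert np.max(np.abs(res_big.x_TVSP - wall_result.x_TVSP)) < 1e-4 * scale
        assert np.max(np.abs(res_big.x_b - 3.0 * wall_result.x_b)) < 1e-12


class TestRunCasePressure:
    def test_ma_free_case(self, params, artery, carotid):
        res = run_case_pressure_clean(params, artery, carotid)
        assert np.array_equal(res.x_ACC, res.x_2C)
        assert np.array_equal(res.x_PPG, res.x_1C)

    def test_static_pressure_static_deflection(self, params, artery):
        """A constant wall force settles both masses at F/kA."""
        F0 = 0.5  # constant force (already pi*a*dp)
        t = np.arange(1600) / 200.0
        dp = PulseSignal(200.0, np.full_like(t, F0 / (np.pi * artery.a)))
        from pulsema.dynamics import run_case_pressure

        res = run_case_pressure(params, artery, dp, None)
        assert res.x_1C[-1] == pytest.approx(F0 / artery.kA, rel=1e-6)
        assert res.x_2C[-1] == pytest.approx(F0 / artery.kA, rel=1e-6)

    def test_equation_residuals_on_returned_motion(self, pressure_result,
                                                   params, artery):
        """Substituting (x_1M, x_2M) back into the TV equations of motion."""
        res = pressure_result
        tvsp = res.tvsp
        k = params.k0 + tvsp.dk
        c = params.c0 + tvsp.dc
        m = params.m0 + tvsp.dm
        v1 = res.motion_1M.velocity
        v2 = res.motion_2M.velocity
        a2 = res.motion_2M.acceleration
        r1 = ((artery.kA + k) * res.x_1M - k * res.x_2M + c * (v1 - v2)
              - res.F)
        r2 = k * (res.x_2M - res.x_1M) + c * (v2 - v1) + m * a2
        scale = np.max(np.abs(res.F))
        assert np.max(np.abs(r1)) < 1e-6 * scale
        assert np.max(np.abs(r2)) < 1e-6 * scale

    def test_acc_decomposition_identity(self, pressure_result):
        resid = (pressure_result.x_ACC - pressure_result.x_2M
                 - pressure_result.x_2b)
        assert np.max(np.abs(resid)) < 1e-14


def run_case_pressure_clean(params, artery, carotid):
    from pulsema.dynamics import run_case_pressure

    return run_case_pressure(params, artery, carotid, None, grid=GRID8)


class TestInstantAttributes:
    def test_pure_cosine(self):
        t = np.arange(2000) / 200.0
        sig = PulseSignal(200.0, np.cos(2 * np.pi * t))
        ia = instantaneous_attributes(sig)
        interior = slice(200, -200)
        assert np.allclose(ia.amplitude[interior], 1.0, atol=0.01)
        assert np.allclose(ia.frequency[interior], 1.0, atol=0.005)

    def test_am_envelope_recovered(self):
        t = np.arange(4000) / 200.0
        env = 1 + 0.1 * np.sin(0.2 * np.pi * t)
        sig = PulseSignal(200.0, env * np.cos(2 * np.pi * t))
        ia = instantaneous_attributes(sig)
        interior = slice(400, -400)
        assert np.max(np.abs(ia.amplitude[interior] - env[interior])
                      / env[interior]) < 0.02

    def test_zero_signal_masked(self):
        sig = PulseSignal(200.0, np.zeros(400))
        ia = instantaneous_attributes(sig)
        assert not ia.valid.any()
        assert np.all(np.isnan(ia.frequency))
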