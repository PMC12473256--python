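"""Time-domain integration of the time-varying TCS equations of motion.

Two excitation routes are modeled:

* wall displacement y(t) as the true pulse signal, base-exciting the 1DOF
  stack: ``(m0+dm) x'' + (c0+dc) x' + (k0+dk) x = (k0+dk) y + (c0+dc) y'``;
* pulsatile pressure dp(t) as the true pulse signal, forcing F = pi*a*dp
  on the arterial wall (a massless spring kA) coupled to the stack — a
  2DOF system whose wall equation is first order.

Both are integrated as first-order state-space systems with an adaptive
explicit Runge-Kutta solver (scipy ``solve_ivp`` RK45, rtol 1e-8,
atol 1e-10 by default), starting from rest.  Velocities come from the
solver state and accelerations from the right-hand side, never from
differencing the output, so that downstream force residuals stay near
solver tolerance.

The scenario drivers :func:`run_case_wall` and :func:`run_case_pressure`
assemble the full decomposition: MA-free response, TVSP distortion,
accelerometer and PPG sensor outputs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.integrate import solve_ivp
from scipy.interpolate import CubicSpline
from scipy.signal import hilbert

from .tcs import DEFAULT_GAINS, TCSParams, TVSPTrajectory, tvsp_from_drift
from .waveforms import (
    ArteryParams,
    HarmonicSpec,
    PulseSignal,
    pressure_to_force,
    scale_harmonics,
    signal_derivative,
)

__all__ = [
    "SolverError",
    "Motion",
    "SimResult1DOF",
    "SimResult2DOF",
    "InstantAttributes",
    "identity_transduction",
    "simulate_1dof_tv",
    "simulate_2dof_tv",
    "drift_pair_2dof",
    "run_case_wall",
    "run_case_pressure",
    "instantaneous_attributes",
    "default_settle_cycles",
]

DEFAULT_SOLVER_OPTS = {"method": "RK45", "rtol": 1e-8, "atol": 1e-10}


class SolverError(RuntimeError):
    """ODE integration failed; carries the solver diagnostics."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


def identity_transduction(u: np.ndarray) -> np.ndarray:
    """Default optical transduction g(u) = u."""
    return u


@dataclass
class Motion:
    """Displacement plus solver-state velocity/acceleration on a grid."""

    signal: PulseSignal
    velocity: np.ndarray
    acceleration: np.ndarray | None
    diagnostics: dict = field(default_factory=dict)


def _excitation_callables(
    y: PulseSignal | HarmonicSpec,
    grid: np.ndarray | None = None,
) -> tuple[Callable, Callable, np.ndarray | None]:
    """(value, derivative) callables; analytic for harmonic specs."""
    if isinstance(y, HarmonicSpec):
        return y, (lambda t: y.derivative(t, 1)), None
    spline = CubicSpline(y.t, y.samples)
    return spline, spline.derivative(1), y.samples


def _check_solution(sol, context: str):
    if not sol.success:
        raise SolverError(
            f"{context}: {sol.message}",
            {"nfev": sol.nfev, "status": sol.status},
        )


def simulate_1dof_tv(
    params: TCSParams,
    tvsp: TVSPTrajectory | None,
    y: PulseSignal | HarmonicSpec,
    grid: np.ndarray | None = None,
    solver_opts: dict | None = None,
) -> Motion:
    """Integrate the (possibly time-varying) base-excited 1DOF equation.

    ``y`` may be a tabulated signal (its grid is the output grid) or a
    harmonic spec (then ``grid`` or the TVSP grid supplies the output
    times).  With ``tvsp=None`` the system is LTI and the steady state
    matches the closed-form transfer function.
    """
    opts = {**DEFAULT_SOLVER_OPTS, **(solver_opts or {})}
    if isinstance(y, PulseSignal):
        t = y.t
        fs = y.fs
    else:
        if grid is None and tvsp is None:
            raise ValueError("harmonic excitation needs an explicit time grid")
        t = grid if grid is not None else tvsp.t
        fs = 1.0 / (t[1] - t[0])
    if tvsp is not None and (tvsp.t[0] > t[0] + 1e-12 or tvsp.t[-1] < t[-1] - 1e-12):
        raise ValueError("TVSP trajectory does not cover the excitation grid")

    fy, fyd, _ = _excitation_callables(y)
    m0, k0, c0 = params.m0, params.k0, params.c0
    if tvsp is None:
        def coeffs(ti):
            return m0, k0, c0
    else:
        fm, fk, fc = tvsp.interpolants()

        def coeffs(ti):
            return m0 + fm(ti), k0 + fk(ti), c0 + fc(ti)

    def rhs(ti, s):
        x, v = s
        mt, kt, ct = coeffs(ti)
        return (v, (kt * (fy(ti) - x) + ct * (fyd(ti) - v)) / mt)

    sol = solve_ivp(rhs, (t[0], t[-1]), (0.0, 0.0), t_eval=t, **opts)
    _check_solution(sol, "1DOF time-varying simulation")
    x, v = sol.y
    # acceleration from the equation of motion on the grid (vectorized)
    if tvsp is None:
        mt, kt, ct = m0, k0, c0
    else:
        mt, kt, ct = m0 + tvsp.dm, k0 + tvsp.dk, c0 + tvsp.dc
    yv, yd = fy(t), fyd(t)
    a = (kt * (yv - x) + ct * (yd - v)) / mt
    return Motion(
        signal=PulseSignal(fs, x, t_start=t[0], label="x"),
        velocity=v,
        acceleration=a,
        diagnostics={"nfev": sol.nfev, "solver": opts["method"]},
    )


def simulate_2dof_tv(
    params: TCSParams,
    artery: ArteryParams,
    tvsp: TVSPTrajectory | None,
    force: PulseSignal | HarmonicSpec,
    grid: np.ndarray | None = None,
    solver_opts: dict | None = None,
) -> tuple[Motion, Motion]:
    """Integrate the 2DOF wall + stack system under a wall force F(t).

    The arterial wall is a massless spring, so its equation is first
    order; states are (x1, x2, x2').  Returns motions at the wall (x1)
    and at the mass (x2).  The wall velocity is recovered from the wall
    equation; the mass acceleration reduces to ``(F - kA*x1)/m(t)``.
    """
    opts = {**DEFAULT_SOLVER_OPTS, **(solver_opts or {})}
    if isinstance(force, PulseSignal):
        t = force.t
        fs = force.fs
    else:
        if grid is None and tvsp is None:
            raise ValueError("harmonic forcing needs an explicit time grid")
        t = grid if grid is not None else tvsp.t
        fs = 1.0 / (t[1] - t[0])

    fF, _, _ = _excitation_callables(force)
    m0, k0, c0, kA = params.m0, params.k0, params.c0, artery.kA
    if tvsp is None:
        def coeffs(ti):
            return m0, k0, c0
    else:
        fm, fk, fc = tvsp.interpolants()

        def coeffs(ti):
            return m0 + fm(ti), k0 + fk(ti), c0 + fc(ti)

    def rhs(ti, s):
        x1, x2, v2 = s
        mt, kt, ct = coeffs(ti)
        Fi = fF(ti)
        v1 = v2 + (Fi - (kA + kt) * x1 + kt * x2) / ct
        a2 = (Fi - kA * x1) / mt
        return (v1, v2, a2)

    sol = solve_ivp(rhs, (t[0], t[-1]), (0.0, 0.0, 0.0), t_eval=t, **opts)
    _check_solution(sol, "2DOF time-varying simulation")
    x1, x2, v2 = sol.y
    if tvsp is None:
        mt, kt, ct = m0, k0, c0
    else:
        mt, kt, ct = m0 + tvsp.dm, k0 + tvsp.dk, c0 + tvsp.dc
    Ft = fF(t)
    v1 = v2 + (Ft - (kA + kt) * x1 + kt * x2) / ct
    a2 = (Ft - kA * x1) / mt
    wall = Motion(PulseSignal(fs, x1, t_start=t[0], label="x1"), v1, None,
                  {"nfev": sol.nfev})
    mass = Motion(PulseSignal(fs, x2, t_start=t[0], label="x2"), v2, a2,
                  {"nfev": sol.nfev})
    return wall, mass


def drift_pair_2dof(
    params: TCSParams,
    artery: ArteryParams,
    x2b: PulseSignal,
    solver_opts: dict | None = None,
) -> tuple[PulseSignal, PulseSignal]:
    """Drift at the wall and its equivalent force, from drift at the mass.

    Force balance of the MA-only motion gives a first-order equation for
    the wall drift x1b driven by the mass drift x2b, plus the drift force
    ``Fb = k0*(x2b-x1b) + c0*(x2b'-x1b') + m0*x2b''``.  The integration
    starts from the quasi-static wall position; any residual
    inconsistency decays with the fast time constant c0/(kA+k0).
    """
    opts = {**DEFAULT_SOLVER_OPTS, **(solver_opts or {})}
    t = x2b.t
    # smoothness guard: drift should be far below Nyquist
    detrended = x2b.samples - np.linspace(
        x2b.samples[0], x2b.samples[-1], len(x2b))
    spec = np.abs(np.fft.rfft(detrended)) ** 2
    freqs = np.fft.rfftfreq(len(x2b), 1 / x2b.fs)
    total = spec.sum()
    if total > 0 and spec[freqs > x2b.fs / 4].sum() > 1e-4 * total:
        warnings.warn("mass drift has spectral energy above fs/4; "
                      "derivatives may be inaccurate", stacklevel=2)
    sp = CubicSpline(t, x2b.samples)
    d1, d2 = sp.derivative(1), sp.derivative(2)
    m0, k0, c0, kA = params.m0, params.k0, params.c0, artery.kA

    def rhs(ti, s):
        return (d1(ti) + (k0 * sp(ti) - (kA + k0) * s[0]) / c0,)

    # quasi-static IC with a first-order slope correction: x1b ~ H(0)*x2b +
    # H'(0)*x2b' suppresses most of the start-up transient
    x1b0 = (k0 / (kA + k0) * x2b.samples[0]
            + c0 * kA / (kA + k0) ** 2 * d1(t[0]))
    sol = solve_ivp(rhs, (t[0], t[-1]), (x1b0,), t_eval=t, **opts)
    _check_solution(sol, "wall-drift propagation")
    x1b = sol.y[0]
    v1b = d1(t) + (k0 * x2b.samples - (kA + k0) * x1b) / c0
    fb = k0 * (x2b.samples - x1b) + c0 * (d1(t) - v1b) + m0 * d2(t)
    return (
        PulseSignal(x2b.fs, x1b, t_start=x2b.t_start, label="x1b"),
        PulseSignal(x2b.fs, fb, t_start=x2b.t_start, label="Fb"),
    )


def default_settle_cycles(params: TCSParams) -> float:
    """Lead-in discarded before analysis: max(5/(zeta0*omega0), 2 cycles)."""
    return max(5.0 / (params.zeta0 * params.omega0) * params.f_c, 2.0)


@dataclass
class SimResult1DOF:
    """Wall-displacement scenario bundle (1DOF stack).

    Invariants held by construction: ``x_ACC = x_M + x_b`` and
    ``x_M = x_C + x_TVSP`` exactly; all series share the grid.
    """

    t: np.ndarray
    fs: float
    params: TCSParams
    tvsp: TVSPTrajectory | None
    y: np.ndarray
    y_dot: np.ndarray
    x_b: np.ndarray
    x_C: np.ndarray
    x_M: np.ndarray
    x_TVSP: np.ndarray
    x_ACC: np.ndarray
    x_PPG: np.ndarray
    x_ACC_MA: np.ndarray
    x_PPG_MA: np.ndarray
    settle_index: int
    diagnostics: dict
    motion_M: Motion
    motion_C: Motion

    def series(self) -> dict[str, np.ndarray]:
        return {
            "y": self.y, "x_b": self.x_b, "x_C": self.x_C, "x_M": self.x_M,
            "x_TVSP": self.x_TVSP, "x_ACC": self.x_ACC, "x_PPG": self.x_PPG,
            "x_ACC_MA": self.x_ACC_MA, "x_PPG_MA": self.x_PPG_MA,
        }

    def as_signal(self, name: str) -> PulseSignal:
        return PulseSignal(self.fs, self.series()[name], t_start=self.t[0],
                           label=name)


@dataclass
class SimResult2DOF:
    """Pulsatile-pressure scenario bundle (2DOF wall + stack).

    Invariants held by construction: ``x_ACC = x_2M + x_2b`` and
    ``x_iM = x_iC + x_iTVSP`` exactly.
    """

    t: np.ndarray
    fs: float
    params: TCSParams
    artery: ArteryParams
    tvsp: TVSPTrajectory | None
    F: np.ndarray
    x_1b: np.ndarray
    x_2b: np.ndarray
    F_b: np.ndarray
    x_1C: np.ndarray
    x_2C: np.ndarray
    x_1M: np.ndarray
    x_2M: np.ndarray
    x_1TVSP: np.ndarray
    x_2TVSP: np.ndarray
    x_ACC: np.ndarray
    x_PPG: np.ndarray
    x_ACC_MA: np.ndarray
    x_PPG_MA: np.ndarray
    settle_index: int
    diagnostics: dict
    motion_1M: Motion
    motion_2M: Motion
    motion_1C: Motion
    motion_2C: Motion

    def series(self) -> dict[str, np.ndarray]:
        return {
            "F": self.F, "x_1b": self.x_1b, "x_2b": self.x_2b, "F_b": self.F_b,
            "x_1C": self.x_1C, "x_2C": self.x_2C, "x_1M": self.x_1M,
            "x_2M": self.x_2M, "x_1TVSP": self.x_1TVSP,
            "x_2TVSP": self.x_2TVSP, "x_ACC": self.x_ACC, "x_PPG": self.x_PPG,
            "x_ACC_MA": self.x_ACC_MA, "x_PPG_MA": self.x_PPG_MA,
        }

    def as_signal(self, name: str) -> PulseSignal:
        return PulseSignal(self.fs, self.series()[name], t_start=self.t[0],
                           label=name)


def run_case_wall(
    params: TCSParams,
    y: PulseSignal | HarmonicSpec,
    drift: PulseSignal | None,
    gains: tuple[float, float, float] = DEFAULT_GAINS,
    normalizer: float | str = "max",
    g: Callable[[np.ndarray], np.ndarray] = identity_transduction,
    settle_cycles: float | None = None,
    solver_opts: dict | None = None,
    grid: np.ndarray | None = None,
) -> SimResult1DOF:
    """Full wall-displacement scenario: drift, TVSPs, sensors, distortions.

    ``drift=None`` (or all-zero gains) gives the MA-free case where the
    accelerometer reads x_C and the PPG sensor reads y.
    """
    if isinstance(y, PulseSignal):
        t, fs = y.t, y.fs
    elif drift is not None:
        t, fs = drift.t, drift.fs
    elif grid is not None:
        t, fs = grid, 1.0 / (grid[1] - grid[0])
    else:
        raise ValueError("need a tabulated signal or grid to fix the sampling")
    if drift is not None and isinstance(y, PulseSignal) and not y.same_grid(drift):
        raise ValueError("pulse and drift must share the sampling grid")

    tvsp = None
    if drift is not None and any(gi != 0 for gi in gains):
        tvsp = tvsp_from_drift(drift, params, gains, normalizer)

    motion_C = simulate_1dof_tv(params, None, y, grid=t, solver_opts=solver_opts)
    if tvsp is not None:
        motion_M = simulate_1dof_tv(params, tvsp, y, grid=t, solver_opts=solver_opts)
    else:
        motion_M = motion_C

    if isinstance(y, HarmonicSpec):
        yv, yd = y(t), y.derivative(t, 1)
    else:
        yv = y.samples
        yd = signal_derivative(y)

    xb = drift.samples if drift is not None else np.zeros_like(t)
    x_C = motion_C.signal.samples
    x_M = motion_M.signal.samples
    x_TVSP = x_M - x_C
    x_ACC = x_M + xb
    x_ACC_MA = x_TVSP + xb
    x_PPG_MA = g(x_TVSP + xb)
    x_PPG = yv + x_PPG_MA
    settle = default_settle_cycles(params) if settle_cycles is None else settle_cycles
    settle_index = min(int(round(settle * fs / params.f_c)), len(t) - 1)
    return SimResult1DOF(
        t=t, fs=fs, params=params, tvsp=tvsp, y=yv, y_dot=yd, x_b=xb,
        x_C=x_C, x_M=x_M, x_TVSP=x_TVSP, x_ACC=x_ACC, x_PPG=x_PPG,
        x_ACC_MA=x_ACC_MA, x_PPG_MA=x_PPG_MA, settle_index=settle_index,
        diagnostics={
            "nfev_M": motion_M.diagnostics.get("nfev"),
            "nfev_C": motion_C.diagnostics.get("nfev"),
        },
        motion_M=motion_M, motion_C=motion_C,
    )


def run_case_pressure(
    params: TCSParams,
    artery: ArteryParams,
    dp: PulseSignal | HarmonicSpec,
    drift_x2b: PulseSignal | None,
    gains: tuple[float, float, float] = DEFAULT_GAINS,
    normalizer: float | str = "max",
    g: Callable[[np.ndarray], np.ndarray] = identity_transduction,
    settle_cycles: float | None = None,
    solver_opts: dict | None = None,
    grid: np.ndarray | None = None,
) -> SimResult2DOF:
    """Full pulsatile-pressure scenario (2DOF wall + stack).

    The mass drift x2b propagates to the wall drift x1b by force balance,
    and the TVSPs are slaved to the stack compression x2b - x1b
    (normalized by its own maximum, mirroring the 1DOF drift law).
    """
    if isinstance(dp, PulseSignal):
        t, fs = dp.t, dp.fs
        force: PulseSignal | HarmonicSpec = pressure_to_force(dp, artery)
    else:
        force = scale_harmonics(dp, np.pi * artery.a)
        if drift_x2b is not None:
            t, fs = drift_x2b.t, drift_x2b.fs
        elif grid is not None:
            t, fs = grid, 1.0 / (grid[1] - grid[0])
        else:
            raise ValueError("need a tabulated signal or grid to fix the sampling")

    if drift_x2b is not None:
        x1b_sig, fb_sig = drift_pair_2dof(params, artery, drift_x2b, solver_opts)
        x1b, x2b, fb = x1b_sig.samples, drift_x2b.samples, fb_sig.samples
    else:
        x1b = x2b = fb = np.zeros_like(t)

    tvsp = None
    if drift_x2b is not None and any(gi != 0 for gi in gains):
        driver = PulseSignal(fs, x2b - x1b, t_start=t[0], label="x2b-x1b")
        tvsp = tvsp_from_drift(driver, params, gains, normalizer)

    m1C, m2C = simulate_2dof_tv(params, artery, None, force, grid=t,
                                solver_opts=solver_opts)
    if tvsp is not None:
        m1M, m2M = simulate_2dof_tv(params, artery, tvsp, force, grid=t,
                                    solver_opts=solver_opts)
    else:
        m1M, m2M = m1C, m2C

    Ft = force(t) if isinstance(force, HarmonicSpec) else force.samples
    x_1C, x_2C = m1C.signal.samples, m2C.signal.samples
    x_1M, x_2M = m1M.signal.samples, m2M.signal.samples
    x_1TVSP = x_1M - x_1C
    x_2TVSP = x_2M - x_2C
    x_ACC = x_2M + x2b
    x_ACC_MA = x_2TVSP + x2b
    g_term = g(x_2TVSP + x2b)
    x_PPG = x_1M + x1b + g_term
    x_PPG_MA = x_1TVSP + x1b + g_term
    settle = default_settle_cycles(params) if settle_cycles is None else settle_cycles
    settle_index = min(int(round(settle * fs / params.f_c)), len(t) - 1)
    return SimResult2DOF(
        t=t, fs=fs, params=params, artery=artery, tvsp=tvsp, F=Ft,
        x_1b=x1b, x_2b=x2b, F_b=fb, x_1C=x_1C, x_2C=x_2C, x_1M=x_1M,
        x_2M=x_2M, x_1TVSP=x_1TVSP, x_2TVSP=x_2TVSP, x_ACC=x_ACC,
        x_PPG=x_PPG, x_ACC_MA=x_ACC_MA, x_PPG_MA=x_PPG_MA,
        settle_index=settle_index,
        diagnostics={
            "nfev_M": m2M.diagnostics.get("nfev"),
            "nfev_C": m2C.diagnostics.get("nfev"),
        },
        motion_1M=m1M, motion_2M=m2M, motion_1C=m1C, motion_2C=m2C,
    )


@dataclass
class InstantAttributes:
    """Analytic-signal instantaneous amplitude, phase and frequency."""

    t: np.ndarray
    amplitude: np.ndarray
    phase: np.ndarray
    frequency: np.ndarray  # Hz; NaN where the envelope vanishes
    valid: np.ndarray


def instantaneous_attributes(
    x: PulseSignal, amplitude_floor: float = 1e-3
) -> InstantAttributes:
    """Instantaneous attributes via the Hilbert analytic signal.

    The signal should be (near) zero-mean over the window; the mean is
    removed before the transform.  Frequency is masked (NaN) where the
    envelope drops below ``amplitude_floor`` times its maximum.
    """
    s = x.samples - np.mean(x.samples)
    analytic = hilbert(s)
    amp = np.abs(analytic)
    phase = np.unwrap(np.angle(analytic))
    freq = np.gradient(phase, x.t) / (2 * np.pi)
    valid = amp > amplitude_floor * (amp.max() if amp.max() > 0 else 1.0)
    freq = np.where(valid, freq, np.nan)
    return InstantAttributes(t=x.t, amplitude=amp, phase=phase,
                             frequency=freq, valid=valid)
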