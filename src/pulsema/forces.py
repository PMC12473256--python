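"""Equivalent-force representation of motion artifacts.

Instead of perturbing the stack parameters, the influence of MA can be
carried entirely by forces applied to the *nominal* time-invariant
system: the drift force F_b, the TVSP force F_TVSP (difference between
the nominal-operator image of the distorted motion and the base-
excitation force), and their sum F_MA.  Driving the nominal system with
the original excitation plus these forces reproduces the distorted
measurement — the force-closure property that certifies the whole
decomposition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp
from scipy.interpolate import CubicSpline

from .dynamics import DEFAULT_SOLVER_OPTS, SimResult1DOF, SimResult2DOF, _check_solution
from .tcs import TCSParams
from .waveforms import ArteryParams, HarmonicSpec, PulseSignal, signal_derivative

__all__ = [
    "ForceSet1DOF",
    "ForceSet2DOF",
    "ReconstructionReport",
    "ReconstructionError",
    "drift_force_1dof",
    "base_excitation_force",
    "equivalent_forces_1dof",
    "equivalent_forces_2dof",
    "reconstruct_from_forces",
]


@dataclass
class ForceSet1DOF:
    """Equivalent forces for the wall-displacement (1DOF) scenario.

    ``F_MA = F_TVSP + F_b`` holds pointwise by construction.
    """

    t: np.ndarray
    fs: float
    F_b: np.ndarray
    F_C: np.ndarray
    F_T: np.ndarray
    F_TVSP: np.ndarray
    F_MA: np.ndarray

    def series(self) -> dict[str, np.ndarray]:
        return {"F_b": self.F_b, "F_C": self.F_C, "F_T": self.F_T,
                "F_TVSP": self.F_TVSP, "F_MA": self.F_MA}


@dataclass
class ForceSet2DOF:
    """Equivalent forces for the pulsatile-pressure (2DOF) scenario.

    F_1MA acts on the arterial wall, F_2MA on the sensor mass;
    ``F_2MA = F_2TVSP + F_b`` holds pointwise by construction.
    """

    t: np.ndarray
    fs: float
    F: np.ndarray
    F_b: np.ndarray
    F_1T: np.ndarray
    F_2T: np.ndarray
    F_1TVSP: np.ndarray
    F_2TVSP: np.ndarray
    F_1MA: np.ndarray
    F_2MA: np.ndarray

    def series(self) -> dict[str, np.ndarray]:
        return {"F": self.F, "F_b": self.F_b, "F_1T": self.F_1T,
                "F_2T": self.F_2T, "F_1TVSP": self.F_1TVSP,
                "F_2TVSP": self.F_2TVSP, "F_1MA": self.F_1MA,
                "F_2MA": self.F_2MA}


def drift_force_1dof(xb: PulseSignal, params: TCSParams) -> PulseSignal:
    """Force associated with baseline drift: ``F_b = m0*xb'' + c0*xb' + k0*xb``.

    Derivatives come from a cubic-spline interpolant of the band-limited
    drift.
    """
    d1 = signal_derivative(xb, 1)
    d2 = signal_derivative(xb, 2)
    fb = params.m0 * d2 + params.c0 * d1 + params.k0 * xb.samples
    return xb.with_samples(fb, label="F_b")


def base_excitation_force(
    y: PulseSignal | HarmonicSpec,
    params: TCSParams,
    grid: np.ndarray | None = None,
) -> PulseSignal:
    """Equivalent force of the base excitation: ``F_C = k0*y + c0*y'``."""
    if isinstance(y, HarmonicSpec):
        if grid is None:
            raise ValueError("harmonic excitation needs a time grid")
        fc = params.k0 * y(grid) + params.c0 * y.derivative(grid, 1)
        fs = 1.0 / (grid[1] - grid[0])
        return PulseSignal(fs, fc, t_start=grid[0], label="F_C")
    fc = params.k0 * y.samples + params.c0 * signal_derivative(y, 1)
    return y.with_samples(fc, label="F_C")


def equivalent_forces_1dof(result: SimResult1DOF, params: TCSParams) -> ForceSet1DOF:
    """Equivalent forces from a completed wall-displacement run.

    ``F_T`` substitutes the distorted motion into the nominal operator
    using the solver-state velocity and acceleration; for an MA-free run
    it collapses onto F_C and F_TVSP vanishes to solver tolerance.
    """
    m = result.motion_M
    f_t = (params.m0 * m.acceleration + params.c0 * m.velocity
           + params.k0 * result.x_M)
    f_c = params.k0 * result.y + params.c0 * result.y_dot
    if np.any(result.x_b):
        xb = PulseSignal(result.fs, result.x_b, t_start=result.t[0])
        f_b = drift_force_1dof(xb, params).samples
    else:
        f_b = np.zeros_like(result.t)
    f_tvsp = f_t - f_c
    return ForceSet1DOF(t=result.t, fs=result.fs, F_b=f_b, F_C=f_c, F_T=f_t,
                        F_TVSP=f_tvsp, F_MA=f_tvsp + f_b)


def equivalent_forces_2dof(
    result: SimResult2DOF, params: TCSParams, artery: ArteryParams
) -> ForceSet2DOF:
    """Equivalent forces from a completed pulsatile-pressure run.

    F_1T and F_2T substitute the distorted motions into the nominal
    left-hand sides of the wall and mass equations; F_1MA = F_1T - F acts
    on the wall and F_2MA = F_2T + F_b on the mass.
    """
    m1, m2 = result.motion_1M, result.motion_2M
    k0, c0, m0, kA = params.k0, params.c0, params.m0, artery.kA
    f_1t = ((kA + k0) * result.x_1M - k0 * result.x_2M
            + c0 * (m1.velocity - m2.velocity))
    f_2t = (k0 * (result.x_2M - result.x_1M)
            + c0 * (m2.velocity - m1.velocity) + m0 * m2.acceleration)
    f_1tvsp = f_1t - result.F
    f_2tvsp = f_2t
    return ForceSet2DOF(
        t=result.t, fs=result.fs, F=result.F, F_b=result.F_b,
        F_1T=f_1t, F_2T=f_2t, F_1TVSP=f_1tvsp, F_2TVSP=f_2tvsp,
        F_1MA=f_1tvsp, F_2MA=f_2tvsp + result.F_b,
    )


@dataclass
class ReconstructionReport:
    """Force-closure check: nominal-LTI reconstruction vs target."""

    reconstructed: tuple[np.ndarray, ...]
    target: tuple[np.ndarray, ...]
    rel_residual: float


class ReconstructionError(RuntimeError):
    def __init__(self, report: ReconstructionReport):
        super().__init__(
            f"force reconstruction residual {report.rel_residual:.3e} "
            "exceeds tolerance"
        )
        self.report = report


def reconstruct_from_forces(
    params: TCSParams,
    artery: ArteryParams | None,
    result: SimResult1DOF | SimResult2DOF,
    forces: ForceSet1DOF | ForceSet2DOF,
    tol: float | None = 1e-3,
    solver_opts: dict | None = None,
) -> ReconstructionReport:
    """Verify that the equivalent forces reproduce the distorted motion.

    1DOF: the nominal LTI system driven by the base excitation plus F_MA
    must reproduce ``x_M + x_b``.  2DOF: the nominal system driven by the
    MA forces alone (F_1MA on the wall, F_2MA on the mass) must reproduce
    ``x_iM + x_ib - x_iC``.  Raises :class:`ReconstructionError` when the
    relative residual exceeds ``tol`` (pass ``tol=None`` to skip).
    """
    opts = {**DEFAULT_SOLVER_OPTS, **(solver_opts or {})}
    if isinstance(forces, ForceSet1DOF):
        report = _reconstruct_1dof(params, result, forces, opts)
    else:
        if artery is None:
            raise ValueError("2DOF reconstruction needs artery parameters")
        report = _reconstruct_2dof(params, artery, result, forces, opts)
    if tol is not None and report.rel_residual > tol:
        raise ReconstructionError(report)
    return report


def _reconstruct_1dof(params, result: SimResult1DOF, forces: ForceSet1DOF, opts):
    t = result.t
    total = CubicSpline(t, forces.F_C + forces.F_MA)
    m0, k0, c0 = params.m0, params.k0, params.c0

    def rhs(ti, s):
        x, v = s
        return (v, (total(ti) - k0 * x - c0 * v) / m0)

    xb = PulseSignal(result.fs, result.x_b, t_start=t[0]) if np.any(result.x_b) \
        else None
    x0 = result.x_M[0] + result.x_b[0]
    v0 = result.motion_M.velocity[0] + (signal_derivative(xb, 1)[0] if xb else 0.0)
    sol = solve_ivp(rhs, (t[0], t[-1]), (x0, v0), t_eval=t, **opts)
    _check_solution(sol, "1DOF force reconstruction")
    recon = sol.y[0]
    target = result.x_M + result.x_b
    scale = np.max(np.abs(result.x_M))
    resid = float(np.max(np.abs(recon - target)) / scale)
    return ReconstructionReport((recon,), (target,), resid)


def _reconstruct_2dof(params, artery, result: SimResult2DOF,
                      forces: ForceSet2DOF, opts):
    t = result.t
    f1 = CubicSpline(t, forces.F_1MA)
    f2 = CubicSpline(t, forces.F_2MA)
    m0, k0, c0, kA = params.m0, params.k0, params.c0, artery.kA

    def rhs(ti, s):
        x1, x2, v2 = s
        v1 = v2 + (f1(ti) - (kA + k0) * x1 + k0 * x2) / c0
        a2 = (f1(ti) + f2(ti) - kA * x1) / m0
        return (v1, v2, a2)

    # targets start at the drift values (MA-free and distorted runs both
    # start from rest, so x_iM - x_iC vanishes at t0)
    x2b = PulseSignal(result.fs, result.x_2b, t_start=t[0]) if np.any(result.x_2b) \
        else None
    x10 = result.x_1M[0] + result.x_1b[0] - result.x_1C[0]
    x20 = result.x_2M[0] + result.x_2b[0] - result.x_2C[0]
    v20 = (result.motion_2M.velocity[0] - result.motion_2C.velocity[0]
           + (signal_derivative(x2b, 1)[0] if x2b else 0.0))
    sol = solve_ivp(rhs, (t[0], t[-1]), (x10, x20, v20), t_eval=t, **opts)
    _check_solution(sol, "2DOF force reconstruction")
    r1, r2 = sol.y[0], sol.y[1]
    tgt1 = result.x_1M + result.x_1b - result.x_1C
    tgt2 = result.x_2M + result.x_2b - result.x_2C
    scale = max(np.max(np.abs(result.x_1M)), np.max(np.abs(result.x_2M)))
    resid = float(
        max(np.max(np.abs(r1 - tgt1)), np.max(np.abs(r2 - tgt2))) / scale
    )
    return ReconstructionReport((r1, r2), (tgt1, tgt2), resid)
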