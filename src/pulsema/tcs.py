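"""Tissue-contact-sensor (TCS) stack parameterization.

The transmission path from the artery to the sensor is a 1DOF
mass-spring-damper: nominal mass m0 (tissue + sensor), stiffness k0 and
damping c0 (tissue), preset by the contact pressure that establishes
tissue-sensor contact.  Motion artifacts drift the stack length, which
perturbs the prestress in the tissue and hence the system parameters —
time-varying system parameters (TVSPs) slaved linearly to the drift.

This module owns the nominal parameter algebra, the drift-to-TVSP map and
the MA-free closed-form transfer functions for both excitation routes:
wall displacement driving the 1DOF stack (base excitation) and pulsatile
pressure driving the 2DOF stack-plus-arterial-wall-spring system.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline

from .waveforms import ArteryParams, HarmonicSpec, PulseSignal

__all__ = [
    "TCSParams",
    "TVSPTrajectory",
    "FrequencyResponse",
    "DEFAULT_GAINS",
    "nominal_params",
    "tvsp_from_drift",
    "transfer_1dof",
    "transfer_2dof",
    "frequency_response_1dof",
    "ma_free_response_1dof",
    "ma_free_response_2dof",
    "params_to_config",
    "params_from_config",
]

#: TVSP gains (gk, gc, gm): dk = gk*k0*xb/max(xb) and likewise for c, m.
#: The mass gain is larger in magnitude so the natural frequency drops as
#: drift compresses the stack.
DEFAULT_GAINS: tuple[float, float, float] = (-1.0 / 3.0, -1.0 / 3.0, -1.0 / 2.0)


@dataclass(frozen=True)
class TCSParams:
    """Nominal 1DOF parameters of the TCS stack plus the heart rate.

    Derived quantities: natural frequency ``omega0 = sqrt(k0/m0)``,
    damping factor ``zeta0 = c0/(2*sqrt(m0*k0))`` and frequency ratio
    ``r0 = omega0/omega_c`` with ``omega_c = 2*pi*f_c``.
    """

    m0: float
    k0: float
    c0: float
    f_c: float

    def __post_init__(self) -> None:
        for name in ("m0", "k0", "c0", "f_c"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v > 0):
                raise ValueError(f"{name} must be positive and finite, got {v}")

    @property
    def omega0(self) -> float:
        return float(np.sqrt(self.k0 / self.m0))

    @property
    def zeta0(self) -> float:
        return self.c0 / (2.0 * np.sqrt(self.m0 * self.k0))

    @property
    def omega_c(self) -> float:
        return 2.0 * np.pi * self.f_c

    @property
    def r0(self) -> float:
        return self.omega0 / self.omega_c


def nominal_params(
    r0: float = 2.0,
    zeta0: float = 1.5,
    k0_over_kA: float = 1.0 / 6.0,
    f_c: float = 1.0,
    kA: float = 1.0,
) -> TCSParams:
    """Nominal TCS parameters from the standard dimensionless triplet.

    Defaults r0 = 2, zeta0 = 1.5 and k0 = kA/6 describe an overdamped
    stack whose natural frequency sits at the second harmonic of the
    heart rate.
    """
    for name, v in (("r0", r0), ("zeta0", zeta0), ("k0_over_kA", k0_over_kA),
                    ("f_c", f_c), ("kA", kA)):
        if not v > 0:
            raise ValueError(f"{name} must be positive, got {v}")
    k0 = k0_over_kA * kA
    m0 = k0 / (r0 * 2.0 * np.pi * f_c) ** 2
    c0 = 2.0 * zeta0 * np.sqrt(m0 * k0)
    return TCSParams(m0=m0, k0=k0, c0=c0, f_c=f_c)


@dataclass(frozen=True)
class TVSPTrajectory:
    """Time-varying parameter perturbations dm(t), dk(t), dc(t).

    Same units as m0, k0, c0; band-limited like the drift that drives
    them.  ``interpolants`` provides smooth callables for the ODE solver.
    """

    t: np.ndarray
    dm: np.ndarray
    dk: np.ndarray
    dc: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        for name in ("dm", "dk", "dc"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != t.shape:
                raise ValueError(f"{name} must share the time grid")
            object.__setattr__(self, name, arr)
        object.__setattr__(self, "t", t)

    def interpolants(self):
        """Cubic-spline callables (fm, fk, fc) over the trajectory grid."""
        return (
            CubicSpline(self.t, self.dm),
            CubicSpline(self.t, self.dk),
            CubicSpline(self.t, self.dc),
        )


def tvsp_from_drift(
    drift: PulseSignal,
    params: TCSParams,
    gains: tuple[float, float, float] = DEFAULT_GAINS,
    normalizer: float | str = "max",
) -> TVSPTrajectory:
    """Map baseline drift linearly to TVSPs.

    ``dk = gk*k0*xb/M`` (likewise dc, dm) where the normalizer M is the
    maximum of the drift over the window (``'max'``), its maximum absolute
    value (``'absmax'``), or an explicit number.  The default gains
    (-1/3, -1/3, -1/2) make the parameters dip by a third (half for the
    mass) at peak drift.
    """
    xb = drift.samples
    gk, gc, gm = gains
    if isinstance(normalizer, str):
        if normalizer == "max":
            m = float(np.max(xb))
            if m <= 0:
                raise ValueError(
                    "normalizer 'max' needs a drift with a positive maximum; "
                    "use 'absmax' or a numeric normalizer"
                )
        elif normalizer == "absmax":
            m = float(np.max(np.abs(xb)))
            if m == 0:
                raise ValueError("cannot normalize an identically-zero drift")
        else:
            raise ValueError(f"unknown normalizer {normalizer!r}")
    else:
        m = float(normalizer)
        if m == 0:
            raise ValueError("numeric normalizer must be nonzero")
    u = xb / m
    dk = gk * params.k0 * u
    dc = gc * params.c0 * u
    dm = gm * params.m0 * u
    if np.any(params.k0 + dk <= 0):
        raise ValueError(f"stiffness gain gk={gk} drives k(t) non-positive")
    if np.any(params.m0 + dm <= 0):
        raise ValueError(f"mass gain gm={gm} drives m(t) non-positive")
    if np.any(params.c0 + dc < 0):
        raise ValueError(f"damping gain gc={gc} drives c(t) negative")
    return TVSPTrajectory(t=drift.t, dm=dm, dk=dk, dc=dc)


@dataclass(frozen=True)
class FrequencyResponse:
    """Complex gains on a positive-frequency grid."""

    f: np.ndarray
    gain: np.ndarray

    @property
    def magnitude(self) -> np.ndarray:
        return np.abs(self.gain)

    @property
    def phase(self) -> np.ndarray:
        return np.angle(self.gain)


def transfer_1dof(params: TCSParams, f):
    """MA-free complex gain x_C/y of the base-excited 1DOF stack.

    ``G0*e^{j*phi0} = (k0 + j*c0*w) / (k0 - m0*w^2 + j*c0*w)`` at
    ``w = 2*pi*f``; the static limit is 1.
    """
    w = 2.0 * np.pi * np.asarray(f, dtype=float)
    num = params.k0 + 1j * params.c0 * w
    den = params.k0 - params.m0 * w**2 + 1j * params.c0 * w
    return num / den


def transfer_2dof(params: TCSParams, artery: ArteryParams, f):
    """MA-free complex gains (x_1C/F, x_2C/F) of the wall + stack system.

    With coupling impedance ``z = k0 + j*c0*w`` and ``d = z - m0*w^2``:
    ``G10 = d / (kA*d - m0*w^2*z)`` (arterial wall) and
    ``G20 = z / (kA*d - m0*w^2*z)`` (mass).  Both tend to 1/kA statically:
    the mass rides the wall.
    """
    w = 2.0 * np.pi * np.asarray(f, dtype=float)
    z = params.k0 + 1j * params.c0 * w
    d = z - params.m0 * w**2
    den = artery.kA * d - params.m0 * w**2 * z
    return d / den, z / den


def frequency_response_1dof(params: TCSParams, f: np.ndarray) -> FrequencyResponse:
    f = np.asarray(f, dtype=float)
    return FrequencyResponse(f=f, gain=transfer_1dof(params, f))


def _filter_harmonics(spec: HarmonicSpec, gain_at) -> HarmonicSpec:
    comps = []
    for n, a, p in spec.components:
        g = complex(gain_at(n * spec.f_c))
        comps.append((n, a * abs(g), p + float(np.angle(g))))
    return HarmonicSpec(spec.f_c, tuple(comps))


def ma_free_response_1dof(spec: HarmonicSpec, params: TCSParams) -> HarmonicSpec:
    """Closed-form MA-free response x_C to a harmonic wall displacement."""
    return _filter_harmonics(spec, lambda f: transfer_1dof(params, f))


def ma_free_response_2dof(
    force: HarmonicSpec, params: TCSParams, artery: ArteryParams
) -> tuple[HarmonicSpec, HarmonicSpec]:
    """Closed-form MA-free responses (x_1C, x_2C) to a harmonic wall force."""
    x1 = _filter_harmonics(force, lambda f: transfer_2dof(params, artery, f)[0])
    x2 = _filter_harmonics(force, lambda f: transfer_2dof(params, artery, f)[1])
    return x1, x2


def params_to_config(params: TCSParams, kA: float = 1.0) -> dict:
    """Flat config mapping of the dimensionless parameter triplet."""
    return {
        "r0": params.r0,
        "zeta0": params.zeta0,
        "k0_over_kA": params.k0 / kA,
        "kA": kA,
        "f_c": params.f_c,
    }


def params_from_config(cfg: dict) -> TCSParams:
    return nominal_params(
        r0=cfg.get("r0", 2.0),
        zeta0=cfg.get("zeta0", 1.5),
        k0_over_kA=cfg.get("k0_over_kA", 1.0 / 6.0),
        f_c=cfg.get("f_c", 1.0),
        kA=cfg.get("kA", 1.0),
    )
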