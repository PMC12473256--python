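"""Synthetic pulse signals and baseline drifts.

All quantities are expressed in normalized units: the arterial-wall
stiffness ``kA`` is taken as 1 force/length and true-pulse amplitudes are
O(1) length units, so every simulated output is a dimensionless ratio.

A pulse signal is a collection of harmonics of the heart rate.  Two
generators are provided: an explicit harmonic series
(:func:`make_harmonic_pulse`, :class:`HarmonicSpec`) and a
physiologic-looking arterial pulse waveform built from two positive bumps
per cycle — systolic peak plus dicrotic wave (:func:`make_synthetic_apw`).
Motion artifacts at rest are band-limited below 0.7 Hz, and
:func:`make_baseline_drift` synthesizes such drifts either as a small
harmonic sum or as a seeded smooth random waveform.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
from scipy.interpolate import CubicSpline

__all__ = [
    "PulseSignal",
    "HarmonicSpec",
    "DriftSpec",
    "ArteryParams",
    "carotid_like_spec",
    "make_harmonic_pulse",
    "make_synthetic_apw",
    "make_baseline_drift",
    "pressure_to_force",
    "scale_harmonics",
    "signal_derivative",
    "write_waveform_csv",
    "read_waveform_csv",
]


@dataclass(frozen=True)
class PulseSignal:
    """Uniformly sampled real-valued time series.

    The universal carrier for wall displacement, pulsatile pressure,
    drifts, simulated responses and equivalent forces.
    """

    fs: float
    samples: np.ndarray
    t_start: float = 0.0
    label: str = ""

    def __post_init__(self) -> None:
        if not (np.isfinite(self.fs) and self.fs > 0):
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        samples = np.asarray(self.samples, dtype=float)
        if samples.ndim != 1 or samples.size < 2:
            raise ValueError("a pulse signal needs >= 2 samples in one dimension")
        if not np.all(np.isfinite(samples)):
            raise ValueError("pulse signal samples must be finite")
        object.__setattr__(self, "samples", samples)

    def __len__(self) -> int:
        return self.samples.size

    @property
    def t(self) -> np.ndarray:
        """Time grid (s)."""
        return self.t_start + np.arange(self.samples.size) / self.fs

    @property
    def duration(self) -> float:
        return self.samples.size / self.fs

    def with_samples(self, samples: np.ndarray, label: str | None = None) -> "PulseSignal":
        """New signal on the same grid."""
        return PulseSignal(self.fs, samples, self.t_start,
                           self.label if label is None else label)

    def same_grid(self, other: "PulseSignal", rtol: float = 1e-9) -> bool:
        return (
            len(self) == len(other)
            and math.isclose(self.fs, other.fs, rel_tol=rtol)
            and math.isclose(self.t_start, other.t_start, rel_tol=rtol, abs_tol=1e-12)
        )

    def _binop(self, other, op, label):
        if isinstance(other, PulseSignal):
            if not self.same_grid(other):
                raise ValueError("signals are on different grids")
            return self.with_samples(op(self.samples, other.samples), label)
        return self.with_samples(op(self.samples, other), label)

    def __add__(self, other):
        return self._binop(other, np.add, self.label)

    def __sub__(self, other):
        return self._binop(other, np.subtract, self.label)

    def __mul__(self, other):
        return self._binop(other, np.multiply, self.label)

    __rmul__ = __mul__


@dataclass(frozen=True)
class HarmonicSpec:
    """Harmonic-series definition of a true pulse signal.

    ``components`` is a sequence of ``(order, amplitude, phase)`` with
    integer order n >= 1; the signal is
    ``sum_n amplitude_n * cos(2*pi*n*f_c*t + phase_n)``.
    """

    f_c: float
    components: tuple[tuple[int, float, float], ...]

    def __post_init__(self) -> None:
        if not self.f_c > 0:
            raise ValueError("fundamental frequency must be positive")
        comps = tuple((int(n), float(a), float(p)) for n, a, p in self.components)
        orders = [c[0] for c in comps]
        if any(n < 1 for n in orders):
            raise ValueError("harmonic orders must be >= 1")
        if len(set(orders)) != len(orders):
            raise ValueError("harmonic orders must be unique")
        if any(c[1] < 0 for c in comps):
            raise ValueError("harmonic amplitudes must be >= 0")
        object.__setattr__(self, "components", comps)

    @property
    def max_order(self) -> int:
        return max((n for n, _, _ in self.components), default=0)

    def __call__(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        out = np.zeros_like(t)
        w = 2 * np.pi * self.f_c
        for n, a, p in self.components:
            out += a * np.cos(n * w * t + p)
        return out

    def derivative(self, t, order: int = 1) -> np.ndarray:
        """Exact time derivative of the harmonic sum."""
        t = np.asarray(t, dtype=float)
        out = np.zeros_like(t)
        w = 2 * np.pi * self.f_c
        for n, a, p in self.components:
            wn = n * w
            # each differentiation multiplies by wn and advances phase by pi/2
            out += a * wn**order * np.cos(wn * t + p + order * np.pi / 2)
        return out


@dataclass(frozen=True)
class DriftSpec:
    """Baseline-drift recipe: what kind of low-frequency waveform to build.

    ``kind='harmonic-sum'`` sums ``(freq_hz, amplitude, phase)`` sine
    components; ``kind='random-smooth'`` splines through seeded random
    knots and truncates the spectrum at ``band_limit``;
    ``kind='from-samples'`` loads a tabulated two-column CSV.
    ``amplitude`` (if not None) rescales the peak absolute value.
    """

    kind: Literal["harmonic-sum", "random-smooth", "from-samples"]
    band_limit: float = 0.7
    amplitude: float | None = 1.0
    seed: int = 0
    components: tuple[tuple[float, float, float], ...] = ((0.2, 0.7, 0.0), (0.35, 0.3, 0.0))
    n_knots: int | None = None
    path: str | None = None

    def __post_init__(self) -> None:
        if self.amplitude is not None and self.amplitude < 0:
            raise ValueError("drift amplitude must be >= 0")
        if not self.band_limit > 0:
            raise ValueError("band limit must be positive")
        object.__setattr__(
            self, "components",
            tuple((float(f), float(a), float(p)) for f, a, p in self.components),
        )
        if self.kind == "harmonic-sum":
            bad = [f for f, _, _ in self.components if f > self.band_limit]
            if bad:
                raise ValueError(
                    f"harmonic-sum components {bad} exceed the band limit "
                    f"{self.band_limit} Hz"
                )
        if self.kind == "from-samples" and not self.path:
            raise ValueError("from-samples drift needs a file path")


@dataclass(frozen=True)
class ArteryParams:
    """Arterial-wall spring stiffness and effective radius.

    Pulsatile pressure translates to a force on the wall via F = pi*a*dp.
    """

    kA: float = 1.0
    a: float = 1.0 / np.pi

    def __post_init__(self) -> None:
        if not (self.kA > 0 and self.a > 0):
            raise ValueError("artery stiffness and radius must be positive")


def carotid_like_spec(
    f_c: float = 1.0,
    n_harmonics: int = 10,
    decay: float = 0.6,
    phase_curvature: float = -0.12,
) -> HarmonicSpec:
    """Default multi-harmonic carotid-like pulse.

    Geometrically decaying amplitudes ``decay**(n-1)`` with a weak
    quadratic phase law that skews the waveform toward a sharp systolic
    upstroke.  A synthetic stand-in for a measured carotid pulse: any
    multi-harmonic waveform exercises the same transmission-path math.
    """
    comps = tuple(
        (n, decay ** (n - 1), phase_curvature * (n - 1) ** 2)
        for n in range(1, n_harmonics + 1)
    )
    return HarmonicSpec(f_c=f_c, components=comps)


def _time_grid(duration: float, fs: float) -> np.ndarray:
    n = int(round(duration * fs))
    if n < 2:
        raise ValueError("duration too short for the requested sampling rate")
    return np.arange(n) / fs


def make_harmonic_pulse(spec: HarmonicSpec, duration: float, fs: float) -> PulseSignal:
    """Evaluate a harmonic series on a uniform grid.

    Rejects sampling rates below 20x the highest harmonic frequency
    (well above Nyquist) so that waveform features are resolved.
    """
    if duration < 2 / spec.f_c:
        raise ValueError("duration must cover at least 2 pulse cycles")
    f_max = spec.max_order * spec.f_c
    if f_max > 0 and fs < 20 * f_max:
        raise ValueError(
            f"fs={fs} Hz is too low for the {spec.max_order}th harmonic at "
            f"{f_max} Hz (Nyquist bound {2 * f_max} Hz; require fs >= {20 * f_max} Hz)"
        )
    t = _time_grid(duration, fs)
    return PulseSignal(fs, spec(t), label="harmonic pulse")


def make_synthetic_apw(
    f_c: float,
    duration: float,
    fs: float,
    heights: tuple[float, float] = (1.0, 0.4),
    centers: tuple[float, float] = (0.30, 0.62),
    widths: tuple[float, float] = (0.045, 0.09),
) -> PulseSignal:
    """Physiologic-looking arterial pulse waveform.

    One cycle is the sum of two strictly periodic positive bumps — the
    systolic peak and the dicrotic wave — built from von-Mises-style
    kernels ``h * exp(kappa*(cos(2*pi*(f_c*t - c)) - 1))``.  ``centers``
    and ``widths`` are fractions of a cycle.  The waveform is phased so
    that each cycle starts at its foot (the pre-systolic minimum).
    """
    for w in widths:
        if w <= 0:
            raise ValueError("bump widths must be positive")

    def evaluate(phase: np.ndarray) -> np.ndarray:
        out = np.zeros_like(phase)
        for h, c, w in zip(heights, centers, widths):
            kappa = 1.0 / (2 * np.pi * w) ** 2  # angular sd ~ w cycles
            out += h * np.exp(kappa * (np.cos(2 * np.pi * (phase - c)) - 1.0))
        return out

    # locate the foot on a fine cycle and shift it to the cycle start
    fine = np.linspace(0.0, 1.0, 2000, endpoint=False)
    foot_phase = fine[np.argmin(evaluate(fine))]
    t = _time_grid(duration, fs)
    sig = PulseSignal(fs, evaluate(f_c * t + foot_phase), label="synthetic APW")
    out = sig.samples
    # warn when bump parameters collide into several near-equal maxima
    one_cycle = out[: max(int(round(fs / f_c)), 2)]
    if one_cycle.size >= 3 and one_cycle.max() > 0:
        interior = (one_cycle[1:-1] > one_cycle[:-2]) & (one_cycle[1:-1] >= one_cycle[2:])
        n_top = int(np.sum(interior & (one_cycle[1:-1] > 0.95 * one_cycle.max())))
        if n_top > 1:
            warnings.warn(
                "synthetic APW bumps overlap into multiple near-equal maxima per cycle",
                stacklevel=2,
            )
    return sig


def _rescale(samples: np.ndarray, amplitude: float | None) -> np.ndarray:
    if amplitude is None:
        return samples
    peak = np.max(np.abs(samples))
    if peak == 0 or amplitude == 0:
        return np.zeros_like(samples)
    return samples * (amplitude / peak)


def make_baseline_drift(spec: DriftSpec, duration: float, fs: float) -> PulseSignal:
    """Band-limited baseline drift (motion artifact at rest, < 0.7 Hz)."""
    t = _time_grid(duration, fs)
    if spec.kind == "harmonic-sum":
        out = np.zeros_like(t)
        for f, a, p in spec.components:
            out += a * np.sin(2 * np.pi * f * t + p)
    elif spec.kind == "random-smooth":
        out = _random_smooth(t, fs, spec)
    elif spec.kind == "from-samples":
        out = _drift_from_file(t, spec)
    else:  # pragma: no cover - guarded by DriftSpec
        raise ValueError(f"unknown drift kind {spec.kind!r}")
    return PulseSignal(fs, _rescale(out, spec.amplitude), label=f"drift:{spec.kind}")


def _random_smooth(t: np.ndarray, fs: float, spec: DriftSpec) -> np.ndarray:
    rng = np.random.default_rng(spec.seed)
    duration = t[-1] + 1 / fs
    # knots spaced ~ half the shortest in-band period, with margins so the
    # spline is well conditioned at both window edges
    n_knots = spec.n_knots or max(6, int(round(2 * spec.band_limit * duration)) + 4)
    knots_t = np.linspace(-1.0, duration + 1.0, n_knots)
    knots_v = rng.standard_normal(n_knots)
    smooth = CubicSpline(knots_t, knots_v)(t)
    # hard truncation above the band limit with a cosine taper below it
    spec_f = np.fft.rfft(smooth)
    freqs = np.fft.rfftfreq(t.size, 1 / fs)
    taper = np.ones_like(freqs)
    lo = 0.8 * spec.band_limit
    ramp = (freqs > lo) & (freqs <= spec.band_limit)
    taper[ramp] = 0.5 * (1 + np.cos(np.pi * (freqs[ramp] - lo) / (spec.band_limit - lo)))
    taper[freqs > spec.band_limit] = 0.0
    return np.fft.irfft(spec_f * taper, n=t.size)


def _drift_from_file(t: np.ndarray, spec: DriftSpec) -> np.ndarray:
    path = Path(spec.path)
    if not path.exists():
        raise FileNotFoundError(f"drift sample file not found: {path}")
    sig = read_waveform_csv(path)
    if sig.duration < t[-1]:
        raise ValueError("tabulated drift is shorter than the requested duration")
    return np.interp(t, sig.t, sig.samples)


def pressure_to_force(dp: PulseSignal, artery: ArteryParams) -> PulseSignal:
    """Pulsatile pressure to force on the arterial wall: F = pi*a*dp."""
    return dp.with_samples(np.pi * artery.a * dp.samples, label="wall force")


def scale_harmonics(spec: HarmonicSpec, factor: float) -> HarmonicSpec:
    """Scale every harmonic amplitude (e.g. pressure -> force by pi*a)."""
    return HarmonicSpec(
        spec.f_c, tuple((n, a * factor, p) for n, a, p in spec.components)
    )


def signal_derivative(sig: PulseSignal, order: int = 1) -> np.ndarray:
    """Derivative of a tabulated signal via a cubic-spline interpolant.

    Used for band-limited drifts where no analytic form is available;
    avoids the edge ringing of FFT differentiation on non-periodic windows.
    """
    return CubicSpline(sig.t, sig.samples).derivative(order)(sig.t)


# -- tabulated waveform I/O --------------------------------------------------

def write_waveform_csv(path: str | Path, sig: PulseSignal) -> None:
    """Two-column CSV (time_s, value) with fs and label in the header."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# fs={float(sig.fs)!r}\n")
        fh.write(f"# label={sig.label}\n")
        fh.write("time_s,value\n")
        for ti, vi in zip(sig.t, sig.samples):
            fh.write(f"{float(ti)!r},{float(vi)!r}\n")


def read_waveform_csv(path: str | Path) -> PulseSignal:
    path = Path(path)
    fs = None
    label = ""
    rows: list[tuple[float, float]] = []
    with path.open() as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                key, _, val = line.lstrip("# ").partition("=")
                if key == "fs":
                    fs = float(val)
                elif key == "label":
                    label = val
                continue
            if line.lower().startswith("time"):
                continue
            a, _, b = line.partition(",")
            rows.append((float(a), float(b)))
    if len(rows) < 2:
        raise ValueError(f"waveform file {path} has fewer than 2 samples")
    t = np.array([r[0] for r in rows])
    v = np.array([r[1] for r in rows])
    dt = np.diff(t)
    if np.any(dt <= 0) or not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-12):
        raise ValueError(f"waveform file {path} is not uniformly sampled")
    if fs is None:
        fs = 1.0 / dt[0]
    return PulseSignal(fs=fs, samples=v, t_start=t[0], label=label)
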