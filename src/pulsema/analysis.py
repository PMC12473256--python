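"""Result-space analysis: spectra, per-cycle metrics, baseline estimation.

Quantifies how baseline drift and TVSP distortion show up in a measured
pulse signal: amplitude spectra and their harmonic sidebands, per-cycle
heart rate and pulse amplitude from detected pulse feet, the classical
cubic-spline baseline estimate (and its failure to recover the true
drift), and the instantaneous frequency-ratio / damping-factor
trajectories of the drifting stack.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.signal import find_peaks, get_window

from .tcs import TCSParams, TVSPTrajectory
from .waveforms import ArteryParams, PulseSignal

__all__ = [
    "SpectrumResult",
    "CycleMetrics",
    "SidebandReport",
    "ParamTrajectories",
    "spectrum",
    "detect_feet",
    "per_cycle_metrics",
    "cse_baseline",
    "param_trajectories",
    "sideband_report",
]


@dataclass(frozen=True)
class SpectrumResult:
    """Single-sided amplitude spectrum.

    ``amplitude[k]`` estimates the amplitude of a cosine at ``f[k]``
    (DC bin holds the mean).  ``signal_power`` is the mean square of the
    windowed time series; :meth:`spectral_power` recovers it from the
    stored amplitudes, so Parseval's identity is checkable.
    """

    f: np.ndarray
    amplitude: np.ndarray
    resolution: float
    window: str
    n_samples: int
    n_fft: int
    fs: float
    signal_power: float

    def spectral_power(self) -> float:
        n, nfft = self.n_samples, self.n_fft
        amp = self.amplitude
        w = (amp * n / 2.0) ** 2 * 2.0  # interior bins carry conjugate twins
        w[0] = (amp[0] * n) ** 2
        if nfft % 2 == 0:
            w[-1] = (amp[-1] * n) ** 2
        return float(np.sum(w) / (n * nfft))

    def energy_in(self, f_lo: float, f_hi: float) -> float:
        """Sum of amplitude^2 over bins with f_lo <= f < f_hi."""
        mask = (self.f >= f_lo) & (self.f < f_hi)
        return float(np.sum(self.amplitude[mask] ** 2))


def spectrum(
    x: PulseSignal,
    window: str = "boxcar",
    zero_pad_factor: int = 4,
) -> SpectrumResult:
    """Single-sided amplitude spectrum with optional zero padding.

    The default rectangular window on an integer number of cycles keeps
    harmonics in single bins; zero padding refines the grid so sideband
    structure around each harmonic is resolved.
    """
    if zero_pad_factor < 1:
        raise ValueError("zero_pad_factor must be >= 1")
    n = len(x)
    w = get_window(window, n, fftbins=True) if window != "boxcar" else np.ones(n)
    xw = x.samples * w
    nfft = n * int(zero_pad_factor)
    X = np.fft.rfft(xw, n=nfft)
    amp = np.abs(X) * 2.0 / n
    amp[0] /= 2.0
    if nfft % 2 == 0:
        amp[-1] /= 2.0
    f = np.fft.rfftfreq(nfft, 1.0 / x.fs)
    return SpectrumResult(
        f=f, amplitude=amp, resolution=x.fs / nfft, window=window,
        n_samples=n, n_fft=nfft, fs=x.fs,
        signal_power=float(np.mean(xw**2)),
    )


def detect_feet(
    x: PulseSignal,
    f_c_hint: float,
    refine: bool = True,
) -> np.ndarray:
    """Pulse-onset (foot) times: the minimum preceding each maximal upstroke.

    Upstrokes are slope maxima separated by at least 0.6 of the expected
    cycle; the foot is the windowed minimum just before each upstroke
    (ties to the earliest sample), optionally refined to sub-sample
    precision by a parabolic fit.  A global linear trend — estimated from
    the first-cycle vs last-cycle means, exactly zero for any periodic
    signal and exact for a linear ramp — is removed first, so the
    detector is insensitive to baseline trends even across flat diastolic
    feet.
    """
    dt = 1.0 / x.fs
    raw = x.samples
    p = int(round(x.fs / f_c_hint))
    if len(raw) >= 2 * p > 0:
        trend_slope = (np.mean(raw[-p:]) - np.mean(raw[:p])) * x.fs / (len(raw) - p)
    else:
        trend_slope = 0.0
    s = raw - trend_slope * (x.t - x.t[0])
    slope = np.gradient(s, dt)
    period = int(round(x.fs / f_c_hint))
    distance = max(int(0.6 * period), 1)
    peaks, _ = find_peaks(slope, distance=distance, height=0.35 * slope.max())
    feet_idx: list[int] = []
    for iu in peaks:
        lo = max(iu - distance, 0)
        i_min = lo + int(np.argmin(s[lo : iu + 1]))
        if not feet_idx or i_min > feet_idx[-1]:
            feet_idx.append(i_min)
    expected = int(round(x.duration * f_c_hint))
    if abs(len(feet_idx) - expected) > 1:
        warnings.warn(
            f"detected {len(feet_idx)} pulse feet but expected ~{expected} "
            f"cycles at {f_c_hint} Hz",
            stacklevel=2,
        )
    times = x.t[feet_idx].astype(float)
    if refine:
        for j, i in enumerate(feet_idx):
            if 0 < i < len(s) - 1:
                denom = s[i - 1] - 2 * s[i] + s[i + 1]
                if denom > 0:
                    times[j] += 0.5 * dt * (s[i - 1] - s[i + 1]) / denom
    return times


@dataclass
class CycleMetrics:
    """Per-cycle heart rate, amplitude and normalized pulse waveforms.

    ``hr_bpm[i] = 60/(onset[i+1]-onset[i])``; ``normalized`` holds each
    foot-to-foot cycle resampled to a fixed number of points and min-max
    normalized into [0, 1].
    """

    onsets: np.ndarray
    hr_bpm: np.ndarray
    amplitude: np.ndarray
    normalized: np.ndarray
    degenerate: np.ndarray


def per_cycle_metrics(
    x: PulseSignal, onsets: np.ndarray, n_points: int = 200
) -> CycleMetrics:
    """Per-cycle metrics between successive pulse feet."""
    onsets = np.asarray(onsets, dtype=float)
    if onsets.size < 2:
        raise ValueError("need at least 2 onsets for per-cycle metrics")
    if np.any(np.diff(onsets) <= 0):
        raise ValueError("onsets must be strictly increasing")
    intervals = np.diff(onsets)
    hr = 60.0 / intervals
    n_cycles = intervals.size
    amps = np.empty(n_cycles)
    norm = np.empty((n_cycles, n_points))
    degenerate = np.zeros(n_cycles, dtype=bool)
    u = np.linspace(0.0, 1.0, n_points)
    for i in range(n_cycles):
        tt = onsets[i] + u * intervals[i]
        cyc = np.interp(tt, x.t, x.samples)
        lo, hi = cyc.min(), cyc.max()
        amps[i] = hi - lo
        if hi > lo:
            norm[i] = (cyc - lo) / (hi - lo)
        else:
            norm[i] = 0.0
            degenerate[i] = True
    return CycleMetrics(onsets=onsets, hr_bpm=hr, amplitude=amps,
                        normalized=norm, degenerate=degenerate)


def cse_baseline(x: PulseSignal, onsets: np.ndarray) -> PulseSignal:
    """Cubic-spline baseline estimate through the pulse-foot points.

    The standard drift estimator in pulse processing: a natural cubic
    spline through (foot time, signal value) evaluated on the full grid.
    It tracks an additive smooth drift at the knots but cannot represent
    the TVSP distortion riding on the harmonics.
    """
    onsets = np.asarray(onsets, dtype=float)
    if onsets.size < 4:
        raise ValueError("cubic-spline baseline estimation needs >= 4 feet")
    knots_v = np.interp(onsets, x.t, x.samples)
    spline = CubicSpline(onsets, knots_v, bc_type="natural")
    return x.with_samples(spline(x.t), label="x_CSE")


def per_cycle_distortion(
    x_ref: PulseSignal,
    x_dist: PulseSignal,
    f_c: float,
) -> dict[str, float]:
    """Headline distortion metrics of one signal against a reference.

    Detects pulse feet on both signals, then reports (in percent):
    ``amp_dev_pct`` — the maximum per-cycle relative deviation of the
    distorted signal's peak-to-foot amplitude from the reference's; and
    ``hr_dev_pct`` — the maximum per-cycle heart-rate deviation of the
    distorted signal from the nominal rate ``60*f_c`` bpm.
    """
    cm_ref = per_cycle_metrics(x_ref, detect_feet(x_ref, f_c))
    cm_dist = per_cycle_metrics(x_dist, detect_feet(x_dist, f_c))
    n = min(cm_ref.amplitude.size, cm_dist.amplitude.size)
    amp_dev = np.max(
        np.abs(cm_dist.amplitude[:n] - cm_ref.amplitude[:n])
        / cm_ref.amplitude[:n]
    )
    hr_nominal = 60.0 * f_c
    hr_dev = np.max(np.abs(cm_dist.hr_bpm - hr_nominal)) / hr_nominal
    return {
        "amp_dev_pct": float(100.0 * amp_dev),
        "hr_dev_pct": float(100.0 * hr_dev),
        "n_cycles": int(n),
    }


@dataclass
class ParamTrajectories:
    """Instantaneous frequency ratio and damping factor of the stack."""

    t: np.ndarray
    r: np.ndarray
    zeta: np.ndarray
    r_total: np.ndarray | None


def param_trajectories(
    tvsp: TVSPTrajectory,
    params: TCSParams,
    artery: ArteryParams | None = None,
) -> ParamTrajectories:
    """r(t), zeta(t) and (with an artery) r_total(t) from the TVSPs.

    ``r(t) = sqrt(k(t)/m(t))/omega_c`` and
    ``zeta(t) = c(t)/(2*sqrt(m(t)*k(t)))`` use the perturbed parameters.
    ``r_total`` folds in the arterial-wall stiffness through the series
    combination ``kA*k(t)/(kA+k(t))`` seen by the mass.
    """
    m = params.m0 + tvsp.dm
    k = params.k0 + tvsp.dk
    c = params.c0 + tvsp.dc
    r = np.sqrt(k / m) / params.omega_c
    zeta = c / (2.0 * np.sqrt(m * k))
    r_total = None
    if artery is not None:
        k_series = artery.kA * k / (artery.kA + k)
        r_total = np.sqrt(k_series / m) / params.omega_c
    return ParamTrajectories(t=tvsp.t, r=r, zeta=zeta, r_total=r_total)


@dataclass
class SidebandReport:
    """Distortion energy concentrated around each harmonic.

    ``band_energy[i]`` integrates amplitude^2 over bins within ``band``
    of harmonic ``i+1`` (bins in overlapping bands are assigned to the
    nearest harmonic); ``in_band_fraction`` uses the union of all bands.
    """

    centers: np.ndarray
    band: float
    band_energy: np.ndarray
    peak_amplitude: np.ndarray
    total_energy: float
    in_band_fraction: float

    @property
    def ratio(self) -> np.ndarray:
        """Per-harmonic distortion energy over harmonic peak amplitude."""
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(self.peak_amplitude > 0,
                            self.band_energy / self.peak_amplitude, np.nan)


def sideband_report(
    spec: SpectrumResult,
    f_c: float,
    n_harmonics: int = 10,
    band: float = 0.7,
) -> SidebandReport:
    """Quantify TVSP sidebands around the heart-rate harmonics."""
    if spec.resolution > band / 4:
        raise ValueError(
            f"spectral resolution {spec.resolution:.4g} Hz too coarse for "
            f"band {band} Hz; need resolution <= band/4"
        )
    if band >= f_c:
        raise ValueError(f"band {band} Hz >= fundamental {f_c} Hz is ambiguous")
    if band > f_c / 2:
        warnings.warn(
            "sideband windows overlap (band > f_c/2); overlapping bins are "
            "assigned to the nearest harmonic",
            stacklevel=2,
        )
    centers = f_c * np.arange(1, n_harmonics + 1)
    # nearest harmonic center for every bin, then keep bins within the band
    idx = np.clip(np.round(spec.f / f_c).astype(int), 1, n_harmonics) - 1
    dist = np.abs(spec.f - centers[idx])
    in_band = dist <= band
    power = spec.amplitude**2
    band_energy = np.zeros(n_harmonics)
    peak_amp = np.zeros(n_harmonics)
    for i in range(n_harmonics):
        sel = in_band & (idx == i)
        band_energy[i] = power[sel].sum()
        peak_amp[i] = spec.amplitude[sel].max() if np.any(sel) else 0.0
    total = float(power.sum())
    frac = float(band_energy.sum() / total) if total > 0 else 0.0
    return SidebandReport(
        centers=centers, band=band, band_energy=band_energy,
        peak_amplitude=peak_amp, total_energy=total, in_band_fraction=frac,
    )
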