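import numpy as np
import pytest

from pulsema import (
    ArteryParams,
    DriftSpec,
    PulseSignal,
    carotid_like_spec,
    make_baseline_drift,
    nominal_params,
    run_case_pressure,
    run_case_wall,
)


@pytest.fixture(scope="session")
def params():
    """Nominal overdamped stack: r0=2, zeta0=1.5, k0=kA/6, 1 Hz heart rate."""
    return nominal_params()


@pytest.fixture(scope="session")
def artery():
    return ArteryParams(kA=1.0, a=1.0 / np.pi)


@pytest.fixture(scope="session")
def carotid():
    """Default 10-harmonic carotid-like pulse at 1 Hz."""
    return carotid_like_spec()


@pytest.fixture(scope="session")
def drift12():
    """Two-tone (0.2 + 0.35 Hz) drift over 12 s at 200 Hz, peak 1."""
    return make_baseline_drift(DriftSpec(kind="harmonic-sum"), 12.0, 200.0)


@pytest.fixture(scope="session")
def wall_result(params, carotid, drift12):
    """Default wall-displacement scenario (drift + TVSPs), 12 cycles."""
    return run_case_wall(params, carotid, drift12)


@pytest.fixture(scope="session")
def pressure_result(params, artery, carotid, drift12):
    """Default pulsatile-pressure scenario, 12 cycles."""
    return run_case_pressure(params, artery, carotid, drift12)


def tail(result, name: str, cycles: float | None = None) -> PulseSignal:
    """Analysis-window view of a named series (lead-in discarded)."""
    sig = result.as_signal(name)
    i0 = result.settle_index
    if cycles is not None:
        i0 = len(sig) - int(round(cycles * result.fs / result.params.f_c))
    return PulseSignal(result.fs, sig.samples[i0:], t_start=result.t[i0],
                       label=name)


def fit_harmonic(t: np.ndarray, s: np.ndarray, f: float) -> complex:
    """Least-squares complex amplitude C with s ~ Re{C * exp(j*2*pi*f*t)}."""
    th = 2 * np.pi * f * t
    A = np.column_stack([np.cos(th), np.sin(th)])
    (c, d), *_ = np.linalg.lstsq(A, s, rcond=None)
    return complex(c, -d)
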