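"""Scenario configuration, reproducible runs and run comparison.

A :class:`ScenarioConfig` captures everything a simulation needs — the
excitation route (wall displacement or pulsatile pressure), the pulse
and drift recipes, stack parameters, TVSP gains, solver and analysis
options — and :func:`run_scenario` turns it into a run directory of CSV
time series, forces, spectra, cycle metrics, sideband summaries and a
JSON manifest.  Runs are fully deterministic for a fixed config.
"""

from __future__ import annotations

import hashlib
import json
import platform
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, field_validator

from . import __version__
from .analysis import (
    cse_baseline,
    detect_feet,
    param_trajectories,
    per_cycle_metrics,
    sideband_report,
    spectrum,
)
from .dynamics import run_case_pressure, run_case_wall
from .forces import equivalent_forces_1dof, equivalent_forces_2dof
from .tcs import nominal_params
from .waveforms import (
    ArteryParams,
    DriftSpec,
    carotid_like_spec,
    make_baseline_drift,
    make_synthetic_apw,
    read_waveform_csv,
)

__all__ = ["ScenarioConfig", "PRESETS", "load_config", "run_scenario",
           "compare_runs"]


class PulseConfig(BaseModel):
    kind: Literal["harmonic", "apw", "file"] = "harmonic"
    n_harmonics: int = 10
    decay: float = 0.6
    phase_curvature: float = -0.12
    heights: tuple[float, float] = (1.0, 0.4)
    centers: tuple[float, float] = (0.30, 0.62)
    widths: tuple[float, float] = (0.045, 0.09)
    path: str | None = None


class DriftConfig(BaseModel):
    kind: Literal["harmonic-sum", "random-smooth", "from-samples", "none"] = "harmonic-sum"
    components: list[tuple[float, float, float]] = Field(
        default_factory=lambda: [(0.2, 0.7, 0.0), (0.35, 0.3, 0.0)]
    )
    band_limit: float = 0.7
    amplitude: float | None = 1.0
    n_knots: int | None = None
    path: str | None = None


class TCSConfig(BaseModel):
    r0: float = 2.0
    zeta0: float = 1.5
    k0_over_kA: float = 1.0 / 6.0
    kA: float = 1.0


class SolverConfig(BaseModel):
    method: str = "RK45"
    rtol: float = 1e-8
    atol: float = 1e-10


class AnalysisConfig(BaseModel):
    n_harmonics: int = 10
    band: float = 0.45
    window: str = "boxcar"
    zero_pad_factor: int = 4
    apw_points: int = 200


class ScenarioConfig(BaseModel):
    """Full description of one reproducible simulation run."""

    case: Literal["wall", "pressure"] = "wall"
    sensors: Literal["acc", "ppg", "both"] = "both"
    f_c: float = 1.0
    cycles: float = 12.0
    fs: float = 200.0
    settle_cycles: float = 2.0
    a: float = 1.0 / np.pi
    pulse: PulseConfig = Field(default_factory=PulseConfig)
    drift: DriftConfig = Field(default_factory=DriftConfig)
    tcs: TCSConfig = Field(default_factory=TCSConfig)
    gains: tuple[float, float, float] = (-1.0 / 3.0, -1.0 / 3.0, -1.0 / 2.0)
    normalizer: float | Literal["max", "absmax"] = "max"
    seed: int = 0

    solver: SolverConfig = Field(default_factory=SolverConfig)
    analysis: AnalysisConfig = Field(default_factory=AnalysisConfig)

    @field_validator("f_c", "cycles", "fs", "a")
    @classmethod
    def _positive(cls, v, info):
        if not v > 0:
            raise ValueError(f"{info.field_name} must be positive")
        return v

    def config_hash(self) -> str:
        blob = json.dumps(self.model_dump(mode="json"), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


PRESETS: dict[str, dict] = {
    # default wall-displacement scenario: carotid-like 10-harmonic pulse,
    # two-tone drift, TVSPs slaved to the drift
    "wall-default": {"case": "wall"},
    # default pulsatile-pressure scenario: same drift at the mass, force
    # pi*a*dp on the arterial wall, TVSPs slaved to the stack compression
    "pressure-default": {"case": "pressure"},
    # MA-free reference
    "wall-clean": {"case": "wall", "drift": {"kind": "none"},
                   "gains": (0.0, 0.0, 0.0)},
}


def load_config(path: str | Path) -> ScenarioConfig:
    """Load a TOML / JSON / YAML scenario file."""
    path = Path(path)
    text = path.read_text()
    if path.suffix == ".toml":
        import tomllib

        data = tomllib.loads(text)
    elif path.suffix in (".yaml", ".yml"):
        import yaml

        data = yaml.safe_load(text)
    else:
        data = json.loads(text)
    return ScenarioConfig.model_validate(data)


def _build_inputs(config: ScenarioConfig):
    duration = config.cycles / config.f_c
    pc = config.pulse
    if pc.kind == "harmonic":
        pulse = carotid_like_spec(config.f_c, pc.n_harmonics, pc.decay,
                                  pc.phase_curvature)
    elif pc.kind == "apw":
        pulse = make_synthetic_apw(config.f_c, duration, config.fs,
                                   pc.heights, pc.centers, pc.widths)
    else:
        pulse = read_waveform_csv(pc.path)
    dc = config.drift
    if dc.kind == "none":
        drift = None
    else:
        spec = DriftSpec(kind=dc.kind, band_limit=dc.band_limit,
                         amplitude=dc.amplitude, seed=config.seed,
                         components=tuple(dc.components),
                         n_knots=dc.n_knots, path=dc.path)
        drift = make_baseline_drift(spec, duration, config.fs)
    params = nominal_params(config.tcs.r0, config.tcs.zeta0,
                            config.tcs.k0_over_kA, config.f_c, config.tcs.kA)
    artery = ArteryParams(kA=config.tcs.kA, a=config.a)
    grid = np.arange(int(round(duration * config.fs))) / config.fs
    return pulse, drift, params, artery, grid


def run_scenario(config: ScenarioConfig, out_dir: str | Path,
                 plot: bool = False) -> Path:
    """Simulate, decompose, analyze and persist one scenario."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pulse, drift, params, artery, grid = _build_inputs(config)
    solver_opts = config.solver.model_dump()

    if config.case == "wall":
        result = run_case_wall(
            params, pulse, drift, gains=config.gains,
            normalizer=config.normalizer, settle_cycles=config.settle_cycles,
            solver_opts=solver_opts, grid=grid,
        )
        forces = equivalent_forces_1dof(result, params)
        measured = {"acc": "x_ACC", "ppg": "x_PPG"}
        spectral_series = ["x_ACC", "x_C", "x_TVSP", "x_b", "x_PPG"]
        force_spectra = ["F_C", "F_TVSP", "F_b"]
    else:
        result = run_case_pressure(
            params, artery, pulse, drift, gains=config.gains,
            normalizer=config.normalizer, settle_cycles=config.settle_cycles,
            solver_opts=solver_opts, grid=grid,
        )
        forces = equivalent_forces_2dof(result, params, artery)
        measured = {"acc": "x_ACC", "ppg": "x_PPG"}
        spectral_series = ["x_ACC", "x_2C", "x_2TVSP", "x_2b", "x_PPG",
                           "x_1C", "x_1TVSP", "x_1b"]
        force_spectra = ["F", "F_1TVSP", "F_2TVSP", "F_b"]

    ts = pd.DataFrame({"time_s": result.t, **result.series()})
    ts.to_csv(out / "timeseries.csv", index=False)
    ff = pd.DataFrame({"time_s": forces.t, **forces.series()})
    ff.to_csv(out / "forces.csv", index=False)

    an = config.analysis
    i0 = result.settle_index
    spectra_frames = []
    for name, arr in {**result.series(), **forces.series()}.items():
        if name not in set(spectral_series) | set(force_spectra):
            continue
        sig = result.as_signal("x_ACC").with_samples(arr)
        sp = spectrum(sig, window=an.window, zero_pad_factor=an.zero_pad_factor)
        spectra_frames.append(pd.DataFrame(
            {"series": name, "freq_hz": sp.f, "amplitude": sp.amplitude}
        ))
    pd.concat(spectra_frames, ignore_index=True).to_csv(
        out / "spectra.csv", index=False)

    # per-cycle metrics on the analysis window of each requested sensor
    metrics_rows = []
    sidebands = {}
    wanted = [config.sensors] if config.sensors != "both" else ["acc", "ppg"]
    analysed = {s: measured[s] for s in wanted}
    # always include the TVSP-only and MA-free responses
    analysed["tvsp_only"] = "x_M" if config.case == "wall" else "x_2M"
    analysed["ma_free"] = "x_C" if config.case == "wall" else "x_2C"
    cse_frames = {}
    for tag, name in analysed.items():
        sig = result.as_signal(name)
        tail = sig.with_samples(sig.samples[i0:])
        tail = type(tail)(tail.fs, tail.samples, t_start=result.t[i0], label=name)
        try:
            feet = detect_feet(tail, config.f_c)
            cm = per_cycle_metrics(tail, feet, n_points=an.apw_points)
        except ValueError:
            continue
        for i, hr in enumerate(cm.hr_bpm):
            metrics_rows.append({
                "series": name, "cycle": i, "onset_s": cm.onsets[i],
                "hr_bpm": hr, "amplitude": cm.amplitude[i],
            })
        if feet.size >= 4:
            cse_frames[name] = cse_baseline(tail, feet).samples
    if metrics_rows:
        pd.DataFrame(metrics_rows).to_csv(out / "cycle_metrics.csv", index=False)
    if cse_frames:
        pd.DataFrame({"time_s": result.t[i0:], **cse_frames}).to_csv(
            out / "cse_baseline.csv", index=False)

    dist_name = "x_TVSP" if config.case == "wall" else "x_2TVSP"
    sig = result.as_signal(dist_name)
    tail = type(sig)(sig.fs, sig.samples[i0:], t_start=result.t[i0])
    sp = spectrum(tail, window=an.window, zero_pad_factor=an.zero_pad_factor)
    try:
        import warnings as _w

        with _w.catch_warnings():
            _w.simplefilter("ignore")
            rep = sideband_report(sp, config.f_c, an.n_harmonics, an.band)
        sidebands[dist_name] = {
            "centers_hz": rep.centers.tolist(),
            "band_hz": rep.band,
            "band_energy": rep.band_energy.tolist(),
            "peak_amplitude": rep.peak_amplitude.tolist(),
            "in_band_fraction": rep.in_band_fraction,
        }
    except ValueError:
        pass
    (out / "sidebands.json").write_text(json.dumps(sidebands, indent=2))

    if result.tvsp is not None:
        traj = param_trajectories(result.tvsp, params,
                                  artery if config.case == "pressure" else None)
        cols = {"time_s": traj.t, "r": traj.r, "zeta": traj.zeta}
        if traj.r_total is not None:
            cols["r_total"] = traj.r_total
        pd.DataFrame(cols).to_csv(out / "param_trajectories.csv", index=False)

    manifest = {
        "config": config.model_dump(mode="json"),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "pulsema_version": __version__,
        "numpy_version": np.__version__,
        "python_version": platform.python_version(),
        "settle_index": int(result.settle_index),
        "diagnostics": {k: (int(v) if v is not None else None)
                        for k, v in result.diagnostics.items()},
        "outputs": sorted(p.name for p in out.glob("*.csv")) + ["sidebands.json"],
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))

    if plot:
        _plot_run(out, result, forces)
    return out


def _plot_run(out: Path, result, forces) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(2, 1, figsize=(9, 6), sharex=True)
    series = result.series()
    for name in ("x_ACC", "x_PPG"):
        axes[0].plot(result.t, series[name], label=name, lw=0.8)
    axes[0].legend(loc="upper right")
    axes[0].set_ylabel("displacement (norm.)")
    for name, arr in forces.series().items():
        axes[1].plot(forces.t, arr, label=name, lw=0.8)
    axes[1].legend(loc="upper right", fontsize=7)
    axes[1].set_xlabel("time (s)")
    axes[1].set_ylabel("force (norm.)")
    fig.tight_layout()
    fig.savefig(out / "overview.png", dpi=120)
    plt.close(fig)


def compare_runs(
    run_a: str | Path, run_b: str | Path, series: list[str] | None = None
) -> dict[str, dict[str, float]]:
    """Max and RMS differences between the time series of two runs."""
    ta = pd.read_csv(Path(run_a) / "timeseries.csv")
    tb = pd.read_csv(Path(run_b) / "timeseries.csv")
    if len(ta) != len(tb) or not np.allclose(ta["time_s"], tb["time_s"]):
        raise ValueError("runs are on different time grids")
    names = series or [c for c in ta.columns if c != "time_s" and c in tb.columns]
    report = {}
    for name in names:
        if name not in ta.columns or name not in tb.columns:
            raise ValueError(f"series {name!r} missing from one of the runs")
        d = ta[name].to_numpy() - tb[name].to_numpy()
        report[name] = {"max_abs": float(np.max(np.abs(d))),
                        "rms": float(np.sqrt(np.mean(d**2)))}
    return report
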