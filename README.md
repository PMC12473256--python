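# pulsema

Motion-artifact modelling for arterial pulse measurement by
accelerometers and PPG sensors.

## The problem

A wearable pulse sensor never touches the artery: the true pulse crosses
the tissue–contact–sensor (TCS) stack, an overdamped mass–spring–damper
`(m0, k0, c0)` preset by the hold-down contact pressure.  Motion
artifacts at rest (< 0.7 Hz) do two things simultaneously:

* **baseline drift** `x_b(t)` — the familiar additive low-frequency
  wander of the measured signal, and
* **time-varying system parameters (TVSPs)** — the same drift perturbs
  the stack's mass/stiffness/damping, `m(t), k(t), c(t) ∝ x_b(t)`,
  producing a small multiplicative distortion that *rides on every
  harmonic* of the pulse and cannot be removed by low-pass filtering or
  cubic-spline baseline estimation.

`pulsema` simulates both effects end to end and separates their
contributions.  With wall displacement `y(t)` as the true pulse, the
mass obeys

```
(m0+m(t)) x'' + (c0+c(t)) x' + (k0+k(t)) x = (k0+k(t)) y + (c0+c(t)) y'
```

so the accelerometer reads `x_ACC = x_M + x_b` and a PPG sensor
`x_PPG = y + g(x_TVSP + x_b)`, where `x_TVSP = x_M − x_C` is the
distortion relative to the MA-free response
`x_C = [(k0 + j c0 ω)/(k0 − m0 ω² + j c0 ω)] · y` per harmonic.  A 2DOF
variant drives the stack through an arterial-wall spring `kA` with the
pulsatile-pressure force `F = π a Δp`.  The package also re-expresses MA
as **equivalent forces** (`F_b`, `F_TVSP`) on the nominal time-invariant
system and verifies the decomposition by reconstruction.

Modules: `waveforms` (synthetic pulses and band-limited drifts),
`tcs` (parameters, drift→TVSP map, closed-form transfer functions),
`dynamics` (time-varying ODE integration, sensor assembly),
`forces` (equivalent forces and force closure),
`analysis` (spectra, pulse feet, per-cycle HR/amplitude, CSE baseline,
harmonic sidebands), `interface`/`cli` (scenario configs and runs).

## Worked example

```python
import numpy as np
from pulsema import (carotid_like_spec, make_baseline_drift, DriftSpec,
                     nominal_params, run_case_wall)
from pulsema.analysis import per_cycle_distortion
from pulsema.waveforms import PulseSignal

params = nominal_params()                      # r0=2, zeta0=1.5, k0=kA/6
pulse = carotid_like_spec()                    # 10 harmonics at 1 Hz
drift = make_baseline_drift(DriftSpec(kind="harmonic-sum", amplitude=None),
                            12.0, 200.0)       # 0.2 + 0.35 Hz two-tone
res = run_case_wall(params, pulse, drift)

i0 = res.settle_index                          # 2-cycle lead-in
win = lambda name: PulseSignal(res.fs, res.series()[name][i0:],
                               t_start=res.t[i0])
print(per_cycle_distortion(win("x_C"), win("x_M"), 1.0))
```

prints

```
{'amp_dev_pct': 1.186943425185959, 'hr_dev_pct': 0.12280596301441923, 'n_cycles': 9}
```

i.e. over the nine analyzed cycles the TVSP distortion alone changes the
per-cycle pulse amplitude by at most ≈ 1.2 % and shifts the per-cycle
heart rate by at most ≈ 0.12 % of the nominal 60 bpm — small in the time
domain, yet its spectrum (see `sideband_report`) concentrates ≥ 85 % of
its energy in sidebands around the pulse harmonics, with the 2nd
harmonic amplified because the stack's natural frequency sits there
(`r0 = 2`).

All quantities are in normalized units (`kA = 1`, pulse amplitude O(1));
outputs are dimensionless ratios.

### Command line

```
pulsema simulate --preset wall-default --out runs/wall
pulsema simulate --preset pressure-default --out runs/pressure
pulsema compare runs/wall runs/wall --series x_ACC
```

A run directory holds `timeseries.csv`, `forces.csv`, `spectra.csv`,
`cycle_metrics.csv`, `cse_baseline.csv`, `sidebands.json`,
`param_trajectories.csv` and a `manifest.json` (config, hash, versions);
runs are byte-identical for a fixed config.

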