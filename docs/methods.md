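# Methods

## The model

A sensor (accelerometer or PPG) pressed against an artery does not read
the true pulse directly: the pulse crosses the tissue–contact–sensor
(TCS) stack, which behaves as an overdamped 1DOF mass–spring–damper with
nominal mass `m0` (tissue + sensor), stiffness `k0` and damping `c0`
(tissue), preset by the hold-down contact pressure.  Motion artifacts
(MA) at rest do two things at once:

1. **Baseline drift** `x_b(t)` — a low-frequency (< 0.7 Hz) displacement
   of the sensor mass relative to the artery: classical additive noise.
2. **Time-varying system parameters (TVSPs)** — the same drift changes
   the stack length and hence the prestress in the tissue, perturbing
   the parameters to `m0 + m(t)`, `k0 + k(t)`, `c0 + c(t)`:
   multiplicative noise riding on every harmonic of the pulse.

Two excitation routes are modeled.

**Wall displacement as the true pulse.**  `y(t)` base-excites the stack:

    (m0+m(t)) x'' + (c0+c(t)) x' + (k0+k(t)) x = (k0+k(t)) y + (c0+c(t)) y'

The accelerometer reads `x_ACC = x_M + x_b` (displacement convention)
and the PPG sensor `x_PPG = y + g(x_TVSP + x_b)` with `g` the optical
transduction (identity by default).  The MA-free response is
`x_C = G0 e^{j phi0} y` per harmonic, with
`G0 e^{j phi0} = (k0 + j c0 w)/(k0 - m0 w^2 + j c0 w)`, and the TVSP
distortion is `x_TVSP = x_M - x_C`.

**Pulsatile pressure as the true pulse.**  The arterial wall is a
massless spring `kA` (its inertia and damping are negligible against its
elasticity); `F = pi*a*dp` forces the wall, forming a 2DOF system whose
wall equation is first order.  Drift at the mass `x_2b` propagates to
the wall (`x_1b`) through the same force balance, and the TVSPs are
slaved to the stack compression `x_2b - x_1b`.  The MA-free gains are

    G10 = d / (kA d - m0 w^2 z),   G20 = z / (kA d - m0 w^2 z)

with `z = k0 + j c0 w`, `d = z - m0 w^2`; both tend to `1/kA`
statically.  (These were re-derived from the frequency-domain 2x2 solve
of the equations of motion; a test pins the implementation against an
independent complex matrix solve at every probed frequency.)

**Drift-to-TVSP law.**  No mechanistic relation is available, so the
TVSPs follow the drift linearly:

    k(t) = gk k0 u(t),  c(t) = gc c0 u(t),  m(t) = gm m0 u(t),
    u(t) = x_b(t) / max x_b(t)

with default gains `(gk, gc, gm) = (-1/3, -1/3, -1/2)`: the mass term
moves faster so the natural frequency drops as drift compresses the
stack.  The normalizer is the positive maximum of the drift over the
simulated window; an `absmax` mode exists for drifts that never go
positive.  Because of the normalization, scaling the drift amplitude
rescales `x_b` but leaves `x_TVSP` unchanged — asserted as a property
test.

**Equivalent forces.**  The MA influence can be moved out of the
parameters and into forces on the *nominal* LTI system: the drift force
`F_b = m0 x_b'' + c0 x_b' + k0 x_b`, the base-excitation force
`F_C = k0 y + c0 y'`, and `F_TVSP = F_T - F_C` where `F_T` is the
nominal operator applied to the distorted motion.  Driving the nominal
system with the excitation plus `F_MA = F_TVSP + F_b` reproduces
`x_M + x_b` (1DOF); in the 2DOF case the MA forces alone (`F_1T - F` on
the wall, `F_2T + F_b` on the mass) reproduce `x_i = x_iM + x_ib - x_iC`
by superposition.  This force-closure property is the master consistency
check of the whole decomposition and is enforced at 1e-3 relative.

## Default parameters

| parameter | default | meaning |
|---|---|---|
| `f_c` | 1 Hz | heart rate (60 bpm) |
| `r0 = omega0/omega_c` | 2 | stack natural frequency at the 2nd harmonic |
| `zeta0` | 1.5 | overdamped stack |
| `k0` | `kA/6` | stack vs arterial-wall stiffness |
| `kA` | 1 | normalized unit of stiffness |
| gains | (-1/3, -1/3, -1/2) | TVSP dip at peak drift |
| `fs` | 200 Hz | ≥ 20x the 10th harmonic at 1 Hz |
| drift band | < 0.7 Hz | MA at rest |

All units are normalized (`kA = 1`, pulse amplitudes O(1)); every output
is a dimensionless ratio, since no absolute tissue properties are
available.

## Synthetic inputs

The true carotid pulse and the measured drift that motivated this model
are not distributable, so both are synthetic stand-ins:

* **Pulse**: 10 harmonics with geometric amplitude decay
  `0.6**(n-1)` and a weak quadratic phase law (`-0.12 (n-1)^2` rad) that
  skews the waveform toward a sharp systolic upstroke.  Any
  multi-harmonic waveform exercises the same transmission-path math; the
  decay rate controls how much energy the high harmonics carry.
  A two-bump (systolic + dicrotic) von-Mises APW generator is also
  provided for waveform-level analyses.
* **Drift**: default two-tone `0.7 sin(2 pi 0.2 t) + 0.3 sin(2 pi 0.35 t)`;
  a seeded `random-smooth` mode splines through random knots and hard-
  truncates the spectrum at the band limit (≥ 99 % of energy below
  0.7 Hz, bit-reproducible per seed).

What the generators do **not** emulate: respiration AM/FM of the pulse,
beat-to-beat physiologic variability, sensor transduction noise, or MA
during activity (0.3–7 Hz, overlapping the pulse band).  Passing tests
therefore demonstrate the mechanics of the drift/TVSP distortion
pathway, not performance on recorded physiological data.

## Numerical choices

* **Integration**: `scipy.integrate.solve_ivp` RK45 with `rtol 1e-8`,
  `atol 1e-10`, starting from rest.  TVSP trajectories enter the
  right-hand side through cubic-spline interpolants.
* **Derivatives**: `y'` (and pressure derivatives) are analytic whenever
  the input is a harmonic spec; tabulated inputs use cubic-spline
  derivatives — spectral differentiation was rejected because the
  simulated windows are not periodic and FFT derivatives ring at the
  edges.  Response velocities come from the solver state and
  accelerations from the ODE right-hand side, never from differencing
  the output.
* **Transients**: the lead-in discarded before analysis is
  `max(5/(zeta0*omega0), 2 cycles)` (2 cycles at the defaults; the
  slowest 1DOF pole decays as `exp(-0.38 omega0 t)`, ~7e-5 after two
  cycles).  The wall-drift propagation starts from a quasi-static
  initial condition with a first-order slope correction; its residual
  transient decays with time constant `c0/(kA+k0)` ≈ 0.03 s, so
  force-balance residuals are checked on the window interior.
* **Problem size**: default runs are 12 cycles at 200 Hz (10 analyzed),
  matching the figure-scale windows this class of simulation uses; all
  headline quantities are stable against longer windows.
* **Spectra**: rectangular window on an integer number of nominal
  cycles, zero-pad factor 4 so 0.2/0.35 Hz sidebands around each
  harmonic are resolved; Parseval's identity is asserted at 1e-9.
* **Foot detection**: feet are windowed minima preceding slope-maxima
  upstrokes, with parabolic sub-sample refinement.  A global linear
  trend (median sample slope, exactly zero for periodic signals) is
  removed first, making the detector trend-robust even across flat
  diastolic feet.  The same detector is applied to every signal so HR
  differences reflect distortion, not detector changes.
* **Sideband bands**: per-harmonic energies assign each frequency bin to
  the nearest harmonic center when bands overlap (warned above
  `f_c/2`, rejected at `>= f_c`); the in-band fraction uses the union of
  bands.
* **CSE baseline**: natural cubic spline through the analyzed signal's
  own foot points — the standard estimator this model shows to be blind
  to TVSP distortion.

## Open design points resolved here

* `r_total(t)` (frequency ratio including the arterial wall) uses the
  series-spring stiffness `kA k(t)/(kA + k(t))` seen by the mass; this
  is an interpretation, flagged as such.
* The drift normalizer is the signed maximum (`max x_b`), with `absmax`
  provided, since the sign convention is ambiguous for predominantly
  negative drifts.
* The 2DOF force-closure target is `x_i = x_iM + x_ib - x_iC`,
  reproduced by the MA forces alone on the nominal system (superposition
  argument in `forces.py`).

## Limitations

* Linearity end to end: the stack is LTI between parameter updates and
  the TVSP–drift relation is linear by assumption; both are model
  assumptions, not measured facts.
* TVSP gains and nominal parameters are plausibility choices — the
  inverse problem (estimating them from a measured signal) is out of
  scope.
* Transverse sensor motion, optical transduction beyond a pluggable
  `g(.)`, and sensor self-noise are not modeled.
* Absolute heart-rate-deviation values depend on the cycle-boundary
  definition; a different foot detector can shift them while leaving the
  qualitative TVSP signatures intact.
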