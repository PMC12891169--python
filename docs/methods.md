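# Methods

## Overview

`lsoloop` simulates a closed-loop binaural localization system: two
adaptive cantilever sensors (artificial cochleae), an MNTB/LSO rate-neuron
circuit per side, and an efferent feedback path from the LSO output back
to the sensors' local feedback gains. The full closed loop has 14 states:
five per sensor channel (tip deflection x, velocity v, beam–ambient
temperature difference θ, high-pass readout u_ac, envelope u_env) plus a
membrane potential for each of the two MNTB and two LSO neurons. A
table-driven open-loop mode replaces the sensor dynamics with measured or
synthetic envelope-transfer curves, leaving 6 states (two envelopes, four
membrane potentials).

## Sensor model

The cantilever is a mass-normalized second-order resonator,

    ẍ + (ω₀/Q₀) ẋ + ω₀² x = α_s θ + F_ext(t),

forced by the sound acceleration F_ext and the thermomechanical bending
α_s θ. The beam temperature relaxes at rate β_s toward the Joule heating
of the integrated resistor,

    θ̇ + β_s θ = γ_s tanh²(u_act / R),    u_act = a_f u_ac + u_dc.

The readout u_s = κ_s x passes an RC high-pass with time constant τ_hpf;
the high-pass is integrated in the substituted form
u̇_ac = κ_s v − u_ac/τ_hpf so no solver output is differentiated. The
envelope extractor is a full-wave rectifier into an RC low-pass:
τ_lpf u̇_env = |u_ac| − u_env.

**Placement of the tanh limiter.** The heating law admits two readings,
γ_s·tanh²(u_act/R) and γ_s·(tanh u_act)²/R². They differ only at large
actuation voltages and shift the critical feedback factor by ≈1.3%. The
package defaults to the first ("current" mode) because the numerical
bifurcation analysis then reproduces the reference critical factor
0.03236 to better than 0.01%, i.e. the reference value was evidently
computed with the limiter applied to u_act/R; the second reading, which
is the one under which the printed units of γ_s (K Ω² s⁻¹ V⁻²) cancel
exactly, remains available as `limiter="voltage"`. All package results
are insensitive to the choice at the operating point |u_act| ≈ 0.1 V,
where tanh is within 10⁻⁴ of linear.

**Critical gain.** With no sound input, any equilibrium has v = 0 and
hence u_ac = 0 (the high-pass blocks DC), so the quiescent state is
closed-form: θ_eq = γ_s tanh²(u_dc/R)/β_s, x_eq = α_s θ_eq/ω₀². As a_f
increases, the complex-conjugate eigenvalue pair of the 4-state Jacobian
crosses the imaginary axis (Hopf bifurcation). `find_critical_gain`
sweeps a_f upward in steps of 10⁻³ to bracket the crossing of the pair's
real part, then bisects to 10⁻⁶ absolute. With the default parameters
(f₀ = 1 kHz, Q₀ = 50, α_s = 19.2 m s⁻² K⁻¹, β_s = 1006.6 s⁻¹,
γ_s = 16.2·10⁶ K Ω² s⁻¹ V⁻², R = 15 Ω, κ_s = 0.602·10⁶ V m⁻¹,
τ_hpf = 1 ms, u_dc = −100 mV) this yields a_f,crit ≈ 0.03236. If the
actuation path is broken (α_s = 0 or γ_s = 0) no crossing exists and a
`NoBifurcationError` is raised.

## Neural model

Each side has a leaky MNTB integrator driven by the *contralateral*
ear's envelope,

    τ_q q̇ = −α_q q + β_q (u_env,contra · w_mntb),   g(q) = max(q, 0),

and a conductance-based LSO neuron combining ipsilateral excitation with
MNTB inhibition,

    τ_r ṙ = −α_r r + (β_r − r)(u_env,ipsi · w_lso) − (γ_r + κ_r r) g(q).

The conductance form confines r to [−γ_r/κ_r, β_r]; the output rate is
the logistic σ(r) = 1/(1 + exp(−α_σ (r − β_σ))). Under constant inputs
both units have closed-form fixed points (q_eq = β_q s_q/α_q and
r_eq = (β_r s_r − γ_r g)/(α_r + s_r + κ_r g)), used as oracles in the
tests. Defaults: τ_q = τ_r = 25 µs, α_q = 2, α_r = 1, β_q = β_r = 1 V,
γ_r = 3 V, κ_r = 4, α_σ = 20 V⁻¹, β_σ = 0.2 V. The input weights carry
no code default — they are the experiment's excitation–inhibition
balance ρ_w = w_lso/w_mntb and are set by the configuration: 2/1 for the
table-driven open-loop experiments, w_lso = 100 with
w_mntb ∈ {200, 400, 750} (ρ_w = 1/2, 1/4, 1/7.5) for the closed loop.

## Efferent feedback

The LSO rates modulate the sensor gains algebraically (no synaptic
delay): a_f,i = k_inv · min(σ_j, k_max) · a_f,crit, with ipsilateral
(i = j) or contralateral (i ≠ j) routing and sign k_inv = ±1, giving the
four conditions ipsi-positive, ipsi-negative, contra-positive,
contra-negative; `topology="none"` applies the constant baseline
k_a_const · a_f,crit instead. The clamp k_max = 0.95 keeps the loop
strictly below the Hopf point, so efferent drive alone can never
destabilize a sensor. The clamp acts on the rate before the sign, as the
gain law is written. The baseline constant defaults to k_a_const = 0.5 —
the midpoint of the σ range, so the no-feedback curve sits centrally
between the positive and negative closed-loop excursions; it is a
configuration key, not a fixed constant.

## Stimulus

A pure tone with constant-sum binaural amplitudes,
F_ext,right/left = (β_ILD ± α_ILD·ILD)·sin(2πft) with α_ILD = β_ILD = 0.5
and f = 1 kHz. The "+" branch is assigned to the right channel, so
positive ILD means a source on the right; only consistency of this
convention matters (all symmetry properties are two-sided). Levels with
|ILD| > β_ILD/α_ILD would require negative amplitudes and are rejected.

## Simulation protocol

Each run follows a two-phase protocol. *Initialization*: 2 s with no
stimulus and constant gains k_a_const·a_f,crit on both sides; the result
is verified against the closed-form quiescent state (sensor states to
10⁻⁶ absolute; the neural tolerances are scaled by the linearized gain
from a residual envelope, since w_mntb ~ 200 amplifies a 10⁻⁸ V envelope
remnant into ~10⁻⁵ V of membrane potential). Non-convergence raises an
error rather than silently proceeding. *Main run*: the chosen feedback
configuration and the stimulus switch on together at t = 0 and the
coupled system is integrated for the stimulus duration (default 1 s).
Because the quiescent state is independent of stimulus and ILD, ILD
sweeps compute the initialization once and reuse it.

Integration uses LSODA (stiff multistep) with rtol 10⁻⁶, atol 10⁻⁹, an
analytic Jacobian, and a numba-compiled right-hand side; a consistency
test pins the compiled kernel to the composition of the public module
functions. The |u_ac| rectifier kink and the rate/clamp corners are
Lipschitz and are handled by the error control without event detection.
Traces are sampled onto a uniform 50 µs grid by dense-output
interpolation so that analysis windows are independent of the solver's
internal steps.

## Analysis metrics

- **σ_eq** — mean LSO rate over the trailing window (0.1 s for
  closed-loop runs; 0.333 s for the table-driven mode).
- **Δσ_eq = σ_right − σ_left** — the lateralization-compensated
  difference code.
- **TT90** — time from stimulus onset to first reaching 90% of the trace
  maximum, with linear interpolation at the crossing. Computed on the
  raw σ trace: at τ_lpf = 5 ms and f = 1 kHz the carrier ripple in σ is
  small, so no smoothing is applied.
- **Temporal slices** — means over consecutive non-overlapping windows
  (default Δt = 0.1 s); a trailing partial window is dropped.
- **Sensitivity dσ_eq/dILD** — central differences at interior grid
  points; first-order one-sided differences at the two ends so the output
  matches the grid length (interior values are unaffected).
- **Equal-activation ILD** — the interpolated zero crossing of Δσ_eq,
  used for the balancing experiments.

## Synthetic sensor tables

`make_surrogate_sensors` generates the transfer tables used by the
open-loop mode: two sensors with resonances at 950 and 986 Hz, envelopes
linear in sound amplitude with slope G/(1 − k_a) (the model sensor's
small-signal resonant gain law), base gain G = 0.5 V per unit amplitude,
a right/left base-gain ratio of 1 + mismatch (default 0.3, emulating
fabrication tolerance of the same order as the feedback tuning range),
and multiplicative Gaussian scatter of 0.5% (seed 42 by default). The
tables emulate the *shape* of measured transfer characteristics —
linearity, gain growth with k_a, inter-sensor mismatch — but not sensor
noise spectra, compression near the critical point, or temperature
drift; conclusions drawn from them concern the neural stage's balancing
behavior, not sensor physics. Tables round-trip through a tidy CSV
(columns sensor, k_a, amplitude, envelope) so measured data can be
substituted directly.

## Numerical choices and degenerate inputs

- Steady-state extraction requires window ≤ trace duration; temporal
  slicing requires Δt ≤ duration; sensitivity requires ≥ 3 uniformly
  spaced, strictly increasing grid points. Violations raise `ValueError`.
- A constant trace has TT90 = 0 (already at its maximum at onset).
- Sweeps sort the ILD grid; per-point failures are collected into one
  `SweepError` naming the offending ILDs.
- Unbounded trajectories (|x| > 1 cm, |r| > 100 V — far outside the
  physical ranges) abort with a diagnostic.
- Mirror symmetry of the binaural equations is exact (the compiled RHS
  is bitwise symmetric under side exchange), but two independently
  integrated mirrored runs agree only to a few times rtol at sensitive
  operating points; tests that verify symmetry to 10⁻⁶ therefore tighten
  the solver to rtol 10⁻⁸.
- Tightening rtol/atol tenfold changes σ_eq by well under 10⁻⁴, so
  reported quantities are solver-converged at the defaults.

## Problem sizes

The test suite runs the closed-loop sweeps on a 21-point ILD grid with
1 s stimuli (the package's standard experiment), the stability matrix on
4 topologies × 3 balances × 5 ILDs, and the open-loop comparisons on
11-point grids; the bifurcation analysis is a 4×4 eigenvalue problem and
takes milliseconds.

## Known limitations

- Single frequency channel per side; no filter banks, no ITD cues, no
  head-related transfer functions, no acoustic propagation.
- One rate neuron per nucleus; no spiking dynamics, populations, or
  GABAergic modulatory adaptation.
- Efferent routing is symmetric and single-source; mixed or asymmetric
  topologies per side are not modeled.
- Sensor readout physics beyond the linear factor κ_s (noise,
  piezo-resistive nonlinearity, drift) is out of scope.
- With the reference neural weights the LSO sigmoid (β_σ = 0.2 V,
  α_σ = 20 V⁻¹) keeps each LSO silent until its ipsilateral ear clearly
  dominates, so the sensitive ILD ranges of the two sides do not overlap
  and cross-hemispheric feedback loops engage only weakly; transient
  ringing driven by contralateral routing is correspondingly weak in
  this regime (the long, oscillatory transients occur for the
  sensitivity-increasing configurations instead, exactly where a
  configuration's σ_eq exceeds the no-feedback baseline).
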