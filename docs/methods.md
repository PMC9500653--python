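# Methods

## Model overview

The package simulates nociceptive pain caused by static mechanical
compression of the skin. Three stages are chained, with no feedback between
stages and the nerve-conduction delay neglected:

stress at the nociceptor → mechanosensitive membrane firing → gate-control
modulation → pain decision.

All three stages are deterministic; there is no stochastic channel noise,
temperature dependence, or cable propagation.

## Mechanics

The skin is a homogeneous, isotropic, linearly elastic half-plane in plane
strain, loaded statically by a uniform pressure q over the strip
y ∈ [−a, a] of its surface. Coordinates: x = depth (positive downward),
y = lateral offset, load centred at y = 0; lengths in mm, stresses in kPa.

Stresses anywhere in the half-plane follow from superposing the Flamant
line-load kernels over the strip (`stress_quadrature`, adaptive quadrature
at 1e−10 absolute / 1e−8 relative tolerance — far below the sensitivity of
the neural stages, since the kernels are smooth for x > 0). On the load
axis the integrals reduce to the closed form

σx = −(q/π)[2 arctan(a/x) + 2ax/(a²+x²)],
σy = −(q/π)[2 arctan(a/x) − 2ax/(a²+x²)], τxy = 0,

implemented in `stress_axis_closed` and verified in the test suite both
against the unsimplified rational-polynomial expressions and against
independent tight-tolerance quadrature. On the axis σx < σy < 0 and
|σx| ≥ |σy|; the transduction stress is |σx|.

The surface x = 0 is handled analytically (`surface_limit`): under the
strip the surface carries the applied traction (σx = σy = −q), outside it
is traction-free, and the strip edges |y| = a are singular points with no
defined value. The quadrature path refuses x = 0 rather than returning a
divergent number.

Linearity means results depend on q only through the ratio σ/σt; depth
enters through the geometric decay of |σx|, which is strictly monotone on
the axis.

## Transduction

The nociceptor membrane is a Connor–Stevens-type Hodgkin–Huxley model:

C dV/dt = I_mech + I_shift − (I_Na + I_K + I_A + I_L),

with I_Na = κ_Na m³h(V−E_Na), I_K = κ_K n⁴(V−E_K), I_A = κ_A A³B(V−E_A),
I_L = κ_L(V−E_L), and first-order gating τx dx/dt = x∞ − x for
x ∈ {m, h, n, A, B}. The removable singularities of the m and n activation
rates (at −29.7 and −45.7 mV) are evaluated by their analytic limits.

Parameters (defaults of `HHParams`):

| parameter | value | units | meaning |
|---|---|---|---|
| C_m | 1 | μF/cm² | membrane capacitance |
| κ_Na, κ_K, κ_A | 120, 20, 47.7 | mS/cm² | maximal conductances |
| κ_L | 0.3 | mS/cm² | leak conductance (see below) |
| E_Na, E_K, E_A, E_L | 55, −72, −75, −17.5 | mV | reversal potentials |
| σ_t | 20 | kPa | mechanical threshold |
| C_m1, C_m2, C_m3 | 2, 2, −1 | μA/cm², –, μA/cm² | mechano-current constants |
| I_shift | 8.1 | μA/cm² | suprarheobase bias while σ ≥ σ_t |

Two parameter choices deserve comment. The leak conductance is set to the
standard Connor–Stevens value 0.3 mS/cm², consistent with every other
conductance and reversal potential in the set; it is exposed as a
configuration parameter. I_shift is interpreted as a current *density*
(8.1 μA/cm²) and is gated on σ ≥ σ_t: its role is to guarantee repetitive
firing once the mechanical threshold is crossed, and an always-on bias of
this size would make the membrane fire with no stimulus at all,
contradicting the sub-threshold quiescence the model is built around. The
Heaviside convention is H(0) = 1, so σ = σ_t is the first firing stress;
the onset is only ever measured by bisection with finite tolerance, so the
convention is not load-bearing.

The zero-stimulus resting potential (≈ −68.06 mV, found by root-finding on
the steady-state current balance) is the quiescent state below threshold.
Default integration: V(0) = −68 mV with gates at steady state, 1200 ms of
classical fixed-step RK4 at dt = 0.01 ms, the first 200 ms discarded as
transient. These sizes make each membrane run cost about a second and leave
RK4 discretisation error far below the 1% frequency tolerance asserted in
the tests (halving dt is verified to move frequencies by < 1%).

A formula property worth knowing: the printed A-current activation curve
A∞(V) marginally exceeds 1 above about +40 mV (A∞(+50) ≈ 1.009). It is
implemented literally, without clipping; because spikes are brief relative
to τ_A the gating variables never leave [0, 1] along trajectories, which
the tests assert directly.

### Firing-frequency extraction

The post-transient window (1000 ms ⇒ 1 Hz spectral resolution) is analysed
two independent ways:

* **fft** (default): mean-subtracted DFT. A spike train spreads power over
  integer harmonics of comparable magnitude, so the reported frequency is
  the *fundamental*: the lowest local spectral peak within 50% of the
  strongest non-DC peak. A trace is declared quiescent (frequency 0) when
  its peak-to-peak range is below 1 mV — action potentials swing tens of
  mV, and a ratio-only criterion could misread a μV-scale settling tail —
  or when the dominant peak amplitude is below 5% of the signal RMS.
* **spike_count**: upward crossings of 0 mV; the rate is the number of
  inter-spike intervals divided by the time they span. (A plain
  count-over-window estimate carries a ±1 spike edge error, ±1 Hz over a
  1 s window, which would spuriously exceed one spectral bin even on
  perfectly periodic traces.)

The two methods agree within one spectral bin on every spiking trace in
the test grid.

At the default geometry the onset behaves like a rheobase: just above
σ_t the input current steps to (C_m1 + C_m3) + I_shift = 9.1 μA/cm² and
the membrane fires at ≈ 16 Hz; frequency then grows monotonically with
stress (≈ 38 Hz at 60 kPa). Bisection over σ ∈ [0, 40] kPa locates the
onset at 20 kPa to the requested 0.5 kPa tolerance.

## Gate control

Four cells — inhibitory SG (Vi), excitatory SG (Ve), T-cell (Vt), midbrain
(Vb) — relax toward −70 mV with common time constant τ = 0.7 (model time
units; reported as ms, though only the trajectory shape matters) under
saturating tanh synaptic drives; see the module docstring for the four
equations. The cell output function is implemented literally as
f(V) = (V − V_thr − V₀)·H(V − V_thr) with V_thr = −55 mV, V₀ = −70 mV and
strict threshold (H(0) = 0, matching "exceeds"). Because of the −V₀ term,
f jumps discontinuously from 0 to ≈ 70 at threshold and saturates every
tanh it feeds; a `fiber_drive_variant="linear"` switch selects the
conventional (V − V_thr) form for exploration.

Fibre inputs: x_l = 0 (compression is carried by small fibres) and
x_s = the nociceptor firing frequency in Hz (`x_s_scale` = 1). Hz is the
only reading under which the circuit can cross the −55 mV pain threshold:
with per-ms rates the tanh drives are ≤ 0.2 and the T-cell can never leave
the neighbourhood of rest.

Integration: RK4, 50 time units at dt = 0.005, from the all-(−70) state
(an exact fixed point under zero input). The pain statistic
(`t_cell_output`) is the maximum of Vt over the final half of the run,
with an `oscillatory` flag when the late-window peak-to-trough range
exceeds 1 mV. The maximum rather than the final value is used because the
literal relay-like feedback makes the circuit *chatter* at the −55 mV
switching boundary instead of settling on a clean plateau: the late-window
maximum equals the plateau when one exists and remains a meaningful
per-cycle peak when it does not.

Two consequences of the relay dynamics, verified numerically:

* Above onset the output is nearly rate-independent: every supra-threshold
  x_s ≥ 16 Hz yields a late-window maximum of about −54.8 ± 0.15 mV. The
  pain *decision* is robust; graded pain *intensity* lives in the firing
  frequency, not in the T-cell level.
* At low rates that the transduction stage never actually delivers
  (0 < x_s ≲ 5 Hz; the firing onset jumps from 0 straight to ≈ 16 Hz),
  the output is non-monotone in x_s. Monotonicity is therefore asserted
  over the operating grid of reachable rates.

## Pipeline and experiments

`run_scenario` chains closed-form on-axis stress (quadrature off-axis) →
|σx| → membrane simulation → firing frequency → gate circuit (x_l = 0,
x_s = frequency) → late-window maximum → pain decision, and records every
stage output in one tidy row. Default experiments: amplitude sweep
{15, 25, 35} kPa at a = 10 mm, depth 1.6 mm (≈ epidermis thickness), and
depth sweep {1, 10, 50} mm at q = 25 kPa. Identical configurations produce
byte-identical tables; the recorded seed is provenance only.

## What the defaults do and do not show

The default scenarios probe the model in its intended regime: static
uniform strip loads of 15–60 kPa, on-axis nociceptors at 1–50 mm. Passing
tests demonstrate internal consistency (stress solutions agree, rate
estimators agree, results are step-size-robust) and the two qualitative
laws the model encodes — pain onset above a stress threshold and
attenuation with depth. They do not validate the model against
experimental pain data: skin viscoelasticity, layering, non-uniform loads,
conduction delay and parameter uncertainty are all outside scope, and the
transduction/gate parameters have not been fitted to measurements.

## Numerical choices, edge cases

* Quadrature: `scipy.integrate.quad`, tolerances 1e−10/1e−8, with the
  kernel peak location passed as a breakpoint for shallow off-axis points.
* RK4 aborts with a diagnostic naming the step if the state leaves
  (−500, 500) mV or becomes non-finite.
* Membrane dt capped at 0.05 ms; gate dt at 0.01 units; frequency analysis
  requires ≥ 800 ms of post-transient signal; gate trajectories must cover
  ≥ 50 time units before an output statistic is computed.
* Degenerate nociceptor depth x = 0 is served only by the analytic surface
  limit; the strip edge |y| = a raises an error.
* Ties/conventions: H(0) = 1 for the mechano-current, H(0) = 0 for the
  gate output function (strict pain threshold, "exceeds −55 mV").
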