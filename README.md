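# skinpain

Simulation of skin pain under local mechanical compression, for researchers
working on tactile perception models and electronic-skin design. The package
answers a quantitative question: given a pressure of amplitude *q* applied
over a strip of width 2*a* on the skin surface, does a nociceptor at depth
*x* report pain, and how does the answer change with amplitude and depth?

The model chains three stages:

1. **Mechanics** — the skin is a semi-infinite elastic half-plane (plane
   strain). The Flamant solution gives the stress at the nociceptor; on the
   load axis the principal stresses are

   σ<sub>x</sub> = −(q/π)[2 arctan(a/x) + 2ax/(a²+x²)],
   σ<sub>y</sub> = −(q/π)[2 arctan(a/x) − 2ax/(a²+x²)],  τ<sub>xy</sub> = 0,

   with σ<sub>x</sub> < σ<sub>y</sub> < 0. The magnitude |σ<sub>x</sub>| of
   the minor principal stress drives transduction.

2. **Transduction** — a modified Hodgkin–Huxley (Connor–Stevens) membrane
   with Na⁺, K⁺, A-type K⁺ and leak currents, driven by a mechanosensitive
   current that switches on above the mechanical threshold σ<sub>t</sub> = 20 kPa:

   C<sub>m</sub> dV<sub>m</sub>/dt = I<sub>mech</sub> + I<sub>shift</sub> − (I<sub>Na</sub> + I<sub>K</sub> + I<sub>A</sub> + I<sub>L</sub>),
   I<sub>mech</sub> = [C<sub>m1</sub> e^((σ−σ<sub>t</sub>)/(σ<sub>t</sub>C<sub>m2</sub>)) + C<sub>m3</sub>]·H(σ−σ<sub>t</sub>).

   Stimulus intensity is encoded in the firing *frequency* of V<sub>m</sub>,
   extracted by FFT (or, as a cross-check, by spike counting).

3. **Gate control** — the four-cell Melzack–Wall gate circuit (inhibitory
   and excitatory substantia-gelatinosa interneurons, T-cell, midbrain
   feedback) driven by the small-fibre rate x<sub>s</sub> = firing frequency
   (x<sub>l</sub> = 0 for noxious compression). Pain is signalled when the
   T-cell output exceeds V<sub>thr</sub> = −55 mV.

Both ODE stages are integrated with classical fixed-step 4th-order
Runge–Kutta and are fully deterministic.

## Worked example

Amplitude sweep at the reference geometry (a = 10 mm, nociceptor on-axis at
1.6 mm — the approximate epidermis thickness):

```sh
skinpain sweep-q --grid 15,25,35 --depth 1.6 --a 10 --out sweep_q
```

prints

```
 q_kPa  depth_mm  sigma_kPa  frequency_Hz  V_t_out_mV  oscillatory_flag  pain
  15.0       1.6  14.974704       0.00000  -70.000000             False False
  25.0       1.6  24.957840      17.99982  -54.846484             False  True
  35.0       1.6  34.940975      22.99977  -54.783132             False  True
```

Reading the rows: at q = 15 kPa the stress at the nociceptor (14.97 kPa)
stays below the 20 kPa mechanical threshold, the membrane never fires, the
gate circuit rests at −70 mV — no pain. At 25 and 35 kPa the nociceptor
fires at 18 and 23 Hz, and the T-cell output settles just above the −55 mV
pain threshold — pain, with intensity encoded in the firing rate. The depth
sweep shows the complementary attenuation (pain at 1 and 10 mm depth,
none at 50 mm where the stress has decayed to 6.2 kPa):

```sh
skinpain sweep-depth --grid 1,10,50 --q 25 --out sweep_depth
```

Every command also writes a tidy CSV and a JSON sidecar with all resolved
parameters; `skinpain run` handles a single scenario and
`skinpain stress-field` tabulates the elastic stress alone. The same
operations are available as library calls (`skinpain.run_scenario`,
`skinpain.sweep_amplitude`, `skinpain.sweep_depth`).

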