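# Methods

## The classical membrane

The simulator implements the space-clamped squid-axon membrane: a single
isopotential patch with capacitance C and three ionic pathways (Na, K,
leak), each an ohmic conductance times a driving force,

    C dV/dt = J_ext − J_m,   J_m = ḡ_Na m³h (V−E_Na) + ḡ_K n⁴ (V−E_K) + ḡ_L (V−E_L).

Spatial propagation (the axial second-derivative term of the cable
equation) is out of scope: the patch is assumed space-clamped, so that term
is identically zero.

Units are the classical ones — mV, ms, µF/cm², mS/cm², mA/cm² — which makes
the voltage equation `dV/dt = 1000 (J_ext − J_m)/C` (mS/cm² × mV = µA/cm²).
This is the unit system in which the standard stimulus magnitudes behave
canonically: 0.001 mA/cm² is subthreshold, 0.01–0.09 mA/cm² drives
repetitive firing, and 0.2 mA/cm² produces one spike followed by
depolarization block.

Gate kinetics use the classical rate functions of the deviation
`v = V − V_rest` with `V_rest = −65 mV`, scaled by the temperature factor
`φ = 3^((T−6.3)/10)` (Q10 = 3 referenced to the 6.3 °C of the original
measurements).  φ multiplies every α and β equally, so steady states are
temperature-independent while every time constant shrinks by 1/φ.  The two
removable singularities (α_m at v = 25 mV, α_n at v = 10 mV) are evaluated
through a second-order series of x/(eˣ−1) inside a 10⁻⁷ window, avoiding
0/0 without introducing a branch discontinuity.

### Parameter choices

* **Reversal potentials.**  Defaults are E_Na = 50, E_K = −77,
  E_L = −54.4 mV.  These are the classical constants expressed relative to
  a −65 mV rest, and they make −65 mV an actual fixed point of the
  zero-stimulus membrane (root-finding the total ionic current gives
  V* = −64.9997 mV).  Rounded values E_K = −70, E_L = −50 mV are sometimes
  quoted for this model and are available via
  `NeuronParams.printed_variant()`, but with them the membrane is ~4 µA/cm²
  out of balance at −65 mV and the quantitative benchmarks (single-pulse
  peaks, 3/6/9 spike counts) are not reproduced; the canonical values
  reproduce all of them to within ~1–6%.
* **β_m divisor.**  The m-gate closing rate is `4 φ e^(−v/18)` by default
  (the classical 18 mV e-fold).  A 20 mV divisor is selectable through
  `KineticsOptions`; it lowers the clamp-step sodium-conductance peak from
  ~2.23 to ~1.85 mS/cm².
* **Maximal conductances** 120/36/0.3 mS/cm² and C = 1 µF/cm² are the
  classical values.

## The memristive membrane

The MHH variant replaces the two active maximal conductances with the
reciprocal memristance of one flux-controlled memristor per channel:

    g_MNa = m³h / M(φ_Na),   g_MK = n⁴ / M(φ_K)   [S/cm², M in Ω·cm²],

gate kinetics unchanged.  Two modelling elements are not fully determined
by the source material and are therefore explicit configuration:

* **Flux drive.**  The flux of an in-circuit memristor is the time integral
  of the voltage across it; here each flux integrates the deviation from
  rest, `dφ/dt = k (V − V_rest)`, independently per channel (a
  `shared_flux` option drives both channels from one state).  The gain
  defaults to k = 0.1 flux units per mV·ms, calibrated so that the
  memristors traverse their active window on the timescale of a single
  action-potential upstroke — reproducing the reported ~1.0–1.4 ms
  activation times of the memductances under the single-pulse and clamp
  protocols.  Much smaller gains leave the memristances pinned at their
  initial plateau, in which regime the membrane is effectively passive
  (peak memductance ~0.05 mS/cm², far below the ~0.5 mS/cm² needed for a
  regenerative sodium upstroke) and no stimulus of the studied family can
  elicit a spike.
* **Memristance law.**  The printed piecewise law (plateaus 20 000 and
  100 Ω·cm², linear segment −3.98×10⁸ φ + 10⁸ on [−0.75, 0.25)) is
  internally inconsistent: the linear segment spans 10⁸ Ω·cm² and never
  meets the plateaus, and a shared 100 Ω·cm² floor caps the sodium
  memductance at ~3.5 mS/cm² — a level at which the potassium branch
  (whose n⁴ gate sits much higher at rest) dominates and the membrane
  cannot spike at all.  The default `reconstructed_continuous` law keeps
  the 20 000 Ω·cm² plateau (the stated initial memductance 0.5×10⁻⁴
  Ω⁻¹cm⁻² is its reciprocal) and interpolates linearly over the flux window
  [−0.25, 0.25) down to a **per-channel** floor:
  * sodium floor `1/ḡ_Na = 1/0.120 Ω·cm²`, so a fully driven sodium
    memristor recovers the classical maximal sodium conductance (with both
    memristors frozen at `1/ḡ` the MHH right-hand side reduces exactly to
    the HH one — a structural invariant the tests check).  The reported
    peak sodium memductances (≈20–30 mΩ⁻¹cm⁻² across the pulse and clamp
    protocols) independently imply a floor of this order (≈10–20 Ω·cm²),
    two decades below the printed 100.
  * potassium floor 100 Ω·cm², the printed floor, which reproduces the
    reported ≈5.2 mΩ⁻¹cm⁻² peak potassium memductance under the single
    pulse.
  The midpoint of either law is ≈10⁴ Ω·cm², matching the stated initial
  memristance.  The as-printed constants remain selectable
  (`law_variant="as_printed"`) for reference.
* **Initial flux.**  Preset `midpoint` (default): φ₀ = 0, M ≈ 10 000 Ω·cm²
  (the stated initial memristance).  Preset `fig8`: φ₀ at the low edge of
  the flux window, M ≈ 20 000 Ω·cm² (the stated initial memductance).
  Every trace records which was used.

Because the memductances at rest are tiny, the MHH membrane's quiescent
point is set by the leak (near E_L), not by the Na/K balance: with zero
stimulus the voltage drifts slowly upward from −65 mV, the flux integrates
the deviation, and the model eventually fires unprovoked.  This is a real
property of the constructed model (and mirrors the reported observation of
spikes arriving before their pulses in long runs), not an artifact.

## Protocols

Stimuli are declarative (`constant`, `pulse`, `pulse_train`, `sinusoid`,
`none`), evaluated pointwise in time; rectangular windows are half-open.
Conventions chosen where the source protocols are underspecified:

* **Single pulse** onset 0.5 ms (the reported ~1.2–1.4 ms voltage peaks are
  consistent with an early pulse).
* **Pulse train** (18 pulses of 1 mA/cm² over 20 ms): period =
  duration/n_pulses ≈ 1.11 ms, onset 0, width 0.015 ms.  The width sets the
  per-pulse charge: 15 µV·s/cm² ≈ a 15 mV depolarization, just
  suprathreshold from rest at 18.5 °C, the regime in which only pulses
  arriving outside the refractory wake fire (5 classical / 6 memristive
  spikes of the 18).  Widths below ~0.012 ms drop both counts; widths above
  ~0.018 ms let every recovery window fire.
* **Sinusoid** `J = J_m sin(2π t/T_in)` — the input period T_in is a true
  period.
* **Voltage clamp**: an ideal instantaneous step to `V_clamp + V_rest` at
  t = 0 from resting gates, 10 ms window (at which the analytic gate
  relaxation reproduces the ~4.5 mS/cm² potassium-conductance peak).  The
  recorded `J_ext` is the holding current.

## Numerics

* **Integrator**: classical fixed-step RK4, default dt = 0.005 ms.
  Deterministic and bit-reproducible; no adaptive stepping, no randomness
  anywhere.  Initial gates are at the steady state of V_rest, removing
  startup transients.
* **Stimulus edges**: the end stage of each RK4 step samples the stimulus
  with a left bias so a rectangle edge on a grid point belongs to the step
  it starts; edges off the grid cost one locally low-order step (spike
  counts and peak times are robust to this — halving dt moves peak times by
  < 0.01 ms).
* **Accuracy**: against a 100×-finer forward-Euler reference the voltage
  agrees to < 0.1 mV (sup-norm over 5 ms) at dt = 0.005 ms for the HH
  membrane and dt = 0.001 ms for the MHH membrane, whose upstroke is
  steeper and whose memristance law has kinks.  Under clamp the gates match
  their closed-form exponentials to < 10⁻⁶.  The current balance
  `C dV/dt/1000 + J_m = J_ext` holds to < 10⁻⁶ mA/cm² when dV/dt is
  estimated by centered differences on a sufficiently fine grid (the
  stencil error scales as dt²).
* **Divergence**: a non-finite state or numeric overflow during integration
  raises an error naming the time reached.

## Spike detection

A spike is an upward crossing of the threshold followed by the local
maximum of the supra-threshold segment; maxima closer than 1 ms merge.  The
default threshold is −20 mV: under sustained strong drive the later spikes
of a train ride on an elevated baseline and peak between about −1 and
−19 mV, while subthreshold responses stay below about −55 mV, so −20 mV
separates the two cleanly across all studied protocols.  (A 0 mV threshold
would count only the first, full-height spike of such trains.)  "Duration
of a spike" is reported as the mean interspike interval — the reported
values (≈7.7, 3.35, 1.95 ms at 6.3/15/20 °C) match 20 ms divided by the
spike count — with the full-width-at-half-maximum also available.

## What the tests do and do not show

All benchmark inputs are generated programmatically from the protocol
definitions; there is no recorded data anywhere, so agreement with the
reported values demonstrates internal consistency of the model chain
(kinetics → membrane → integrator → analysis) against printed experimental
summaries, not fidelity to new biological recordings.  The MHH comparisons
additionally depend on the documented reconstruction of the memristance
law; quantities that are robust to that reconstruction (spike counts,
ordering of peak times, which model overshoots) should be trusted more than
its exact peak values.  Fine timing values (±0.05 ms) depend on solver and
protocol details that the benchmarks leave unstated.

## Known limitations

* Single isopotential compartment; no cable propagation, no networks.
* Deterministic gating only (no channel noise, no Markov channel models);
  Q10 fixed at 3.
* The memristor is the idealized piecewise-linear flux-controlled element
  described above, not a device-physics model.
* The MHH resting state is metastable by construction (slow flux drift);
  very long unstimulated runs fire spontaneously.
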