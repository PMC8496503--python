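# hhmem

Conductance-based simulation of the squid-axon spiking neuron — the
classical Hodgkin–Huxley (HH) membrane and a memristive variant (MHH) in
which the Na⁺ and K⁺ channel conductances are supplied by flux-controlled
memristors — with stimulus protocols, voltage clamp and spike-train
analysis.  It is aimed at computational neuroscientists and neuromorphic
circuit designers who want a small, deterministic, fully testable reference
implementation of both models.

## The models

The space-clamped membrane obeys

    C dV/dt = J_ext − (J_Na + J_K + J_L),      J_x = g_x (V − E_x)

with `g_Na = ḡ_Na m³h`, `g_K = ḡ_K n⁴`, `g_L = ḡ_L`, and first-order gate
kinetics

    dx/dt = (x_∞(V) − x)/τ_x(V),   x ∈ {m, n, h},

whose transition rates α_x(V), β_x(V) are the classical squid-axon forms in
the deviation `v = V − V_rest` (V_rest = −65 mV), all scaled by a Q10 = 3
temperature factor `φ = 3^((T−6.3)/10)`.  Defaults: C = 1 µF/cm²,
ḡ_Na/ḡ_K/ḡ_L = 120/36/0.3 mS/cm², E_Na/E_K/E_L = 50/−77/−54.4 mV.

In the memristive variant the two active maximal conductances are replaced
by reciprocal memristances,

    g_MNa = m³h / M(φ_Na),    g_MK = n⁴ / M(φ_K),

where each memristance follows a piecewise-linear, non-increasing law
between a 20 000 Ω·cm² plateau (channel nearly shut) and a per-channel
floor, and each flux integrates the voltage deviation from rest,
`dφ/dt = k (V − V_rest)`.  See `docs/methods.md` for the law, its
calibration and its caveats.

## A worked example

```python
from hhmem import NeuronParams, StimulusSpec, run_current_clamp, detect_spikes, spike_stats

stim = StimulusSpec(kind="constant", amplitude=0.08, duration=20.0)  # mA/cm^2, ms
for temperature in (6.3, 15.0, 20.0):
    trace = run_current_clamp("hh", NeuronParams(temperature=temperature), stim=stim)
    m = detect_spikes(trace)
    print(temperature, m.count, spike_stats(m).mean_isi)
```

prints

```
6.3 3 7.960000000000001
15.0 6 3.332
20.0 9 2.185625
```

— the same 0.08 mA/cm² drive fires 3, 6 and 9 action potentials in 20 ms as
the bath warms, with the mean interspike interval shrinking roughly as 1/φ.
The `examples/` directory has one short script per capability (temperature
sweep, voltage clamp with its closed-form cross-check, HH-vs-MHH single
pulse, pulse-train selectivity, sinusoidal drive), each printing the
numbers it computes and what they mean.

A command-line interface mirrors the library:

```bash
hhmem presets                      # list named protocols (fig5a ... fig14e)
hhmem simulate --preset fig11a --out out/   # trace CSV + metrics JSON
hhmem clamp    --preset fig10a --out out/
hhmem analyze  out/fig11a_hh.csv
hhmem compare  out/fig11a_hh.csv out/fig11b_mhh.csv
```

Traces are plain CSV with a JSON metadata header; metrics are JSON;
comparison reports are CSV tables.  Configs are YAML, schema-validated,
with every preset overridable key by key.

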