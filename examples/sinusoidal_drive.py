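"""Spiking patterns under sinusoidal drive of varying period.

A 0.01 mA/cm^2 sinusoid is swept over input periods from 10 us to 60 ms at
18.5 C.  Very fast drives average out before the membrane can depolarize;
slow drives spend long stretches below threshold.  The memristive variant
responds over a wider band of input periods than the classical membrane.
"""

from hhmem import MemristorConfig, NeuronParams, StimulusSpec, detect_spikes, run_current_clamp

params = NeuronParams(temperature=18.5)

print("T_in (ms)   HH spikes   MHH spikes")
for t_in in (0.01, 1.0, 5.0, 20.0, 60.0):
    stim = StimulusSpec(kind="sinusoid", amplitude=0.01, sine_period=t_in,
                        duration=max(20.0, 3.0 * t_in))
    counts = []
    for model in ("hh", "mhh"):
        tr = run_current_clamp(model, params,
                               mem=MemristorConfig() if model == "mhh" else None,
                               stim=stim)
        counts.append(detect_spikes(tr).count)
    print(f"{t_in:9.2f}   {counts[0]:9d}   {counts[1]:10d}")
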