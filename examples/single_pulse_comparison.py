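"""Classical versus memristive response to a single current pulse.

A 0.1 mA/cm^2, 0.1 ms pulse at 18.5 C fires one action potential in both
models.  In the memristive variant the channel conductances are reciprocal
memristances driven by the integrated voltage deviation, so the sodium
pathway unlocks during the upstroke: the spike peaks higher and earlier,
while the potassium memductance stays far below the classical conductance.
"""

from hhmem import (
    MemristorConfig,
    NeuronParams,
    StimulusSpec,
    compare_models,
    run_current_clamp,
)

params = NeuronParams(temperature=18.5)
pulse = StimulusSpec(kind="pulse", amplitude=0.1, onset=0.5, width=0.1, duration=5.0)

hh = run_current_clamp("hh", params, stim=pulse)
mhh = run_current_clamp("mhh", params, mem=MemristorConfig(), stim=pulse)

report = compare_models(hh, mhh)
print(report.to_string(index=False, float_format=lambda x: f"{x:.3f}"))
print()
print("delta = mhh - hh.  The memristive spike peaks ~13 mV higher and")
print("~0.2 ms earlier; its potassium branch passes less current, which is")
print("what lets the voltage overshoot further.")
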