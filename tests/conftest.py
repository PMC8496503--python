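import pytest

from hhmem import (
    MemristorConfig,
    NeuronParams,
    StimulusSpec,
    run_current_clamp,
)

SINGLE_PULSE = StimulusSpec(kind="pulse", amplitude=0.1, onset=0.5, width=0.1, duration=5.0)
REVERSE_PULSE = StimulusSpec(kind="pulse", amplitude=-0.1, onset=0.5, width=0.1, duration=5.0)


@pytest.fixture(scope="session")
def warm_params():
    """Membrane at the warm experimental temperature used for the pulse protocols."""
    return NeuronParams(temperature=18.5)


@pytest.fixture(scope="session")
def hh_pulse_trace(warm_params):
    """HH response to a single 0.1 mA/cm^2, 0.1 ms pulse at 18.5 C."""
    return run_current_clamp("hh", warm_params, stim=SINGLE_PULSE)


@pytest.fixture(scope="session")
def mhh_pulse_trace(warm_params):
    """MHH response to the same pulse, default memristor configuration."""
    return run_current_clamp("mhh", warm_params, mem=MemristorConfig(), stim=SINGLE_PULSE)
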