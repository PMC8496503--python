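"""Experiment configuration: a validated, serializable description of one
simulation run (model variant, membrane parameters, memristor law, stimulus
or clamp protocol, step size) plus a registry of named presets encoding the
standard comparison experiments.

Configs are YAML/JSON mappings validated by pydantic with unknown keys
rejected, so every run is fully reproducible from its echoed config.
"""

from __future__ import annotations

from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError, model_validator

from .kinetics import KineticsOptions
from .membrane import MemristorConfig, NeuronParams
from .simulate import Trace, run_current_clamp, run_voltage_clamp
from .stimulus import ClampSpec, StimulusSpec

__all__ = ["ExperimentConfig", "ConfigError", "load_config", "get_preset", "preset_names", "PRESETS"]


class ConfigError(ValueError):
    """Invalid experiment configuration."""


class _Model(BaseModel):
    model_config = ConfigDict(extra="forbid")


class NeuronParamsModel(_Model):
    C: float = 1.0
    E_Na: float = 50.0
    E_K: float = -77.0
    E_L: float = -54.4
    g_Na_max: float = 120.0
    g_K_max: float = 36.0
    g_L_max: float = 0.3
    v_rest: float = -65.0


class MemristorModel(_Model):
    law_variant: Literal["reconstructed_continuous", "as_printed"] = "reconstructed_continuous"
    M_high: float = 20000.0
    M_low_na: float = 1.0 / 0.120
    M_low_k: float = 100.0
    flux_lo: float = -0.25
    flux_hi: float = 0.25
    flux_gain: float = 0.1
    flux_init: Literal["midpoint", "fig8"] = "midpoint"
    shared_flux: bool = False


class StimulusModel(_Model):
    kind: Literal["constant", "pulse", "pulse_train", "sinusoid", "none"] = "none"
    amplitude: float = 0.0
    onset: float = 0.0
    width: Optional[float] = None
    n_pulses: int = 1
    period: Optional[float] = None
    sine_period: Optional[float] = None
    duration: float = Field(20.0, gt=0)


class ClampModel(_Model):
    V_clamp: float
    duration: float = Field(10.0, gt=0)


class ExperimentConfig(_Model):
    """One experiment: which model(s) to run, under which protocol."""

    name: str = "custom"
    model: Literal["hh", "mhh", "both"] = "hh"
    temperature: float = 6.3
    beta_m_divisor: float = 18.0
    params: NeuronParamsModel = NeuronParamsModel()
    memristor: MemristorModel = MemristorModel()
    stimulus: Optional[StimulusModel] = None
    clamp: Optional[ClampModel] = None
    dt: float = Field(0.005, gt=0)
    spike_threshold: float = -20.0
    min_separation: float = 1.0

    @model_validator(mode="after")
    def _one_protocol(self) -> "ExperimentConfig":
        if (self.stimulus is None) == (self.clamp is None):
            raise ValueError("exactly one of 'stimulus' or 'clamp' must be given")
        return self

    # -- conversion to the domain dataclasses ------------------------------
    def neuron_params(self) -> NeuronParams:
        return NeuronParams(temperature=self.temperature, **self.params.model_dump())

    def kinetics_options(self) -> KineticsOptions:
        return KineticsOptions(
            temperature=self.temperature,
            v_rest=self.params.v_rest,
            beta_m_divisor=self.beta_m_divisor,
        )

    def memristor_config(self) -> MemristorConfig:
        return MemristorConfig(**self.memristor.model_dump())

    def stimulus_spec(self) -> StimulusSpec | None:
        return None if self.stimulus is None else StimulusSpec(**self.stimulus.model_dump())

    def clamp_spec(self) -> ClampSpec | None:
        return None if self.clamp is None else ClampSpec(**self.clamp.model_dump())

    def run(self) -> dict[str, Trace]:
        """Execute the experiment; returns one trace per model variant."""
        models = ("hh", "mhh") if self.model == "both" else (self.model,)
        out: dict[str, Trace] = {}
        for m in models:
            kwargs = dict(
                params=self.neuron_params(),
                mem=self.memristor_config() if m == "mhh" else None,
                dt=self.dt,
                options=self.kinetics_options(),
            )
            if self.stimulus is not None:
                out[m] = run_current_clamp(m, stim=self.stimulus_spec(), **kwargs)
            else:
                out[m] = run_voltage_clamp(m, clamp=self.clamp_spec(), **kwargs)
            out[m].metadata["experiment"] = self.name
        return out


def load_config(path: str | Path) -> ExperimentConfig:
    """Load and validate a YAML (or JSON) experiment config.

    A mapping containing ``preset: <name>`` starts from that preset's
    definition; any further keys override it.  Unknown keys anywhere are
    rejected with the offending key named in the error.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError(f"config root must be a mapping, got {type(raw).__name__}")
    return config_from_dict(raw)


def config_from_dict(raw: dict) -> ExperimentConfig:
    raw = dict(raw)
    preset_name = raw.pop("preset", None)
    try:
        if preset_name is not None:
            base = get_preset(preset_name).model_dump()
            _deep_update(base, raw)
            return ExperimentConfig(**base)
        return ExperimentConfig(**raw)
    except ValidationError as exc:
        offending = ", ".join(
            "->".join(str(loc) for loc in err["loc"]) or "<root>" for err in exc.errors()
        )
        raise ConfigError(f"invalid config (offending keys: {offending}): {exc}") from exc


def _deep_update(base: dict, upd: dict) -> None:
    for k, v in upd.items():
        if isinstance(v, dict) and isinstance(base.get(k), dict):
            _deep_update(base[k], v)
        else:
            base[k] = v


# ---------------------------------------------------------------------------
# Presets: the standard experiments, named after the figures they reproduce.
# ---------------------------------------------------------------------------

def _c(name: str, **kw) -> ExperimentConfig:
    return ExperimentConfig(name=name, **kw)


def _const(amplitude: float, duration: float = 20.0, width: float | None = None) -> dict:
    return dict(kind="constant", amplitude=amplitude, duration=duration, width=width)


_TRAIN_WIDTH = 0.015  # ms; ~15 mV depolarization per pulse, just suprathreshold


def _train(duration: float, n_pulses: int, amplitude: float = 1.0) -> dict:
    return dict(
        kind="pulse_train",
        amplitude=amplitude,
        n_pulses=n_pulses,
        period=duration / n_pulses,
        width=_TRAIN_WIDTH,
        duration=duration,
    )


def _pulse(amplitude: float, duration: float = 5.0) -> dict:
    return dict(kind="pulse", amplitude=amplitude, onset=0.5, width=0.1, duration=duration)


def _build_presets() -> dict[str, ExperimentConfig]:
    p: dict[str, ExperimentConfig] = {}
    # firing vs temperature, constant 0.08 mA/cm^2 for 20 ms
    for tag, temp in [("a", 6.3), ("b", 15.0), ("c", 20.0), ("d", 35.0), ("e", -20.0)]:
        p[f"fig5{tag}"] = _c(f"fig5{tag}", model="hh", temperature=temp,
                             stimulus=StimulusModel(**_const(0.08)))
    # firing vs stimulus intensity
    for tag, amp in [("a", 0.001), ("b", 0.01), ("c", 0.09), ("d", 0.2)]:
        p[f"fig6{tag}"] = _c(f"fig6{tag}", model="hh", temperature=18.5,
                             stimulus=StimulusModel(**_const(amp)))
    # firing vs stimulus action time (constant 0.08, window = action time)
    for tag, at in [("a", 1.0), ("b", 10.0), ("c", 20.0), ("d", 50.0)]:
        p[f"fig7{tag}"] = _c(f"fig7{tag}", model="hh", temperature=6.3,
                             stimulus=StimulusModel(**_const(0.08, duration=at + 10.0, width=at)))
    # memductance evolution under constant drive
    p["fig8"] = _c("fig8", model="mhh", temperature=6.3,
                   memristor=MemristorModel(flux_init="fig8"),
                   stimulus=StimulusModel(**_const(0.08)))
    # voltage clamp
    for tag, model, vc in [("a", "hh", 20.0), ("b", "mhh", 20.0),
                           ("c", "hh", 80.0), ("d", "mhh", 80.0)]:
        p[f"fig10{tag}"] = _c(f"fig10{tag}", model=model, temperature=6.3,
                              clamp=ClampModel(V_clamp=vc, duration=10.0))
    # single forward / reverse pulse
    p["fig11a"] = _c("fig11a", model="hh", temperature=18.5, stimulus=StimulusModel(**_pulse(0.1)))
    p["fig11b"] = _c("fig11b", model="mhh", temperature=18.5, stimulus=StimulusModel(**_pulse(0.1)))
    p["fig11c"] = _c("fig11c", model="hh", temperature=18.5, stimulus=StimulusModel(**_pulse(-0.1)))
    p["fig11d"] = _c("fig11d", model="mhh", temperature=18.5, stimulus=StimulusModel(**_pulse(-0.1)))
    # three intensities
    for tag, amp in [("1", 0.5), ("2", 1.0), ("3", 2.0)]:
        p[f"fig12a{tag}"] = _c(f"fig12a{tag}", model="hh", temperature=18.5,
                               stimulus=StimulusModel(**_pulse(amp)))
        p[f"fig12b{tag}"] = _c(f"fig12b{tag}", model="mhh", temperature=18.5,
                               stimulus=StimulusModel(**_pulse(amp)))
    # pulse trains (1 mA/cm^2 pulses at 0.9 pulses/ms)
    for tag, model, dur, n in [("a", "hh", 20.0, 18), ("b", "mhh", 20.0, 18),
                               ("c", "hh", 100.0, 90), ("d", "mhh", 100.0, 90),
                               ("e", "hh", 200.0, 180), ("f", "mhh", 200.0, 180)]:
        p[f"fig13{tag}"] = _c(f"fig13{tag}", model=model, temperature=18.5,
                              stimulus=StimulusModel(**_train(dur, n)))
    # sinusoidal drive
    for tag, t_in in [("a", 0.01), ("b", 1.0), ("c", 5.0), ("d", 20.0), ("e", 60.0)]:
        p[f"fig14{tag}"] = _c(f"fig14{tag}", model="both", temperature=18.5,
                              stimulus=StimulusModel(kind="sinusoid", amplitude=0.01,
                                                     sine_period=t_in,
                                                     duration=max(20.0, 3.0 * t_in)))
    return p


PRESETS: dict[str, ExperimentConfig] = _build_presets()


def preset_names() -> list[str]:
    return sorted(PRESETS)


def get_preset(name: str) -> ExperimentConfig:
    try:
        return PRESETS[name].model_copy(deep=True)
    except KeyError:
        raise ConfigError(
            f"unknown preset {name!r}; available: {', '.join(preset_names())}"
        ) from None
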