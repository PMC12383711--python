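"""Configuration containers for the decoding pipeline.

Every tunable parameter of the pipeline lives in one of the frozen-default
dataclasses below and can be overridden from a YAML file.  Defaults follow
the recording set-up the pipeline targets (64-channel ECoG at 586 Hz,
59-sample ~100 ms blocks) and textbook values for the neuron and reservoir
models where the application itself does not pin them down.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml


@dataclass
class SignalConfig:
    """Acquisition-side constants: sampling, blocking, band-pass."""

    sample_rate: float = 586.0       # Hz
    n_channels: int = 64
    block_len: int = 59              # samples per streamed block (~100 ms)
    band_low_hz: float = 0.5
    band_high_hz: float = 300.0
    filter_order: int = 4            # Butterworth order (applied zero-phase)

    @property
    def block_duration_s(self) -> float:
        return self.block_len / self.sample_rate


@dataclass
class FeatureConfig:
    """Morlet wavelet bank and area-under-curve combination."""

    central_freqs: tuple = tuple(float(f) for f in range(10, 151, 10))
    wavelet_cycles: float = 7.0      # Gaussian envelope width in cycles
    auc_domain: str = "hz"           # "hz" | "index": trapezoid abscissa
    coeff_kind: str = "magnitude"    # "magnitude" | "power"
    kernel_sigmas: float = 3.0       # kernel truncation, in envelope sigmas


@dataclass
class SnnConfig:
    """LIF neuron, synapse and STDP parameters of the 3D spiking cube.

    Membrane constants are standard cortical-neuron textbook values; the
    feature-to-current gain is not set here but calibrated from data so the
    cube fires near ``target_rate_hz`` for median-strength features.
    """

    tau_m_ms: float = 20.0
    v_rest_mv: float = -65.0
    v_th_mv: float = -50.0
    v_reset_mv: float = -65.0
    t_ref_ms: float = 2.0
    r_m_mohm: float = 10.0           # membrane resistance, MOhm (I in nA)
    dt_ms: float = 0.1

    # synapses
    w0: float = 0.5                  # distance-kernel weight scale
    w_max: float = 1.0
    p_exc: float = 0.8               # fraction of excitatory (Dale) neurons
    distance_kernel: str = "exp_decay"  # or "linear_proportional"
    tau_syn_ms: float = 5.0
    syn_gain_na: float = 0.02        # post-synaptic current per unit weight

    # STDP (nearest-neighbour, additive, sign-preserving).  Amplitudes are
    # kept small so recurrent potentiation cannot run away and the weight
    # drift per session stays in the few-percent range.
    a_plus: float = 1e-4
    a_minus: float = 1.2e-4
    tau_plus_ms: float = 20.0
    tau_minus_ms: float = 20.0
    stdp_on: bool = True

    # feature drive
    target_rate_hz: float = 20.0     # calibration target for median feature


@dataclass
class EsnConfig:
    """Echo state network reservoir and RLS readout parameters."""

    n_reservoir: int = 500
    rho: float = 0.9                 # spectral radius after scaling
    leak: float = 0.3
    density: float = 0.1
    input_scale: float = 0.5
    lam: float = 1.0                 # RLS forgetting factor (1 = plain RLS)
    delta: float = 1e-2              # P(0) = I / delta


@dataclass
class PipelineConfig:
    signal: SignalConfig = field(default_factory=SignalConfig)
    features: FeatureConfig = field(default_factory=FeatureConfig)
    snn: SnnConfig = field(default_factory=SnnConfig)
    esn: EsnConfig = field(default_factory=EsnConfig)
    feedback_threshold: float = 0.0  # NRD score below which MCD output flips
    # weight of the NRD's single action-context input relative to the 64
    # rate inputs; without it the context channel is drowned out
    nrd_action_gain: float = 6.0


def _update(obj, data: dict):
    for key, value in data.items():
        if not hasattr(obj, key):
            raise KeyError(f"unknown config key: {key!r}")
        current = getattr(obj, key)
        if dataclasses.is_dataclass(current):
            _update(current, value)
        else:
            if isinstance(current, tuple) and isinstance(value, list):
                value = tuple(value)
            setattr(obj, key, value)


def load_config(path: str | Path | None = None) -> PipelineConfig:
    """Build a :class:`PipelineConfig`, optionally overridden from YAML."""
    cfg = PipelineConfig()
    if path is not None:
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        _update(cfg, data)
    return cfg


def save_config(cfg: PipelineConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(dataclasses.asdict(cfg), fh, sort_keys=False)
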