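"""Synthetic labeled ECoG sessions.

The clinical recordings the decoder was designed around are not publicly
available, so this module generates sessions with the same structure: 64
channels at 586 Hz, ~11 minutes each, an alternating idle/walk cue
schedule, and a per-block satisfaction label.  The signal model is a
standard sensorimotor ECoG motif rather than a biophysical simulation:

* 1/f^alpha pink background noise on every channel (alpha = 1), scaled so
  the signal amplitude is of the order of a few hundred microvolts
  peak-to-peak;
* beta (20-30 Hz) and high-gamma (70-90 Hz) band-limited components on all
  channels; on a designated set of 16 "motor-strip" channels the executed
  walk state raises high-gamma amplitude by 50% and lowers beta amplitude
  by 30%.

The *executed* state drives the signal; the *cue* defines the desired
action label.  With probability ``p_err`` a whole cue segment is executed
wrongly (fatigue/distraction episodes), making every block of that segment
non-satisfactory (SATIS = 0).  SATIS is therefore the deterministic
indicator executed == cue.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import signal as sp_signal

from .io import BLOCK_LEN, LabelStream, SessionRecord, write_edf

__all__ = ["SynthConfig", "generate_session", "write_session",
           "generate_database", "validate_separability"]


@dataclass
class SynthConfig:
    n_sessions: int = 9
    session_minutes: float = 11.0
    n_channels: int = 64
    sample_rate: float = 586.0
    mean_segment_s: float = 10.0        # mean idle/walk cue segment length
    p_err: float = 0.15                 # per-segment execution error rate

    # background noise
    noise_alpha: float = 1.0            # 1/f^alpha exponent
    noise_std_uv: float = 40.0

    # band-limited components (base amplitude on every channel)
    beta_band_hz: tuple = (20.0, 30.0)
    beta_std_uv: float = 12.0
    beta_walk_factor: float = 0.7       # walk lowers beta by 30%
    gamma_band_hz: tuple = (70.0, 90.0)
    gamma_std_uv: float = 8.0
    gamma_walk_factor: float = 1.5      # walk raises high-gamma by 50%
    motor_channels: tuple = tuple(range(24, 40))

    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.p_err <= 1.0:
            raise ValueError("p_err must lie in [0, 1]")
        nyq = self.sample_rate / 2.0
        for band in (self.beta_band_hz, self.gamma_band_hz):
            if not (0.5 < band[0] < band[1] < 0.95 * nyq):
                raise ValueError(f"band {band} outside (0.5, "
                                 f"{0.95 * nyq:g}) Hz")
        if self.mean_segment_s * self.sample_rate < BLOCK_LEN:
            raise ValueError("segments must be longer than one block")

    @property
    def n_blocks(self) -> int:
        return int(self.session_minutes * 60 * self.sample_rate) // BLOCK_LEN


def _pink_noise(rng: np.random.Generator, n: int, alpha: float
                ) -> np.ndarray:
    """Gaussian 1/f^alpha noise of length n, unit variance."""
    freqs = np.fft.rfftfreq(n)
    shaping = np.zeros_like(freqs)
    shaping[1:] = freqs[1:] ** (-alpha / 2.0)
    spec = (rng.normal(size=len(freqs)) + 1j * rng.normal(size=len(freqs)))
    spec *= shaping
    x = np.fft.irfft(spec, n)
    return x / x.std()


def _band_noise(rng: np.random.Generator, n: int, band, fs: float
                ) -> np.ndarray:
    """Band-limited Gaussian noise, unit variance."""
    sos = sp_signal.butter(4, band, btype="bandpass", fs=fs, output="sos")
    x = sp_signal.sosfilt(sos, rng.normal(size=n + 1000))[1000:]
    return x / x.std()


def _draw_schedule(rng: np.random.Generator, cfg: SynthConfig):
    """Alternating idle/walk cue segments in whole blocks.

    Segment durations are uniform on [0.5, 1.5] x mean; each segment's
    executed state flips from the cue with probability p_err.
    """
    mean_blocks = cfg.mean_segment_s * cfg.sample_rate / BLOCK_LEN
    cues, executed, bounds = [], [], []
    pos, state = 0, "idle"
    while pos < cfg.n_blocks:
        length = max(1, int(round(rng.uniform(0.5, 1.5) * mean_blocks)))
        length = min(length, cfg.n_blocks - pos)
        exe = state
        if rng.random() < cfg.p_err:
            exe = "walk" if state == "idle" else "idle"
        cues.append(state)
        executed.append(exe)
        bounds.append((pos, pos + length))
        pos += length
        state = "walk" if state == "idle" else "idle"
    return cues, executed, bounds


def generate_session(cfg: SynthConfig, session_index: int = 0
                     ) -> tuple:
    """One synthetic (SessionRecord, LabelStream) pair.

    Deterministic for a fixed (cfg.seed, session_index) pair.
    """
    rng = np.random.default_rng([cfg.seed, session_index])
    # full session duration (not trimmed to whole blocks), so the EDF
    # writer's whole-record constraint is met for whole/half minutes;
    # the trailing partial block carries the last segment's state
    n_samples = int(round(cfg.session_minutes * 60 * cfg.sample_rate))
    cues, executed, bounds = _draw_schedule(rng, cfg)

    # walk-state envelope per sample, from executed segments
    walk_env = np.zeros(n_samples, dtype=bool)
    for exe, (b0, b1) in zip(executed, bounds):
        if exe == "walk":
            hi = n_samples if b1 >= cfg.n_blocks else b1 * BLOCK_LEN
            walk_env[b0 * BLOCK_LEN:hi] = True

    motor = np.zeros(cfg.n_channels, dtype=bool)
    motor[list(cfg.motor_channels)] = True
    samples = np.empty((n_samples, cfg.n_channels))
    for ch in range(cfg.n_channels):
        x = cfg.noise_std_uv * _pink_noise(rng, n_samples, cfg.noise_alpha)
        beta = _band_noise(rng, n_samples, cfg.beta_band_hz, cfg.sample_rate)
        gamma = _band_noise(rng, n_samples, cfg.gamma_band_hz,
                            cfg.sample_rate)
        beta_amp = np.full(n_samples, cfg.beta_std_uv)
        gamma_amp = np.full(n_samples, cfg.gamma_std_uv)
        if motor[ch]:
            beta_amp[walk_env] *= cfg.beta_walk_factor
            gamma_amp[walk_env] *= cfg.gamma_walk_factor
        samples[:, ch] = x + beta_amp * beta + gamma_amp * gamma

    action = np.empty(cfg.n_blocks, dtype=object)
    satis = np.empty(cfg.n_blocks, dtype=int)
    for cue, exe, (b0, b1) in zip(cues, executed, bounds):
        action[b0:b1] = cue
        satis[b0:b1] = 1 if exe == cue else 0
    record = SessionRecord(samples=samples, sample_rate=cfg.sample_rate,
                           session_id=session_index)
    return record, LabelStream(action, satis)


def write_session(record: SessionRecord, labels: LabelStream,
                  edf_path: str | Path, beh_path: str | Path) -> None:
    """Write a session as an EDF/behaviour-CSV file pair.

    The EDF encoder trims to whole data records; whole-minute sessions at
    586 Hz divide evenly, so nothing is lost for generated sessions.
    """
    import pandas as pd
    written = write_edf(edf_path, record.samples, record.sample_rate,
                        list(record.channel_ids))
    n_blocks = written // BLOCK_LEN
    if n_blocks != len(labels):
        raise ValueError(f"EDF trimming changed the block count "
                         f"({n_blocks} vs {len(labels)} labels); use a "
                         f"whole-minute session length")
    pd.DataFrame({
        "block": np.arange(len(labels)),
        "action": labels.action_desired,
        "satis": labels.satis,
    }).to_csv(beh_path, index=False)


def generate_database(cfg: SynthConfig, out_dir: str | Path) -> list:
    """Generate and write cfg.n_sessions sessions plus a manifest;
    returns the (edf, behaviour) file pairs."""
    import dataclasses
    import json
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    pairs = []
    for s in range(cfg.n_sessions):
        record, labels = generate_session(cfg, s)
        edf = out_dir / f"session_{s + 1:02d}.edf"
        beh = out_dir / f"session_{s + 1:02d}_beh.csv"
        write_session(record, labels, edf, beh)
        pairs.append((edf, beh))
    manifest = {"config": dataclasses.asdict(cfg),
                "sessions": [[p[0].name, p[1].name] for p in pairs]}
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return pairs


def validate_separability(record: SessionRecord, labels: LabelStream,
                          cfg: SynthConfig) -> dict:
    """Quality gate: walk vs idle band power on the modulated band.

    Computes Welch power in the high-gamma band during executed-walk and
    executed-idle blocks per channel and reports the power ratio plus a
    log-power effect size.  Uses the satisfaction label to recover the
    executed state from the cue.
    """
    cue = labels.action_desired
    executed = np.where(labels.satis == 1, cue,
                        np.where(cue == "idle", "walk", "idle"))
    fs = record.sample_rate
    band = cfg.gamma_band_hz

    def band_power(blocks_mask):
        idx = np.flatnonzero(blocks_mask)
        segs = [record.samples[k * BLOCK_LEN:(k + 1) * BLOCK_LEN]
                for k in idx]
        data = np.concatenate(segs, axis=0)
        freqs, psd = sp_signal.welch(data, fs=fs, nperseg=min(512,
                                                             len(data)),
                                     axis=0)
        sel = (freqs >= band[0]) & (freqs <= band[1])
        return psd[sel].mean(axis=0)

    p_walk = band_power(executed == "walk")
    p_idle = band_power(executed == "idle")
    ratio = p_walk / p_idle
    effect = np.log(ratio)
    motor = np.zeros(record.n_channels, dtype=bool)
    motor[list(cfg.motor_channels)] = True
    return {
        "band_hz": band,
        "power_ratio": ratio,
        "log_effect": effect,
        "motor_channels": motor,
        "mean_ratio_motor": float(ratio[motor].mean()),
        "mean_ratio_other": float(ratio[~motor].mean()),
    }
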