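"""Actor-critic decoding: training approaches, testing experiments,
corrective feedback and the pseudo-online session loop.

The motor-control decoder (MCD, actor) maps the spiking cube's firing
rates to an action (idle/walk); the neural-response decoder (NRD, critic)
maps the rates plus an action input to a satisfaction prediction.  Both
are echo state networks whose readouts are trained online by RLS.

Four training approaches differ in two choices:

* whether the MCD target is always the desired action (TA1, TA3) or the
  desired action reverted whenever the block is labeled non-satisfactory
  (TA2, TA4);
* whether the NRD's action input is the desired action (TA1; reverted on
  SATIS=0 in TA2) or the MCD's own prediction (TA3; reverted on SATIS=0 in
  TA4).

Three testing experiments feed the NRD with the desired action (TE1) or
the MCD prediction (TE2); TE3 is the TE2 protocol applied to TA3/TA4
trained models.  Optionally the NRD's continuous output gates a corrective
flip of the MCD's action (feedback).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import esn as esn_mod
from . import features as feat_mod
from . import io as io_mod
from . import snn as snn_mod
from .config import PipelineConfig

__all__ = ["Codec", "BlockResult", "ModelBundle", "revert", "mcd_target",
           "nrd_action_input", "train_block", "test_block",
           "apply_feedback", "build_bundle", "run_session", "save_bundle",
           "load_bundle", "TRAIN_APPROACHES", "TEST_EXPERIMENTS"]

TRAIN_APPROACHES = ("TA1", "TA2", "TA3", "TA4")
TEST_EXPERIMENTS = ("TE1", "TE2", "TE3")


@dataclass
class Codec:
    """Numeric encoding of the label alphabets and decision thresholds.

    idle/walk and SATIS=0/1 are encoded as -1/+1; both decisions threshold
    the continuous readout at 0 (>= 0 maps to walk / SATIS=1).
    """

    action_threshold: float = 0.0
    satis_threshold: float = 0.0

    def encode_action(self, action: str) -> float:
        if action == "idle":
            return -1.0
        if action == "walk":
            return 1.0
        raise ValueError(f"unknown action {action!r}")

    def decode_action(self, y: float) -> str:
        return "walk" if y >= self.action_threshold else "idle"

    def encode_satis(self, satis: int) -> float:
        if satis in (0, 1):
            return 2.0 * satis - 1.0
        raise ValueError(f"unknown satis label {satis!r}")

    def decode_satis(self, y: float) -> int:
        return 1 if y >= self.satis_threshold else 0


@dataclass
class BlockResult:
    block_index: int
    action_desired: str | None
    satis_label: int | None
    action_predicted: str
    satis_predicted: int
    y_mcd: float
    y_nrd: float
    mcd_error: float | None = None   # prediction - target (training only)
    nrd_error: float | None = None
    action_after_feedback: str | None = None
    feedback_applied: bool = False   # True when the NRD gated the action


def revert(action: str) -> str:
    """Swap idle <-> walk."""
    if action == "idle":
        return "walk"
    if action == "walk":
        return "idle"
    raise ValueError(f"unknown action {action!r}")


def mcd_target(action_desired: str, satis: int, approach: str) -> str:
    """MCD training target for one block.

    TA1/TA3 always use the desired action; TA2/TA4 revert it when the
    block is labeled non-satisfactory.
    """
    if approach not in TRAIN_APPROACHES:
        raise ValueError(f"unknown training approach {approach!r}")
    if approach in ("TA1", "TA3"):
        return action_desired
    return action_desired if satis == 1 else revert(action_desired)


def nrd_action_input(action_desired: str | None,
                     action_predicted: str | None,
                     satis: int | None, mode: str) -> str:
    """Action fed to the NRD alongside the ECoG features.

    TA1/TE1: desired action; TA2: desired action, reverted on SATIS=0;
    TA3/TE2/TE3: predicted action; TA4: predicted action, reverted on
    SATIS=0.
    """
    if mode in ("TA1", "TE1"):
        return action_desired
    if mode == "TA2":
        return action_desired if satis == 1 else revert(action_desired)
    if mode in ("TA3", "TE2", "TE3"):
        return action_predicted
    if mode == "TA4":
        return action_predicted if satis == 1 else revert(action_predicted)
    raise ValueError(f"unknown mode {mode!r}")


def apply_feedback(action_predicted: str, y_nrd: float,
                   threshold: float = 0.0) -> str:
    """Corrective feedback: flip the MCD action when the NRD's continuous
    output falls below the satisfaction threshold; ties keep the action."""
    if y_nrd < threshold:
        return revert(action_predicted)
    return action_predicted


@dataclass
class ModelBundle:
    """Everything that persists across blocks and sessions."""

    cube: snn_mod.CubeState
    mcd: esn_mod.EsnState
    nrd: esn_mod.EsnState
    bank: feat_mod.WaveletBank
    codec: Codec = field(default_factory=Codec)
    cfg: PipelineConfig = field(default_factory=PipelineConfig)
    calibrated: bool = False
    provenance: dict = field(default_factory=dict)

    @property
    def rate_norm(self) -> float:
        """Calibration target rate used to normalise reservoir inputs."""
        return self.cube.params.target_rate_hz

    def encode_rates(self, rates: np.ndarray) -> np.ndarray:
        """Centre and scale firing rates for the reservoirs.

        Rates are centred at the calibration target so the reservoir input
        is O(1) around zero; an uncentred rate vector would bias every
        tanh unit toward saturation.
        """
        r = np.asarray(rates, dtype=float)
        return (r - self.rate_norm) / self.rate_norm


def build_bundle(cfg: PipelineConfig | None = None, seed: int = 0,
                 coords: np.ndarray | None = None) -> ModelBundle:
    cfg = cfg or PipelineConfig()
    n_ch = cfg.signal.n_channels
    cube = snn_mod.build_cube(coords, seed=seed, params=cfg.snn)
    if cube.n != n_ch:
        raise ValueError(f"cube size {cube.n} != channel count {n_ch}")
    e = cfg.esn
    mcd = esn_mod.init_esn(e.n_reservoir, n_ch, e.rho, e.leak, e.density,
                           e.input_scale, seed=seed + 1, lam=e.lam,
                           delta=e.delta)
    nrd = esn_mod.init_esn(e.n_reservoir, n_ch + 1, e.rho, e.leak,
                           e.density, e.input_scale, seed=seed + 2,
                           lam=e.lam, delta=e.delta)
    bank = feat_mod.WaveletBank.from_config(cfg.features,
                                            cfg.signal.sample_rate,
                                            cfg.signal.block_len)
    return ModelBundle(cube=cube, mcd=mcd, nrd=nrd, bank=bank, cfg=cfg)


def train_block(bundle: ModelBundle, rates: np.ndarray, action_desired: str,
                satis: int, approach: str, block_index: int = 0
                ) -> BlockResult:
    """One training step of both decoders on one block's firing rates.

    The MCD reservoir is updated and its readout trained first (against the
    approach-dependent target); the NRD then receives the rates plus its
    action input and is trained against the satisfaction label.
    """
    if approach not in TRAIN_APPROACHES:
        raise ValueError(f"unknown training approach {approach!r}")
    if action_desired is None or satis is None:
        raise ValueError("training requires both behaviour labels")
    codec = bundle.codec
    u = bundle.encode_rates(rates)

    esn_mod.esn_update(bundle.mcd, u)
    y_mcd = esn_mod.readout(bundle.mcd)
    action_predicted = codec.decode_action(y_mcd)
    target = codec.encode_action(mcd_target(action_desired, satis, approach))
    _, e_prior = esn_mod.rls_step(bundle.mcd, target)
    mcd_error = -e_prior                      # prediction - target

    a_in = nrd_action_input(action_desired, action_predicted, satis,
                            approach)
    u_nrd = np.concatenate(
        [u, [bundle.cfg.nrd_action_gain * codec.encode_action(a_in)]])
    esn_mod.esn_update(bundle.nrd, u_nrd)
    y_nrd = esn_mod.readout(bundle.nrd)
    satis_predicted = codec.decode_satis(y_nrd)
    _, e_prior_n = esn_mod.rls_step(bundle.nrd, codec.encode_satis(satis))
    nrd_error = -e_prior_n

    return BlockResult(block_index, action_desired, satis, action_predicted,
                       satis_predicted, y_mcd, y_nrd, mcd_error, nrd_error)


def test_block(bundle: ModelBundle, rates: np.ndarray,
               action_desired: str | None, experiment: str,
               feedback_on: bool = False, satis_label: int | None = None,
               block_index: int = 0) -> BlockResult:
    """One testing step: reservoirs evolve, readouts are frozen.

    TE1 feeds the NRD the desired action (and therefore requires it);
    TE2/TE3 feed the MCD's prediction.  With ``feedback_on`` the NRD's
    continuous output gates a corrective flip of the MCD action.
    """
    if experiment not in TEST_EXPERIMENTS:
        raise ValueError(f"unknown testing experiment {experiment!r}")
    if experiment == "TE1" and action_desired is None:
        raise ValueError("TE1 requires the desired action from the DB")
    codec = bundle.codec
    u = bundle.encode_rates(rates)

    esn_mod.esn_update(bundle.mcd, u)
    y_mcd = esn_mod.readout(bundle.mcd)
    action_predicted = codec.decode_action(y_mcd)

    a_in = nrd_action_input(action_desired, action_predicted, None,
                            experiment)
    u_nrd = np.concatenate(
        [u, [bundle.cfg.nrd_action_gain * codec.encode_action(a_in)]])
    esn_mod.esn_update(bundle.nrd, u_nrd)
    y_nrd = esn_mod.readout(bundle.nrd)
    satis_predicted = codec.decode_satis(y_nrd)

    if feedback_on:
        after = apply_feedback(action_predicted, y_nrd,
                               bundle.cfg.feedback_threshold)
    else:
        after = action_predicted
    return BlockResult(block_index, action_desired, satis_label,
                       action_predicted, satis_predicted, y_mcd, y_nrd,
                       action_after_feedback=after,
                       feedback_applied=feedback_on)


def run_session(bundle: ModelBundle, record: io_mod.SessionRecord,
                labels: io_mod.LabelStream | None, mode: str,
                feedback_on: bool = False, stdp: bool | None = None,
                preprocessed: bool = False) -> list:
    """Stream one session through features -> cube -> decoders.

    ``mode`` is a training approach (TA1..TA4) or testing experiment
    (TE1..TE3).  Reservoir states reset at the session boundary; the cube's
    membrane state and plastic weights carry over from previous sessions.
    On the first training call the feature-to-current gain is calibrated
    from this session's early blocks.  ``stdp`` overrides the configured
    plasticity switch for this session (testing keeps STDP on by default).
    """
    training = mode in TRAIN_APPROACHES
    if not training and mode not in TEST_EXPERIMENTS:
        raise ValueError(f"unknown mode {mode!r}")
    if training and labels is None:
        raise ValueError("training requires behaviour labels")
    if labels is not None and len(labels) != record.n_blocks:
        raise ValueError(f"label/block misalignment: {len(labels)} labels "
                         f"vs {record.n_blocks} blocks")
    sig = bundle.cfg.signal
    if not preprocessed:
        record = io_mod.preprocess(record, sig.band_low_hz, sig.band_high_hz,
                                   sig.filter_order)
    n_blocks = record.n_blocks
    blocks = record.samples[:n_blocks * sig.block_len].reshape(
        n_blocks, sig.block_len, record.n_channels)
    feats = feat_mod.extract_features_batch(
        blocks, bundle.bank, domain=bundle.cfg.features.auc_domain,
        kind=bundle.cfg.features.coeff_kind)

    if training and not bundle.calibrated:
        snn_mod.calibrate_gain(bundle.cube, feats[:min(50, n_blocks)])
        bundle.calibrated = True
    if not bundle.calibrated:
        raise RuntimeError("bundle must be trained (gain-calibrated) "
                           "before testing")

    old_stdp = bundle.cube.params.stdp_on
    if stdp is not None:
        bundle.cube.params.stdp_on = stdp
    # session boundary: reservoirs restart from rest
    bundle.mcd.x = np.zeros_like(bundle.mcd.x)
    bundle.nrd.x = np.zeros_like(bundle.nrd.x)

    window_ms = 1000.0 * sig.block_duration_s
    results = []
    try:
        for k in range(n_blocks):
            rates = snn_mod.present_block(bundle.cube,
                                          feats[k].astype(float),
                                          window_ms)
            if training:
                res = train_block(bundle, rates, labels.action_desired[k],
                                  int(labels.satis[k]), mode,
                                  block_index=k)
            else:
                act = labels.action_desired[k] if labels is not None else None
                sat = int(labels.satis[k]) if labels is not None else None
                res = test_block(bundle, rates, act, mode,
                                 feedback_on=feedback_on, satis_label=sat,
                                 block_index=k)
            results.append(res)
    finally:
        bundle.cube.params.stdp_on = old_stdp
    return results


# ---------------------------------------------------------------------------
# persistence

def save_bundle(bundle: ModelBundle, out_dir: str | Path) -> None:
    """Serialise a model bundle to a directory.

    The SNN weight matrix goes to CSV for inspection; the full cube and
    reservoir states go to NPZ; the manifest records mode provenance.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    snn_mod.snapshot_weights(bundle.cube, out / "snn_weights.csv")
    c = bundle.cube
    np.savez(out / "cube_state.npz", coords=c.coords, sign=c.sign,
             mag=c.mag, v=c.v, i_syn=c.i_syn, last_spike=c.last_spike,
             refr_until=c.refr_until, t_now=c.t_now, gain=c.gain)
    esn_mod.save_esn(bundle.mcd, out / "esn_mcd.npz")
    esn_mod.save_esn(bundle.nrd, out / "esn_nrd.npz")
    import dataclasses
    manifest = {
        "config": dataclasses.asdict(bundle.cfg),
        "calibrated": bundle.calibrated,
        "provenance": bundle.provenance,
    }
    with open(out / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)


def load_bundle(in_dir: str | Path) -> ModelBundle:
    from .config import load_config, _update
    inp = Path(in_dir)
    with open(inp / "manifest.yaml") as fh:
        manifest = yaml.safe_load(fh)
    cfg = load_config()
    _update(cfg, manifest["config"])
    d = np.load(inp / "cube_state.npz")
    cube = snn_mod.CubeState(
        coords=d["coords"], sign=d["sign"], mag=d["mag"], v=d["v"],
        i_syn=d["i_syn"], last_spike=d["last_spike"],
        refr_until=d["refr_until"], t_now=float(d["t_now"]),
        gain=float(d["gain"]), params=cfg.snn)
    mcd = esn_mod.load_esn(inp / "esn_mcd.npz")
    nrd = esn_mod.load_esn(inp / "esn_nrd.npz")
    bank = feat_mod.WaveletBank.from_config(cfg.features,
                                            cfg.signal.sample_rate,
                                            cfg.signal.block_len)
    return ModelBundle(cube=cube, mcd=mcd, nrd=nrd, bank=bank,
                       cfg=cfg, calibrated=bool(manifest["calibrated"]),
                       provenance=manifest.get("provenance", {}))
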