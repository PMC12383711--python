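"""3D spiking-neuron cube: 64 LIF neurons at electrode positions.

One leaky integrate-and-fire neuron sits at each ECoG electrode coordinate.
All ordered pairs are connected by signed synapses whose initial magnitude
depends on the 3D distance between the electrodes; each presynaptic neuron
is excitatory or inhibitory as a whole (Dale's principle).  Synapse
magnitudes adapt continuously through nearest-neighbour pair-based STDP
while the sign is fixed at initialisation.

A feature block drives the cube for one ~100 ms window: feature row i of
channel e is the injected current of neuron e during sub-interval i
(zero-order hold).  The per-neuron spike counts over the window, divided by
its duration, are the firing-rate vector passed on to the decoders.

The hot loop is compiled with numba; :func:`lif_step` and
:func:`stdp_update` expose the same dynamics step-by-step for testing and
inspection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from numba import njit

from .config import SnnConfig

__all__ = ["CubeState", "default_electrode_grid", "build_cube", "lif_step",
           "stdp_update", "present_block", "snapshot_weights",
           "lif_rate_closed_form", "current_for_rate", "calibrate_gain"]


def default_electrode_grid() -> np.ndarray:
    """Two planar 4x8 electrode grids (4 mm pitch) separated by 20 mm in x.

    Stand-in geometry for a bilateral pair of epidural implants; real
    implant coordinates can be loaded from CSV instead.
    """
    coords = []
    for grid in range(2):
        x0 = grid * (3 * 4.0 + 20.0)
        for col in range(4):
            for row in range(8):
                coords.append((x0 + col * 4.0, row * 4.0, 0.0))
    return np.asarray(coords, dtype=float)


def load_coords_csv(path: str | Path) -> np.ndarray:
    import pandas as pd
    df = pd.read_csv(path)
    return df[["x_mm", "y_mm", "z_mm"]].to_numpy(dtype=float)


@dataclass
class CubeState:
    """Full mutable state of the spiking cube."""

    coords: np.ndarray            # (n, 3) mm
    sign: np.ndarray              # (n, n) int8, fixed at build time
    mag: np.ndarray               # (n, n) float, in [0, w_max], diag 0
    v: np.ndarray                 # (n,) membrane potentials, mV
    i_syn: np.ndarray             # (n,) synaptic currents, nA
    last_spike: np.ndarray        # (n,) ms (-inf sentinel = never)
    refr_until: np.ndarray        # (n,) ms
    t_now: float                  # ms, advances across blocks
    gain: float                   # feature -> injected current (nA per unit)
    params: SnnConfig = field(default_factory=SnnConfig)

    @property
    def n(self) -> int:
        return len(self.coords)

    @property
    def weights(self) -> np.ndarray:
        """Signed synaptic matrix (row = presynaptic neuron)."""
        return self.sign * self.mag

    def copy(self) -> "CubeState":
        return CubeState(self.coords.copy(), self.sign.copy(), self.mag.copy(),
                         self.v.copy(), self.i_syn.copy(),
                         self.last_spike.copy(), self.refr_until.copy(),
                         self.t_now, self.gain, self.params)


def build_cube(coords: np.ndarray | None = None, seed: int = 0,
               params: SnnConfig | None = None) -> CubeState:
    """Initialise the cube with distance-dependent random synapses.

    Magnitudes are w0 * kernel(d_ij) * U(0.5, 1.5); the kernel either decays
    exponentially with distance (sigma = half the median pairwise distance)
    or grows linearly with it, selected by ``params.distance_kernel``.
    """
    params = params or SnnConfig()
    if coords is None:
        coords = default_electrode_grid()
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 3:
        raise ValueError(f"coords must be (n, 3), got {coords.shape}")
    rng = np.random.default_rng(seed)
    n = len(coords)
    # duplicate positions would make the distance kernel degenerate
    d = np.linalg.norm(coords[:, None] - coords[None, :], axis=-1)
    dup = (d + np.eye(n)) == 0
    if dup.any():
        warnings.warn("duplicate electrode coordinates; applying 1e-3 mm "
                      "jitter", stacklevel=2)
        coords = coords + rng.normal(0.0, 1e-3, coords.shape)
        d = np.linalg.norm(coords[:, None] - coords[None, :], axis=-1)
    off = d[~np.eye(n, dtype=bool)]
    if params.distance_kernel == "exp_decay":
        sigma = 0.5 * np.median(off)
        kern = np.exp(-d / sigma)
    elif params.distance_kernel == "linear_proportional":
        kern = d / off.max()
    else:
        raise ValueError(f"unknown distance_kernel "
                         f"{params.distance_kernel!r}")
    mag = params.w0 * kern * rng.uniform(0.5, 1.5, size=(n, n))
    mag = np.clip(mag, 0.0, params.w_max)
    np.fill_diagonal(mag, 0.0)
    exc = rng.random(n) < params.p_exc
    sign = np.repeat(np.where(exc, 1, -1)[:, None], n, axis=1).astype(np.int8)
    np.fill_diagonal(sign, 0)
    return CubeState(
        coords=coords, sign=sign, mag=mag,
        v=np.full(n, params.v_rest_mv),
        i_syn=np.zeros(n),
        last_spike=np.full(n, -np.inf),
        refr_until=np.full(n, -np.inf),
        t_now=0.0, gain=1.0, params=params)


# ---------------------------------------------------------------------------
# reference (numpy) dynamics, one step / one spike list at a time

def lif_step(state: CubeState, input_currents: np.ndarray, dt: float
             ) -> np.ndarray:
    """Advance all membranes one Euler step; returns the spike mask.

    tau_m dV/dt = -(V - V_rest) + R * I.  Neurons at threshold are reset and
    enter an absolute refractory period.  ``input_currents`` is the total
    current (injected + synaptic), in nA.
    """
    p = state.params
    currents = np.asarray(input_currents, dtype=float)
    if not np.all(np.isfinite(currents)):
        raise ValueError("non-finite input currents")
    active = state.t_now >= state.refr_until
    dv = (-(state.v - p.v_rest_mv) + p.r_m_mohm * currents) * (dt / p.tau_m_ms)
    state.v = np.where(active, state.v + dv, p.v_reset_mv)
    state.t_now += dt
    spikes = state.v >= p.v_th_mv
    if spikes.any():
        state.v[spikes] = p.v_reset_mv
        state.refr_until[spikes] = state.t_now + p.t_ref_ms
    if not np.all(np.isfinite(state.v)):
        bad = int(np.flatnonzero(~np.isfinite(state.v))[0])
        raise FloatingPointError(f"non-finite membrane potential at neuron "
                                 f"{bad}")
    return spikes


def stdp_update(state: CubeState, spike_events) -> CubeState:
    """Apply nearest-neighbour pair-based STDP for an ordered spike list.

    ``spike_events`` is an iterable of (time_ms, neuron) in non-decreasing
    time order.  For each spike of neuron n at time t: every incoming
    synapse i->n is potentiated by A_plus * exp(-(t - t_i)/tau_plus) using
    i's most recent spike, and every outgoing synapse n->m is depressed by
    A_minus * exp(-(t - t_m)/tau_minus) using m's most recent spike.
    Simultaneous spikes (dt == 0) are skipped.  Magnitudes are clipped to
    [0, w_max]; signs never change.
    """
    p = state.params
    for t, n in spike_events:
        dt_pre = t - state.last_spike
        pot = np.where(np.isfinite(dt_pre) & (dt_pre > 0),
                       p.a_plus * np.exp(-dt_pre / p.tau_plus_ms), 0.0)
        pot[n] = 0.0
        connected = state.sign[:, n] != 0
        state.mag[:, n] = np.minimum(
            state.mag[:, n] + pot * connected, p.w_max)
        dt_post = t - state.last_spike
        dep = np.where(np.isfinite(dt_post) & (dt_post > 0),
                       p.a_minus * np.exp(-dt_post / p.tau_minus_ms), 0.0)
        dep[n] = 0.0
        state.mag[n, :] = np.maximum(state.mag[n, :] - dep, 0.0)
        state.last_spike[n] = t
    return state


# ---------------------------------------------------------------------------
# fused numba kernel for streaming

@njit(cache=True)
def _simulate_window(currents, sign, mag, v, i_syn, last_spike, refr_until,
                     t0, dt, n_steps, tau_m, v_rest, v_th, v_reset, t_ref,
                     r_m, tau_syn, syn_gain, w_max, a_plus, a_minus,
                     tau_plus, tau_minus, stdp_on):
    """One stimulation window; mutates the state arrays in place."""
    n_rows, n = currents.shape
    counts = np.zeros(n, dtype=np.int64)
    syn_decay = np.exp(-dt / tau_syn)
    window = n_steps * dt
    for step in range(n_steps):
        t = t0 + (step + 1) * dt
        row = int((step * dt) * n_rows / window)
        if row > n_rows - 1:
            row = n_rows - 1
        for j in range(n):
            i_syn[j] *= syn_decay
        for j in range(n):
            if t0 + step * dt < refr_until[j]:
                v[j] = v_reset
            else:
                total = currents[row, j] + i_syn[j]
                v[j] += (-(v[j] - v_rest) + r_m * total) * (dt / tau_m)
        for j in range(n):
            if v[j] >= v_th and t0 + step * dt >= refr_until[j]:
                v[j] = v_reset
                refr_until[j] = t + t_ref
                counts[j] += 1
                # synaptic transmission
                for m in range(n):
                    i_syn[m] += syn_gain * sign[j, m] * mag[j, m]
                if stdp_on:
                    for i in range(n):
                        if i == j or sign[i, j] == 0:
                            continue
                        dpre = t - last_spike[i]
                        if np.isfinite(dpre) and dpre > 0:
                            w = mag[i, j] + a_plus * np.exp(-dpre / tau_plus)
                            mag[i, j] = w if w < w_max else w_max
                    for m in range(n):
                        if m == j or sign[j, m] == 0:
                            continue
                        dpost = t - last_spike[m]
                        if np.isfinite(dpost) and dpost > 0:
                            w = mag[j, m] - a_minus * np.exp(
                                -dpost / tau_minus)
                            mag[j, m] = w if w > 0.0 else 0.0
                last_spike[j] = t
    return counts


def present_block(state: CubeState, feature_block: np.ndarray,
                  window_ms: float | None = None) -> np.ndarray:
    """Drive the cube with one feature block; returns firing rates (Hz).

    Feature row i of channel e sets neuron e's injected current to
    ``gain * feature`` during sub-interval i of the window (zero-order
    hold).  Membrane potentials, synaptic currents and plastic weights
    persist to the next block.
    """
    p = state.params
    feats = np.asarray(feature_block, dtype=float)
    if feats.ndim != 2 or feats.shape[1] != state.n:
        raise ValueError(f"feature block must be [n_rows x {state.n}], "
                         f"got {feats.shape}")
    if not np.all(np.isfinite(feats)):
        raise ValueError("non-finite features")
    if window_ms is None:
        window_ms = 100.0
    n_steps = max(1, int(round(window_ms / p.dt_ms)))
    currents = np.ascontiguousarray(state.gain * feats)
    counts = _simulate_window(
        currents, state.sign, state.mag, state.v, state.i_syn,
        state.last_spike, state.refr_until, state.t_now, p.dt_ms, n_steps,
        p.tau_m_ms, p.v_rest_mv, p.v_th_mv, p.v_reset_mv, p.t_ref_ms,
        p.r_m_mohm, p.tau_syn_ms, p.syn_gain_na, p.w_max, p.a_plus,
        p.a_minus, p.tau_plus_ms, p.tau_minus_ms, p.stdp_on)
    state.t_now += n_steps * p.dt_ms
    if not np.all(np.isfinite(state.v)):
        bad = int(np.flatnonzero(~np.isfinite(state.v))[0])
        raise FloatingPointError(f"non-finite membrane potential at neuron "
                                 f"{bad}")
    return counts / (n_steps * p.dt_ms / 1000.0)


def snapshot_weights(state: CubeState, path: str | Path) -> None:
    """Write the signed weight matrix as CSV (one row per presynaptic
    neuron), for connectivity diagnostics."""
    np.savetxt(path, state.weights, delimiter=",")


# ---------------------------------------------------------------------------
# rate calibration

def lif_rate_closed_form(current_na: float, params: SnnConfig) -> float:
    """Steady firing rate of an isolated LIF neuron under constant current.

    f = 1 / (t_ref + tau_m * ln(RI / (RI - (V_th - V_rest)))), 0 below
    rheobase.
    """
    ri = params.r_m_mohm * current_na
    dv = params.v_th_mv - params.v_rest_mv
    if ri <= dv:
        return 0.0
    t_isi = params.t_ref_ms + params.tau_m_ms * np.log(ri / (ri - dv))
    return 1000.0 / t_isi


def current_for_rate(rate_hz: float, params: SnnConfig) -> float:
    """Inverse of :func:`lif_rate_closed_form` (constant-current LIF)."""
    if rate_hz <= 0:
        raise ValueError("rate must be positive")
    t_int = 1000.0 / rate_hz - params.t_ref_ms
    if t_int <= 0:
        raise ValueError("rate exceeds the refractory limit")
    dv = params.v_th_mv - params.v_rest_mv
    ri = dv / (1.0 - np.exp(-t_int / params.tau_m_ms))
    return ri / params.r_m_mohm


def calibrate_gain(state: CubeState, feature_blocks: np.ndarray,
                   target_hz: float | None = None) -> float:
    """Set the feature->current gain so the median feature of a calibration
    pass drives an isolated neuron at ``target_hz`` (closed-form inverse).
    """
    p = state.params
    target = p.target_rate_hz if target_hz is None else target_hz
    med = float(np.median(np.asarray(feature_blocks)))
    if med <= 0:
        raise ValueError("median calibration feature is not positive")
    state.gain = current_for_rate(target, p) / med
    return state.gain
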