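"""Echo state network with a recursive-least-squares readout.

The reservoir is a sparse random tanh network scaled to a fixed spectral
radius and updated with a leaky integrator; only the linear readout (plus
bias) is trained, one sample at a time, by exponentially weighted RLS.  Two
instances of this module form the decoding stage: the motor-control decoder
(actor) reads the cube's firing rates, the neural-response decoder (critic)
reads the rates plus an action input.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.sparse.linalg import eigs as sparse_eigs

__all__ = ["EsnState", "init_esn", "esn_update", "readout", "rls_step",
           "save_esn", "load_esn"]


@dataclass
class EsnState:
    x: np.ndarray        # (N,) reservoir state
    w_in: np.ndarray     # (N, n_in)
    w: np.ndarray        # (N, N) recurrent weights, spectral radius rho
    w_out: np.ndarray    # (N+1,) readout incl. bias
    p: np.ndarray        # (N+1, N+1) RLS inverse-correlation matrix
    leak: float
    lam: float           # forgetting factor
    _w_csr: object = None     # cached sparse view of w (not serialised)
    _steps: int = 0           # RLS steps since last symmetry check

    @property
    def n_reservoir(self) -> int:
        return len(self.x)

    @property
    def n_in(self) -> int:
        return self.w_in.shape[1]

    def copy(self) -> "EsnState":
        return EsnState(self.x.copy(), self.w_in.copy(), self.w.copy(),
                        self.w_out.copy(), self.p.copy(), self.leak, self.lam)


def _spectral_radius(w: np.ndarray) -> float:
    if w.shape[0] <= 2:
        return float(np.abs(np.linalg.eigvals(w)).max())
    # fixed start vector keeps the Arnoldi iteration deterministic
    v0 = np.ones(w.shape[0])
    val = sparse_eigs(w, k=1, which="LM", return_eigenvectors=False,
                      maxiter=10000, v0=v0)
    return float(np.abs(val[0]))


def init_esn(n_reservoir: int, n_in: int, rho: float = 0.9,
             leak: float = 0.3, density: float = 0.1,
             input_scale: float = 0.5, seed: int = 0,
             lam: float = 1.0, delta: float = 1e-2) -> EsnState:
    """Random reservoir scaled to spectral radius ``rho``; zero readout.

    P is initialised to I/delta, the standard RLS prior equivalent to ridge
    regularisation with strength delta.
    """
    if n_reservoir < 1:
        raise ValueError("n_reservoir must be >= 1")
    if rho <= 0:
        raise ValueError("spectral radius must be positive")
    if not 0 < leak <= 1:
        raise ValueError("leak must be in (0, 1]")
    rng = np.random.default_rng(seed)
    w = rng.uniform(-1.0, 1.0, size=(n_reservoir, n_reservoir))
    mask = rng.random((n_reservoir, n_reservoir)) < density
    w = np.where(mask, w, 0.0)
    if not mask.any():  # degenerate density: keep one connection
        w[0, 0] = rng.uniform(-1.0, 1.0)
    radius = _spectral_radius(w)
    if radius == 0.0:
        raise ValueError("reservoir has zero spectral radius; "
                         "increase density")
    w *= rho / radius
    w_in = rng.uniform(-input_scale, input_scale, size=(n_reservoir, n_in))
    return EsnState(
        x=np.zeros(n_reservoir), w_in=w_in, w=w,
        w_out=np.zeros(n_reservoir + 1),
        p=np.eye(n_reservoir + 1) / delta,
        leak=leak, lam=lam)


def esn_update(state: EsnState, u: np.ndarray) -> EsnState:
    """Leaky tanh state update: x <- (1-a) x + a tanh(W_in u + W x)."""
    u = np.asarray(u, dtype=float)
    if u.shape != (state.n_in,):
        raise ValueError(f"input must have length {state.n_in}, "
                         f"got shape {u.shape}")
    if not np.all(np.isfinite(u)):
        raise ValueError("non-finite reservoir input")
    if state._w_csr is None:
        from scipy import sparse
        state._w_csr = sparse.csr_matrix(state.w)
    pre = state.w_in @ u + state._w_csr @ state.x
    state.x = (1.0 - state.leak) * state.x + state.leak * np.tanh(pre)
    return state


def readout(state: EsnState) -> float:
    """Linear readout y = W_out . [x; 1]."""
    return float(state.w_out[:-1] @ state.x + state.w_out[-1])


def rls_step(state: EsnState, target: float) -> tuple:
    """One exponentially weighted RLS update of the readout.

    Returns the a-priori error target - y (the training error driving the
    update).  P is kept symmetric; round-off asymmetry is checked and
    repaired on a fixed cadence (every 64 updates) to keep the per-step
    cost down.
    """
    z = np.concatenate([state.x, [1.0]])
    pz = state.p @ z
    denom = state.lam + z @ pz
    gain = pz / denom
    e_prior = float(target) - float(state.w_out @ z)
    state.w_out = state.w_out + gain * e_prior
    state.p -= np.outer(gain, pz)
    if state.lam != 1.0:
        state.p *= 1.0 / state.lam
    state._steps += 1
    if state._steps % 64 == 0:
        asym = np.abs(state.p - state.p.T).max()
        if asym > 1e-8 * max(1.0, np.abs(state.p).max()):
            state.p = 0.5 * (state.p + state.p.T)
    return state, e_prior


def save_esn(state: EsnState, path: str | Path) -> None:
    np.savez(path, x=state.x, w_in=state.w_in, w=state.w, w_out=state.w_out,
             p=state.p, leak=state.leak, lam=state.lam)


def load_esn(path: str | Path) -> EsnState:
    d = np.load(path)
    return EsnState(x=d["x"], w_in=d["w_in"], w=d["w"], w_out=d["w_out"],
                    p=d["p"], leak=float(d["leak"]), lam=float(d["lam"]))
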