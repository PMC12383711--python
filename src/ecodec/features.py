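"""Morlet wavelet / area-under-curve feature extraction.

Each streamed 59x64 ECoG block is decomposed channel-wise with a bank of
complex Morlet wavelets (15 central frequencies, 10..150 Hz by default).
For every sample ``i`` and electrode ``e`` the 15 coefficient magnitudes
form a curve over frequency whose area under the curve (trapezoidal
integral over Hz) is the scalar feature.  The result is a feature matrix of
the same 59x64 shape as the block, suitable for driving the spiking cube.

Blocks are transformed in isolation (reflection padding supplies the edge
context) so the operation is valid in pseudo-online streaming, where future
samples are not available.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import fft as sfft

from .config import FeatureConfig

__all__ = ["WaveletBank", "morlet_transform", "auc_combine", "extract_features",
           "extract_features_batch"]


def morlet_kernel(freq_hz: float, cycles: float, sample_rate: float,
                  n_sigmas: float = 3.0) -> np.ndarray:
    """Complex Morlet kernel, L1-normalised so that a unit-amplitude tone at
    the central frequency yields a coefficient magnitude of ~1.

    The Gaussian envelope has sigma_t = cycles / (2 pi f); the kernel is
    truncated at ``n_sigmas`` envelope standard deviations.
    """
    sigma_t = cycles / (2.0 * np.pi * freq_hz)
    half = int(np.ceil(n_sigmas * sigma_t * sample_rate))
    t = np.arange(-half, half + 1) / sample_rate
    envelope = np.exp(-0.5 * (t / sigma_t) ** 2)
    kernel = envelope * np.exp(2j * np.pi * freq_hz * t)
    # factor 2 recovers the amplitude of a real tone from its analytic half
    return 2.0 * kernel / envelope.sum()


@dataclass
class WaveletBank:
    """Bank of complex Morlet kernels sharing one sampling rate.

    Kernels and the stacked correlation matrix used by the batched
    transform are built lazily and cached.
    """

    central_freqs: np.ndarray
    cycles: float
    sample_rate: float
    n_sigmas: float = 3.0
    block_len: int = 59

    _kernels: list = field(default=None, repr=False, compare=False)
    _stacks32: list = field(default=None, repr=False, compare=False)
    _stacks64: list = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        freqs = np.asarray(self.central_freqs, dtype=float)
        if freqs.ndim != 1 or len(freqs) == 0:
            raise ValueError("central_freqs must be a non-empty 1-D sequence")
        if np.any(np.diff(freqs) <= 0):
            raise ValueError("central_freqs must be strictly increasing")
        if freqs[-1] >= self.sample_rate / 2:
            raise ValueError(
                f"central frequency {freqs[-1]:g} Hz is at or above the "
                f"Nyquist frequency {self.sample_rate / 2:g} Hz")
        if freqs[0] <= 0:
            raise ValueError("central frequencies must be positive")
        self.central_freqs = freqs

    @classmethod
    def from_config(cls, cfg: FeatureConfig, sample_rate: float,
                    block_len: int = 59) -> "WaveletBank":
        return cls(np.asarray(cfg.central_freqs, float), cfg.wavelet_cycles,
                   sample_rate, cfg.kernel_sigmas, block_len)

    def __len__(self) -> int:
        return len(self.central_freqs)

    @property
    def kernels(self) -> list:
        if self._kernels is None:
            self._kernels = [
                morlet_kernel(f, self.cycles, self.sample_rate, self.n_sigmas)
                for f in self.central_freqs]
        return self._kernels

    @property
    def pad(self) -> int:
        """Reflection padding: half the longest kernel."""
        return (len(self.kernels[0]) - 1) // 2

    def _stacks(self, dtype) -> list:
        """Per-frequency real matrices [2*block_len, block_len + 2*half_j]
        whose product with a slice of the padded block evaluates Re/Im of
        every correlation sample for that band.  Splitting by frequency
        keeps each matrix only as wide as its own kernel requires."""
        attr = "_stacks32" if dtype == np.float32 else "_stacks64"
        cached = getattr(self, attr)
        if cached is not None:
            return cached
        n_b = self.block_len
        stacks = []
        for kern in self.kernels:
            half = (len(kern) - 1) // 2
            width = n_b + 2 * half
            comp = np.zeros((2, n_b, width))
            for i in range(n_b):
                comp[0, i, i:i + len(kern)] = kern.real
                comp[1, i, i:i + len(kern)] = kern.imag
            stacks.append((half, comp.reshape(2 * n_b, width).astype(dtype)))
        setattr(self, attr, stacks)
        return stacks


def _check_block(block_data: np.ndarray, bank: WaveletBank) -> np.ndarray:
    block_data = np.asarray(block_data, dtype=float)
    if block_data.ndim != 2 or block_data.shape[0] != bank.block_len:
        raise ValueError(
            f"block must be [{bank.block_len} x n_channels], "
            f"got {block_data.shape}")
    if not np.all(np.isfinite(block_data)):
        raise ValueError("block contains non-finite samples")
    return block_data


def morlet_transform(block_data: np.ndarray, bank: WaveletBank) -> np.ndarray:
    """Coefficient magnitudes, shape [block_len x n_channels x n_freqs].

    Entry (i, e, j) is |correlation of channel e with kernel j| at sample i,
    with the block reflection-padded by half the longest kernel.
    """
    block_data = _check_block(block_data, bank)
    n_b = bank.block_len
    pad = bank.pad
    padded = np.pad(block_data, ((pad, pad), (0, 0)), mode="reflect")
    out = np.empty((n_b, block_data.shape[1], len(bank)))
    for j, kern in enumerate(bank.kernels):
        half = (len(kern) - 1) // 2
        # correlate each channel with the kernel; sample i of the block sits
        # at padded index pad + i, so row i uses padded[pad+i-half : ...+half]
        nfft = sfft.next_fast_len(padded.shape[0] + len(kern) - 1)
        spec = sfft.fft(padded, nfft, axis=0)
        kspec = sfft.fft(np.conj(kern[::-1]), nfft)
        conv = sfft.ifft(spec * kspec[:, None], axis=0)
        start = len(kern) - 1 + (pad - half)  # aligns tau window to sample 0
        out[:, :, j] = np.abs(conv[start:start + n_b])
    return out


def auc_combine(coeff: np.ndarray, bank: WaveletBank,
                domain: str = "hz", kind: str = "magnitude") -> np.ndarray:
    """Collapse the frequency axis by trapezoidal integration.

    ``domain`` selects the abscissa (central frequencies in Hz, or the bare
    band index); ``kind`` integrates magnitudes or their squares.
    """
    coeff = np.asarray(coeff)
    if coeff.ndim != 3 or coeff.shape[-1] != len(bank):
        raise ValueError(f"expected [.. x .. x {len(bank)}] tensor, "
                         f"got {coeff.shape}")
    if not np.all(np.isfinite(coeff)):
        raise ValueError("non-finite wavelet coefficients")
    if kind == "power":
        coeff = coeff ** 2
    elif kind != "magnitude":
        raise ValueError(f"unknown coeff_kind {kind!r}")
    if domain == "hz":
        x = bank.central_freqs
    elif domain == "index":
        x = np.arange(len(bank), dtype=float)
    else:
        raise ValueError(f"unknown auc_domain {domain!r}")
    return np.trapezoid(coeff, x=x, axis=-1)


def extract_features(block_data: np.ndarray, bank: WaveletBank,
                     domain: str = "hz", kind: str = "magnitude") -> np.ndarray:
    """Feature matrix [block_len x n_channels]: AUC over the Morlet bank."""
    return auc_combine(morlet_transform(block_data, bank), bank, domain, kind)


def extract_features_batch(blocks: np.ndarray, bank: WaveletBank,
                           domain: str = "hz", kind: str = "magnitude",
                           dtype=np.float32, chunk: int = 128) -> np.ndarray:
    """Feature matrices for many blocks at once, shape [B x 59 x 64].

    Equivalent to :func:`extract_features` per block but evaluated through a
    single stacked matrix product per chunk, in reduced precision by
    default; used by the streaming pipeline for throughput.
    """
    blocks = np.asarray(blocks, dtype=dtype)
    if blocks.ndim != 3 or blocks.shape[1] != bank.block_len:
        raise ValueError(f"expected [B x {bank.block_len} x n_ch] array, "
                         f"got {blocks.shape}")
    n_blocks, n_b, n_ch = blocks.shape
    n_f = len(bank)
    stacks = bank._stacks(dtype)
    pad = bank.pad
    if domain == "hz":
        x = bank.central_freqs
    elif domain == "index":
        x = np.arange(n_f, dtype=float)
    else:
        raise ValueError(f"unknown auc_domain {domain!r}")
    if kind not in ("magnitude", "power"):
        raise ValueError(f"unknown coeff_kind {kind!r}")
    out = np.empty((n_blocks, n_b, n_ch), dtype=dtype)
    for lo in range(0, n_blocks, chunk):
        part = blocks[lo:lo + chunk]                     # (b, 59, ch)
        padded = np.pad(part, ((0, 0), (pad, pad), (0, 0)), mode="reflect")
        flat = np.ascontiguousarray(
            padded.transpose(1, 0, 2).reshape(padded.shape[1], -1))
        mag = np.empty((n_f, n_b, flat.shape[1]), dtype=dtype)
        for j, (half, stack) in enumerate(stacks):
            sl = flat[pad - half:pad + n_b + half]
            prod = stack @ sl                            # (2*59, b*ch)
            prod = prod.reshape(2, n_b, -1)
            np.sqrt(prod[0] ** 2 + prod[1] ** 2, out=mag[j])
        if kind == "power":
            mag *= mag
        feats = np.trapezoid(mag, x=x, axis=0)           # (59, b*ch)
        out[lo:lo + chunk] = feats.reshape(n_b, part.shape[0], n_ch
                                           ).transpose(1, 0, 2)
    return out
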